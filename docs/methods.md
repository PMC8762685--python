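# Methods

This note records the model, the defaults and the judgment calls behind
`shapevolve`, in the order the pipeline runs.

## Radial-frequency shapes

A genome holds, for each radial frequency f = 1..10, an amplitude
A_f ≥ 0 (internal units), a phase φ_f ∈ (0, 360] degrees and a binary gate
g_f. Synthesis samples

    r(θ_i) = R + s · Σ_f g_f A_f sin(f θ_i + φ_f π/180),   θ_i = 2πi/N

at N = 360 angles, base radius R = 30 px. The sinusoid basis is sine;
sine vs cosine is equivalent up to a 90° phase shift, so this is
documented rather than configurable. The amplitude scale is s = R/100:
amplitudes keep their 50–150 bookkeeping units while 100 units modulate by
one full radius. Phases are stored in degrees and converted to radians
only inside synthesis. A negative modulated radius is allowed — the point
reflects through the origin, producing the internal loops characteristic
of large-amplitude shapes; those loops are a deliberate part of the shape
space, not an error.

Initialization: A_f ~ Uniform(50, 150)/f (an approximate 1/f natural-image
spectrum; so f = 2 spans 25–75, f = 3 spans 16.7–50), φ_f ~ Uniform(1, 360),
g_f ~ Bernoulli(0.5). The gate probability at generation 1 is a choice —
0.5 maximizes initial diversity — and is configurable.

## Rasterization and geometry

Masks are 128×128 at 1 px/cell, the contour centered on its vertex
centroid; an oversized contour is shrunk (never enlarged) with a logged
factor. Filling uses the nonzero winding rule, so self-intersecting
contours render their loops as filled lobes rather than holes — an
interpretation chosen because the skeleton and area analyses need a single
filled region that matches the visual appearance of outline stimuli.

Perimeter is the closed polygon arc length; area is the shoelace formula
for simple contours. For self-intersecting contours the shoelace value is
ill-defined (loop interiors can count twice or cancel), so area falls back
to the foreground count of the filled mask; whether loop interiors should
count once or twice is genuinely open, and the mask count (= once) is the
documented choice. The curvature index P²/A is 4π for a circle and scale-
and rotation-invariant by construction.

## Similarity metrics

* **Skeleton.** Masks are thinned by iterated morphological thinning run
  to convergence (`skimage.morphology.thin`, the same primitive as
  MATLAB's `bwmorph(…, 'thin', Inf)`). The distance is the mean, over
  distractor skeleton points, of the nearest-neighbor Euclidean distance
  to the target skeleton, minimized over alignments. "Maximal alignment"
  is implemented as centroid translation plus an exhaustive rotation
  search in 1° steps (reflection off by default, available by flag):
  deterministic and oracle-checkable. The measure is directed
  (distractor → target); a symmetric variant is provided but not default.
  No scale normalization is applied by default because all stimuli share
  the 30-px base radius; a `normalize_scale` flag exists for size-jittered
  analyses.
* **Curvature.** |P²/A(a) − P²/A(b)|.
* **Spectrum.** The radius-from-centroid sequence of the (360-point)
  contour is Fourier-transformed; amplitudes at frequencies 1..K are
  scaled by 2/N so a pure genome-synthesized shape recovers s·A_f at its
  active frequencies; the DC term is excluded. Distance is the L2 norm
  after zero-padding the shorter spectrum. Amplitudes only — phases are
  deliberately discarded, which is what makes the spectra
  rotation-invariant. Radius-from-centroid is well defined for any closed
  contour traversed by arc length, including mildly non-star-shaped
  silhouettes; strongly self-occluding silhouettes would alias, a known
  limitation.

## The genetic algorithm

Pool 12, parents 3, offspring 9, eight generations. Easy selection: the
three lowest mean RTs. Hard selection: the three highest scores
slope − w·meanRT with w = 0.15 by default. Offspring parents are drawn
uniformly at random without self-pairing (the simplest faithful reading
of "randomly selecting two parent genomes" that preserves recombination).
Crossover is element-wise 50/50 over the 30 elements in the fixed order
amplitudes, phases, gates. Mutation hits each element independently with
probability 0.02: gates flip, amplitudes ×2 or ÷2 with equal probability
(the direction probabilities being another undocumented point), phases
redraw from Uniform(1, 360). Mutation applies to offspring only, not the
carried-over parents (configurable). One seeded stream drives each
generation in the order pairing → crossover → mutation, so runs replay
exactly.

Constraint masks (`clamp_on` at a prescribed amplitude with free phase,
`force_off` at zero amplitude) are applied at initialization and after
every variation step; pinned amplitudes and gates are also excluded from
mutation, so the mask is invariant under the whole loop — tested, not
assumed.

**The hard-score sign.** The printed hard score slope − 0.15·meanRT is
implemented verbatim as the default of `hard_fitness` (and that is the
value the acceptance script reports). But in simulation its −0.15·meanRT
term dominates the slope term by an order of magnitude, so *maximizing* it
selects the fastest — easiest — distractors: hard-direction runs under the
verbatim weight drift easier (measured: mean RT ~755 → ~690 ms over eight
generations at defaults). Because the score's stated purpose is to promote
difficult search, end-to-end simulation runs default to the sign-flipped
weight −0.15 (score = slope + 0.15·meanRT), exposed as
`RT_PROMOTING_HARD_WEIGHT` and switchable via `evolve_run(...,
rt_promoting_hard=False)`. Both behaviors are kept on the surface; the
intent behind the printed sign is not guessed.

## The simulated observer

Entirely invented plumbing — a stand-in for measured human RTs, not a
model fitted to any human data. A metric distance d is normalized to
s = 1/(1 + d/scale) with per-metric scales (spectrum 15 px, skeleton 4 px,
curvature 15), chosen so that generation-1 random distractors land mid-range
(measured spread of s against the example targets ≈ 0.35–0.75). A Hill
function q = s^k/(s^k + h^k) with h = 0.5, k = 4 gives the probability a
distractor survives preattentive filtering and is inspected. Expected
items inspected: present trials 1 + (n−1)·q/2 (the target is found midway
through the inspected subset on average); absent trials n·q·1.5 + 1
(exhaustive rechecking). RT = 500 + 50·inspected + noise, noise Gaussian
SD 60 ms truncated at −t0/2 so RT stays positive. All values live in
`ObserverParams` (one YAML/JSON file); a recorded trial CSV can replace
the simulation verbatim.

What the generator does *not* emulate: practice effects, fatigue, error
rates (accuracy is constant-correct), eye movements, crowding, and any
dependence of RT on display geometry beyond set size. Passing the
end-to-end tests therefore shows the *mechanism* (selection on RT moves
pools along the similarity axis the observer is sensitive to), not that
human search would quantitatively match.

## Search displays and analysis

Evolution paradigm: target always present, homogeneous distractors,
set-size blocks run sequentially (12 trials at 16, then 12 at 24) with
distractor order a seeded permutation within each block. Items sit on a
circle of radius 5× the item base radius with a random global rotation —
the array geometry is unstated in the source procedure; this default
guarantees no overlap at set size 24.

Present/absent paradigm: 300 trials, set sizes 8/12/16 balanced exactly,
target present on exactly half of each set-size cell (counterbalanced, not
Bernoulli, so the marginals are testable as exact), orientations jittered
within ±25°, sizes by ±10% (the jitter magnitude for size is unstated; ±10%
is a documented guess). RTs strictly above 10,000 ms are excluded before
analysis — the boundary value is kept — and slopes come from an OLS line
through the per-set-size mean RTs, per presence condition.

## Problem sizes and numerical choices

Acceptance-scale runs use 10⁶ mutation element draws, 10⁵ crossover
offspring, 10⁵ genome initializations, 10³ isoperimetric checks, 10⁴
display compositions and 20 seeded 8-generation run pairs; the whole
suite completes in well under a minute per criterion on one CPU. Skeleton
alignment tolerance against the brute-force oracle is 10⁻⁹; geometric
identities use relative tolerances of 10⁻³ (raster-free) or 2%
(rasterized). Example target genomes (HF/LF/BB/TP analogues) are labeled
approximations — the originals were published only as figures — and the
rabbit silhouette is a synthetic star-shaped body + head + ears radius
function; both are fixtures for exercising the machinery, not assets
recovered from the source material.
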