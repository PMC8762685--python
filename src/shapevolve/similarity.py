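"""Target-distractor shape similarity parameterizations.

Three complementary measures of how much a distractor resembles a target:

* ``skeleton_distance`` -- mean nearest-point Euclidean distance between
  the medial-axis skeletons of the two shapes after best rigid alignment
  (centroid translation plus an exhaustive rotation search).
* ``curvature_distance`` -- absolute difference of the total-curvature
  index P^2/A (dimensionless; 4*pi for a circle).
* ``spectrum_distance`` -- L2 norm between radial Fourier amplitude
  spectra, with the shorter spectrum zero-padded.

Skeletons come from iterated morphological thinning run to convergence.
The skeleton measure is directed (distractor -> target) by default; a
symmetric variant averages both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import thin

from .genome import AmplitudeSpectrum, RFGenome
from .synthesis import ShapeContour, ShapeMask, SynthConfig, isoperimetric_ratio, rasterize, synthesize_contour

__all__ = [
    "SkeletonPoints",
    "AlignmentConfig",
    "skeletonize",
    "skeleton_distance",
    "curvature_distance",
    "contour_spectrum",
    "spectrum_distance",
    "shape_distance",
    "METRICS",
]


class SimilarityError(ValueError):
    """Raised for empty skeletons or invalid metric inputs."""


@dataclass(frozen=True)
class SkeletonPoints:
    """Point set of a 1-px-wide thinned medial representation."""

    points: np.ndarray  # (n, 2) array of (x, y) raster coordinates
    source_mask_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise SimilarityError("skeleton must contain at least one point")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class AlignmentConfig:
    """Rigid-alignment search settings for the skeleton metric."""

    rotation_step: float = 1.0  # degrees
    allow_reflection: bool = False
    center: str = "centroid"
    normalize_scale: bool = False  # needed only when stimuli differ in size

    def __post_init__(self) -> None:
        if not 0 < self.rotation_step <= 90:
            raise SimilarityError("rotation_step must be in (0, 90] degrees")
        if self.center != "centroid":
            raise SimilarityError("only centroid centering is supported")


def skeletonize(m: ShapeMask) -> SkeletonPoints:
    """Medial skeleton by iterated morphological thinning to convergence.

    Thinning passes repeat until the raster no longer changes, leaving a
    1-px-wide subset of the original foreground.
    """
    if not m.grid.any():
        raise SimilarityError("cannot skeletonize an empty mask")
    thinned = thin(m.grid)  # iterates until convergence by default
    rr, cc = np.nonzero(thinned)
    return SkeletonPoints(points=np.column_stack([cc, rr]).astype(float), source_mask_shape=m.grid.shape)


def _rotations(step: float) -> np.ndarray:
    n = int(round(360.0 / step))
    return np.deg2rad(step * np.arange(n))


def skeleton_distance(
    distractor: SkeletonPoints,
    target: SkeletonPoints,
    cfg: AlignmentConfig = AlignmentConfig(),
) -> float:
    """Mean distractor-to-target nearest-point distance after best alignment.

    Both point sets are translated to a common centroid; the distractor set
    is rotated through the full circle in ``rotation_step`` increments (and
    reflected, if enabled); the reported value is the minimum over the
    search of the mean nearest-neighbor distance from distractor points to
    target points.  Directed: distances run distractor -> target.
    """
    if len(distractor) == 0 or len(target) == 0:
        raise SimilarityError("skeleton_distance requires non-empty skeletons")
    d = distractor.points - distractor.centroid
    t = target.points - target.centroid
    if cfg.normalize_scale:
        ds = np.sqrt((d**2).sum(axis=1).mean())
        ts = np.sqrt((t**2).sum(axis=1).mean())
        if ds > 0 and ts > 0:
            d = d / ds * ts
    tree = cKDTree(t)
    candidates = [d]
    if cfg.allow_reflection:
        candidates.append(d * [-1.0, 1.0])
    best = np.inf
    for base in candidates:
        for ang in _rotations(cfg.rotation_step):
            ca, sa = np.cos(ang), np.sin(ang)
            rotated = base @ np.array([[ca, sa], [-sa, ca]])
            mean_nn = tree.query(rotated)[0].mean()
            if mean_nn < best:
                best = float(mean_nn)
    return best


def symmetric_skeleton_distance(
    a: SkeletonPoints, b: SkeletonPoints, cfg: AlignmentConfig = AlignmentConfig()
) -> float:
    """Mean of the two directed skeleton distances."""
    return 0.5 * (skeleton_distance(a, b, cfg) + skeleton_distance(b, a, cfg))


def curvature_distance(
    a: ShapeContour, b: ShapeContour, cfg: SynthConfig = SynthConfig()
) -> float:
    """Absolute difference of the shapes' total-curvature indices P^2/A."""
    return abs(isoperimetric_ratio(a, cfg) - isoperimetric_ratio(b, cfg))


def contour_spectrum(c: ShapeContour, K: int = 359) -> AmplitudeSpectrum:
    """Radial Fourier amplitude spectrum of a closed contour.

    The radius sequence (distance of each contour point from the contour
    centroid, in traversal order) is Fourier-transformed; the spectrum
    holds the amplitude at frequencies 1..K, scaled by 2/N so that a pure
    genome-synthesized shape recovers amp_scale * amplitude[f] at its
    active frequencies.  The DC term (mean radius) is excluded.
    """
    n = len(c)
    if not 1 <= K <= n - 1:
        raise SimilarityError(f"K must be in [1, {n - 1}] for a {n}-point contour")
    r = np.hypot(*(c.points - c.centroid).T)
    mags = np.abs(np.fft.fft(r)) * 2.0 / n
    return AmplitudeSpectrum(amps=mags[1 : K + 1])


def spectrum_distance(a: AmplitudeSpectrum, b: AmplitudeSpectrum) -> float:
    """L2 norm between amplitude spectra, zero-padding the shorter one."""
    k = max(len(a), len(b))
    pa = np.zeros(k)
    pa[: len(a)] = a.amps
    pb = np.zeros(k)
    pb[: len(b)] = b.amps
    return float(np.linalg.norm(pa - pb))


# ---------------------------------------------------------------------------
# Uniform front-end over the three metrics

METRICS = ("skeleton", "curvature", "spectrum")


def _as_contour(shape, cfg: SynthConfig) -> ShapeContour:
    if isinstance(shape, ShapeContour):
        return shape
    if isinstance(shape, RFGenome):
        return synthesize_contour(shape, cfg)
    raise SimilarityError(f"cannot interpret {type(shape).__name__} as a shape")


def shape_distance(
    a,
    b,
    metric: str = "spectrum",
    cfg: SynthConfig = SynthConfig(),
    alignment: AlignmentConfig = AlignmentConfig(),
    spectrum_k: int | None = None,
) -> float:
    """Distance between two shapes (genomes or contours) under one metric."""
    ca, cb = _as_contour(a, cfg), _as_contour(b, cfg)
    if metric == "curvature":
        return curvature_distance(ca, cb, cfg)
    if metric == "spectrum":
        k = spectrum_k if spectrum_k is not None else min(len(ca), len(cb)) // 2
        return spectrum_distance(contour_spectrum(ca, k), contour_spectrum(cb, k))
    if metric == "skeleton":
        sa = skeletonize(rasterize(ca, cfg, fill=True))
        sb = skeletonize(rasterize(cb, cfg, fill=True))
        return skeleton_distance(sa, sb, alignment)
    raise SimilarityError(f"unknown metric {metric!r}; choose from {METRICS}")
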