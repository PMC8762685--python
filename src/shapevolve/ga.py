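"""The evolutionary loop over distractor genomes.

Each generation, every distractor in a 12-strong pool is scored from its
search trials.  Three parents are selected -- the fastest mean RTs when
evolving toward easy search, or the highest hard-fitness score
``slope - hard_weight * mean RT`` when evolving toward hard search.  The
next pool is the three parents carried over unchanged (elitism) plus nine
offspring, each built by uniform crossover of two distinct parents (every
genome element inherited from either parent with probability 0.5) followed
by element-wise mutation: with probability ``mutation_rate`` a gate flips,
an amplitude doubles or halves (equal odds), or a phase is redrawn
uniformly from 1-360 degrees.

Constraint masks freeze chosen frequencies for the whole run: ``clamp_on``
pins the gate open at a prescribed amplitude (phase stays free),
``force_off`` pins the gate closed at zero amplitude.

A single seeded random stream drives each generation, consumed in a fixed
documented order (parent pairing, then crossover, then mutation, offspring
by offspring), so runs replay exactly from (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence
import uuid

import numpy as np

from .genome import N_FREQUENCIES, InitConfig, RFGenome, random_genome

__all__ = [
    "FitnessScore",
    "GAConfig",
    "ConstraintMask",
    "Population",
    "hard_fitness",
    "score_distractors",
    "select_parents",
    "crossover",
    "mutate",
    "evolve",
    "apply_constraints",
    "initial_population",
]

#: Weight of mean RT in the hard-direction fitness score, as printed.
DEFAULT_HARD_WEIGHT = 0.15

#: Sign-flipped weight (score = slope + 0.15 * mean RT).  Under a simulated
#: observer the verbatim score is dominated by the -0.15 * meanRT term and
#: selects *fast* distractors; this documented alternative rewards long RTs
#: so that hard-direction runs actually harden the search.  See docs.
RT_PROMOTING_HARD_WEIGHT = -0.15


class ScoringError(ValueError):
    """Raised when trial logs cannot support fitness scoring."""


def hard_fitness(slope: float, mean_rt: float, weight: float = DEFAULT_HARD_WEIGHT) -> float:
    """Hard-direction fitness: slope - weight * mean RT (weight 0.15)."""
    return slope - weight * mean_rt


@dataclass(frozen=True)
class FitnessScore:
    """Per-distractor fitness derived from one generation's trials."""

    distractor_id: str
    mean_rt: float
    rt_small: float
    rt_large: float
    slope: float
    score_easy: float
    score_hard: float


@dataclass(frozen=True)
class ConstraintMask:
    """Per-frequency evolution constraints (length 10).

    modes[f] is "free", "clamp_on" (gate forced 1, amplitude pinned to
    amps[f], phase free) or "force_off" (gate forced 0, amplitude 0).
    """

    modes: tuple[str, ...] = ("free",) * N_FREQUENCIES
    amps: tuple[float, ...] = (0.0,) * N_FREQUENCIES

    def __post_init__(self) -> None:
        if len(self.modes) != N_FREQUENCIES or len(self.amps) != N_FREQUENCIES:
            raise ValueError(f"mask must cover all {N_FREQUENCIES} frequencies")
        for mode, amp in zip(self.modes, self.amps):
            if mode not in ("free", "clamp_on", "force_off"):
                raise ValueError(f"unknown constraint mode {mode!r}")
            if mode == "clamp_on" and amp < 0:
                raise ValueError("clamp_on amplitude must be non-negative")
        object.__setattr__(self, "modes", tuple(self.modes))
        object.__setattr__(self, "amps", tuple(float(a) for a in self.amps))

    @classmethod
    def free(cls) -> "ConstraintMask":
        return cls()

    @classmethod
    def for_target(cls, target: RFGenome, direction: str) -> "ConstraintMask":
        """Pin the target's active frequencies: clamp_on at the target
        amplitudes for easy evolution, force_off for hard evolution."""
        active = (target.gates * target.amplitudes) > 0
        mode = "clamp_on" if direction == "easy" else "force_off"
        modes = tuple(mode if a else "free" for a in active)
        amps = tuple(float(t) if a else 0.0 for a, t in zip(active, target.amplitudes))
        return cls(modes=modes, amps=amps)

    @property
    def is_free(self) -> bool:
        return all(m == "free" for m in self.modes)

    def satisfied_by(self, g: RFGenome) -> bool:
        for f, mode in enumerate(self.modes):
            if mode == "clamp_on" and (g.gates[f] != 1 or g.amplitudes[f] != self.amps[f]):
                return False
            if mode == "force_off" and (g.gates[f] != 0 or g.amplitudes[f] != 0.0):
                return False
        return True


@dataclass(frozen=True)
class GAConfig:
    """Evolutionary-loop settings (defaults follow the study procedure)."""

    pool_size: int = 12
    n_parents: int = 3
    mutation_rate: float = 0.02
    hard_weight: float = DEFAULT_HARD_WEIGHT
    n_generations: int = 8
    direction: str = "easy"
    constraint: ConstraintMask = field(default_factory=ConstraintMask)
    mutate_parents: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n_parents < self.pool_size:
            raise ValueError("n_parents must be smaller than pool_size")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.direction not in ("easy", "hard"):
            raise ValueError("direction must be 'easy' or 'hard'")


@dataclass(frozen=True)
class Population:
    """One generation's distractor pool."""

    genomes: tuple[RFGenome, ...]
    generation: int = 1
    direction: str = "easy"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomes", tuple(self.genomes))
        if self.generation < 1:
            raise ValueError("generation index starts at 1")

    def __len__(self) -> int:
        return len(self.genomes)

    def ids(self) -> list[str]:
        return [g.id for g in self.genomes]


# ---------------------------------------------------------------------------
# Scoring and selection


def score_distractors(trials: Iterable, cfg: GAConfig = GAConfig()) -> list[FitnessScore]:
    """Fitness per distractor from its trials at two set sizes.

    mean_rt averages all the distractor's trials; the slope is the
    two-point slope of the mean RTs at the small and large set size.
    Order follows first appearance in the trial list.
    """
    by_id: dict[str, list] = {}
    set_sizes: set[int] = set()
    for t in trials:
        by_id.setdefault(t.distractor_id, []).append(t)
        set_sizes.add(t.set_size)
    if not by_id:
        raise ScoringError("no trials to score")
    if len(set_sizes) != 2:
        raise ScoringError(f"scoring needs exactly two set sizes, got {sorted(set_sizes)}")
    ss_small, ss_large = sorted(set_sizes)
    scores = []
    for did, recs in by_id.items():
        rts = np.array([r.rt_ms for r in recs], dtype=float)
        small = [r.rt_ms for r in recs if r.set_size == ss_small]
        large = [r.rt_ms for r in recs if r.set_size == ss_large]
        if not small or not large:
            missing = ss_small if not small else ss_large
            raise ScoringError(f"distractor {did!r} has no trial at set size {missing}")
        rt_small = float(np.mean(small))
        rt_large = float(np.mean(large))
        slope = (rt_large - rt_small) / (ss_large - ss_small)
        mean_rt = float(rts.mean())
        scores.append(
            FitnessScore(
                distractor_id=did,
                mean_rt=mean_rt,
                rt_small=rt_small,
                rt_large=rt_large,
                slope=slope,
                score_easy=mean_rt,
                score_hard=hard_fitness(slope, mean_rt, cfg.hard_weight),
            )
        )
    return scores


def select_parents(scores: Sequence[FitnessScore], cfg: GAConfig = GAConfig()) -> list[str]:
    """Ids of the n_parents fittest distractors.

    Easy direction: lowest mean RT (fastest search).  Hard direction:
    highest hard-fitness score.  Ties resolve to the earlier entry in the
    score list (stable sort).
    """
    if len(scores) < cfg.n_parents:
        raise ScoringError(f"need at least {cfg.n_parents} scored distractors, got {len(scores)}")
    if cfg.direction == "easy":
        key = lambda i: scores[i].score_easy
    else:
        key = lambda i: -scores[i].score_hard
    order = sorted(range(len(scores)), key=key)  # stable: ties keep list order
    return [scores[i].distractor_id for i in order[: cfg.n_parents]]


# ---------------------------------------------------------------------------
# Variation operators
#
# A genome is treated as 30 elements in the fixed order
# amplitudes[0..9], phases[0..9], gates[0..9].


def crossover(a: RFGenome, b: RFGenome, rng: np.random.Generator) -> RFGenome:
    """Uniform crossover: each of the 30 elements comes from either parent
    with probability 0.5; lineage records both parent ids."""
    pick_b = rng.random(3 * N_FREQUENCIES) < 0.5
    amps = np.where(pick_b[:10], b.amplitudes, a.amplitudes)
    phases = np.where(pick_b[10:20], b.phases, a.phases)
    gates = np.where(pick_b[20:], b.gates, a.gates)
    return RFGenome(
        amplitudes=amps,
        phases=phases,
        gates=gates,
        id=uuid.uuid4().hex,
        lineage=(a.id, b.id),
    )


def mutate(g: RFGenome, cfg: GAConfig, rng: np.random.Generator) -> RFGenome:
    """Element-wise mutation at cfg.mutation_rate per element.

    A mutated amplitude doubles or halves with equal probability; a mutated
    phase is redrawn from Uniform(1, 360) degrees; a mutated gate flips.
    Frequencies pinned by the constraint mask keep their amplitude and gate
    (their phase can still mutate under clamp_on, matching the procedure
    where pinned frequencies keep target amplitudes but free phases).
    """
    hit = rng.random(3 * N_FREQUENCIES) < cfg.mutation_rate
    amps = g.amplitudes.copy()
    phases = g.phases.copy()
    gates = g.gates.copy()
    pinned = np.array([m != "free" for m in cfg.constraint.modes])
    for f in range(N_FREQUENCIES):
        if hit[f] and not pinned[f]:
            amps[f] *= 2.0 if rng.random() < 0.5 else 0.5
    for f in range(N_FREQUENCIES):
        if hit[10 + f]:
            phases[f] = rng.uniform(1.0, 360.0)
    for f in range(N_FREQUENCIES):
        if hit[20 + f] and not pinned[f]:
            gates[f] = 1 - gates[f]
    if not hit.any():
        return g
    return replace(g, amplitudes=amps, phases=phases, gates=gates)


def apply_constraints(
    g: RFGenome, mask: ConstraintMask, target: RFGenome | None = None
) -> RFGenome:
    """Force a genome to satisfy a constraint mask.

    clamp_on(f): gate 1 and amplitude pinned (to the target's amplitude at
    f when a target is given, else the mask's stored amplitude); the phase
    is untouched.  force_off(f): gate 0, amplitude 0.  free: untouched.
    """
    if mask.is_free:
        return g
    amps = g.amplitudes.copy()
    gates = g.gates.copy()
    for f, mode in enumerate(mask.modes):
        if mode == "clamp_on":
            gates[f] = 1
            amps[f] = target.amplitudes[f] if target is not None else mask.amps[f]
        elif mode == "force_off":
            gates[f] = 0
            amps[f] = 0.0
    return replace(g, amplitudes=amps, gates=gates)


# ---------------------------------------------------------------------------
# Pool construction


def initial_population(
    cfg: GAConfig,
    rng: np.random.Generator,
    init: InitConfig = InitConfig(),
    target: RFGenome | None = None,
) -> Population:
    """Generation-1 pool of pool_size random genomes, constraint-applied."""
    genomes = []
    for _ in range(cfg.pool_size):
        g = random_genome(init, rng)
        genomes.append(apply_constraints(g, cfg.constraint, target))
    return Population(genomes=tuple(genomes), generation=1, direction=cfg.direction)


def evolve(
    pop: Population,
    scores: Sequence[FitnessScore],
    cfg: GAConfig,
    rng: np.random.Generator,
    target: RFGenome | None = None,
) -> Population:
    """One generation step: 3 selected parents carried over verbatim plus
    9 offspring from crossover of random distinct parent pairs followed by
    mutation, with the constraint mask enforced on every output genome."""
    scored_ids = {s.distractor_id for s in scores}
    missing = [g.id for g in pop.genomes if g.id not in scored_ids]
    if missing:
        raise ScoringError(f"scores missing for pool members {missing}")
    parent_ids = select_parents(scores, cfg)
    by_id = {g.id: g for g in pop.genomes}
    parents = [by_id[pid] for pid in parent_ids]
    next_pool: list[RFGenome] = list(parents)
    n_offspring = cfg.pool_size - cfg.n_parents
    for _ in range(n_offspring):
        i, j = rng.choice(cfg.n_parents, size=2, replace=False)
        child = crossover(parents[i], parents[j], rng)
        child = mutate(child, cfg, rng)
        child = apply_constraints(child, cfg.constraint, target)
        next_pool.append(child)
    if cfg.mutate_parents:
        next_pool[: cfg.n_parents] = [
            apply_constraints(mutate(p, cfg, rng), cfg.constraint, target)
            for p in parents
        ]
    out = Population(genomes=tuple(next_pool), generation=pop.generation + 1, direction=cfg.direction)
    bad = [g.id for g in out.genomes if not cfg.constraint.satisfied_by(g)]
    if bad:  # defensive: construction above should make this unreachable
        raise RuntimeError(f"constraint violated by output genomes {bad}")
    return out
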