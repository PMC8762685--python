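"""Synthetic search observer: similarity-guided reaction times.

Human reaction time is the fitness signal the evolutionary procedure was
designed around; this module supplies a stand-in so the loop can run and
be tested without human data.  The model is deliberately simple serial
search with similarity-guided filtering:

* a target-distractor distance ``d`` (any of the three shape metrics) is
  mapped to a normalized similarity ``s = 1 / (1 + d / sim_scale)``;
* a Hill function turns similarity into the probability ``q`` that a
  distractor survives preattentive filtering and must be inspected;
* on target-present trials the observer inspects on average half of the
  surviving distractors before hitting the target; on target-absent trials
  it exhaustively rechecks (``absent_exhaustive_factor``);
* RT = t0 + t_item * (items inspected) + truncated Gaussian noise.

Every parameter lives in :class:`ObserverParams`; a recorded trial log can
replace the simulation wherever a list of :class:`TrialRecord` is expected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .similarity import AlignmentConfig, shape_distance
from .synthesis import SynthConfig

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "inspection_probability",
    "normalized_similarity",
    "simulate_rt",
    "run_generation",
    "DEFAULT_SIM_SCALE",
]

#: Distance scale per metric used to normalize similarities: s = 1/(1+d/scale).
#: Chosen so that a typical generation-1 random distractor lands near the
#: middle of the similarity range for its metric (pixels for skeleton and
#: spectrum distances, dimensionless for the curvature index difference).
DEFAULT_SIM_SCALE = {"spectrum": 15.0, "skeleton": 4.0, "curvature": 15.0}


@dataclass(frozen=True)
class ObserverParams:
    """Tunable parameters of the simulated observer.

    t0 : base/residual time in ms; t_item : serial cost per inspected item
    in ms; half_sim : similarity at which a distractor is inspected with
    probability 0.5; steepness : Hill exponent; noise_sd : RT noise SD in
    ms (truncated below at -t0/2); absent_exhaustive_factor : extra
    scrutiny on target-absent trials; sim_scale : distance normalization
    scale (None picks the per-metric default).
    """

    t0: float = 500.0
    t_item: float = 50.0
    half_sim: float = 0.5
    steepness: float = 4.0
    noise_sd: float = 60.0
    absent_exhaustive_factor: float = 1.5
    sim_scale: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.t0, self.t_item, self.noise_sd) < 0:
            raise ValueError("t0, t_item and noise_sd must be non-negative")
        if self.steepness <= 0 or self.half_sim <= 0:
            raise ValueError("steepness and half_sim must be positive")

    def scale_for(self, metric: str) -> float:
        if self.sim_scale is not None:
            return self.sim_scale
        return DEFAULT_SIM_SCALE[metric]

    @classmethod
    def from_file(cls, path: str | Path) -> "ObserverParams":
        """Load parameters from a YAML or JSON mapping."""
        text = Path(path).read_text()
        try:
            obj = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            obj = yaml.safe_load(text)
        return cls(**obj)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass(frozen=True)
class TrialRecord:
    """One search trial outcome."""

    generation: int
    distractor_id: str
    set_size: int
    target_present: bool
    rt_ms: float
    correct: bool = True

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def normalized_similarity(distance: float, scale: float) -> float:
    """Map a metric distance >= 0 to a similarity in (0, 1]."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + distance / scale)


def inspection_probability(similarity: float, p: ObserverParams) -> float:
    """Hill-function probability that a distractor must be inspected.

    q = s^k / (s^k + half_sim^k); 0 at s = 0, 0.5 at s = half_sim, and
    strictly increasing in s.
    """
    if similarity < 0:
        raise ValueError("similarity must be non-negative")
    sk = similarity**p.steepness
    return sk / (sk + p.half_sim**p.steepness)


def _noise(p: ObserverParams, rng: np.random.Generator) -> float:
    if p.noise_sd == 0:
        return 0.0
    lo = -p.t0 / 2.0
    # truncated Gaussian by rejection; the bound is ~4 SD out at defaults
    for _ in range(1000):
        x = rng.normal(0.0, p.noise_sd)
        if x >= lo:
            return float(x)
    return lo


def simulate_rt(
    set_size: int,
    target_present: bool,
    similarity: float,
    p: ObserverParams,
    rng: np.random.Generator,
    generation: int = 0,
    distractor_id: str = "",
) -> TrialRecord:
    """Simulate one trial's RT from the target-distractor similarity."""
    q = inspection_probability(similarity, p)
    if target_present:
        inspected = 1.0 + (set_size - 1) * q * 0.5
    else:
        inspected = set_size * q * p.absent_exhaustive_factor + 1.0
    rt = p.t0 + p.t_item * inspected + _noise(p, rng)
    return TrialRecord(
        generation=generation,
        distractor_id=distractor_id,
        set_size=set_size,
        target_present=target_present,
        rt_ms=max(rt, 1e-9),
    )


def run_generation(
    pop,
    target_shape,
    schedule: Sequence,
    p: ObserverParams,
    metric: str = "spectrum",
    rng: np.random.Generator | None = None,
    synth: SynthConfig = SynthConfig(),
    alignment: AlignmentConfig = AlignmentConfig(),
) -> list[TrialRecord]:
    """Simulate every scheduled trial for one generation's pool.

    The target-distractor distance is computed once per distractor under
    the chosen metric and cached across the generation's trials.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    scale = p.scale_for(metric)
    by_id = {g.id: g for g in pop.genomes}
    sim_cache: dict[str, float] = {}
    records = []
    for spec in schedule:
        did = spec.distractor_id
        if did not in sim_cache:
            d = shape_distance(by_id[did], target_shape, metric=metric, cfg=synth, alignment=alignment)
            sim_cache[did] = normalized_similarity(d, scale)
        records.append(
            simulate_rt(
                set_size=spec.set_size,
                target_present=spec.target_present,
                similarity=sim_cache[did],
                p=p,
                rng=rng,
                generation=pop.generation,
                distractor_id=did,
            )
        )
    return records


def write_trials_csv(records: Iterable[TrialRecord], path: str | Path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["generation", "trial_index", "distractor_id", "set_size", "target_present", "rt_ms"])
        for i, r in enumerate(records):
            w.writerow([r.generation, i, r.distractor_id, r.set_size, int(r.target_present), f"{r.rt_ms:.3f}"])


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Load a recorded trial log (e.g. human data) as TrialRecords."""
    import csv

    records = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                TrialRecord(
                    generation=int(row["generation"]),
                    distractor_id=row["distractor_id"],
                    set_size=int(row["set_size"]),
                    target_present=bool(int(row["target_present"])),
                    rt_ms=float(row["rt_ms"]),
                )
            )
    return records
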