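"""Display composition, trial scheduling, RT filtering and slope analysis.

Covers the two search paradigms:

* the evolution paradigm -- target always present among homogeneous
  distractors at set sizes 16 and 24, run in sequential set-size blocks
  with distractor order shuffled within each block (24 trials per
  generation for a 12-strong pool);
* the present/absent paradigm -- set sizes 8/12/16, target present on
  exactly half the trials, item orientations jittered within +/-25 degrees
  and sizes jittered by a +/-10% scale factor, 300 experimental trials,
  with RTs above 10,000 ms excluded before slope analysis.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ga import Population
from .genome import read_population
from .observer import ObserverParams, TrialRecord, normalized_similarity, simulate_rt
from .similarity import AlignmentConfig, shape_distance
from .synthesis import SynthConfig

__all__ = [
    "DisplaySpec",
    "ScheduleConfig",
    "TrialSpec",
    "build_schedule",
    "compose_display",
    "run_exp4_block",
    "filter_rts",
    "rt_setsize_slopes",
    "metrics_over_generations",
]

logger = logging.getLogger(__name__)


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial, before simulation."""

    distractor_id: str
    set_size: int
    target_present: bool = True


@dataclass(frozen=True)
class DisplaySpec:
    """Geometry of one search display: items on a circle around fixation."""

    set_size: int
    positions: np.ndarray  # (set_size, 2), pixels relative to fixation
    orientations: np.ndarray  # degrees per item
    sizes: np.ndarray  # scale factor per item
    target_index: int | None
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (self.set_size, 2):
            raise ScheduleError("positions must be (set_size, 2)")
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.ptp(radii) > 1.0:
            raise ScheduleError("items must be equidistant from center within 1 px")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", np.asarray(self.orientations, dtype=float))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=float))
        object.__setattr__(self, "item_ids", tuple(self.item_ids))


@dataclass(frozen=True)
class ScheduleConfig:
    """Trial scheduling and display-jitter settings."""

    set_sizes: tuple[int, ...] = (16, 24)
    trials_per_distractor_per_setsize: int = 1
    blocked_by_setsize: bool = True
    exp4_mode: bool = False
    exp4_set_sizes: tuple[int, ...] = (8, 12, 16)
    exp4_present_rate: float = 0.5
    exp4_orientation_jitter: float = 25.0
    exp4_size_jitter: float = 0.10
    exp4_n_trials: int = 300
    rt_exclusion_ms: float = 10_000.0
    array_radius_factor: float = 5.0  # display circle radius in units of item base_radius
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.set_sizes + self.exp4_set_sizes):
            raise ScheduleError("set sizes must be positive")
        if not 0.0 <= self.exp4_present_rate <= 1.0:
            raise ScheduleError("present rate must be a probability")
        if self.exp4_orientation_jitter < 0 or self.exp4_size_jitter < 0:
            raise ScheduleError("jitter bounds must be non-negative")


def build_schedule(
    pop: Population, cfg: ScheduleConfig = ScheduleConfig(), rng: np.random.Generator | None = None
) -> list[TrialSpec]:
    """Evolution-paradigm schedule: sequential set-size blocks, each
    containing every distractor once (per repeat) in seeded shuffled order;
    the target is always present."""
    if len(pop) == 0:
        raise ScheduleError("empty distractor pool")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = pop.ids()
    schedule: list[TrialSpec] = []
    for ss in cfg.set_sizes:
        block = [did for _ in range(cfg.trials_per_distractor_per_setsize) for did in ids]
        order = rng.permutation(len(block))
        schedule.extend(TrialSpec(block[i], ss, True) for i in order)
    return schedule


def compose_display(
    target_id: str,
    distractor_id: str,
    set_size: int,
    cfg: ScheduleConfig = ScheduleConfig(),
    rng: np.random.Generator | None = None,
    present: bool = True,
    base_radius: float = 30.0,
) -> DisplaySpec:
    """Place set_size items evenly on a circle around fixation.

    Distractor orientations are Uniform(0, 360) in the evolution paradigm,
    or Uniform(-jitter, +jitter) with +/-size-jitter scale factors in
    exp4_mode; the whole array gets a random rotation offset and the
    target (when present) a uniformly random position.
    """
    if set_size < 2:
        raise ScheduleError("set_size must be at least 2")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    array_r = cfg.array_radius_factor * base_radius
    offset = rng.uniform(0, 2 * np.pi)
    ang = offset + 2 * np.pi * np.arange(set_size) / set_size
    positions = array_r * np.column_stack([np.cos(ang), np.sin(ang)])
    if cfg.exp4_mode:
        j = cfg.exp4_orientation_jitter
        orientations = rng.uniform(-j, j, set_size)
        sizes = 1.0 + rng.uniform(-cfg.exp4_size_jitter, cfg.exp4_size_jitter, set_size)
    else:
        orientations = rng.uniform(0.0, 360.0, set_size)
        sizes = np.ones(set_size)
    target_index = int(rng.integers(set_size)) if present else None
    item_ids = [distractor_id] * set_size
    if target_index is not None:
        item_ids[target_index] = target_id
    return DisplaySpec(
        set_size=set_size,
        positions=positions,
        orientations=orientations,
        sizes=sizes,
        target_index=target_index,
        item_ids=tuple(item_ids),
    )


def run_exp4_block(
    target_silhouette,
    distractor_set: Sequence,
    cfg: ScheduleConfig,
    observer: ObserverParams,
    rng: np.random.Generator | None = None,
    metric: str = "spectrum",
    synth: SynthConfig = SynthConfig(),
    alignment: AlignmentConfig = AlignmentConfig(),
) -> list[TrialRecord]:
    """Present/absent search block against a silhouette target.

    Trials are exactly counterbalanced: set sizes split evenly and the
    target present on exactly exp4_present_rate of trials within every set
    size, in seeded shuffled order.  Each trial draws one homogeneous
    distractor uniformly from the set.
    """
    if not distractor_set:
        raise ScheduleError("distractor set must be non-empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.exp4_n_trials
    sizes = cfg.exp4_set_sizes
    if n % len(sizes):
        raise ScheduleError(f"{n} trials cannot balance over set sizes {sizes}")
    per_size = n // len(sizes)
    n_present = int(round(per_size * cfg.exp4_present_rate))
    conditions = [
        (ss, i < n_present)
        for ss in sizes
        for i in range(per_size)
    ]
    order = rng.permutation(len(conditions))

    scale = observer.scale_for(metric)
    sims: list[float] = []
    for dshape in distractor_set:
        d = shape_distance(dshape, target_silhouette, metric=metric, cfg=synth, alignment=alignment)
        sims.append(normalized_similarity(d, scale))

    records = []
    for idx in order:
        ss, present = conditions[idx]
        k = int(rng.integers(len(distractor_set)))
        # display composition consumes the jitter stream even though the
        # simulated RT depends only on set size, presence and similarity
        compose_display("target", f"distractor_{k}", ss, cfg, rng, present=present)
        records.append(
            simulate_rt(ss, present, sims[k], observer, rng, generation=0, distractor_id=f"distractor_{k}")
        )
    return records


def filter_rts(records: Iterable[TrialRecord], cfg: ScheduleConfig = ScheduleConfig()) -> list[TrialRecord]:
    """Drop trials with RT strictly above the exclusion threshold."""
    records = list(records)
    kept = [r for r in records if r.rt_ms <= cfg.rt_exclusion_ms]
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("filter_rts removed %d of %d trials above %.0f ms", n_removed, len(records), cfg.rt_exclusion_ms)
    return kept


def rt_setsize_slopes(records: Iterable[TrialRecord]) -> dict[str, tuple[float, float]]:
    """Per-condition (slope ms/item, intercept ms) of mean RT vs set size.

    Ordinary least squares through the per-set-size mean RTs, separately
    for target-present and target-absent trials.
    """
    df = pd.DataFrame(
        [(r.target_present, r.set_size, r.rt_ms) for r in records],
        columns=["present", "set_size", "rt_ms"],
    )
    if df.empty:
        raise ScheduleError("no records to analyze")
    out: dict[str, tuple[float, float]] = {}
    for present, sub in df.groupby("present"):
        means = sub.groupby("set_size")["rt_ms"].mean()
        if len(means) < 2:
            raise ScheduleError("slope analysis needs at least two set sizes per condition")
        slope, intercept = np.polyfit(means.index.to_numpy(float), means.to_numpy(), 1)
        out["present" if present else "absent"] = (float(slope), float(intercept))
    return out


def metrics_over_generations(
    run_dir: str | Path,
    target_shape,
    synth: SynthConfig = SynthConfig(),
    alignment: AlignmentConfig = AlignmentConfig(),
    metrics: tuple[str, ...] = ("skeleton", "curvature", "spectrum"),
) -> pd.DataFrame:
    """Per-generation mean RT and pool-mean similarity metrics vs target.

    Expects ``generation_NN.json`` population files and a ``trials.csv``
    log in run_dir, as written by :func:`shapevolve.run.evolve_run`.
    Returns one row per generation with columns mean_rt, skeleton_d,
    curvature_d, spectrum_d (for the metrics requested).
    """
    run_dir = Path(run_dir)
    pop_files = sorted(run_dir.glob("generation_*.json"))
    if not pop_files:
        raise FileNotFoundError(f"no generation_*.json population files in {run_dir}")
    trials_path = run_dir / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"missing {trials_path}")
    trials = pd.read_csv(trials_path)

    rows = []
    for i, pf in enumerate(pop_files, start=1):
        gen = int(pf.stem.split("_")[1])
        if gen != i:
            missing = [f"generation_{k:02d}.json" for k in range(1, gen) if not (run_dir / f"generation_{k:02d}.json").exists()]
            raise FileNotFoundError(f"missing generation files: {missing}")
        genomes = read_population(pf)
        row: dict[str, float] = {"generation": gen}
        gen_trials = trials[trials["generation"] == gen]
        row["mean_rt"] = float(gen_trials["rt_ms"].mean()) if len(gen_trials) else np.nan
        for metric in metrics:
            vals = [
                shape_distance(g, target_shape, metric=metric, cfg=synth, alignment=alignment)
                for g in genomes
            ]
            row[f"{metric}_d"] = float(np.mean(vals))
        rows.append(row)
    return pd.DataFrame(rows).set_index("generation")


def write_trial_csv(records: Iterable[TrialRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["generation", "trial_index", "distractor_id", "set_size", "target_present", "rt_ms"])
        for i, r in enumerate(records):
            w.writerow([r.generation, i, r.distractor_id, r.set_size, int(r.target_present), f"{r.rt_ms:.3f}"])
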