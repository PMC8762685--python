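"""End-to-end evolution runs: GA loop closed by the simulated observer.

One run evolves a 12-distractor pool against a fixed target for
``n_generations`` generations.  Each generation simulates the scheduled
search trials (24 by default: every distractor once at each of two set
sizes), scores the distractors, and evolves the pool.  Results are
returned in memory and optionally written to a run directory as
per-generation population JSON, a trial-log CSV and a summary CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ga import (
    GAConfig,
    Population,
    RT_PROMOTING_HARD_WEIGHT,
    evolve,
    initial_population,
    score_distractors,
)
from .genome import InitConfig, RFGenome, write_population
from .observer import ObserverParams, TrialRecord, run_generation
from .experiment import ScheduleConfig, build_schedule, write_trial_csv
from .similarity import AlignmentConfig, shape_distance
from .synthesis import SynthConfig

__all__ = ["EvolutionRun", "evolve_run"]


@dataclass
class EvolutionRun:
    """History of one evolution run."""

    populations: list[Population] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    summary: pd.DataFrame | None = None

    @property
    def n_generations(self) -> int:
        return len(self.populations)

    def mean_rt(self, generation: int) -> float:
        rts = [t.rt_ms for t in self.trials if t.generation == generation]
        return float(np.mean(rts))


def evolve_run(
    target,
    direction: str = "easy",
    ga: GAConfig | None = None,
    observer: ObserverParams = ObserverParams(),
    schedule_cfg: ScheduleConfig = ScheduleConfig(),
    init: InitConfig = InitConfig(),
    synth: SynthConfig = SynthConfig(),
    alignment: AlignmentConfig = AlignmentConfig(),
    metric: str = "spectrum",
    seed: int | None = None,
    out_dir: str | Path | None = None,
    rt_promoting_hard: bool = True,
) -> EvolutionRun:
    """Run a full evolution experiment with the simulated observer.

    ``rt_promoting_hard=True`` (default for simulations) runs hard-direction
    selection with the sign-flipped weight (slope + 0.15 * mean RT) so that
    long-RT distractors are the ones promoted; pass False to select on the
    verbatim printed score.  The target may be an RFGenome or a
    ShapeContour.
    """
    if ga is None:
        hw = RT_PROMOTING_HARD_WEIGHT if (direction == "hard" and rt_promoting_hard) else 0.15
        ga = GAConfig(direction=direction, hard_weight=hw, seed=seed)
    rng = np.random.default_rng(ga.seed if seed is None else seed)

    target_genome = target if isinstance(target, RFGenome) else None
    pop = initial_population(ga, rng, init, target_genome)
    run = EvolutionRun()
    rows = []
    for _ in range(ga.n_generations):
        run.populations.append(pop)
        sched = build_schedule(pop, schedule_cfg, rng)
        records = run_generation(pop, target, sched, observer, metric, rng, synth, alignment)
        run.trials.extend(records)
        dists = [
            shape_distance(g, target, metric=metric, cfg=synth, alignment=alignment)
            for g in pop.genomes
        ]
        rows.append(
            {
                "generation": pop.generation,
                "mean_rt": float(np.mean([r.rt_ms for r in records])),
                f"{metric}_d": float(np.mean(dists)),
            }
        )
        if pop.generation < ga.n_generations:
            scores = score_distractors(records, ga)
            pop = evolve(pop, scores, ga, rng, target_genome)
    run.summary = pd.DataFrame(rows).set_index("generation")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for p in run.populations:
            write_population(list(p.genomes), out_dir / f"generation_{p.generation:02d}.json")
        write_trial_csv(run.trials, out_dir / "trials.csv")
        run.summary.to_csv(out_dir / "summary.csv")
    return run
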