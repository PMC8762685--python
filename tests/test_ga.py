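"""Fitness scoring, selection, crossover, mutation and pool evolution."""

import numpy as np
import pytest

from conftest import make_genome
from shapevolve import (
    ConstraintMask,
    GAConfig,
    Population,
    apply_constraints,
    crossover,
    evolve,
    hard_fitness,
    initial_population,
    mutate,
    score_distractors,
    select_parents,
)
from shapevolve.ga import FitnessScore, ScoringError
from shapevolve.observer import TrialRecord


def trial(did, ss, rt, gen=1):
    return TrialRecord(generation=gen, distractor_id=did, set_size=ss, target_present=True, rt_ms=rt)


def score(did, mean_rt=1000.0, slope=50.0, hard_weight=0.15):
    return FitnessScore(
        distractor_id=did,
        mean_rt=mean_rt,
        rt_small=mean_rt - 25 * slope / 2,
        rt_large=mean_rt + 25 * slope / 2,
        slope=slope,
        score_easy=mean_rt,
        score_hard=hard_fitness(slope, mean_rt, hard_weight),
    )


class TestScoring:
    def test_two_setsize_arithmetic(self):
        trials = [trial("d1", 16, 1000.0), trial("d1", 24, 1400.0)]
        [s] = score_distractors(trials)
        assert s.mean_rt == 1200.0
        assert s.slope == 50.0
        assert s.score_easy == 1200.0
        assert s.score_hard == pytest.approx(50.0 - 0.15 * 1200.0)  # == -130

    def test_equal_rts_give_zero_slope(self):
        [s] = score_distractors([trial("d", 16, 900.0), trial("d", 24, 900.0)])
        assert s.slope == 0.0

    def test_missing_set_size_names_distractor(self):
        trials = [trial("good", 16, 1000.0), trial("good", 24, 1100.0), trial("bad", 16, 950.0)]
        with pytest.raises(ScoringError, match="bad"):
            score_distractors(trials)

    def test_hard_fitness_weight_magnitude(self):
        assert -hard_fitness(0.0, 1.0) == pytest.approx(0.15, abs=1e-12)


class TestSelection:
    def test_easy_picks_fastest_mean_rts(self):
        scores = [score(d, mean_rt=rt) for d, rt in zip("abcde", [900, 1200, 800, 1500, 1000])]
        assert select_parents(scores, GAConfig(direction="easy")) == ["c", "a", "e"]

    def test_hard_tie_resolves_to_earlier_index(self):
        scores = [
            score("a", slope=90), score("b", slope=80), score("c", slope=70),
            score("d", slope=70), score("e", slope=10),
        ]
        assert select_parents(scores, GAConfig(direction="hard")) == ["a", "b", "c"]

    def test_all_equal_takes_first_three(self):
        scores = [score(d) for d in "abcde"]
        assert select_parents(scores, GAConfig()) == ["a", "b", "c"]

    def test_too_few_scores_rejected(self):
        with pytest.raises(ScoringError):
            select_parents([score("a"), score("b")], GAConfig())


class TestCrossover:
    def test_identical_parents_give_identical_offspring(self, rng):
        a = make_genome({2: 30.0}, id="a")
        b = make_genome({2: 30.0}, id="b")
        child = crossover(a, b, rng)
        assert np.array_equal(child.amplitudes, a.amplitudes)
        assert np.array_equal(child.phases, a.phases)
        assert np.array_equal(child.gates, a.gates)
        assert child.lineage == ("a", "b")

    def test_inheritance_is_fifty_fifty(self):
        rng = np.random.default_rng(21)
        a = make_genome(np.arange(1.0, 11.0), phases=np.arange(11.0, 21.0), gates=np.ones(10, int), id="a")
        b = make_genome(np.arange(101.0, 111.0), phases=np.arange(111.0, 121.0), gates=np.zeros(10, int), id="b")
        n, from_a = 20_000, 0
        for _ in range(n):
            ch = crossover(a, b, rng)
            from_a += int((ch.amplitudes < 100).sum() + (ch.phases < 100).sum() + ch.gates.sum())
        frac = from_a / (n * 30)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_seeded_reproducibility(self):
        a = make_genome(np.arange(1.0, 11.0), id="a")
        b = make_genome(np.arange(101.0, 111.0), id="b")
        c1 = crossover(a, b, np.random.default_rng(5))
        c2 = crossover(a, b, np.random.default_rng(5))
        assert np.array_equal(c1.amplitudes, c2.amplitudes)
        assert np.array_equal(c1.phases, c2.phases)


class TestMutation:
    def test_zero_rate_is_identity(self, genome_factory, rng):
        g = genome_factory()
        assert mutate(g, GAConfig(mutation_rate=0.0), rng) is g

    def test_amplitude_mutations_double_or_halve(self):
        g = make_genome(np.full(10, 40.0))
        rng = np.random.default_rng(2)
        changed = []
        for _ in range(300):
            m = mutate(g, GAConfig(mutation_rate=0.5), rng)
            changed.extend(m.amplitudes[m.amplitudes != 40.0])
        assert changed
        assert set(np.unique(changed)) <= {20.0, 80.0}

    def test_mutated_phases_stay_in_range(self):
        g = make_genome({1: 10.0})
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = mutate(g, GAConfig(mutation_rate=0.5), rng)
            assert np.all((m.phases >= 1.0) & (m.phases <= 360.0))

    def test_empirical_rate_matches_config(self):
        g = make_genome(np.full(10, 40.0), phases=np.full(10, 90.0), gates=np.ones(10, int))
        rng = np.random.default_rng(4)
        n, hits = 5000, 0
        for _ in range(n):
            m = mutate(g, GAConfig(mutation_rate=0.02), rng)
            hits += int(
                (m.amplitudes != g.amplitudes).sum()
                + (m.phases != g.phases).sum()
                + (m.gates != g.gates).sum()
            )
        assert hits / (30 * n) == pytest.approx(0.02, abs=0.004)

    def test_pinned_frequencies_never_mutate_amp_or_gate(self):
        mask = ConstraintMask.for_target(make_genome({2: 45.0, 6: 14.0}), "easy")
        cfg = GAConfig(mutation_rate=1.0, constraint=mask)
        g = apply_constraints(make_genome(np.full(10, 40.0)), mask)
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = mutate(g, cfg, rng)
            assert m.gates[1] == 1 and m.amplitudes[1] == 45.0
            assert m.gates[5] == 1 and m.amplitudes[5] == 14.0


class TestConstraints:
    def test_easy_mask_clamps_target_frequencies(self, bb_target, genome_factory):
        mask = ConstraintMask.for_target(bb_target, "easy")
        g = apply_constraints(genome_factory(), mask, bb_target)
        assert g.gates[1] == 1 and g.amplitudes[1] == bb_target.amplitudes[1]
        assert g.gates[5] == 1 and g.amplitudes[5] == bb_target.amplitudes[5]

    def test_hard_mask_forces_target_frequencies_off(self, bb_target, genome_factory):
        mask = ConstraintMask.for_target(bb_target, "hard")
        g = apply_constraints(genome_factory(), mask)
        assert g.gates[1] == 0 and g.amplitudes[1] == 0.0
        assert g.gates[5] == 0 and g.amplitudes[5] == 0.0

    def test_free_mask_is_identity(self, genome_factory):
        g = genome_factory()
        assert apply_constraints(g, ConstraintMask.free()) is g

    def test_clamped_phases_remain_free(self, bb_target, genome_factory):
        mask = ConstraintMask.for_target(bb_target, "easy")
        g = genome_factory()
        assert np.array_equal(apply_constraints(g, mask).phases, g.phases)


class TestEvolve:
    def _pop_and_scores(self, cfg, seed=0, rts=None):
        rng = np.random.default_rng(seed)
        pop = initial_population(cfg, rng)
        rts = rts or {g.id: 800.0 + 50 * i for i, g in enumerate(pop.genomes)}
        trials = [t for g in pop.genomes for t in
                  (trial(g.id, 16, rts[g.id]), trial(g.id, 24, rts[g.id] + 200))]
        return pop, score_distractors(trials, cfg), rng

    def test_next_pool_is_three_parents_plus_nine_offspring(self):
        cfg = GAConfig(direction="easy", seed=0)
        pop, scores, rng = self._pop_and_scores(cfg)
        nxt = evolve(pop, scores, cfg, rng)
        assert len(nxt) == 12 and nxt.generation == 2
        parent_ids = select_parents(scores, cfg)
        assert [g.id for g in nxt.genomes[:3]] == parent_ids
        by_id = {g.id: g for g in pop.genomes}
        for pid, g in zip(parent_ids, nxt.genomes[:3]):
            assert g is by_id[pid]  # carried over verbatim
        for child in nxt.genomes[3:]:
            assert len(child.lineage) == 2
            assert set(child.lineage) <= set(parent_ids)

    def test_no_mutation_closure_on_duplicate_parent(self, rng):
        p = make_genome({3: 22.0}, id="p")
        cfg = GAConfig(mutation_rate=0.0)
        child = mutate(crossover(p, p, rng), cfg, rng)
        assert np.array_equal(child.amplitudes, p.amplitudes)
        assert np.array_equal(child.phases, p.phases)

    def test_same_seed_gives_identical_next_population(self):
        cfg = GAConfig(direction="hard", seed=1)
        pop, scores, _ = self._pop_and_scores(cfg, seed=1)
        n1 = evolve(pop, scores, cfg, np.random.default_rng(42))
        n2 = evolve(pop, scores, cfg, np.random.default_rng(42))
        for a, b in zip(n1.genomes, n2.genomes):
            assert np.array_equal(a.amplitudes, b.amplitudes)
            assert np.array_equal(a.phases, b.phases)
            assert np.array_equal(a.gates, b.gates)

    def test_elitism_best_fitness_never_worsens(self):
        # deterministic surrogate fitness: amplitude of frequency 1
        cfg = GAConfig(direction="easy", seed=3)
        rng = np.random.default_rng(3)
        pop = initial_population(cfg, rng)
        best = np.inf
        for _ in range(6):
            fitness = {g.id: float(g.amplitudes[0]) for g in pop.genomes}
            trials = [t for g in pop.genomes for t in
                      (trial(g.id, 16, 500 + fitness[g.id]), trial(g.id, 24, 500 + fitness[g.id]))]
            scores = score_distractors(trials, cfg)
            gen_best = min(fitness.values())
            assert gen_best <= best + 1e-12
            best = min(best, gen_best)
            pop = evolve(pop, scores, cfg, rng)

    def test_constraint_mask_invariant_over_generations(self, bb_target):
        mask = ConstraintMask.for_target(bb_target, "hard")
        cfg = GAConfig(direction="hard", constraint=mask, seed=9)
        rng = np.random.default_rng(9)
        pop = initial_population(cfg, rng, target=bb_target)
        for _ in range(5):
            assert all(mask.satisfied_by(g) for g in pop.genomes)
            trials = [t for i, g in enumerate(pop.genomes) for t in
                      (trial(g.id, 16, 700.0 + 13 * i), trial(g.id, 24, 900.0 + 17 * i))]
            pop = evolve(pop, score_distractors(trials, cfg), cfg, rng, bb_target)
        assert all(mask.satisfied_by(g) for g in pop.genomes)
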