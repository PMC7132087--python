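"""GP rule search: fitness, variation operators, covering loop."""

import numpy as np
import pytest

from rulegp import (
    Dataset,
    FixtureSpec,
    GPConfig,
    Literal,
    Op,
    Rule,
    candidate_thresholds,
    crossover,
    evolve_rule,
    fitness,
    format_rule,
    init_population,
    local_search,
    make_box,
    make_case_a,
    max_length_bound,
    mutate,
    sequential_cover,
)
from conftest import random_interval_rule


def toy_dataset():
    """1-D, two clusters: class 0 at {1,2,3}, class 1 at {7,8,9}."""
    return Dataset(X=[[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]],
                   y=[0, 0, 0, 1, 1, 1], attribute_names=["a0"],
                   class_labels=[0, 1])


class TestCandidateThresholds:
    def test_midpoints(self):
        data = Dataset(X=[[1.0], [2.0], [4.0]], y=[0, 0, 1],
                       attribute_names=["a0"], class_labels=[0, 1])
        np.testing.assert_allclose(candidate_thresholds(data, 0), [1.5, 3.0])

    def test_constant_column_empty(self):
        data = Dataset(X=[[5.0, 1.0], [5.0, 2.0]], y=[0, 1],
                       attribute_names=["a0", "a1"], class_labels=[0, 1])
        assert len(candidate_thresholds(data, 0)) == 0

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            candidate_thresholds(toy_dataset(), 5)


class TestFitness:
    def test_perfect_single_literal_scores_one(self):
        cfg = GPConfig(length_penalty_weight=0.0)
        rule = Rule([Literal(0, Op.GE, 5.0)], 1)
        report = fitness(rule, toy_dataset(), 1, cfg)
        assert report.score == 1.0
        assert (report.tp, report.fp, report.tn, report.fn) == (3, 0, 3, 0)

    def test_rule_covering_nothing_scores_zero(self):
        rule = Rule([Literal(0, Op.GE, 100.0)], 1)
        assert fitness(rule, toy_dataset(), 1, GPConfig()).score == 0.0

    def test_rule_covering_everything_scores_zero(self):
        report = fitness(Rule([Literal(0, Op.GE, -100.0)], 1),
                         toy_dataset(), 1, GPConfig())
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0
        assert report.score == 0.0

    def test_counts_partition_dataset(self):
        rng = np.random.default_rng(0)
        data = toy_dataset()
        for _ in range(50):
            rule = random_interval_rule(rng, 1)
            r = fitness(rule, data, 1, GPConfig())
            assert r.tp + r.fp + r.tn + r.fn == data.n
            assert 0.0 <= r.score <= 1.0

    def test_ne_literals_penalized(self):
        cfg = GPConfig(ne_penalty_weight=0.2)
        clean = Rule([Literal(0, Op.GE, 5.0)], 1)
        punctured = Rule([Literal(0, Op.GE, 5.0), Literal(0, Op.NE, 1.0)], 1)
        assert (fitness(punctured, toy_dataset(), 1, cfg).score
                < fitness(clean, toy_dataset(), 1, cfg).score)

    def test_absent_target_raises(self):
        with pytest.raises(ValueError):
            fitness(Rule([], 1), toy_dataset(), 99, GPConfig())


class TestInitPopulation:
    def test_size_cover_and_bound(self, case_a_dataset, small_cfg):
        data = case_a_dataset
        pop = init_population(data, 1, small_cfg,
                              rng=np.random.default_rng(4))
        assert len(pop) == small_cfg.population_size
        upper = small_cfg.upper_length(data.d, data.class_size(0))
        target_X = data.X[data.class_mask(1)]
        for rule in pop:
            assert 1 <= rule.length <= upper
            assert rule.covers_matrix(target_X).any()

    def test_deterministic_under_seed(self, case_a_dataset, small_cfg):
        p1 = init_population(case_a_dataset, 1, small_cfg,
                             rng=np.random.default_rng(9))
        p2 = init_population(case_a_dataset, 1, small_cfg,
                             rng=np.random.default_rng(9))
        assert [format_rule(r) for r in p1] == [format_rule(r) for r in p2]

    def test_empty_target_raises(self, case_a_dataset, small_cfg):
        with pytest.raises(ValueError):
            init_population(case_a_dataset, "absent", small_cfg)


class TestCrossover:
    def test_one_point_exchange(self):
        L = [Literal(i, Op.GE, float(i)) for i in range(4)]
        a, b = Rule(L[:2], 1), Rule(L[2:], 1)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(50):
            c1, c2 = crossover(a, b, rng)
            seen.add(c1.literals)
            # children literals always come from the parents
            assert set(c1.literals) | set(c2.literals) <= set(L)
        assert (L[0], L[3]) in seen  # cut after position 1 occurs

    def test_self_crossover_preserves_coverage(self):
        rng = np.random.default_rng(1)
        pts = np.round(rng.uniform(0, 10, size=(100, 2)), 2)
        for _ in range(50):
            a = random_interval_rule(rng, 2)
            c1, c2 = crossover(a, a, rng)
            np.testing.assert_array_equal(a.covers_matrix(pts),
                                          c1.covers_matrix(pts))
            np.testing.assert_array_equal(a.covers_matrix(pts),
                                          c2.covers_matrix(pts))

    def test_children_respect_length_bound(self):
        rng = np.random.default_rng(2)
        upper = 4
        for _ in range(1000):
            a = random_interval_rule(rng, 3, max_len=6)
            b = random_interval_rule(rng, 3, max_len=6)
            c1, c2 = crossover(a, b, rng, upper=upper)
            assert c1.length <= upper and c2.length <= upper


class TestMutate:
    def test_never_empties_a_rule(self, small_cfg):
        data = toy_dataset()
        rng = np.random.default_rng(3)
        rule = Rule([Literal(0, Op.GE, 5.0)], 1)
        for _ in range(200):
            rule_m = mutate(rule, data, small_cfg, rng)
            assert rule_m.length >= 1

    def test_never_exceeds_bound(self, small_cfg):
        data = toy_dataset()
        rng = np.random.default_rng(4)
        upper = 2
        rule = Rule([Literal(0, Op.GE, 1.5), Literal(0, Op.LE, 8.5)], 1)
        for _ in range(200):
            assert mutate(rule, data, small_cfg, rng, upper=upper).length <= upper

    def test_deterministic_chain(self, small_cfg):
        data = toy_dataset()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            rule = Rule([Literal(0, Op.GE, 5.0)], 1)
            chain = []
            for _ in range(20):
                rule = mutate(rule, data, small_cfg, rng)
                chain.append(format_rule(rule))
            out.append(chain)
        assert out[0] == out[1]


class TestLocalSearch:
    def test_never_decreases_fitness(self, case_a_dataset):
        cfg = GPConfig()
        rng = np.random.default_rng(6)
        data = case_a_dataset
        for _ in range(200):
            rule = random_interval_rule(rng, 2, label=1)
            before = fitness(rule, data, 1, cfg).score
            after = fitness(local_search(rule, data, 1, cfg), data, 1, cfg).score
            assert after >= before

    def test_idempotent(self, case_a_dataset):
        cfg = GPConfig()
        rule = Rule([Literal(0, Op.GE, 6.0)], 1)
        once = local_search(rule, case_a_dataset, 1, cfg)
        twice = local_search(once, case_a_dataset, 1, cfg)
        assert format_rule(once) == format_rule(twice)

    def test_moves_threshold_to_class_boundary(self):
        """On line-separable data the threshold ends between the classes."""
        data = make_case_a(FixtureSpec(case="A", n_per_class=100,
                                       margin=0.5, seed=33))
        cfg = GPConfig()
        rule = local_search(Rule([Literal(0, Op.GE, 8.0)], 1), data, 1, cfg)
        (lit,) = rule.literals
        assert 4.5 <= lit.threshold <= 5.5
        assert fitness(rule, data, 1, cfg).sensitivity == 1.0


class TestEvolveRule:
    def test_solves_case_a(self, case_a_dataset):
        cfg = GPConfig(seed=1)
        rule, report = evolve_rule(case_a_dataset, 1, cfg,
                                   rng=np.random.default_rng(1))
        assert report.score >= 0.95
        assert rule.length == 1  # a single separating line suffices

    def test_zero_generations_runs(self, case_a_dataset, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, generations=0)
        rule, report = evolve_rule(case_a_dataset, 1, cfg,
                                   rng=np.random.default_rng(2))
        assert rule.length >= 1
        assert 0.0 <= report.score <= 1.0

    def test_deterministic(self, case_a_dataset, small_cfg):
        runs = [evolve_rule(case_a_dataset, 1, small_cfg,
                            rng=np.random.default_rng(7))[0]
                for _ in range(2)]
        assert format_rule(runs[0]) == format_rule(runs[1])


class TestSequentialCover:
    def test_case_b_two_corner_rules(self, case_b_dataset):
        data = case_b_dataset
        cfg = GPConfig(seed=5)
        rules = sequential_cover(data, 0, cfg, rng=np.random.default_rng(5))
        assert len(rules) == 2
        # each rule covers exactly one corner cluster of class 0
        lower_corner = data.X[(data.X[:, 0] < 3) & (data.X[:, 1] < 3)]
        upper_corner = data.X[(data.X[:, 0] > 7) & (data.X[:, 1] > 7)]
        for corner in (lower_corner, upper_corner):
            covering = [r for r in rules if r.covers_matrix(corner).all()]
            assert len(covering) == 1
        # and no rule covers class 1
        class1 = data.X[data.class_mask(1)]
        for r in rules:
            assert not r.covers_matrix(class1).any()

    def test_rules_within_length_bound(self, case_b_dataset, small_cfg):
        data = case_b_dataset
        for cls in data.class_labels:
            k = data.n - data.class_size(cls)
            upper = max_length_bound(data.d, k).upper
            rules = sequential_cover(data, cls, small_cfg,
                                     rng=np.random.default_rng(8))
            assert all(1 <= r.length <= upper for r in rules)

    def test_coverage_stop_zero_gives_no_rules(self, case_a_dataset):
        cfg = GPConfig(coverage_stop=0.0)
        assert sequential_cover(case_a_dataset, 1, cfg) == []

    def test_uncovered_strictly_decreases(self, case_b_dataset):
        data = case_b_dataset
        cfg = GPConfig(seed=2)
        rules = sequential_cover(data, 0, cfg, rng=np.random.default_rng(2))
        uncovered = data.class_mask(0)
        for r in rules:
            newly = r.covers_matrix(data.X) & uncovered
            assert newly.any()
            uncovered &= ~newly

    def test_terminates_at_max_rules(self, overlap_dataset):
        import dataclasses
        cfg = GPConfig(population_size=20, generations=5, seed=0,
                       max_rules_per_class=3, min_rule_precision=0.0,
                       coverage_stop=1.0)
        rules = sequential_cover(overlap_dataset, 0, cfg,
                                 rng=np.random.default_rng(0))
        assert len(rules) <= 3


class TestGPConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = GPConfig(population_size=42, seed=3, length_bound_mode="strict_2d")
        path = tmp_path / "cfg.yaml"
        path.write_text(cfg.to_yaml())
        assert GPConfig.from_yaml(str(path)) == cfg

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            GPConfig(crossover_prob=1.5)

    def test_length_bound_modes(self):
        assert GPConfig(length_bound_mode="strict_2d").upper_length(3, 50) == 6
        assert GPConfig(length_bound_mode="kd").upper_length(3, 50) == 150
        assert GPConfig(length_bound_mode="7").upper_length(3, 50) == 7
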