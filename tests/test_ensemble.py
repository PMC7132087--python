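"""Three-component ensemble: dispatch, intersection handling, evaluation."""

import numpy as np
import pytest

from rulegp import (
    AMBIGUOUS,
    UNKNOWN,
    Dataset,
    EnsembleModel,
    GPConfig,
    Literal,
    Op,
    Rule,
    RuleClassifier,
    boundary_depth,
    build_ensemble,
    evaluate,
    load_model,
    predict,
    predict_dbc,
    predict_ic,
    predict_mc,
    save_model,
    trivial_classifier,
)
from conftest import grid_intersect_oracle


def manual_model() -> EnsembleModel:
    """Hand-built two-class model on [0,10]^2.

    Class 0 owns the left half-plane (x <= 5), class 1 the horizontal
    band (y in [4, 6]); they overlap in the left part of the band.
    """
    r0 = Rule([Literal(0, Op.LE, 5.0)], 0)
    r1 = Rule([Literal(1, Op.GE, 4.0), Literal(1, Op.LE, 6.0)], 1)
    mc = RuleClassifier(rules_by_class={0: [r0], 1: [r1]}, classes=[0, 1])
    return EnsembleModel(
        mc=mc, intersections=[(r0, r1)],
        dbc_centroids={0: np.array([2.0, 2.0]), 1: np.array([8.0, 8.0])},
        training_domain=[(0.0, 10.0), (0.0, 10.0)], cfg=GPConfig())


class TestPredictMC:
    def test_unique_fire(self):
        assert predict_mc(manual_model(), (2.0, 1.0)) == 0

    def test_ambiguous_in_overlap(self):
        assert predict_mc(manual_model(), (2.0, 5.0)) == AMBIGUOUS

    def test_unknown_outside_all_rules(self):
        assert predict_mc(manual_model(), (8.0, 1.0)) == UNKNOWN

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_mc(manual_model(), (1.0,))


class TestBoundaryDepth:
    def test_midpoint_depth(self):
        rule = Rule([Literal(0, Op.GE, 1.0), Literal(0, Op.LE, 3.0)], 1)
        assert boundary_depth(rule, (2.0,)) == 1.0

    def test_on_boundary_is_zero(self):
        rule = Rule([Literal(0, Op.GE, 1.0), Literal(0, Op.LE, 3.0)], 1)
        assert boundary_depth(rule, (1.0,)) == 0.0

    def test_unconstrained_attribute_ignored(self):
        rule = Rule([Literal(0, Op.GE, 1.0)], 1)
        assert boundary_depth(rule, (2.0, 99.0)) == 1.0

    def test_uncovered_pattern_rejected(self):
        rule = Rule([Literal(0, Op.GE, 1.0)], 1)
        with pytest.raises(ValueError):
            boundary_depth(rule, (0.0,))


class TestPredictIC:
    def test_deeper_rule_wins(self):
        model = manual_model()
        # (1, 5): depth in r0 = 4 (x: 5-1), depth in r1 = 1 (y: 5-4 = 6-5)
        assert predict_ic(model, (1.0, 5.0)) == 0
        # (4.9, 5): depth in r0 = 0.1, depth in r1 = 1 -> class 1
        assert predict_ic(model, (4.9, 5.0)) == 1

    def test_tie_broken_by_shorter_rule(self):
        # both rules contain (2, 5) at equal depth 1; r_short has 1 literal
        r_short = Rule([Literal(0, Op.GE, 1.0)], 0)  # depth 1 at x=2
        r_long = Rule([Literal(1, Op.GE, 4.0), Literal(1, Op.LE, 6.0)], 1)
        mc = RuleClassifier(rules_by_class={0: [r_short], 1: [r_long]},
                            classes=[1, 0])  # declared order favors 1
        model = EnsembleModel(mc=mc, intersections=[],
                              dbc_centroids={0: np.zeros(2), 1: np.ones(2)},
                              training_domain=[(0, 10), (0, 10)],
                              cfg=GPConfig())
        assert predict_ic(model, (2.0, 5.0)) == 0  # shorter rule wins the tie

    def test_final_tie_uses_class_order(self):
        ra = Rule([Literal(0, Op.GE, 1.0)], "a")
        rb = Rule([Literal(0, Op.GE, 1.0)], "b")
        mc = RuleClassifier(rules_by_class={"b": [rb], "a": [ra]},
                            classes=["b", "a"])
        model = EnsembleModel(mc=mc, intersections=[],
                              dbc_centroids={"a": np.zeros(1), "b": np.ones(1)},
                              training_domain=[(0, 10)], cfg=GPConfig())
        assert predict_ic(model, (2.0,)) == "b"

    def test_rejects_non_ambiguous(self):
        with pytest.raises(ValueError):
            predict_ic(manual_model(), (2.0, 1.0))


class TestPredictDbC:
    def test_nearest_centroid(self):
        model = manual_model()
        assert predict_dbc(model, (2.0, 2.0)) == 0  # exactly at centroid
        assert predict_dbc(model, (9.0, 9.0)) == 1

    def test_tie_goes_to_first_declared_class(self):
        model = manual_model()
        assert predict_dbc(model, (5.0, 5.0)) == 0  # equidistant

    def test_simple_distance(self):
        model = manual_model()
        # centroids (2,2) and (8,8); (3,3) is nearer (2,2)
        assert predict_dbc(model, (3.0, 3.0)) == 0


class TestDispatch:
    def test_total_on_grid(self):
        model = manual_model()
        xs = np.linspace(0, 10, 50)
        for x in xs:
            for y in xs:
                assert predict(model, (x, y)) in (0, 1)

    def test_dispatch_matches_components(self):
        model = manual_model()
        assert predict(model, (2.0, 1.0)) == predict_mc(model, (2.0, 1.0))
        assert predict(model, (8.0, 1.0)) == predict_dbc(model, (8.0, 1.0))
        assert predict(model, (2.0, 5.0)) == predict_ic(model, (2.0, 5.0))

    def test_class_without_rules_goes_to_dbc_not_ic(self):
        model = manual_model()
        model.mc.rules_by_class[1] = []
        # patterns of the now-ruleless class fall to UNKNOWN -> DbC
        assert predict_mc(model, (8.0, 5.0)) == UNKNOWN
        assert predict(model, (8.0, 5.0)) == predict_dbc(model, (8.0, 5.0))


class TestBuildEnsemble:
    def test_case_a_separable(self, case_a_dataset):
        model = build_ensemble(case_a_dataset, GPConfig(seed=3))
        assert all(1 <= len(r) <= 2 for r in model.mc.rules_by_class.values())
        assert model.intersections == []
        report = evaluate(model, case_a_dataset)
        assert report.accuracy == 100.0
        assert report.intersection_pattern_count == 0

    def test_centroids_are_class_means(self, case_a_dataset):
        model = build_ensemble(case_a_dataset, GPConfig(seed=3))
        data = case_a_dataset
        for cls in data.class_labels:
            np.testing.assert_allclose(
                model.dbc_centroids[cls], data.X[data.class_mask(cls)].mean(axis=0))

    def test_overlap_fixture_has_intersections(self, overlap_dataset):
        model = build_ensemble(overlap_dataset, GPConfig(seed=1))
        assert len(model.intersections) >= 1
        for ra, rb in model.intersections:
            assert ra.class_label != rb.class_label
            assert grid_intersect_oracle(ra, rb, model.training_domain)

    def test_intersection_list_matches_oracle(self, overlap_dataset):
        model = build_ensemble(overlap_dataset, GPConfig(seed=1))
        listed = {(str(a), str(b)) for a, b in model.intersections}
        classes = model.classes
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                for ra in model.mc.rules_by_class[ca]:
                    for rb in model.mc.rules_by_class[cb]:
                        expect = grid_intersect_oracle(
                            ra, rb, model.training_domain)
                        assert ((str(ra), str(rb)) in listed) == expect

    def test_single_class_rejected(self):
        data = Dataset(X=[[0.0], [1.0]], y=[1, 1], attribute_names=["a0"],
                       class_labels=[1])
        with pytest.raises(ValueError):
            build_ensemble(data, GPConfig())


class TestEvaluate:
    def test_complementary_paths_partition_test_set(self, overlap_dataset):
        model = build_ensemble(overlap_dataset, GPConfig(seed=4))
        report = evaluate(model, overlap_dataset)
        assert (report.intersection_pattern_count
                + report.unknown_pattern_count) <= report.n_test
        assert 0.0 <= report.accuracy <= 100.0

    def test_trivial_classifier_memorizes_training_set(self, case_c_dataset):
        data = case_c_dataset
        rules = {cls: trivial_classifier(data, cls)
                 for cls in data.class_labels}
        mc = RuleClassifier(rules_by_class=rules, classes=data.class_labels)
        centroids = {cls: data.X[data.class_mask(cls)].mean(axis=0)
                     for cls in data.class_labels}
        model = EnsembleModel(mc=mc, intersections=[],
                              dbc_centroids=centroids,
                              training_domain=data.domain(), cfg=GPConfig())
        assert evaluate(model, data).accuracy == 100.0

    def test_unseen_class_rejected(self, case_a_dataset):
        model = build_ensemble(case_a_dataset, GPConfig(seed=3))
        bad = Dataset(X=[[1.0, 1.0], [2.0, 2.0]], y=[0, "mystery"],
                      attribute_names=["x", "y"], class_labels=[0, "mystery"])
        with pytest.raises(ValueError):
            evaluate(model, bad)

    def test_report_table_lists_key_metrics(self, case_a_dataset):
        model = build_ensemble(case_a_dataset, GPConfig(seed=3))
        table = evaluate(model, case_a_dataset).to_table()
        for key in ("accuracy_pct", "rules_total", "intersection_patterns",
                    "unknown_patterns"):
            assert key in table


class TestSerialization:
    def test_round_trip(self, tmp_path, case_a_dataset):
        model = build_ensemble(case_a_dataset, GPConfig(seed=3))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.classes == model.classes
        for cls in model.classes:
            assert ([str(r) for r in back.mc.rules_by_class[cls]]
                    == [str(r) for r in model.mc.rules_by_class[cls]])
            np.testing.assert_allclose(back.dbc_centroids[cls],
                                       model.dbc_centroids[cls])
        # predictions survive the round trip
        for row in case_a_dataset.X[:20]:
            assert predict(back, row) == predict(model, row)

    def test_identical_seeds_give_identical_bytes(self, tmp_path,
                                                  case_a_dataset):
        payloads = []
        for run in range(2):
            model = build_ensemble(case_a_dataset, GPConfig(seed=11))
            out = tmp_path / f"run{run}"
            save_model(model, out)
            payloads.append((out / "rules.txt").read_bytes()
                            + (out / "model.json").read_bytes())
        assert payloads[0] == payloads[1]
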