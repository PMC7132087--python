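"""Reproducible benchmark suites over the synthetic geometries.

Each function re-runs a piece of the method from scratch under seeded
conditions and returns plain numbers: worked-example counts from the
planar rule-generalization analysis, rule-length-bound compliance over
many random fixtures, agreement of the analytic intersection test with
a dense sampling oracle, the trivial classifier's structure, threshold
and accuracy recovery on separable geometries, prediction totality,
and byte-level determinism.  The acceptance script and the acceptance
tests both drive these functions.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .core import Literal, Op, Rule, max_length_bound, rules_intersect, \
    trivial_classifier, rule_covers
from .data import Dataset, stratified_split
from .ensemble import (
    AMBIGUOUS,
    UNKNOWN,
    build_ensemble,
    evaluate,
    predict,
    predict_mc,
    save_model,
)
from .fixtures import (
    FixtureSpec,
    make_box,
    make_case_a,
    make_case_b,
    make_case_c,
    make_overlap,
)
from .search import GPConfig, evolve_rule, sequential_cover

_INTERVAL_OPS = (Op.LT, Op.LE, Op.GT, Op.GE)

#: Reduced GP budget for the many-fixture bound suite.
SMALL_CFG = GPConfig(population_size=30, generations=15)


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1_000_003 + offset) % (2**31 - 1)


# -------------------------------------------------------------------------
# Worked examples from the planar generalization analysis
# -------------------------------------------------------------------------

def most_general_rule_length(seed: int) -> int:
    """Literals in the rule evolved for the line-separable planar case.

    A single threshold literal (a half-plane) suffices there, the most
    general rule the plane admits.
    """
    data = make_case_a(FixtureSpec(case="A", n_per_class=100, margin=0.5,
                                   seed=_sub_seed(seed, 1)))
    cfg = replace(GPConfig(), seed=_sub_seed(seed, 2))
    rule, _ = evolve_rule(data, 1, cfg, rng=np.random.default_rng(cfg.seed))
    return rule.length


def least_general_generalizing_length(d: int = 2, k: int = 6) -> int:
    """Length of the least general generalizing rule: the hyperrectangle,
    i.e. the lower end of the [2d, kd] bound."""
    return max_length_bound(d, k).lower


def case_c_rule_count(seed: int) -> int:
    """Rules the covering loop needs for the outer class of the
    horizontal-band geometry (nominally the two threshold rules
    y <= y1 and y >= y2)."""
    data = make_case_c(FixtureSpec(case="C", n_per_class=50, margin=0.5,
                                   seed=_sub_seed(seed, 3),
                                   thresholds={"n_band": 20}))
    cfg = replace(GPConfig(), seed=_sub_seed(seed, 4))
    rules = sequential_cover(data, 0, cfg, rng=np.random.default_rng(cfg.seed))
    return len(rules)


def observed_component_count(seed: int, grid_n: int = 50) -> int:
    """Distinct classifier components exercised over a dense grid.

    Trains on the crossing-bars geometry (whose rules genuinely
    intersect) and dispatches every grid node; counts how many of the
    {unique-rule, intersection, distance-fallback} paths actually fire.
    Bars of half-width 0.25 at 120 patterns per class keep each bar
    rule's precision comfortably above the acceptance threshold, so
    both classes reliably contribute a rule and the central overlap
    exists.
    """
    data = make_overlap(FixtureSpec(case="A", n_per_class=120,
                                    seed=_sub_seed(seed, 5),
                                    thresholds={"half_width": 0.25}))
    cfg = replace(GPConfig(), seed=_sub_seed(seed, 6))
    model = build_ensemble(data, cfg)
    paths = set()
    axes = [np.linspace(lo, hi, grid_n) for lo, hi in model.training_domain]
    for x in axes[0]:
        for y in axes[1]:
            outcome = predict_mc(model, (x, y))
            paths.add("IC" if outcome == AMBIGUOUS
                      else "DbC" if outcome == UNKNOWN else "MC")
    return len(paths)


# -------------------------------------------------------------------------
# Property suites
# -------------------------------------------------------------------------

_FIXTURE_MAKERS = {
    "A": make_case_a, "B": make_case_b, "C": make_case_c,
    "box": make_box, "overlap": make_overlap,
}


def random_fixture(rng: np.random.Generator) -> Dataset:
    case = ("A", "B", "C", "box", "overlap")[int(rng.integers(5))]
    d = int(rng.integers(2, 4)) if case == "box" else 2
    spec = FixtureSpec(case=case, n_per_class=int(rng.integers(30, 60)),
                       d=d, margin=0.5, seed=int(rng.integers(2**31 - 1)))
    return _FIXTURE_MAKERS[case](spec)


def length_bound_suite(seed: int, n_fixtures: int = 50,
                       cfg: GPConfig = SMALL_CFG) -> dict:
    """Induce rules on many random fixtures; count length-bound breaches.

    Every rule must satisfy ``1 <= length <= max(2d, kd)`` with ``k``
    the size of the class opposite the one being learned.
    """
    rng = np.random.default_rng(_sub_seed(seed, 10))
    n_rules = 0
    violations = 0
    for _ in range(n_fixtures):
        data = random_fixture(rng)
        for cls in data.class_labels:
            k = data.n - data.class_size(cls)
            upper = max_length_bound(data.d, k).upper
            run_cfg = replace(cfg, seed=int(rng.integers(2**31 - 1)))
            rules = sequential_cover(data, cls, run_cfg,
                                     rng=np.random.default_rng(run_cfg.seed))
            n_rules += len(rules)
            violations += sum(not 1 <= r.length <= upper for r in rules)
    return {"violations": violations, "n_rules": n_rules}


def grid_intersect_oracle(a: Rule, b: Rule, domain, n: int = 100) -> bool:
    """Sampling cross-check for the analytic intersection test.

    Evaluates both rules on an ``n``-per-axis grid refined with each
    literal threshold and its immediate neighborhood, so axis-aligned
    overlaps of any width are sampled.
    """
    eps = 1e-9
    axes = []
    for j, (lo, hi) in enumerate(domain):
        vals = list(np.linspace(lo, hi, n))
        for lit in (*a.literals, *b.literals):
            if lit.attr_index == j:
                vals.extend([lit.threshold - eps, lit.threshold,
                             lit.threshold + eps])
        axes.append(np.unique(np.clip(vals, lo, hi)))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    return bool((a.covers_matrix(pts) & b.covers_matrix(pts)).any())


def _random_rule(rng: np.random.Generator, d: int, label) -> Rule:
    n_lits = int(rng.integers(1, 5))
    lits = [Literal(int(rng.integers(d)),
                    _INTERVAL_OPS[int(rng.integers(4))],
                    float(np.round(rng.uniform(0, 10), 2)))
            for _ in range(n_lits)]
    return Rule(lits, label)


def intersection_oracle_suite(seed: int, n_pairs: int = 200) -> dict:
    """Analytic intersection vs grid oracle on random planar rule pairs,
    plus the ensemble's enumerated intersection list on planar fixtures."""
    rng = np.random.default_rng(_sub_seed(seed, 20))
    domain = [(0.0, 10.0), (0.0, 10.0)]
    agree = sum(
        rules_intersect(a, b, domain) == grid_intersect_oracle(a, b, domain)
        for a, b in ((_random_rule(rng, 2, 0), _random_rule(rng, 2, 1))
                     for _ in range(n_pairs)))

    ensemble_ok = True
    for maker_seed, maker in ((21, make_case_a), (22, make_overlap)):
        data = maker(FixtureSpec(case="A", n_per_class=60, margin=0.5,
                                 seed=_sub_seed(seed, maker_seed)))
        cfg = replace(GPConfig(), seed=_sub_seed(seed, maker_seed + 10))
        model = build_ensemble(data, cfg)
        listed = {(str(a), str(b)) for a, b in model.intersections}
        classes = model.classes
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                for ra in model.mc.rules_by_class[ca]:
                    for rb in model.mc.rules_by_class[cb]:
                        oracle = grid_intersect_oracle(
                            ra, rb, model.training_domain)
                        if ((str(ra), str(rb)) in listed) != oracle:
                            ensemble_ok = False
    return {"agreements": agree, "n_pairs": n_pairs,
            "ensemble_matches_oracle": ensemble_ok}


def trivial_classifier_suite(seed: int) -> dict:
    """Structure and training recall of the maximally-overfit rule set."""
    rng = np.random.default_rng(_sub_seed(seed, 30))
    checked = 0
    structure_ok = True
    recalled = 0
    total = 0
    for _ in range(5):
        data = random_fixture(rng)
        for cls in data.class_labels:
            rules = trivial_classifier(data, cls)
            size = data.class_size(cls)
            structure_ok &= len(rules) == size
            structure_ok &= all(r.length == data.d for r in rules)
            X_cls = data.X[data.class_mask(cls)]
            recalled += sum(any(rule_covers(r, row) for r in rules)
                            for row in X_cls)
            total += size
            checked += 1
    return {"structure_ok": structure_ok, "n_classifiers": checked,
            "recall_pct": 100.0 * recalled / total}


def case_a_recovery_suite(seed: int, n_seeds: int = 10) -> dict:
    """Train/test recovery on the line-separable case.

    n=100 per class, margin 0.5; success = test accuracy >= 95 % with
    at most 2 rules per class.
    """
    successes = 0
    accuracies = []
    for i in range(n_seeds):
        s = _sub_seed(seed, 40 + i)
        data = make_case_a(FixtureSpec(case="A", n_per_class=100, margin=0.5,
                                       seed=s))
        train, test = stratified_split(data, 0.3, seed=s)
        cfg = replace(GPConfig(), seed=s)
        model = build_ensemble(train, cfg)
        report = evaluate(model, test)
        accuracies.append(report.accuracy)
        max_rules = max(len(r) for r in model.mc.rules_by_class.values())
        successes += report.accuracy >= 95.0 and max_rules <= 2
    return {"successes": successes, "n_seeds": n_seeds,
            "mean_accuracy_pct": float(np.mean(accuracies))}


def box_recovery_suite(seed: int, n_seeds: int = 10) -> dict:
    """Face recovery on the 3-D box geometry.

    n=220 per class so each face is identifiable: the slab of
    outside samples adjacent to a given face is a small fraction of
    the outside volume, and roughly ten boundary-relevant samples per
    face are needed to pin it within the margin.  Success = every
    learned threshold of the inside class within the margin of a true
    face of its attribute.
    """
    faces = [(3.0, 7.0)] * 3
    margin = 0.5
    successes = 0
    for i in range(n_seeds):
        s = _sub_seed(seed, 60 + i)
        data = make_box(FixtureSpec(case="box", n_per_class=220, d=3,
                                    margin=margin, seed=s))
        cfg = replace(GPConfig(), seed=s)
        rules = sequential_cover(data, 1, cfg, rng=np.random.default_rng(s))
        ok = bool(rules)
        for rule in rules:
            for lit in rule.literals:
                lo, hi = faces[lit.attr_index]
                if not (abs(lit.threshold - lo) <= margin
                        or abs(lit.threshold - hi) <= margin):
                    ok = False
        successes += ok
    return {"successes": successes, "n_seeds": n_seeds}


def totality_suite(seed: int, grid_n: int = 50) -> dict:
    """Dispatch must label every node of a dense grid over the domain."""
    data = make_overlap(FixtureSpec(case="A", n_per_class=60,
                                    seed=_sub_seed(seed, 80)))
    cfg = replace(GPConfig(), seed=_sub_seed(seed, 81))
    model = build_ensemble(data, cfg)
    axes = [np.linspace(lo, hi, grid_n) for lo, hi in model.training_domain]
    labeled = 0
    for x in axes[0]:
        for y in axes[1]:
            if predict(model, (x, y)) in model.classes:
                labeled += 1
    return {"labeled": labeled, "n_nodes": grid_n * grid_n,
            "labeled_pct": 100.0 * labeled / (grid_n * grid_n)}


def determinism_suite(seed: int) -> dict:
    """Two identically-seeded runs must serialize byte-identically."""
    data = make_case_b(FixtureSpec(case="B", n_per_class=50, margin=0.5,
                                   seed=_sub_seed(seed, 90)))
    cfg = replace(GPConfig(), seed=_sub_seed(seed, 91))
    payloads = []
    with tempfile.TemporaryDirectory() as tmp:
        for run in range(2):
            out = Path(tmp) / f"run{run}"
            save_model(build_ensemble(data, cfg), out)
            payloads.append((out / "rules.txt").read_bytes()
                            + (out / "model.json").read_bytes())
    return {"identical": payloads[0] == payloads[1]}
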