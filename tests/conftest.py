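"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rulegp import (
    FixtureSpec,
    GPConfig,
    Literal,
    Op,
    Rule,
    make_case_a,
    make_case_b,
    make_case_c,
    make_overlap,
    rule_covers,
)

INTERVAL_OPS = (Op.LT, Op.LE, Op.GT, Op.GE)


def grid_intersect_oracle(a: Rule, b: Rule, domain, n: int = 100,
                          refine: bool = True) -> bool:
    """Dense grid sampling: do the two rules cover a common point?

    Independent of the analytic interval-intersection test — it just
    evaluates both rules at every node of a grid with ``n`` points per
    axis.  With ``refine`` the grid axes additionally include every
    literal threshold and its immediate neighborhood, so overlaps
    thinner than the base grid spacing are still sampled.
    """
    eps = 1e-9
    axes = []
    for j, (lo, hi) in enumerate(domain):
        vals = list(np.linspace(lo, hi, n))
        if refine:
            for lit in (*a.literals, *b.literals):
                if lit.attr_index == j:
                    t = lit.threshold
                    vals.extend([t - eps, t, t + eps])
        axes.append(np.unique(np.clip(vals, lo, hi)))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    mask = a.covers_matrix(pts) & b.covers_matrix(pts)
    return bool(mask.any())


def random_interval_rule(rng: np.random.Generator, d: int, label=1,
                         max_len: int = 4, lo: float = 0.0,
                         hi: float = 10.0) -> Rule:
    """A random conjunction of interval literals over [lo, hi]^d."""
    n_lits = int(rng.integers(1, max_len + 1))
    lits = [Literal(int(rng.integers(d)),
                    INTERVAL_OPS[int(rng.integers(4))],
                    float(np.round(rng.uniform(lo, hi), 2)))
            for _ in range(n_lits)]
    return Rule(lits, label)


@pytest.fixture(scope="session")
def small_cfg() -> GPConfig:
    """A reduced GP budget for the many-run suites."""
    return GPConfig(population_size=30, generations=15, seed=0)


@pytest.fixture(scope="session")
def case_a_dataset():
    return make_case_a(FixtureSpec(case="A", n_per_class=50, margin=0.5, seed=7))


@pytest.fixture(scope="session")
def case_b_dataset():
    return make_case_b(FixtureSpec(case="B", n_per_class=50, margin=0.5, seed=8))


@pytest.fixture(scope="session")
def case_c_dataset():
    return make_case_c(FixtureSpec(case="C", n_per_class=50, margin=0.5, seed=9))


@pytest.fixture(scope="session")
def overlap_dataset():
    return make_overlap(FixtureSpec(case="A", n_per_class=60, seed=21))
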