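"""Genetic-programming rule search inside a sequential-covering loop.

One rule is evolved at a time for a target class.  Fitness rewards
discrimination (sensitivity x specificity) and penalizes long rules and
``!=`` literals, encoding the two generalization pressures: the fewer
the literals the more general the rule, and puncture literals shrink
coverage toward memorized points.  Rule length is capped by the
``[2d, kd]`` bound, where ``k`` is the size of the class opposite the
one being learned.  The covering loop accepts a rule, removes the
target patterns it covers, and searches again until the class is
(almost) covered.

Because rules are pure conjunctions, candidates are represented as flat
literal lists rather than expression trees; crossover exchanges literal
sublists and mutation perturbs thresholds, flips operators, or
adds/drops literals.  A hill-climbing local search over candidate
thresholds refines the final rule of each GP run.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import yaml

from .core import (
    EQ_ATOL,
    INTERVAL_OPS,
    Literal,
    Op,
    Rule,
    max_length_bound,
    simplify_rule,
)
from .data import Dataset

__all__ = ["GPConfig", "FitnessReport", "candidate_thresholds", "fitness",
           "init_population", "crossover", "mutate", "local_search",
           "evolve_rule", "sequential_cover"]


@dataclass(frozen=True)
class GPConfig:
    """Tunable parameters of the evolutionary rule search.

    ``length_bound_mode`` selects the rule-length cap: ``"kd"`` uses the
    full interval upper bound ``max(2d, kd)``, ``"strict_2d"`` forces
    the maximally general hyperrectangle cap ``2d``, and an integer
    string fixes a custom cap.  ``allow_eq``/``allow_ne`` control which
    equality operators the search grammar may emit; ``==`` is off by
    default (it pins single values and overfits), ``!=`` is allowed but
    penalized through ``ne_penalty_weight``.
    """

    population_size: int = 100
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.3
    tournament_size: int = 3
    length_bound_mode: str = "kd"
    length_penalty_weight: float = 0.05
    ne_penalty_weight: float = 0.2
    min_rule_precision: float = 0.9
    coverage_stop: float = 0.98
    max_rules_per_class: int = 10
    seed: int = 0
    allow_eq: bool = False
    allow_ne: bool = True
    eq_atol: float = EQ_ATOL
    dbc_k_neighbors: int = 0  # 0 = class centroids; k >= 1 = k-NN fallback

    def __post_init__(self) -> None:
        for name in ("population_size", "generations", "tournament_size",
                     "max_rules_per_class"):
            if getattr(self, name) < (0 if name == "generations" else 1):
                raise ValueError(f"{name} must be positive")
        for name in ("crossover_prob", "mutation_prob", "min_rule_precision",
                     "coverage_stop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ne_penalty_weight < 0 or self.length_penalty_weight < 0:
            raise ValueError("penalty weights must be >= 0")
        mode = self.length_bound_mode
        if mode not in ("kd", "strict_2d") and not str(mode).isdigit():
            raise ValueError(
                "length_bound_mode must be 'kd', 'strict_2d', or an integer")

    def upper_length(self, d: int, k: int) -> int:
        """Resolve the active maximum rule length for dimension/opponent size."""
        bound = max_length_bound(d, max(k, 1))
        if self.length_bound_mode == "strict_2d":
            return bound.lower
        if self.length_bound_mode == "kd":
            return bound.upper
        return max(1, int(self.length_bound_mode))

    def to_yaml(self) -> str:
        """Flat key/value serialization of the configuration."""
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_path) -> "GPConfig":
        if hasattr(text_or_path, "read"):
            raw = yaml.safe_load(text_or_path)
        else:
            text = str(text_or_path)
            if "\n" not in text and not text.strip().startswith("{"):
                try:
                    with open(text, encoding="utf-8") as fh:
                        raw = yaml.safe_load(fh)
                except FileNotFoundError:
                    raw = yaml.safe_load(text)
            else:
                raw = yaml.safe_load(text)
        return cls(**(raw or {}))


@dataclass(frozen=True)
class FitnessReport:
    """Confusion counts and the penalized discrimination score of a rule."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    length_penalty: float
    score: float


def candidate_thresholds(data: Dataset, attr: int) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values of an attribute.

    These are the only threshold positions that change coverage on the
    training set; a constant attribute yields an empty list.
    """
    if attr >= data.d:
        raise IndexError(f"attribute {attr} out of range for d={data.d}")
    vals = np.unique(data.X[:, attr])
    if len(vals) < 2:
        return np.empty(0)
    return (vals[:-1] + vals[1:]) / 2.0


def _counts(rule: Rule, X: np.ndarray, target_mask: np.ndarray,
            atol: float) -> tuple[int, int, int, int]:
    covered = rule.covers_matrix(X, atol=atol)
    tp = int((covered & target_mask).sum())
    fp = int((covered & ~target_mask).sum())
    fn = int((~covered & target_mask).sum())
    tn = int((~covered & ~target_mask).sum())
    return tp, fp, tn, fn


def fitness(rule: Rule, data: Dataset, target, cfg: GPConfig) -> FitnessReport:
    """Score a rule for one target class.

    ``score = sensitivity * specificity * (1 - penalty)`` clipped to
    ``[0, 1]``, with ``penalty = lambda * (length - 1) / upper_bound +
    w_ne * (#NE literals) / length``.  The score reaches 1 only when the
    rule covers every target pattern and nothing else with zero
    penalties.
    """
    target_mask = data.class_mask(target)
    if not target_mask.any():
        raise ValueError(f"target class {target!r} not present")
    tp, fp, tn, fn = _counts(rule, data.X, target_mask, cfg.eq_atol)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    k = int((~target_mask).sum())
    upper = cfg.upper_length(data.d, k)
    n_ne = sum(1 for lit in rule.literals if lit.op is Op.NE)
    penalty = 0.0
    if rule.length > 0:
        penalty = (cfg.length_penalty_weight * (rule.length - 1) / upper
                   + cfg.ne_penalty_weight * n_ne / rule.length)
    score = float(np.clip(sens * spec * (1.0 - penalty), 0.0, 1.0))
    return FitnessReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                         specificity=spec, length_penalty=penalty, score=score)


class _Evaluator:
    """Caches fitness scores and candidate thresholds for one GP run."""

    def __init__(self, data: Dataset, target, cfg: GPConfig):
        self.data = data
        self.target = target
        self.cfg = cfg
        self.target_mask = data.class_mask(target)
        self.k = int((~self.target_mask).sum())
        self.upper = cfg.upper_length(data.d, max(self.k, 1))
        self.candidates = [candidate_thresholds(data, j) for j in range(data.d)]
        self._cache: dict = {}

    def report(self, rule: Rule) -> FitnessReport:
        key = (rule.literals,)
        hit = self._cache.get(key)
        if hit is None:
            hit = fitness(rule, self.data, self.target, self.cfg)
            self._cache[key] = hit
        return hit

    def score(self, rule: Rule) -> float:
        return self.report(rule).score


def _random_literal_for(pattern: np.ndarray, attr: int, cands: np.ndarray,
                        cfg: GPConfig, rng: np.random.Generator) -> Optional[Literal]:
    """A random literal on ``attr`` guaranteed to cover ``pattern``."""
    x = float(pattern[attr])
    ops = list(INTERVAL_OPS)
    if cfg.allow_ne:
        ops.append(Op.NE)
    if cfg.allow_eq:
        ops.append(Op.EQ)
    rng.shuffle(ops)
    for op in ops:
        if op is Op.EQ:
            return Literal(attr, Op.EQ, x)
        if len(cands) == 0:
            continue
        if op in (Op.GE, Op.GT):
            ok = cands[cands < x] if op is Op.GT else cands[cands <= x]
        elif op in (Op.LE, Op.LT):
            ok = cands[cands > x] if op is Op.LT else cands[cands >= x]
        else:  # NE: any candidate clear of the pattern value
            ok = cands[np.abs(cands - x) > cfg.eq_atol]
        if len(ok):
            return Literal(attr, op, float(rng.choice(ok)))
    return None


def init_population(data: Dataset, target, cfg: GPConfig,
                    rng: Optional[np.random.Generator] = None) -> list[Rule]:
    """Seeded initial population.

    Each rule starts from a randomly drawn target-class pattern and
    carries 1-4 literals on random attributes, with thresholds chosen
    from the candidate grid so the seed pattern stays covered.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(data, target, cfg)
    target_idx = np.flatnonzero(ev.target_mask)
    if len(target_idx) == 0:
        raise ValueError(f"target class {target!r} is empty")
    pop = []
    for _ in range(cfg.population_size):
        seed_row = data.X[rng.choice(target_idx)]
        n_lits = min(int(rng.integers(1, 5)), ev.upper)
        lits = []
        for _ in range(n_lits):
            attr = int(rng.integers(data.d))
            lit = _random_literal_for(seed_row, attr, ev.candidates[attr], cfg, rng)
            if lit is not None:
                lits.append(lit)
        if not lits:  # all attributes constant: pin the seed pattern
            lits = [Literal(0, Op.LE, float(seed_row[0]))]
        rule = simplify_rule(Rule(lits, target), atol=cfg.eq_atol)
        pop.append(_truncate(rule, ev.upper))
    return pop


def _truncate(rule: Rule, upper: int) -> Rule:
    if rule.length <= upper:
        return rule
    return Rule(rule.literals[:upper], rule.class_label)


def crossover(a: Rule, b: Rule, rng: np.random.Generator,
              upper: int = 10**9, atol: float = EQ_ATOL) -> tuple[Rule, Rule]:
    """One-point exchange of literal sublists.

    Children are truncated from the tail if they exceed the length
    bound, then simplified.
    """
    cut = int(rng.integers(0, max(a.length, b.length) + 1))
    c1 = Rule(a.literals[:cut] + b.literals[cut:], a.class_label)
    c2 = Rule(b.literals[:cut] + a.literals[cut:], b.class_label)
    c1 = _truncate(simplify_rule(c1, atol=atol), upper)
    c2 = _truncate(simplify_rule(c2, atol=atol), upper)
    return c1, c2


def mutate(rule: Rule, data: Dataset, cfg: GPConfig,
           rng: np.random.Generator,
           candidates: Optional[list[np.ndarray]] = None,
           upper: Optional[int] = None) -> Rule:
    """Apply one uniformly chosen edit and simplify.

    Moves: shift a threshold to an adjacent candidate, flip an operator
    within ``{<, <=, >, >=}``, add a random literal (below the bound),
    or drop a literal (above length 1).
    """
    if candidates is None:
        candidates = [candidate_thresholds(data, j) for j in range(data.d)]
    if upper is None:
        upper = cfg.upper_length(data.d, max(data.n - 1, 1))
    moves = ["perturb", "flip"]
    if rule.length < upper:
        moves.append("add")
    if rule.length > 1:
        moves.append("drop")
    move = moves[int(rng.integers(len(moves)))]
    lits = list(rule.literals)

    if move == "drop":
        del lits[int(rng.integers(len(lits)))]
    elif move == "add":
        attr = int(rng.integers(data.d))
        cands = candidates[attr]
        ops = list(INTERVAL_OPS) + ([Op.NE] if cfg.allow_ne else []) \
            + ([Op.EQ] if cfg.allow_eq else [])
        op = ops[int(rng.integers(len(ops)))]
        if len(cands):
            lits.append(Literal(attr, op, float(rng.choice(cands))))
        # constant attribute: no candidate thresholds, mutation is a no-op
    elif lits:
        i = int(rng.integers(len(lits)))
        lit = lits[i]
        if move == "flip" and lit.op in INTERVAL_OPS:
            others = [op for op in INTERVAL_OPS if op is not lit.op]
            lits[i] = Literal(lit.attr_index, others[int(rng.integers(3))],
                              lit.threshold)
        elif move == "perturb":
            cands = candidates[lit.attr_index]
            if len(cands):
                pos = int(np.searchsorted(cands, lit.threshold))
                step = -1 if rng.random() < 0.5 else 1
                new_pos = int(np.clip(pos + step, 0, len(cands) - 1))
                lits[i] = Literal(lit.attr_index, lit.op, float(cands[new_pos]))
    if not lits:
        return rule
    return _truncate(simplify_rule(Rule(lits, rule.class_label),
                                   atol=cfg.eq_atol), upper)


def local_search(rule: Rule, data: Dataset, target, cfg: GPConfig,
                 _ev: Optional[_Evaluator] = None) -> Rule:
    """Greedy refinement of one rule over the candidate-threshold grid.

    Three kinds of strictly-improving moves are applied until none
    helps: (1) re-optimize each interval literal's threshold over all
    candidates (vectorized confusion counts); (2) drop a literal whose
    removal does not hurt discrimination (the length penalty then makes
    the shorter rule strictly better); (3) add the single best new
    interval literal when it pays for its length penalty (this is what
    completes a missing face of a box-shaped class).  The returned
    score is never below the input score.

    A final fitness-neutral pass re-centers every interval threshold in
    its data-free gap (see :func:`_max_margin_thresholds`), which
    leaves the confusion counts untouched but makes the decision
    boundary canonical and robust to where unseen patterns fall inside
    the gap.
    """
    ev = _ev if _ev is not None else _Evaluator(data, target, cfg)
    best = simplify_rule(rule, atol=cfg.eq_atol)
    best_score = ev.score(best)
    improved = True
    guard = 0
    while improved and guard < 1_000:
        improved = False
        # Move 1: per-literal threshold sweep.
        for i, lit in enumerate(best.literals):
            if lit.op not in INTERVAL_OPS:
                continue
            cands = ev.candidates[lit.attr_index]
            if len(cands) == 0:
                continue
            others = Rule([l for j, l in enumerate(best.literals) if j != i],
                          best.class_label)
            relevant = others.covers_matrix(ev.data.X, atol=cfg.eq_atol)
            j = _best_threshold(ev, relevant, lit.attr_index, lit.op)
            lits = list(best.literals)
            lits[i] = Literal(lit.attr_index, lit.op, float(cands[j]))
            trial = Rule(lits, best.class_label)
            trial_score = ev.score(trial)
            if trial_score > best_score:
                best, best_score = trial, trial_score
                improved = True
        # Move 2: prune a redundant literal.
        if best.length > 1:
            for i in range(best.length):
                trial = Rule([l for j, l in enumerate(best.literals) if j != i],
                             best.class_label)
                trial_score = ev.score(trial)
                if trial_score > best_score:
                    best, best_score = trial, trial_score
                    improved = True
                    break
        # Move 3: add the best single new interval literal.
        if best.length < ev.upper:
            covered = best.covers_matrix(ev.data.X, atol=cfg.eq_atol)
            add_best = None
            for attr in range(ev.data.d):
                cands = ev.candidates[attr]
                if len(cands) == 0:
                    continue
                for op in (Op.GE, Op.LE):
                    j = _best_threshold(ev, covered, attr, op)
                    trial = Rule(best.literals + (Literal(attr, op, float(cands[j])),),
                                 best.class_label)
                    trial_score = ev.score(trial)
                    if trial_score > best_score and (
                            add_best is None or trial_score > add_best[0]):
                        add_best = (trial_score, trial)
            if add_best is not None:
                best_score, best = add_best
                best = simplify_rule(best, atol=cfg.eq_atol)
                improved = True
        guard += 1
    return _max_margin_thresholds(best, ev)


def _best_threshold(ev: _Evaluator, relevant: np.ndarray, attr: int,
                    op: Op) -> int:
    """Index of the candidate threshold maximizing sensitivity x specificity.

    ``relevant`` masks the patterns satisfying the rest of the rule;
    confusion counts for every candidate come from prefix sums over the
    sorted attribute values, so the sweep is O(n log n).  The length
    penalty does not depend on the threshold, so this ranking is exact.
    """
    cands = ev.candidates[attr]
    col = ev.data.X[relevant, attr]
    pos = ev.target_mask[relevant]
    order = np.argsort(col, kind="stable")
    col_sorted = col[order]
    pos_sorted = pos[order].astype(int)
    cum_pos = np.concatenate([[0], np.cumsum(pos_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(1 - pos_sorted)])
    side = "left" if op in (Op.GE, Op.LT) else "right"
    idx = np.searchsorted(col_sorted, cands, side=side)
    if op in (Op.GE, Op.GT):  # covered: values above the cut
        tp = cum_pos[-1] - cum_pos[idx]
        fp = cum_neg[-1] - cum_neg[idx]
    else:                     # covered: values below the cut
        tp = cum_pos[idx]
        fp = cum_neg[idx]
    n_pos = int(ev.target_mask.sum())
    n_neg = int((~ev.target_mask).sum())
    objective = (tp / n_pos) * ((n_neg - fp) / n_neg) if n_neg else tp / n_pos
    return int(np.argmax(objective))


def _max_margin_thresholds(rule: Rule, ev: _Evaluator) -> Rule:
    """Center each interval threshold in its data-free gap.

    For every ``{<, <=, >, >=}`` literal, the set of thresholds that
    keep the rule's covered-pattern set unchanged is an interval
    bounded by the nearest pattern value the literal keeps and the
    nearest it excludes (among patterns satisfying the other literals).
    The threshold is placed midway between the *estimated support
    edges* of the two sides: each side's edge is its nearest value
    extrapolated outward by one average inter-point spacing (the
    uniform maximum-spacing correction), which removes the bias a raw
    nearest-point midpoint suffers when one side is sparsely sampled.
    The corrected position is clipped to the fitness-neutral interval,
    so the confusion counts never change.  Vacuous literals are left
    untouched.
    """
    rule = simplify_rule(rule, atol=ev.cfg.eq_atol)
    lits = list(rule.literals)
    X = ev.data.X
    # The gap for one literal depends on where the others sit, so the
    # pass is iterated to a fixed point (each update preserves the
    # rule's covered set, hence stays fitness-neutral).
    for _ in range(5):
        changed = False
        for i, lit in enumerate(lits):
            if lit.op not in INTERVAL_OPS:
                continue
            others = Rule([l for j, l in enumerate(lits) if j != i],
                          rule.class_label)
            relevant = others.covers_matrix(X, atol=ev.cfg.eq_atol)
            if not relevant.any():
                continue
            col = X[relevant, lit.attr_index]
            if lit.op in (Op.GE, Op.GT):
                kept_mask = (col >= lit.threshold if lit.op is Op.GE
                             else col > lit.threshold)
            else:
                kept_mask = (col <= lit.threshold if lit.op is Op.LE
                             else col < lit.threshold)
            if kept_mask.all() or not kept_mask.any():
                continue  # vacuous or empty on the relevant set
            kept = col[kept_mask]
            excl = col[~kept_mask]
            lower_side = excl if lit.op in (Op.GE, Op.GT) else kept
            upper_side = kept if lit.op in (Op.GE, Op.GT) else excl
            v_lo, v_hi = float(lower_side.max()), float(upper_side.min())
            # Support-edge extrapolation by one average spacing per side.
            attr_lo = float(X[:, lit.attr_index].min())
            attr_hi = float(X[:, lit.attr_index].max())
            lo_span = (v_lo - float(lower_side.min()) if len(lower_side) > 1
                       else v_lo - attr_lo)
            hi_span = (float(upper_side.max()) - v_hi if len(upper_side) > 1
                       else attr_hi - v_hi)
            lo_edge = v_lo + lo_span / len(lower_side)
            hi_edge = v_hi - hi_span / len(upper_side)
            t = (lo_edge + hi_edge) / 2.0
            # Clip into the open fitness-neutral gap (v_lo, v_hi).
            eps = 1e-12 * max(1.0, abs(v_hi), abs(v_lo))
            t = float(np.clip(t, v_lo + eps, v_hi - eps))
            if t != lit.threshold:
                lits[i] = Literal(lit.attr_index, lit.op, t)
                changed = True
        if not changed:
            break
    return Rule(lits, rule.class_label)


def _tournament(pop: list[Rule], scores: list[float], size: int,
                rng: np.random.Generator) -> Rule:
    idx = rng.integers(0, len(pop), size=size)
    best = max(idx, key=lambda i: (scores[i], -pop[i].length))
    return pop[best]


def evolve_rule(data: Dataset, target, cfg: GPConfig,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[Rule, FitnessReport]:
    """Evolve a single rule for ``target`` with a generational GP.

    Tournament selection, elitism of one, crossover and mutation at the
    configured probabilities; the best individual of the final
    generation is refined by :func:`local_search`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(data, target, cfg)
    pop = init_population(data, target, cfg, rng=rng)
    scores = [ev.score(r) for r in pop]

    for _ in range(cfg.generations):
        elite_i = int(np.argmax(scores))
        nxt = [pop[elite_i]]
        while len(nxt) < cfg.population_size:
            p1 = _tournament(pop, scores, cfg.tournament_size, rng)
            p2 = _tournament(pop, scores, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_prob:
                c1, c2 = crossover(p1, p2, rng, upper=ev.upper, atol=cfg.eq_atol)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if rng.random() < cfg.mutation_prob:
                    child = mutate(child, data, cfg, rng,
                                   candidates=ev.candidates, upper=ev.upper)
                nxt.append(child)
                if len(nxt) >= cfg.population_size:
                    break
        pop = nxt
        scores = [ev.score(r) for r in pop]

    best = pop[int(np.argmax(scores))]
    best = local_search(best, data, target, cfg, _ev=ev)
    best = _truncate(simplify_rule(best, atol=cfg.eq_atol), ev.upper)
    if best.length == 0:
        best = Rule([Literal(0, Op.LE, float(np.max(data.X[:, 0])))], target)
    return best, ev.report(best)


def sequential_cover(data: Dataset, target, cfg: GPConfig,
                     rng: Optional[np.random.Generator] = None) -> list[Rule]:
    """Induce an ordered rule set covering one class.

    Each accepted rule must reach ``min_rule_precision`` on the still
    uncovered data and cover at least one new target pattern; its
    covered target patterns are then removed (negatives are always all
    retained) and the search repeats until the ``coverage_stop``
    fraction of the class is covered, ``max_rules_per_class`` is
    reached, or no acceptable rule is found.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    target_mask = data.class_mask(target)
    if not target_mask.any():
        raise ValueError(f"target class {target!r} is empty")
    n_target = int(target_mask.sum())
    uncovered = target_mask.copy()
    rules: list[Rule] = []

    while len(rules) < cfg.max_rules_per_class:
        covered_frac = 1.0 - uncovered.sum() / n_target
        if covered_frac >= cfg.coverage_stop:
            break
        keep = uncovered | ~target_mask
        sub = data.subset(np.flatnonzero(keep))
        rule, report = evolve_rule(sub, target, cfg, rng=rng)
        precision = (report.tp / (report.tp + report.fp)
                     if report.tp + report.fp else 0.0)
        covers_new = rule.covers_matrix(data.X, atol=cfg.eq_atol) & uncovered
        if precision < cfg.min_rule_precision or not covers_new.any():
            break
        rules.append(rule)
        uncovered &= ~covers_new
    return rules
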