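"""Rule representation and evaluation semantics.

A classification rule is a conjunction of *literals* — single comparison
constraints ``attribute op threshold`` — implying a class label (IF/THEN
form).  Geometrically every rule carves out a region of the pattern space:
literals over ``{<, <=, >, >=}`` intersect half-spaces into (subshapes of)
axis-aligned hyperrectangles, ``==`` pins an attribute to a point, and
``!=`` punctures the region at a single value.  This module provides the
rule algebra: evaluation, the exact region a rule covers, an analytic
rule/rule intersection test, the maximum-rule-length bound ``[2d, kd]``,
the trivial (one-equality-rule-per-pattern) classifier, rule
simplification, and a lossless text serialization.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Op",
    "Literal",
    "Rule",
    "LengthBound",
    "Interval",
    "Region",
    "EQ_ATOL",
    "evaluate_literal",
    "rule_covers",
    "max_length_bound",
    "rule_region",
    "rules_intersect",
    "trivial_classifier",
    "simplify_rule",
    "format_rule",
    "parse_rule",
    "write_rules",
    "read_rules",
]

#: Absolute tolerance for == / != comparisons on continuous attributes.
#: Exact equality on reals is measure-zero; a small band makes the
#: equality operators usable on floating-point data.
EQ_ATOL = 1e-9


class Op(enum.Enum):
    """The six comparison operators a literal may use.

    ``LE``/``GE`` include equality, ``LT``/``GT`` exclude it.  The
    inequality operators tend to generalize (they bound half-spaces);
    ``EQ``/``NE`` tend to overfit (they pin or puncture single values).
    """

    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="
    EQ = "=="
    NE = "!="

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Op.{self.name}"


#: Operators that bound intervals (generalizing set).
INTERVAL_OPS = (Op.LT, Op.LE, Op.GT, Op.GE)


@dataclass(frozen=True)
class Literal:
    """One comparison constraint on the pattern space.

    Parameters
    ----------
    attr_index:
        Column of the pattern matrix the constraint applies to.
    op:
        One of the six :class:`Op` members.
    threshold:
        Comparison value, in the units of the attribute (standardized
        units if the dataset was standardized).
    """

    attr_index: int
    op: Op
    threshold: float

    def __post_init__(self) -> None:
        if self.attr_index < 0:
            raise ValueError(f"attr_index must be >= 0, got {self.attr_index}")
        if not isinstance(self.op, Op):
            raise TypeError(f"op must be an Op member, got {self.op!r}")

    def __str__(self) -> str:
        return f"(a{self.attr_index} {self.op.value} {_fmt_threshold(self.threshold)})"


@dataclass(frozen=True)
class Rule:
    """A conjunction of literals (antecedent) implying a class label.

    An empty antecedent is the universally-true rule: it covers every
    pattern.  Induced rules always carry at least one literal; the empty
    rule only arises as an algebraic identity.
    """

    literals: tuple[Literal, ...]
    class_label: object

    def __init__(self, literals: Iterable[Literal], class_label: object):
        object.__setattr__(self, "literals", tuple(literals))
        object.__setattr__(self, "class_label", class_label)

    @property
    def length(self) -> int:
        """Number of literals in the antecedent."""
        return len(self.literals)

    def covers(self, pattern: Sequence[float], atol: float = EQ_ATOL) -> bool:
        """True iff every literal is satisfied by ``pattern``."""
        return rule_covers(self, pattern, atol=atol)

    def covers_matrix(self, X: np.ndarray, atol: float = EQ_ATOL) -> np.ndarray:
        """Vectorized coverage over an ``n x d`` pattern matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D pattern matrix")
        mask = np.ones(X.shape[0], dtype=bool)
        for lit in self.literals:
            if lit.attr_index >= X.shape[1]:
                raise IndexError(
                    f"literal attribute {lit.attr_index} out of range for d={X.shape[1]}"
                )
            col = X[:, lit.attr_index]
            mask &= _compare_vec(col, lit.op, lit.threshold, atol)
            if not mask.any():
                break
        return mask

    def __str__(self) -> str:
        return format_rule(self)


def _compare_vec(col: np.ndarray, op: Op, t: float, atol: float) -> np.ndarray:
    if op is Op.LT:
        return col < t
    if op is Op.LE:
        return col <= t
    if op is Op.GT:
        return col > t
    if op is Op.GE:
        return col >= t
    if op is Op.EQ:
        return np.abs(col - t) <= atol
    return np.abs(col - t) > atol  # NE


def evaluate_literal(pattern: Sequence[float], lit: Literal, atol: float = EQ_ATOL) -> bool:
    """Evaluate a single literal against one pattern.

    Raises ``IndexError`` if the literal's attribute is outside the
    pattern's dimension.
    """
    if lit.attr_index >= len(pattern):
        raise IndexError(
            f"literal attribute {lit.attr_index} out of range for d={len(pattern)}"
        )
    x = float(pattern[lit.attr_index])
    t = lit.threshold
    if lit.op is Op.LT:
        return x < t
    if lit.op is Op.LE:
        return x <= t
    if lit.op is Op.GT:
        return x > t
    if lit.op is Op.GE:
        return x >= t
    if lit.op is Op.EQ:
        return abs(x - t) <= atol
    return abs(x - t) > atol


def rule_covers(rule: Rule, pattern: Sequence[float], atol: float = EQ_ATOL) -> bool:
    """True iff every literal of ``rule`` holds on ``pattern``.

    A rule with an empty antecedent covers every pattern (empty
    conjunction is true).
    """
    return all(evaluate_literal(pattern, lit, atol=atol) for lit in rule.literals)


@dataclass(frozen=True)
class LengthBound:
    """The admissible range for a rule's maximum length.

    ``2d`` literals describe a hyperrectangle, the least general shape
    that still generalizes in ``d`` dimensions; ``k*d`` literals arise
    from excluding each of the ``k`` opposite-class patterns attribute
    by attribute.  ``upper`` is clipped to ``max(2d, kd)`` so the
    interval never inverts when ``k < 2``.
    """

    d: int
    k: int
    lower: int
    upper: int


def max_length_bound(d: int, k: int) -> LengthBound:
    """Maximum-rule-length interval ``[2d, max(2d, kd)]``.

    Parameters
    ----------
    d:
        Pattern-space dimension.
    k:
        Number of patterns in the class opposite to the one being
        learned.
    """
    if d < 1:
        raise ValueError(f"d must be a positive integer, got {d}")
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    lower = 2 * d
    upper = max(lower, k * d)
    return LengthBound(d=d, k=k, lower=lower, upper=upper)


@dataclass
class Interval:
    """One attribute's interval constraint inside a :class:`Region`."""

    low: float = -math.inf
    high: float = math.inf
    low_open: bool = False
    high_open: bool = False

    @property
    def empty(self) -> bool:
        if self.low > self.high:
            return True
        return self.low == self.high and (self.low_open or self.high_open)

    @property
    def degenerate(self) -> bool:
        """Single-point interval."""
        return not self.empty and self.low == self.high

    def contains(self, x: float) -> bool:
        if self.low_open:
            if not x > self.low:
                return False
        elif not x >= self.low:
            return False
        if self.high_open:
            return x < self.high
        return x <= self.high

    def tighten_low(self, value: float, open_: bool) -> None:
        if value > self.low or (value == self.low and open_ and not self.low_open):
            self.low, self.low_open = value, open_

    def tighten_high(self, value: float, open_: bool) -> None:
        if value < self.high or (value == self.high and open_ and not self.high_open):
            self.high, self.high_open = value, open_


@dataclass
class Region:
    """The exact point set a rule covers.

    Per-attribute intervals from the inequality and equality literals,
    plus *punctures*: values excluded by ``!=`` literals.  Punctures are
    measure-zero and cannot empty a non-degenerate interval; they can
    empty a point interval produced by an ``==`` pin.
    """

    intervals: dict[int, Interval] = field(default_factory=dict)
    punctures: set[tuple[int, float]] = field(default_factory=set)
    eq_pins: set[tuple[int, float]] = field(default_factory=set)
    empty: bool = False

    def interval(self, attr: int) -> Interval:
        return self.intervals.get(attr, Interval())

    def contains(self, pattern: Sequence[float], atol: float = EQ_ATOL) -> bool:
        if self.empty:
            return False
        for attr, iv in self.intervals.items():
            if attr >= len(pattern):
                raise IndexError(f"attribute {attr} out of range")
            if not iv.contains(float(pattern[attr])):
                return False
        for attr, v in self.punctures:
            if abs(float(pattern[attr]) - v) <= atol:
                return False
        return True


def rule_region(rule: Rule, atol: float = EQ_ATOL) -> Region:
    """Translate a rule's literals into the region they jointly cover.

    Inconsistent constraints (e.g. ``x >= 5 AND x <= 3``) produce a
    region flagged ``empty``.
    """
    region = Region()
    for lit in rule.literals:
        iv = region.intervals.setdefault(lit.attr_index, Interval())
        if lit.op is Op.GE:
            iv.tighten_low(lit.threshold, False)
        elif lit.op is Op.GT:
            iv.tighten_low(lit.threshold, True)
        elif lit.op is Op.LE:
            iv.tighten_high(lit.threshold, False)
        elif lit.op is Op.LT:
            iv.tighten_high(lit.threshold, True)
        elif lit.op is Op.EQ:
            # An == pin collapses the interval to [t - atol, t + atol];
            # we model it as the point t and record the pin.
            iv.tighten_low(lit.threshold, False)
            iv.tighten_high(lit.threshold, False)
            region.eq_pins.add((lit.attr_index, lit.threshold))
        else:  # NE
            region.punctures.add((lit.attr_index, lit.threshold))
    for attr, iv in region.intervals.items():
        if iv.empty:
            region.empty = True
        elif iv.degenerate:
            # A point interval dies if a puncture sits on it.
            point = iv.low
            if any(a == attr and abs(v - point) <= atol for a, v in region.punctures):
                region.empty = True
    return region


def rules_intersect(
    a: Rule,
    b: Rule,
    domain: Sequence[tuple[float, float]],
    atol: float = EQ_ATOL,
) -> bool:
    """Do the regions of two rules overlap inside a finite domain box?

    Computed analytically by per-attribute interval intersection.
    Punctures (``!=``) remove measure-zero sets and are ignored unless
    the intersected interval has collapsed to a single point.
    """
    ra, rb = rule_region(a, atol=atol), rule_region(b, atol=atol)
    if ra.empty or rb.empty:
        return False
    d = len(domain)
    for lit in (*a.literals, *b.literals):
        if lit.attr_index >= d:
            raise IndexError(
                f"literal attribute {lit.attr_index} out of range for domain of dim {d}"
            )
    punctures = ra.punctures | rb.punctures
    for attr in range(d):
        lo, hi = domain[attr]
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("domain must be a finite bounding box")
        iv = Interval(low=lo, high=hi)
        for src in (ra, rb):
            other = src.interval(attr)
            iv.tighten_low(other.low, other.low_open)
            iv.tighten_high(other.high, other.high_open)
        if iv.empty:
            return False
        if iv.degenerate:
            point = iv.low
            if any(a_ == attr and abs(v - point) <= atol for a_, v in punctures):
                return False
    return True


def trivial_classifier(data, cls) -> list[Rule]:
    """The maximally-overfit rule set for one class.

    One rule per training pattern of ``cls``, each with exactly ``d``
    equality literals pinning the pattern's attribute values.  The rule
    count equals the class size; training recall on the class is 100 %
    by construction.
    """
    X, y = data.X, data.y
    mask = np.asarray([label == cls for label in y])
    if not mask.any():
        raise ValueError(f"class {cls!r} has no patterns")
    rules = []
    for row in X[mask]:
        lits = [Literal(j, Op.EQ, float(row[j])) for j in range(X.shape[1])]
        rules.append(Rule(lits, cls))
    return rules


def simplify_rule(rule: Rule, atol: float = EQ_ATOL) -> Rule:
    """Merge redundant literals on the same attribute.

    The covered-pattern set is unchanged and the result is never longer
    than the input.  Contradictory constraints are kept (two literals)
    so the empty coverage is preserved; callers can detect emptiness via
    ``rule_region(rule).empty``.
    """
    per_attr: dict[int, dict] = {}
    order: list[int] = []
    for lit in rule.literals:
        a = lit.attr_index
        if a not in per_attr:
            per_attr[a] = {"iv": Interval(), "ne": [], "eq": []}
            order.append(a)
        slot = per_attr[a]
        if lit.op is Op.GE:
            slot["iv"].tighten_low(lit.threshold, False)
        elif lit.op is Op.GT:
            slot["iv"].tighten_low(lit.threshold, True)
        elif lit.op is Op.LE:
            slot["iv"].tighten_high(lit.threshold, False)
        elif lit.op is Op.LT:
            slot["iv"].tighten_high(lit.threshold, True)
        elif lit.op is Op.EQ:
            if not any(abs(v - lit.threshold) <= atol for v in slot["eq"]):
                slot["eq"].append(lit.threshold)
        else:
            if not any(abs(v - lit.threshold) <= atol for v in slot["ne"]):
                slot["ne"].append(lit.threshold)

    out: list[Literal] = []
    for a in order:
        slot = per_attr[a]
        iv: Interval = slot["iv"]
        eqs: list[float] = slot["eq"]
        if len(eqs) > 1:
            # Mutually contradictory pins: keep two to preserve emptiness.
            out.append(Literal(a, Op.EQ, eqs[0]))
            out.append(Literal(a, Op.EQ, eqs[1]))
            continue
        if eqs:
            v = eqs[0]
            out.append(Literal(a, Op.EQ, v))
            # A bound is droppable only if the pin's tolerance ball
            # [v - atol, v + atol] lies strictly inside it; otherwise
            # the bound still trims the ball and must be kept.
            keep_low = not (iv.low == -math.inf
                            or (v - atol > iv.low)
                            or (v - atol == iv.low and not iv.low_open))
            keep_high = not (iv.high == math.inf
                             or (v + atol < iv.high)
                             or (v + atol == iv.high and not iv.high_open))
            kept_iv = Interval(
                low=iv.low if keep_low else -math.inf,
                high=iv.high if keep_high else math.inf,
                low_open=iv.low_open if keep_low else False,
                high_open=iv.high_open if keep_high else False)
            out.extend(_interval_literals(a, kept_iv))
            for t in slot["ne"]:
                if abs(t - v) <= 2 * atol:  # puncture can trim the pin's ball
                    out.append(Literal(a, Op.NE, t))
            continue
        out.extend(_interval_literals(a, iv))
        for t in slot["ne"]:
            if iv.contains(t) or _interval_distance(iv, t) <= atol:
                out.append(Literal(a, Op.NE, t))
            # NE thresholds well outside the interval are vacuous: dropped.
    return Rule(out, rule.class_label)


def _interval_distance(iv: Interval, t: float) -> float:
    if t < iv.low:
        return iv.low - t
    if t > iv.high:
        return t - iv.high
    return 0.0


def _interval_literals(attr: int, iv: Interval) -> list[Literal]:
    lits = []
    if iv.low != -math.inf:
        lits.append(Literal(attr, Op.GT if iv.low_open else Op.GE, iv.low))
    if iv.high != math.inf:
        lits.append(Literal(attr, Op.LT if iv.high_open else Op.LE, iv.high))
    return lits


# --------------------------------------------------------------------------
# Text serialization: "IF (a3 >= 1.25) AND (a3 <= 2) THEN class=1"
# Thresholds are printed at 6 significant digits; parse/emit round-trips
# losslessly at that precision.
# --------------------------------------------------------------------------

def _fmt_threshold(t: float) -> str:
    return f"{t:.6g}"


def format_rule(rule: Rule) -> str:
    """Render a rule in IF/THEN text form."""
    if rule.literals:
        antecedent = " AND ".join(str(lit) for lit in rule.literals)
    else:
        antecedent = "TRUE"
    return f"IF {antecedent} THEN class={rule.class_label}"


_LIT_RE = re.compile(r"\(a(\d+) (<=|>=|==|!=|<|>) ([^)]+)\)")
_RULE_RE = re.compile(r"^IF (.+) THEN class=(.+)$")


def parse_rule(text: str) -> Rule:
    """Parse one rule from its IF/THEN text form."""
    m = _RULE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable rule: {text!r}")
    antecedent, label = m.group(1), m.group(2)
    if antecedent.strip() == "TRUE":
        return Rule([], _parse_label(label))
    lits = []
    for part in antecedent.split(" AND "):
        lm = _LIT_RE.match(part.strip())
        if not lm:
            raise ValueError(f"unparseable literal: {part!r}")
        lits.append(Literal(int(lm.group(1)), Op(lm.group(2)), float(lm.group(3))))
    return Rule(lits, _parse_label(label))


def _parse_label(text: str):
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def write_rules(rules: Iterable[Rule], path) -> None:
    """Write rules one per line in the text serialization."""
    with open(path, "w", encoding="utf-8") as fh:
        for rule in rules:
            fh.write(format_rule(rule) + "\n")


def read_rules(path) -> list[Rule]:
    """Read a rule file written by :func:`write_rules`."""
    rules = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rules.append(parse_rule(line))
    return rules
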