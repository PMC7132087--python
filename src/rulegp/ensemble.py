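"""Three-component ensemble resolving the rule-intersection problem.

A rule-based classifier induced per class (the *main classifier*, MC)
partitions the pattern space imperfectly: rules from different classes
can overlap (a pattern fires rules of two or more classes — the rule
intersection problem) and some regions are covered by no rule at all.
The ensemble routes each pattern to exactly one of three components:

* **MC** — when rules of exactly one class fire, that class wins;
* **IC** (intersection classifier) — when rules of several classes
  fire, the rule holding the pattern *deepest* inside its boundaries
  wins (ties: fewer literals, then declared class order);
* **DbC** (distance-based classifier) — when no rule fires, the nearest
  class centroid (Euclidean) decides; a k-NN variant is available
  behind ``GPConfig.dbc_k_neighbors``.

The three components cover complementary regions, so the ensemble is
total: it returns a class label for every point of the space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    Rule,
    format_rule,
    parse_rule,
    rule_covers,
    rule_region,
    rules_intersect,
)
from .data import Dataset
from .search import GPConfig, sequential_cover

__all__ = ["RuleClassifier", "EnsembleModel", "EvalReport", "AMBIGUOUS",
           "UNKNOWN", "build_ensemble", "predict_mc", "boundary_depth",
           "predict_ic", "predict_dbc", "predict", "evaluate",
           "save_model", "load_model"]

#: Sentinel outcomes of the main classifier.
AMBIGUOUS = "AMBIGUOUS"
UNKNOWN = "UNKNOWN"


@dataclass
class RuleClassifier:
    """Per-class ordered rule sets — the main classifier (MC)."""

    rules_by_class: dict
    classes: list

    def __post_init__(self) -> None:
        for cls, rules in self.rules_by_class.items():
            for rule in rules:
                if rule.class_label != cls:
                    raise ValueError(
                        f"rule {format_rule(rule)} filed under class {cls!r}")
        if not any(self.rules_by_class.get(c) for c in self.classes):
            raise ValueError("at least one class must have a rule")

    def firing_rules(self, pattern, atol: float) -> list[Rule]:
        return [rule
                for cls in self.classes
                for rule in self.rules_by_class.get(cls, [])
                if rule_covers(rule, pattern, atol=atol)]


@dataclass
class EnsembleModel:
    """MC rules plus the intersection list, centroids, and training domain."""

    mc: RuleClassifier
    intersections: list  # (rule_a, rule_b) cross-class pairs that overlap
    dbc_centroids: dict  # class -> mean vector
    training_domain: list  # per-attribute (min, max)
    cfg: GPConfig = field(default_factory=GPConfig)
    train_X: Optional[np.ndarray] = None  # retained only for k-NN DbC
    train_y: Optional[np.ndarray] = None

    @property
    def classes(self) -> list:
        return self.mc.classes

    @property
    def n_components(self) -> int:
        """MC, IC, and DbC."""
        return 3


@dataclass
class EvalReport:
    """Test-set evaluation in the shape of a rules-vs-accuracy table."""

    accuracy: float  # percent correct, in [0, 100]
    rules_total: int
    rules_per_class: dict
    intersection_pattern_count: int  # patterns firing rules of >= 2 classes
    intersection_rule_pairs: int     # overlapping cross-class rule pairs
    unknown_pattern_count: int       # patterns firing no rule
    per_class_sensitivity: dict
    per_class_specificity: dict
    n_test: int

    def to_table(self) -> str:
        """Flat delimited summary (accuracy, rule and intersection counts)."""
        lines = ["metric\tvalue",
                 f"accuracy_pct\t{self.accuracy:.2f}",
                 f"rules_total\t{self.rules_total}"]
        for cls in self.rules_per_class:
            lines.append(f"rules_class_{cls}\t{self.rules_per_class[cls]}")
        lines.append(f"intersection_patterns\t{self.intersection_pattern_count}")
        lines.append(f"intersection_rule_pairs\t{self.intersection_rule_pairs}")
        lines.append(f"unknown_patterns\t{self.unknown_pattern_count}")
        for cls in self.per_class_sensitivity:
            lines.append(
                f"sensitivity_class_{cls}\t{self.per_class_sensitivity[cls]:.4f}")
            lines.append(
                f"specificity_class_{cls}\t{self.per_class_specificity[cls]:.4f}")
        return "\n".join(lines)


def build_ensemble(train: Dataset, cfg: GPConfig) -> EnsembleModel:
    """Train the full three-component model.

    Runs the sequential-covering GP once per class to form MC,
    enumerates every overlapping cross-class rule pair inside the
    training bounding box, and records per-class centroids for DbC.
    """
    classes = list(train.class_labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for cls in classes:
        if train.class_size(cls) == 0:
            raise ValueError(f"class {cls!r} is empty")

    seeds = np.random.SeedSequence(cfg.seed).spawn(len(classes))
    rules_by_class = {}
    for cls, ss in zip(classes, seeds):
        rng = np.random.default_rng(ss)
        rules_by_class[cls] = sequential_cover(train, cls, cfg, rng=rng)
    mc = RuleClassifier(rules_by_class=rules_by_class, classes=classes)

    domain = train.domain()
    intersections = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1:]:
            for ra in rules_by_class[ca]:
                for rb in rules_by_class[cb]:
                    if rules_intersect(ra, rb, domain, atol=cfg.eq_atol):
                        intersections.append((ra, rb))

    centroids = {cls: train.X[train.class_mask(cls)].mean(axis=0)
                 for cls in classes}
    keep_train = cfg.dbc_k_neighbors >= 1
    return EnsembleModel(
        mc=mc, intersections=intersections, dbc_centroids=centroids,
        training_domain=domain, cfg=cfg,
        train_X=train.X.copy() if keep_train else None,
        train_y=train.y.copy() if keep_train else None)


def predict_mc(model: EnsembleModel, pattern):
    """Main-classifier outcome: a class, AMBIGUOUS, or UNKNOWN."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape[0] != len(model.training_domain):
        raise ValueError(
            f"pattern dimension {pattern.shape[0]} != model dimension "
            f"{len(model.training_domain)}")
    firing = model.mc.firing_rules(pattern, model.cfg.eq_atol)
    labels = {r.class_label for r in firing}
    if len(labels) == 1:
        return next(iter(labels))
    if len(labels) >= 2:
        return AMBIGUOUS
    return UNKNOWN


def boundary_depth(rule: Rule, pattern) -> float:
    """How deep inside a rule's region a covered pattern sits.

    Minimum, over the rule's interval constraints, of the distance from
    the pattern to that constraint's boundary; unconstrained attributes
    contribute infinity, a pattern exactly on a boundary has depth 0.
    """
    pattern = np.asarray(pattern, dtype=float)
    if not rule_covers(rule, pattern):
        raise ValueError("pattern is not covered by the rule")
    region = rule_region(rule)
    depth = math.inf
    for attr, iv in region.intervals.items():
        x = float(pattern[attr])
        if iv.low != -math.inf:
            depth = min(depth, x - iv.low)
        if iv.high != math.inf:
            depth = min(depth, iv.high - x)
    return depth


def predict_ic(model: EnsembleModel, pattern):
    """Resolve an ambiguous pattern by deepest rule containment.

    Ties broken by the firing rule with fewer literals, then by the
    declared class order.  Raises if the pattern is not ambiguous.
    """
    pattern = np.asarray(pattern, dtype=float)
    firing = model.mc.firing_rules(pattern, model.cfg.eq_atol)
    if len({r.class_label for r in firing}) < 2:
        raise ValueError("predict_ic requires an AMBIGUOUS pattern")
    class_order = {cls: i for i, cls in enumerate(model.classes)}

    def sort_key(rule: Rule):
        return (-boundary_depth(rule, pattern), rule.length,
                class_order[rule.class_label])

    return min(firing, key=sort_key).class_label


def predict_dbc(model: EnsembleModel, pattern):
    """Distance-based fallback: nearest class centroid (or k-NN vote).

    Euclidean distance; ties go to the first class in declared order.
    """
    pattern = np.asarray(pattern, dtype=float)
    k = model.cfg.dbc_k_neighbors
    if k >= 1 and model.train_X is not None:
        dists = np.linalg.norm(model.train_X - pattern, axis=1)
        nearest = np.argsort(dists, kind="stable")[:k]
        votes = {}
        for i in nearest:
            votes[model.train_y[i]] = votes.get(model.train_y[i], 0) + 1
        order = {cls: i for i, cls in enumerate(model.classes)}
        return min(votes, key=lambda c: (-votes[c], order[c]))
    best_cls, best_dist = None, math.inf
    for cls in model.classes:
        dist = float(np.linalg.norm(pattern - model.dbc_centroids[cls]))
        if dist < best_dist:  # strict: earlier class wins ties
            best_cls, best_dist = cls, dist
    return best_cls


def predict(model: EnsembleModel, pattern):
    """Full three-way dispatch; always returns a class label."""
    outcome = predict_mc(model, pattern)
    if outcome == AMBIGUOUS:
        return predict_ic(model, pattern)
    if outcome == UNKNOWN:
        return predict_dbc(model, pattern)
    return outcome


def evaluate(model: EnsembleModel, test: Dataset) -> EvalReport:
    """Accuracy, rule counts, and intersection/unknown tallies on a test set."""
    unseen = set(test.class_labels) - set(model.classes)
    if unseen:
        raise ValueError(f"test set contains unseen class label(s): {unseen!r}")
    n = test.n
    correct = 0
    ambiguous = 0
    unknown = 0
    preds = []
    for row, label in zip(test.X, test.y):
        outcome = predict_mc(model, row)
        if outcome == AMBIGUOUS:
            ambiguous += 1
            pred = predict_ic(model, row)
        elif outcome == UNKNOWN:
            unknown += 1
            pred = predict_dbc(model, row)
        else:
            pred = outcome
        preds.append(pred)
        if pred == label:
            correct += 1

    sens, spec = {}, {}
    preds_arr = np.asarray(preds, dtype=object)
    for cls in model.classes:
        actual = test.class_mask(cls)
        predicted = preds_arr == cls
        tp = int((actual & predicted).sum())
        fn = int((actual & ~predicted).sum())
        tn = int((~actual & ~predicted).sum())
        fp = int((~actual & predicted).sum())
        sens[cls] = tp / (tp + fn) if tp + fn else 0.0
        spec[cls] = tn / (tn + fp) if tn + fp else 0.0

    rules_per_class = {cls: len(model.mc.rules_by_class.get(cls, []))
                       for cls in model.classes}
    return EvalReport(
        accuracy=100.0 * correct / n,
        rules_total=sum(rules_per_class.values()),
        rules_per_class=rules_per_class,
        intersection_pattern_count=ambiguous,
        intersection_rule_pairs=len(model.intersections),
        unknown_pattern_count=unknown,
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        n_test=n)


# --------------------------------------------------------------------------
# Serialization: rules.txt (one rule per line) + model.json sidecar with
# centroids, domain, class order, and the config snapshot.
# --------------------------------------------------------------------------

def save_model(model: EnsembleModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for cls in model.classes:
        for rule in model.mc.rules_by_class.get(cls, []):
            lines.append(format_rule(rule))
    (directory / "rules.txt").write_text("\n".join(lines) + "\n",
                                         encoding="utf-8")
    from dataclasses import asdict
    sidecar = {
        "classes": [_jsonable(c) for c in model.classes],
        "centroids": {str(c): [float(v) for v in vec]
                      for c, vec in model.dbc_centroids.items()},
        "training_domain": [[float(lo), float(hi)]
                            for lo, hi in model.training_domain],
        "intersections": [[format_rule(a), format_rule(b)]
                          for a, b in model.intersections],
        "config": asdict(model.cfg),
    }
    (directory / "model.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_model(directory) -> EnsembleModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    cfg = GPConfig(**sidecar["config"])
    classes = sidecar["classes"]
    rules = [parse_rule(line)
             for line in (directory / "rules.txt").read_text(
                 encoding="utf-8").splitlines() if line.strip()]
    rules_by_class = {cls: [r for r in rules if r.class_label == cls]
                      for cls in classes}
    mc = RuleClassifier(rules_by_class=rules_by_class, classes=classes)
    by_text = {format_rule(r): r for r in rules}
    intersections = [(by_text[a], by_text[b])
                     for a, b in sidecar["intersections"]]
    centroids = {}
    for cls in classes:
        centroids[cls] = np.asarray(sidecar["centroids"][str(cls)], dtype=float)
    domain = [(lo, hi) for lo, hi in sidecar["training_domain"]]
    return EnsembleModel(mc=mc, intersections=intersections,
                         dbc_centroids=centroids, training_domain=domain,
                         cfg=cfg)


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value
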