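"""Deterministic synthetic geometries for rule-induction experiments.

Three planar binary-classification cases plus a d-dimensional
box-separable generator:

* **Case A** — two classes split by a single vertical line ``x = x1``;
  the one-literal rule ``(x >= x1)`` separates them, the most general
  rule the plane admits.
* **Case B** — Class-1 fills a central rectangle while Class-0 occupies
  two opposite corners; a one-literal half-plane now overfits, but the
  four-literal rectangle (the least general generalizing shape, ``2d``
  literals) covers Class-1, and Class-0 needs the two corner rules
  ``(x <= x1) AND (y <= y1)`` and ``(x >= x2) AND (y >= y2)``.
* **Case C** — Class-1 sits in a horizontal band, Class-0 above and
  below it; Class-0 is covered exactly by the two threshold rules
  ``(y <= y1)`` and ``(y >= y2)``, whereas a single rule excluding each
  Class-1 point with ``!=`` literals (``k*d`` of them) overfits.
* **box** — Class-1 uniform inside a d-dimensional axis-aligned box,
  Class-0 outside it, separated by a margin; the ``2d``-literal box rule
  is exact by construction.

Generators are pure functions of their spec (seed included), so every
test runs without downloads and reproduces byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import Dataset

__all__ = ["FixtureSpec", "make_case_a", "make_case_b", "make_case_c",
           "make_box", "make_overlap", "DOMAIN"]

#: Default planar domain for the three cases.
DOMAIN = (0.0, 10.0)


@dataclass
class FixtureSpec:
    """Geometry and sampling parameters for one synthetic dataset.

    ``thresholds`` holds the case's geometry constants; each generator
    fills sensible defaults when it is empty.  ``margin`` keeps the
    classes separated (by the case's nominal rules) when ``noise_sd``
    is 0; Gaussian jitter with ``noise_sd > 0`` may break separability
    and is meant for robustness checks only.
    """

    case: str = "A"
    n_per_class: int = 50
    d: int = 2
    margin: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.case in ("A", "B", "C") and self.d != 2:
            raise ValueError(f"case {self.case} is planar (d=2)")


def _finish(X: np.ndarray, y: list, spec: FixtureSpec, rng: np.random.Generator,
            names: Optional[list[str]] = None) -> Dataset:
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    if names is None:
        names = [f"a{j}" for j in range(X.shape[1])]
    return Dataset(X=X, y=np.asarray(y, dtype=object), attribute_names=names,
                   class_labels=[0, 1])


def make_case_a(spec: FixtureSpec) -> Dataset:
    """Line-separable planar data: Class-1 at ``x >= x1 + margin``,
    Class-0 at ``x <= x1 - margin``."""
    if spec.case != "A":
        raise ValueError("spec.case must be 'A'")
    t = {"x1": 5.0, **spec.thresholds}
    lo, hi = DOMAIN
    x1 = t["x1"]
    if not lo + spec.margin < x1 < hi - spec.margin:
        raise ValueError("x1 +/- margin must fit inside the domain")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    c0 = np.column_stack([
        rng.uniform(lo, x1 - spec.margin, n), rng.uniform(lo, hi, n)])
    c1 = np.column_stack([
        rng.uniform(x1 + spec.margin, hi, n), rng.uniform(lo, hi, n)])
    X = np.vstack([c0, c1])
    y = [0] * n + [1] * n
    return _finish(X, y, spec, rng, names=["x", "y"])


def make_case_b(spec: FixtureSpec) -> Dataset:
    """Rectangle vs. two opposite corners.

    Class-1 fills the central rectangle ``[bx1, bx2] x [by1, by2]``;
    Class-0 splits between the lower-left region ``x <= x1, y <= y1``
    and the upper-right region ``x >= x2, y >= y2``.
    """
    if spec.case != "B":
        raise ValueError("spec.case must be 'B'")
    t = {"x1": 2.5, "y1": 2.5, "x2": 7.5, "y2": 7.5,
         "bx1": 3.5, "bx2": 6.5, "by1": 3.5, "by2": 6.5, **spec.thresholds}
    lo, hi = DOMAIN
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    m = spec.margin
    n_low = n // 2
    n_high = n - n_low
    corner_lo = np.column_stack([
        rng.uniform(lo, t["x1"] - m, n_low), rng.uniform(lo, t["y1"] - m, n_low)])
    corner_hi = np.column_stack([
        rng.uniform(t["x2"] + m, hi, n_high), rng.uniform(t["y2"] + m, hi, n_high)])
    c1 = np.column_stack([
        rng.uniform(t["bx1"] + m, t["bx2"] - m, n),
        rng.uniform(t["by1"] + m, t["by2"] - m, n)])
    X = np.vstack([corner_lo, corner_hi, c1])
    y = [0] * n + [1] * n
    return _finish(X, y, spec, rng, names=["x", "y"])


def make_case_c(spec: FixtureSpec) -> Dataset:
    """Horizontal band: Class-1 strictly inside ``(y1, y2)``, Class-0
    below ``y1`` and above ``y2``.

    Class-1 defaults to 6 patterns (``thresholds['n_band']``), the size
    at which the single puncture rule excluding each band point with
    ``!=`` literals reaches ``k*d = 12`` literals.
    """
    if spec.case != "C":
        raise ValueError("spec.case must be 'C'")
    t = {"y1": 3.0, "y2": 7.0, "n_band": 6, **spec.thresholds}
    lo, hi = DOMAIN
    rng = np.random.default_rng(spec.seed)
    n0 = spec.n_per_class
    m = spec.margin
    if t["y1"] + m >= t["y2"] - m:
        raise ValueError("band is empty at this margin")
    n_below = n0 // 2
    n_above = n0 - n_below
    below = np.column_stack([
        rng.uniform(lo, hi, n_below), rng.uniform(lo, t["y1"], n_below)])
    above = np.column_stack([
        rng.uniform(lo, hi, n_above), rng.uniform(t["y2"], hi, n_above)])
    n1 = int(t["n_band"])
    band = np.column_stack([
        rng.uniform(lo, hi, n1), rng.uniform(t["y1"] + m, t["y2"] - m, n1)])
    X = np.vstack([below, above, band])
    y = [0] * n0 + [1] * n1
    return _finish(X, y, spec, rng, names=["x", "y"])


def make_box(spec: FixtureSpec) -> Dataset:
    """d-dimensional box-separable data.

    Class-1 uniform inside the box shrunk by ``margin``; Class-0 uniform
    over the domain minus the box expanded by ``margin``.  The
    ``2d``-literal box rule separates the classes exactly.

    ``thresholds`` may give ``faces`` as a list of per-attribute
    ``(low, high)`` pairs; the default box is ``[3, 7]`` per axis on the
    ``[0, 10]`` domain.
    """
    if spec.case != "box":
        raise ValueError("spec.case must be 'box'")
    if spec.d < 1:
        raise ValueError("d must be >= 1")
    lo, hi = DOMAIN
    faces = spec.thresholds.get("faces") or [(3.0, 7.0)] * spec.d
    if len(faces) != spec.d:
        raise ValueError("faces must give one (low, high) pair per attribute")
    m = spec.margin
    for flo, fhi in faces:
        if flo - m <= lo or fhi + m >= hi or flo + m >= fhi - m:
            raise ValueError("box plus margin must fit strictly inside the domain")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    inner = np.column_stack([
        rng.uniform(flo + m, fhi - m, n) for flo, fhi in faces])
    # Rejection-sample the outside region (box expanded by margin removed).
    outer = []
    while len(outer) < n:
        cand = rng.uniform(lo, hi, size=(4 * n, spec.d))
        inside = np.ones(cand.shape[0], dtype=bool)
        for j, (flo, fhi) in enumerate(faces):
            inside &= (cand[:, j] >= flo - m) & (cand[:, j] <= fhi + m)
        outer.extend(cand[~inside])
    outer = np.asarray(outer[:n])
    X = np.vstack([outer, inner])
    y = [0] * n + [1] * n
    return _finish(X, y, spec, rng)


def make_overlap(spec: FixtureSpec) -> Dataset:
    """Two orthogonal bars crossing in a shared central square.

    Class-0 fills a horizontal bar (all ``x``, ``y`` in a narrow band),
    Class-1 a vertical bar (all ``y``, ``x`` in a narrow band).  The
    natural axis-aligned rule for each class is its bar, and the bars
    overlap in the central square, so the induced rules of the two
    classes genuinely intersect — the geometry that creates ambiguous
    (multi-class) predictions.  ``thresholds['half_width']`` sets the
    bar half-width (default 0.3 around the domain center, at which a
    bar rule's expected precision stays well above typical acceptance
    precision thresholds while the central overlap remains populated).
    """
    t = {"half_width": 0.3, **spec.thresholds}
    lo, hi = DOMAIN
    center = (lo + hi) / 2.0
    w = t["half_width"]
    if not 0 < w < (hi - lo) / 2:
        raise ValueError("half_width must fit inside the domain")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    c0 = np.column_stack([rng.uniform(lo, hi, n),
                          rng.uniform(center - w, center + w, n)])
    c1 = np.column_stack([rng.uniform(center - w, center + w, n),
                          rng.uniform(lo, hi, n)])
    X = np.vstack([c0, c1])
    y = [0] * n + [1] * n
    return _finish(X, y, spec, rng, names=["x", "y"])
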