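# Methods

This note records the model, the design choices made where the design
was genuinely open, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Rule model and semantics

A rule is a conjunction of literals `(attribute, op, threshold)` with
`op ∈ {<, ≤, >, ≥, =, ≠}`, implying a class label. `≤`/`≥` include
equality; `<`/`>` exclude it. Equality on continuous attributes is
evaluated with an absolute tolerance (`EQ_ATOL = 1e-9`, configurable):
`=` accepts values within the tolerance of the threshold, `≠` rejects
them. Without a tolerance band, equality on reals would hold on a
measure-zero set and the two operators would be useless on
floating-point data.

Every rule maps deterministically to the region of pattern space it
covers: per-attribute intervals from the inequality literals (open or
closed endpoints per operator), point pins from `=`, and punctures
(excluded values) from `≠`. Rule/rule intersection is decided
analytically by per-attribute interval intersection within a finite
domain box. Punctures remove measure-zero sets, so they are ignored
unless the intersected interval has collapsed to a single point, in
which case a puncture on that point empties it. This convention treats
the pattern space as continuous; on genuinely discrete attributes a
puncture could empty a wider set, which this package does not model.

The maximum length of a useful rule is bounded by `[2d, k·d]`: `2d`
literals describe a hyperrectangle, the least general shape that still
generalizes in `d` dimensions, and `k·d` literals arise from excluding
each of the `k` opposite-class patterns attribute by attribute (the
fully memorizing construction). The upper end is clipped to
`max(2d, k·d)` so the interval never inverts for `k < 2`, which the
original interval implicitly assumes. The *trivial classifier* — one
`d`-literal equality rule per training pattern — is provided as the
reference point of maximal overfitting: rule count equals class size
and training recall is 100 % by construction.

Rule simplification merges redundant literals per attribute (dominated
bounds dropped, vacuous punctures removed) without ever changing the
covered set; contradictory constraints are kept as a two-literal core
so that emptiness remains detectable from the rule text.

Serialization is line-oriented:
`IF (a0 >= 1.25) AND (a0 <= 2) THEN class=1`, thresholds at six
significant digits, attributes named `a0..a(d−1)`; parse/emit
round-trips losslessly at that precision.

## Search

Because the grammar is pure conjunction, candidates are flat literal
lists, not expression trees — a tree would add structure the semantics
cannot use. The generational GP uses:

* initialization seeded from target-class patterns: 1–4 literals on
  random attributes, thresholds drawn from the candidate grid so the
  seed pattern stays covered;
* tournament selection (size 3), elitism of one, one-point crossover of
  literal sublists (children truncated to the length bound, then
  simplified), and a uniform choice of mutation: shift a threshold to
  an adjacent candidate, flip an inequality operator, add a literal
  (below the bound), or drop one (above length 1);
* defaults: population 100, generations 50, crossover probability 0.8,
  mutation probability 0.3. Population, generations and tournament size
  follow the configuration contract; the variation probabilities are
  conventional GP values chosen once.

Candidate thresholds are the midpoints between consecutive distinct
values of each attribute in the training data — the only positions at
which coverage can change.

Fitness is `sensitivity × specificity × (1 − penalty)`, clipped to
[0, 1], with `penalty = λ·(length−1)/upper + w·(#≠ literals)/length`
(defaults λ = 0.05, w = 0.2). The product form makes a rule that covers
nothing, or everything, worth 0; the two penalty terms encode the two
generalization pressures — short rules, few punctures. `=` is excluded
from the search grammar by default (it pins single values) and `≠` is
allowed but penalized; both are configurable.

### Local refinement

The final rule of each GP run is refined greedily with three kinds of
strictly-improving moves, iterated to quiescence:

1. **threshold sweep** — each interval literal's threshold is
   re-optimized over *all* candidates at once (confusion counts for
   every candidate come from prefix sums over the sorted attribute
   values). A single-step "adjacent candidate" climb was evaluated and
   rejected: fitness is piecewise constant in a threshold, so adjacent
   moves sit on plateaus and are never strictly improving, leaving the
   climb stuck arbitrarily far from the optimum.
2. **prune** — drop a literal whose removal does not hurt
   discrimination; the length penalty then makes the shorter rule
   strictly better, so vacuous literals are removed deterministically.
3. **add** — insert the single best new interval literal when it pays
   for its penalty; this is what completes a missing face of a
   box-shaped class.

A final, fitness-neutral pass re-centers every interval threshold in
its data-free gap. For each literal, the thresholds preserving the
covered set form an interval bounded by the nearest kept and nearest
excluded pattern values (among patterns satisfying the rest of the
rule). The threshold is placed midway between the *estimated support
edges* of the two sides: each side's nearest value is extrapolated
outward by one average inter-point spacing (the uniform maximum-spacing
correction, with the dataset-wide attribute range as the known endpoint
when a side has a single point). A raw nearest-point midpoint is biased
toward the densely sampled side; the correction removes most of that
bias when one side is sparse. Because each adjustment stays inside the
coverage-preserving interval, confusion counts — and hence the fitness
score — never change; the pass is iterated to a fixed point because one
literal's gap depends on where the others sit. The result is a
canonical, max-margin rule that is robust to where unseen patterns fall
inside the gaps.

### Sequential covering

Rules are accepted one at a time: a rule must reach the configured
precision (default 0.9) on the not-yet-covered data and cover at least
one new target pattern; its covered targets are then removed (negatives
are always retained, so the length bound's `k` is stable) and the loop
stops at 98 % class coverage, 10 rules, or the first unacceptable rule.
All stopping constants are configuration fields.

## Ensemble

The main classifier (MC) fires all rules; exactly one class firing
yields that class, several yield AMBIGUOUS, none yields UNKNOWN. The
two fallback components are deliberately simple and config-isolated,
since only their roles — "based on rule boundary" and "distance-based"
— are fixed by the architecture:

* **IC** resolves AMBIGUOUS by deepest containment: for each firing
  rule, the depth of the pattern is the minimum distance to any of the
  rule's interval boundaries (unconstrained attributes contribute
  infinity); the deepest rule wins, ties broken by fewer literals, then
  declared class order. Deterministic and testable; other boundary
  functions would slot in behind the same interface.
* **DbC** resolves UNKNOWN by nearest class centroid (Euclidean, in the
  training space; ties to the first declared class). A k-NN variant is
  available behind `GPConfig.dbc_k_neighbors` (off by default; when on,
  the model retains the training matrix).

Cross-class rule intersections are enumerated pairwise with the
analytic test, restricted to the training bounding box. The dispatch is
total by construction: every pattern takes exactly one of the three
paths.

Model files are text: `rules.txt` (one rule per line) plus a
`model.json` sidecar with class order, centroids, domain, the
intersection list, and the full configuration snapshot. Identical seeds
give byte-identical files.

## Data handling

CSV with a header row is the input format (class column by name or
index, default last; missing or non-numeric cells are rejected with the
offending cell named). Standardization is to mean 0 and population
(1/n) variance 1 — population variance so that "variance 1" holds
exactly on the set it was fitted on; constant attributes map to zeros
with sd recorded as 1. Parameters are stored for exact inversion. For
modeling, parameters should be fitted on training data and applied to
test data (both modes are exposed; the visual diagnostics standardize
whole datasets, which is fine for display but would leak in
evaluation). Stratified splitting and k-folding delegate to
scikit-learn with seeded shuffling, behind validation of the per-class
feasibility constraints.

## Visual diagnostics

PCA to three components (scikit-learn, full SVD) with a deterministic
sign convention: each component is flipped so its largest-magnitude
loading is positive. The heatmap artifact is the matrix itself —
attributes × patterns, columns grouped contiguously by class in
declared order, original order kept within a class (no within-class
reordering criterion is imposed), with (min, midpoint, max) color
anchors; rendering to pixels is cosmetic and delegated to matplotlib.
The silhouette score (Euclidean, standardized space) is the numeric
stand-in for the visual separability judgment; it is an extension, not
part of the core method, and singleton classes are skipped with a
warning since their silhouette is undefined.

## Synthetic geometries

The fixture module generates the planar geometries that motivate the
length bound, plus two others:

* **Case A** — line-separable classes; the one-literal half-plane rule
  is exact.
* **Case B** — central rectangle vs. two opposite corners; the
  rectangle (2d literals) and the two corner rules are exact, and no
  single axis-aligned box isolates the corner class.
* **Case C** — horizontal band (default 6 band patterns, at which the
  puncture rule excluding each band point reaches `k·d` = 12 literals)
  vs. outer class covered exactly by two threshold rules.
* **box** — d-dimensional box vs. outside, separated by a margin.
* **overlap** — two orthogonal bars crossing in a central square. A
  shared-strip geometry was considered and rejected: any rule meeting
  the default precision threshold on such data avoids the strip, so
  induced rules of different classes never intersect; crossing bars
  yield high-precision per-class rules that genuinely overlap, which is
  the phenomenon the ensemble exists to handle.

Defaults: domain `[0, 10]` per axis, 50 patterns per class, margin 0.5,
no noise. Generators are pure functions of their spec (seed included).
`noise_sd > 0` adds Gaussian jitter that may break separability; it is
for robustness experiments only. These geometries probe the rule
machinery, not real clinical data: attributes are independent and
uniform, classes are balanced, and boundaries are axis-aligned, so
passing benchmarks demonstrates correctness of the algorithmic
behavior, not expected accuracy on real datasets.

## Benchmark conditions

The seeded benchmark suites (`rulegp.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) fix their problem
sizes as follows:

* the line-separable recovery experiment uses 100 patterns per class,
  margin 0.5, a 70/30 stratified split, 10 seeds;
* the box-face recovery experiment uses d = 3, margin 0.5, and 220
  patterns per class. The size follows from identifiability: a face can
  only be located within ± margin if outside samples adjacent to that
  face exist, and the adjacent slab is ≈ 4.6 % of the outside volume,
  so ~10 boundary-relevant samples per face require a couple of hundred
  patterns per class;
* the component-count demonstration uses crossing bars of half-width
  0.25 with 120 patterns per class, at which each bar rule's expected
  precision (≈ 0.95) sits well above the 0.9 acceptance threshold, so
  both classes reliably contribute a rule and the central overlap is
  exercised;
* the two-rule band demonstration samples the band with 20 patterns:
  with only the nominal 6, the opposite class is so small that slab
  rules dodging 6 points are legitimately competitive, and the
  two-threshold structure is not identifiable from data;
* the many-fixture length-bound suite runs the GP at population 30 /
  15 generations — the bound is a structural invariant and does not
  need a converged search.

## Known limitations

* Only numeric attributes; categorical data must be integer-encoded
  upstream (`=`/`≠` on the codes), and no imputation is performed.
* CSV is the only input format.
* The IC decision function and DbC metric are stand-ins constrained
  only by their architectural roles; both are isolated behind the
  configuration.
* Fitness and genetic operators are this package's own design within
  the stated pressures (discrimination, shortness, few punctures);
  other choices satisfying the same pressures are possible.
* The intersection test treats `≠` punctures as measure-zero, which is
  exact for continuous attributes only.
* Multi-class data is handled one-vs-rest per class with pairwise
  intersection enumeration; no cost-sensitive or probabilistic output
  is provided.
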