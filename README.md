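# rulegp

Evolutionary induction of interpretable IF/THEN classification rules for
tabular (e.g. clinical) data, with an intersection-aware three-component
ensemble and class-separability diagnostics.

## The problem and the method

Clinical decision support wants classifiers a physician can read. A
*rule* is a conjunction of threshold constraints implying a class,

```
IF (a3 >= 1.25) AND (a3 <= 2.00) THEN class=1
```

Each literal `a_j op t` with `op ∈ {<, ≤, >, ≥, =, ≠}` constrains one
attribute, so a rule carves an axis-aligned region out of the
d-dimensional pattern space: half-spaces and hyperrectangles for the
inequality operators, pinned points for `=`, punctured space for `≠`.
Fewer literals mean a more general rule; a hyperrectangle — the least
general shape that still generalizes — needs `2d` literals, and a rule
that excludes each of the `k` opposite-class patterns attribute by
attribute needs `k·d`. That gives a principled cap on rule length: the
search never builds rules longer than `max(2d, k·d)`.

Rules are induced one at a time by **sequential covering**: a
genetic-programming search (flat literal lists, one-point crossover,
threshold/operator/length mutations, tournament selection, a greedy
local refinement of thresholds) evolves the best rule for the target
class, the target patterns it covers are removed, and the search
repeats. The fitness of a rule is

```
score = sensitivity × specificity × (1 − λ·(len−1)/len_max − w·#≠/len)
```

so discrimination is rewarded while long rules and `≠` literals (which
memorize rather than generalize) are penalized.

Per-class rule sets overlap in general — a pattern may fire rules of two
classes (the *rule intersection* problem) or no rule at all. Prediction
therefore dispatches through three complementary components:

* **MC** — the rule-based main classifier: rules of exactly one class
  fire → that class;
* **IC** — the intersection classifier: rules of several classes fire →
  the rule holding the pattern deepest inside its boundaries wins;
* **DbC** — the distance-based fallback: no rule fires → nearest class
  centroid in standardized space.

The `viz` module supplies the companion diagnostics: standardization to
mean 0 / variance 1, PCA to three components for a scatter view, a
class-framed attributes × patterns heatmap matrix, and a silhouette
score that quantifies how separable the classes look — compact,
separable classes predict classifiers with few rules and small
intersections; interlinked classes predict the opposite.

## Worked example

Generate the rectangle-vs-corners geometry (Class-1 in a central box,
Class-0 in two opposite corners), train, and read the rules:

```sh
$ rulegp synth --case B --n 50 --seed 7 --out case_b.csv
wrote 100 patterns (2 attributes) to case_b.csv

$ rulegp train --data case_b.csv --seed 7 --out model/
seed=7
metric  value
accuracy_pct    100.00
rules_total     3
rules_class_0   2
rules_class_1   1
intersection_patterns   0
intersection_rule_pairs 2
unknown_patterns        0
...

$ cat model/rules.txt
IF (a0 <= 2.99449) THEN class=0
IF (a1 > 6.96752) THEN class=0
IF (a1 >= 2.95828) AND (a0 < 6.98088) THEN class=1
```

The learner covers Class-0 with one rule per corner cluster and Class-1
with a single two-literal region; held-out accuracy is 100 %. Note
`intersection_rule_pairs = 2` with `intersection_patterns = 0`: the
rule *regions* overlap in empty space (the model's IC would arbitrate
there), but no test pattern falls in the overlap. `rulegp viz` adds the
separability diagnostics:

```sh
$ rulegp viz --data case_b.csv --out viz/
overall_silhouette      0.3573
silhouette_class_0      -0.0979
silhouette_class_1      0.8125
```

The compact central class scores high; the split-in-two corner class
scores low — exactly the visual intuition the heatmap and scatter
convey.

Library use mirrors the CLI:

```python
from rulegp import FixtureSpec, GPConfig, build_ensemble, evaluate, make_case_b
from rulegp.data import stratified_split

data = make_case_b(FixtureSpec(case="B", n_per_class=50, seed=7))
train, test = stratified_split(data, 0.3, seed=7)
model = build_ensemble(train, GPConfig(seed=7))
print(evaluate(model, test).to_table())
```

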