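# Methods

## Problem and representation

The task is binary screening of online pharmacies — legitimate (LOP) vs
illicit (IOP) — from web *structure* rather than content. The observable is
a bipartite weighted graph: pharmacies `i ∈ P`, referral websites `j ∈ W`,
and backlink counts `l_ij ≥ 1` on realised edges (absent pairs are zero).
Training labels `y_i` split the labeled pharmacies into a safe set `P_s`
and a rogue set `P_r`. Identifiers are opaque strings; no URL
canonicalisation is attempted, so sub-domains of one referrer count as
distinct referrers.

Structure-based prediction rests on one empirical regularity: pharmacies
tend to be referred to by websites that also refer to other pharmacies of
the same status, with good referrers clustering into groups that share
target pharmacies while bad referrers scatter links widely.

## RRPM

Referrer quality: `M_j = (n_s_j − n_r_j) / n_j`, where the `n`-counts are
over *distinct labeled* pharmacies referrer `j` links to. Multiplicity
deliberately does not enter `M_j` (a referrer spamming one pharmacy should
not look more committed to a class), but it does weight the pharmacy-level
aggregate, the reliability score `R_i = Σ_j l_ij·M_j / Σ_j l_ij` over the
pharmacy's training-known referrers. Consequences built into the code:

* `M_j ∈ [−1, 1]` with the endpoints meaning pure-illicit / pure-legitimate
  referral behaviour; `R_i` inherits the bound as a weighted mean.
* Referrers linking only to unlabeled pharmacies receive *no* quality —
  defaulting them to 0 would silently drag `R_i` toward the threshold.
* A pharmacy with edges but no training-known referrer is *indeterminate*:
  `R_i := 0`, flagged. A pharmacy with no edges at all is not scored; the
  classifier answers `unknown` (abstention).
* Both `M_j` and `R_i` are invariant under uniform scaling of all counts.

Decision rule: illicit iff `R_i < T`; the boundary `R_i = T` is legitimate
(strict inequality). Threshold strategies:

* `conservative` (default): `T = max{R_i : i ∈ P_r in training}`. Any
  pharmacy scoring below the *worst-looking* illicit trainer is flagged, so
  false "legitimate" calls are rare — the right asymmetry when a missed
  illicit pharmacy is costlier than a flagged legitimate one. Under heavy
  class imbalance this deliberately sacrifices specificity.
* `accuracy_max`: scan candidate cut points and keep the training-accuracy
  maximiser, ties toward larger `T`. Because training accuracy is a step
  function that changes only when `T` crosses an observed score, the scan
  evaluates the unique scores and the midpoints of consecutive unique
  scores; this hits every attainable accuracy value without the quadratic
  all-pairs midpoint set.

## RKNN

Each pharmacy is the integer vector of its backlink counts over the
training referrer axis (the union of referrers with ≥ 1 edge to a labeled
pharmacy). Queries are compared by Euclidean distance; the K nearest
trainers vote, and with `K_s` legitimate among them the query is legitimate
iff `R_x = K_s/K > 0.5` — an even split goes to illicit, the safety-first
reading of the strict inequality. Numerical choices:

* Counts are used raw by default (`log1p` is available but off): no
  transform is part of the method definition.
* Squared distances are accumulated in exact int64 arithmetic, so distance
  ties are exact; ties are broken by ascending pharmacy identifier, making
  predictions independent of training-row order.
* Query referrers unseen in training are dropped before the distance: they
  add the same constant to every squared distance and cannot change the
  ranking (asserted as a test invariant).
* A query with no edges is `unknown`, as in RRPM.

## Evaluation

Stratified k-fold cross-validation (default 10 folds): per class, shuffled
identifiers are dealt round-robin, so per-class fold counts differ by ≤ 1.
Plain unstratified folds are unusable at a 50:713 imbalance — a fold can
miss the minority class. Models are refitted per fold on training labels
only; fold confusions are pooled into one table before computing metrics
(per-fold averaging would be noisy with 5 minority cases per fold).

Metrics, with illicit as the positive class: accuracy; sensitivity
`TP/(TP+FN)`; specificity `TN/(TN+FP)`; Cohen's kappa
`(p_o − p_e)/(1 − p_e)` on the decided 2×2 table, with the degenerate
`p_e = 1` case mapped to 1 for perfect agreement else 0 and flagged.
Predicted-unknowns are excluded by default (`exclude`); the
`count_as_error` policy instead charges them to accuracy and to the
sensitivity/specificity of their actual class. A separate screening
statistic, `error_rate_with_unknown`, restricts to pharmacies whose actual
status is known and reports `(misclassified + predicted-unknown)/total` as
a percentage — the arithmetic used when checking model output against a
certification database that abstention still fails.

## Synthetic referral ecosystem

The generator emulates the structural phenomena above, not any particular
dataset (the real backlink data is proprietary):

| parameter | default | meaning |
|---|---|---|
| `n_legit`, `n_illicit` | 50, 713 | study-scale class imbalance |
| `n_good_ref`, `n_bad_ref` | 120, 480 | scattered bad referrers outnumber clustered good ones roughly like the class ratio |
| `purity_good`, `purity_bad` | 0.95 | probability a referrer's link targets its own class |
| `links_per_referrer` | 8.0 | mean out-degree, `1 + Poisson(mean − 1)` |
| `multiplicity_mean` | 3.0 | mean backlink count per realised pair, geometric on {1, 2, ...} |
| `cluster_good`, `n_good_clusters` | True, 12 | good referrers form groups with shared target pools |
| `seed` | — | sole source of randomness |

Clusters partition the legitimate pharmacies into small pools; every good
referrer in a cluster cycles its in-class links over the whole pool, so
pool-mates end up referred by the same referrer group with comparable
counts — the co-referral geometry both classifiers exploit (and without
which Euclidean nearest-neighbor search on sparse count vectors collapses
toward the lowest-degree vectors). Bad referrers pick targets uniformly in
the illicit class. Off-class links (probability `1 − purity`) go uniformly
to the other class. Query generation adds unlabeled pharmacies in three
strata: no edges at all (forcing `unknown`), edges only to brand-new
referrers (forcing the indeterminate score), and class-conditional edges
through the existing referrers.

What the generator does **not** model: the real (unknown) backlink-count
distribution, hub referrers spanning many clusters, temporal churn of
pharmacies, and adversarial link manipulation. Passing tests therefore
demonstrate correctness of the algorithms and their qualitative behaviour
under the assumed geometry, not field performance on live web data.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything at the study scale
(763 pharmacies, ~600 referrers, ~4.5k edges) or smaller; oracle
cross-checks use 10–50 random graphs of ≤ 100 pharmacies, where dense
brute-force recomputation is trivially checkable. All stochastic components
take explicit integer seeds (numpy `default_rng`); there is no global
random state, and fixed-seed reruns are byte-identical including serialised
tables.

## Known limitations

* The indeterminate convention (`R_i := 0`) places no-evidence pharmacies
  *above* any negative conservative threshold, i.e. predicts legitimate for
  them; under `accuracy_max` thresholds (typically positive at high purity)
  they fall to illicit. The convention is faithful but worth remembering
  when reading predictions.
* The conservative threshold is an extreme statistic of the illicit score
  distribution and is sensitive to a single anomalous training pharmacy.
* Kappa is near-meaningless at extreme imbalance when a classifier
  predicts almost everything illicit; it is reported alongside, never
  instead of, sensitivity and specificity.
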