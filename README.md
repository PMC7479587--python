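# refpharm

Referral-link classifiers for telling **legitimate online pharmacies (LOPs)**
from **illicit ones (IOPs)**.

Illicit online pharmacies sell prescription drugs and controlled substances
without safeguards, and they outnumber certified pharmacies by an order of
magnitude while opening and closing faster than certification databases can
track them. Content-based detection is easy to game — an illicit shop can
simply copy a legitimate storefront. The *structure of the web around* a
pharmacy is much harder to fake: which referral websites link to it, and what
else those referrers link to. `refpharm` implements two classifiers built on
that idea, plus the evaluation harness and a synthetic referral-ecosystem
generator so the whole pipeline runs without proprietary web-analytics data.

## The models

The data is a bipartite weighted graph: pharmacies *i*, referral websites
*j*, and backlink counts *l<sub>ij</sub>* (the number of links from referrer
*j* to pharmacy *i*). Training labels partition pharmacies into a safe set
*P<sub>s</sub>* and a rogue set *P<sub>r</sub>*.

**RRPM (referral rating prediction method).** Each referrer gets a quality

> *M<sub>j</sub>* = (*n<sup>s</sup><sub>j</sub>* − *n<sup>r</sup><sub>j</sub>*) / *n<sub>j</sub>* ∈ [−1, 1],

where *n<sup>s</sup><sub>j</sub>*, *n<sup>r</sup><sub>j</sub>*, *n<sub>j</sub>*
count the distinct legitimate, illicit and all labeled pharmacies *j* refers
to (*M<sub>j</sub>* = 1: refers only to LOPs; −1: only to IOPs). A query
pharmacy then gets a backlink-weighted reliability score

> *R<sub>i</sub>* = Σ<sub>j</sub> *l<sub>ij</sub>* *M<sub>j</sub>* / Σ<sub>j</sub> *l<sub>ij</sub>*

over its training-known referrers (*R<sub>i</sub>* := 0 when it has none —
"indeterminate"), and is classified **illicit iff *R<sub>i</sub>* < T**.
The default threshold is deliberately conservative — *T* = max
*R<sub>i</sub>* over illicit training pharmacies — so that a pharmacy
predicted legitimate is very unlikely to be illicit (sensitivity-first
screening); an alternative strategy picks the *T* maximising training
accuracy.

**RKNN (referral-based K-nearest neighbor).** Pharmacies are points in the
space of backlink-count vectors; a query is classified by the majority
status of its K nearest training pharmacies under Euclidean distance, with
*R<sub>x</sub>* = K<sub>s</sub>/K as prediction strength (legitimate iff
*R<sub>x</sub>* > 0.5, so an even split goes to illicit).

Both models answer **unknown** for a pharmacy with no referral data at all.
Evaluation uses stratified 10-fold cross-validation with accuracy, Cohen's
kappa, sensitivity (illicit caught) and specificity (legitimate recognised),
and a screening-style error rate in which a model-unknown counts as an error.

## Worked example

Simulate a tiny labeled ecosystem (20 pharmacies) plus 8 unlabeled query
pharmacies, fit RRPM, and classify the queries:

```sh
refpharm simulate --out-edges edges.csv --out-labels labels.csv \
    --preset tiny --seed 11 --queries 8 --frac-no-referral 0.25
refpharm fit --edges edges.csv --labels labels.csv --method rrpm --out rrpm.json
# -> fitted rrpm: 24 referrer qualities, T=-0.458333 (conservative)
refpharm predict --edges edges.csv --model rrpm.json --queries queries.txt --out pred.csv
```

`pred.csv` (queries.txt listed the 8 query ids):

```
pharmacy,status,reliability,total_links,indeterminate,threshold
Q0000,unknown,0.000000,0,True,-0.458333
Q0001,unknown,0.000000,0,True,-0.458333
Q0002,legitimate,0.000000,0,True,-0.458333
Q0003,legitimate,0.666667,6,False,-0.458333
Q0004,illicit,-1.000000,13,False,-0.458333
Q0005,legitimate,0.666667,2,False,-0.458333
Q0006,illicit,-0.679012,27,False,-0.458333
Q0007,legitimate,0.333333,8,False,-0.458333
```

Q0000/Q0001 have no referral data, so the model abstains (*unknown*).
Q0002 links only to referrers unseen in training: its reliability is the
indeterminate 0, which sits above this run's negative threshold — a genuine
limitation of the indeterminate convention (here the true status was
illicit). The scored queries separate cleanly: strongly negative reliability
(Q0004, Q0006) means the pharmacy's referrers mostly point at illicit
pharmacies.

Model comparison on the same data (4 folds):

```sh
refpharm sweep-k --edges edges.csv --labels labels.csv --k-max 3 --folds 4 --seed 11 --out sweep.csv
```

```
model,accuracy,kappa,specificity,sensitivity,n_evaluated,n_unknown
r1nn,0.900000,0.800000,1.000000,0.833333,20,0
r2nn,0.850000,0.680851,0.750000,0.916667,20,0
r3nn,0.900000,0.800000,1.000000,0.833333,20,0
rrpm_conservative,0.950000,0.897959,1.000000,0.916667,20,0
rrpm_accuracy_max,1.000000,1.000000,1.000000,1.000000,20,0
```

The library mirrors the CLI one-to-one (`refpharm.generate_graph`,
`fit_rrpm`, `fit_rknn`, `cross_validate`, `sweep_k`, ...); see the module
docstrings.

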