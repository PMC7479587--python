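"""Cross-validation harness and performance metrics.

Metrics follow the screening convention with *illicit* as the positive
class: sensitivity is the fraction of illicit pharmacies correctly
identified, specificity the fraction of legitimate ones (so Type I
error = 1 - specificity and Type II error = 1 - sensitivity).  Cohen's
kappa is the chance-corrected agreement on the two decided classes;
predictions of "unknown" (a pharmacy with no referral data) are tracked in
a three-way confusion table and handled by an explicit policy:

* ``exclude`` (default for CV) — predicted-unknown cases are dropped;
* ``count_as_error`` — they count against accuracy and against the
  sensitivity/specificity of their actual class.

Under both policies kappa is computed on the decided 2x2 table only.

Cross-validation is stratified: with a 50-vs-713 class imbalance plain
folds can lack the minority class entirely.  Folds depend only on the
labels and the seed, so different methods evaluated with the same seed see
identical folds (paired comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MetricError, SplitError
from .referral_graph import ILLICIT, LEGITIMATE, UNKNOWN, LabelSet, ReferralGraph

STATUSES = (ILLICIT, LEGITIMATE, UNKNOWN)

EXCLUDE = "exclude"
COUNT_AS_ERROR = "count_as_error"


@dataclass
class ConfusionSummary:
    """Counts indexed by (predicted, actual) over the three statuses."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, predicted: str, actual: str, n: int = 1) -> None:
        if predicted not in STATUSES or actual not in STATUSES:
            raise ValueError(f"invalid status pair ({predicted!r}, {actual!r})")
        self.counts[(predicted, actual)] = self.counts.get((predicted, actual), 0) + n

    def get(self, predicted: str, actual: str) -> int:
        return self.counts.get((predicted, actual), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class MetricsReport:
    """Accuracy, kappa, sensitivity and specificity of one evaluation."""

    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    n_evaluated: int
    n_unknown_predictions: int
    kappa_degenerate: bool = False


def stratified_kfold_split(
    labels: LabelSet, n_folds: int, seed: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Partition the labeled pharmacies into stratified folds.

    Within each class, identifiers are shuffled reproducibly and dealt
    round-robin, so per-class counts differ by at most 1 across folds.
    Returns (train_ids, test_ids) pairs, one per fold.
    """
    if n_folds < 2:
        raise SplitError(f"need at least 2 folds, got {n_folds}")
    rng = np.random.default_rng(seed)
    fold_members: list[list[str]] = [[] for _ in range(n_folds)]
    for cls_ids in (sorted(labels.rogue), sorted(labels.safe)):
        if cls_ids and len(cls_ids) < n_folds:
            raise SplitError(
                f"a class has {len(cls_ids)} members, fewer than {n_folds} folds"
            )
        perm = rng.permutation(len(cls_ids))
        for pos, idx in enumerate(perm):
            fold_members[pos % n_folds].append(cls_ids[idx])
    all_ids = set(labels.labels)
    out = []
    for members in fold_members:
        test = tuple(sorted(members))
        train = tuple(sorted(all_ids - set(members)))
        out.append((train, test))
    return out


def _cohen_kappa(tp: int, fn: int, fp: int, tn: int) -> tuple[float, bool]:
    """Kappa on a decided 2x2 table; degenerate marginals (p_e = 1) yield
    1 for perfect agreement, else 0, with a flag."""
    n = tp + fn + fp + tn
    if n == 0:
        raise MetricError("kappa on an empty table")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if p_e >= 1.0:
        return (1.0 if p_o == 1.0 else 0.0), True
    return (p_o - p_e) / (1.0 - p_e), False


def compute_metrics(
    confusion: ConfusionSummary, unknown_policy: str = EXCLUDE
) -> MetricsReport:
    """Metrics from a pooled confusion table over actual-known pharmacies.

    Cases with actual status "unknown" are never scored (no ground truth).
    """
    if unknown_policy not in (EXCLUDE, COUNT_AS_ERROR):
        raise ConfigError(f"unknown policy {unknown_policy!r}")
    tp = confusion.get(ILLICIT, ILLICIT)
    fn = confusion.get(LEGITIMATE, ILLICIT)
    fp = confusion.get(ILLICIT, LEGITIMATE)
    tn = confusion.get(LEGITIMATE, LEGITIMATE)
    u_ill = confusion.get(UNKNOWN, ILLICIT)
    u_leg = confusion.get(UNKNOWN, LEGITIMATE)
    n_unknown = u_ill + u_leg
    if unknown_policy == EXCLUDE:
        n = tp + fn + fp + tn
        sens_den = tp + fn
        spec_den = tn + fp
    else:
        n = tp + fn + fp + tn + n_unknown
        sens_den = tp + fn + u_ill
        spec_den = tn + fp + u_leg
    if n == 0:
        raise MetricError("no evaluated pharmacies after applying the unknown policy")
    kappa, degenerate = _cohen_kappa(tp, fn, fp, tn) if (tp + fn + fp + tn) else (0.0, True)
    return MetricsReport(
        accuracy=(tp + tn) / n,
        kappa=kappa,
        sensitivity=tp / sens_den if sens_den else float("nan"),
        specificity=tn / spec_den if spec_den else float("nan"),
        n_evaluated=n,
        n_unknown_predictions=n_unknown,
        kappa_degenerate=degenerate,
    )


def cross_validate(
    graph: ReferralGraph,
    labels: LabelSet,
    method: str,
    *,
    k: int | None = None,
    strategy: str = "conservative",
    n_folds: int = 10,
    seed: int = 0,
    unknown_policy: str = EXCLUDE,
) -> tuple[MetricsReport, ConfusionSummary]:
    """Stratified k-fold CV of one classifier; fold confusions are pooled.

    ``method`` is "rrpm" (with ``strategy`` conservative or accuracy_max) or
    "rknn" (with neighbor count ``k``).  Within each fold the model —
    including RRPM's referrer qualities and threshold, or RKNN's axis — is
    fitted only on the training labels; test-fold labels never enter the fit.
    """
    from . import rknn as rknn_mod
    from . import rrpm as rrpm_mod

    if method not in ("rrpm", "rknn"):
        raise ConfigError(f"unknown method {method!r}")
    if method == "rknn" and not k:
        raise ConfigError("rknn needs a neighbor count k")
    folds = stratified_kfold_split(labels, n_folds, seed)
    pooled = ConfusionSummary()
    for train_ids, test_ids in folds:
        train_labels = labels.subset(train_ids)
        if method == "rrpm":
            model = rrpm_mod.fit_rrpm(graph, train_labels, strategy)
            predict = lambda pid: rrpm_mod.classify_rrpm(graph, pid, model).status
        else:
            model = rknn_mod.fit_rknn(graph, train_labels, k)
            predict = lambda pid: rknn_mod.classify_rknn(graph, pid, model).status
        for pid in test_ids:
            pooled.add(predict(pid), labels[pid])
    return compute_metrics(pooled, unknown_policy), pooled


def error_rate_with_unknown(confusion: ConfusionSummary) -> float:
    """Error rate (percent) over pharmacies whose ACTUAL status is known.

    A predicted-unknown counts as an error alongside outright
    misclassifications — the accounting used when screening search results
    against a certification database.
    """
    tp = confusion.get(ILLICIT, ILLICIT)
    fn = confusion.get(LEGITIMATE, ILLICIT)
    fp = confusion.get(ILLICIT, LEGITIMATE)
    tn = confusion.get(LEGITIMATE, LEGITIMATE)
    u = confusion.get(UNKNOWN, ILLICIT) + confusion.get(UNKNOWN, LEGITIMATE)
    total = tp + fn + fp + tn + u
    if total == 0:
        raise MetricError("no pharmacies with known actual status")
    return 100.0 * (fn + fp + u) / total
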