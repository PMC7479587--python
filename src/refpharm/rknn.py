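"""Referral-based K-nearest-neighbor classifier (RKNN).

Each pharmacy is represented by its raw backlink-count vector over the
referrer axis (the union of referrers with at least one edge to a training
pharmacy).  A query x is compared with every training pharmacy i by the
Euclidean distance

    D_i = sqrt( sum_j (l_xj - l_ij)^2 ),

the K nearest training pharmacies are taken (distance ties broken by
ascending pharmacy identifier), and with K_s legitimate and K_r illicit
neighbors (K_s + K_r = K) the prediction strength is R_x = K_s / K: the
query is predicted legitimate iff R_x > 0.5, so an even-K split
(R_x = 0.5) is classified illicit — the safety-first reading.  A query with
no referral edges at all is classified "unknown".

Counts enter the distance untransformed by default (an optional ``log1p``
flag exists); query referrers unseen in training are dropped before the
distance computation, which provably never changes the neighbor ranking
(they add one constant to every squared distance).

Squared distances are accumulated in exact int64 arithmetic so that ties —
which the identifier tie-break must see — are exact rather than
float-dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import AxisMismatchError, ConfigError, FitError
from .referral_graph import (
    ILLICIT,
    LEGITIMATE,
    UNKNOWN,
    BacklinkVector,
    LabelSet,
    ReferralGraph,
)

_FORMAT_VERSION = 1


@dataclass
class NeighborResult:
    """The K nearest training pharmacies of one query, with vote counts.

    ``neighbors`` is ordered by non-decreasing distance; ``r_x`` = K_s / K is
    the fraction of legitimate pharmacies among them (prediction strength).
    """

    neighbors: list[tuple[str, float]]
    k_safe: int
    k_rogue: int

    @property
    def k(self) -> int:
        return self.k_safe + self.k_rogue

    @property
    def r_x(self) -> float:
        return self.k_safe / self.k


@dataclass
class RKNNPrediction:
    status: str                          # legitimate | illicit | unknown
    neighbors: NeighborResult | None     # None when status is unknown


@dataclass
class RKNNModel:
    """Training backlink vectors on a fixed referrer axis, their labels, and K."""

    axis: tuple[str, ...]
    pharmacy_ids: tuple[str, ...]
    matrix: sp.csr_matrix               # int64, shape (n_train, len(axis))
    labels: tuple[str, ...]             # aligned with pharmacy_ids
    k: int
    log1p: bool = False
    _row_sq: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if not 1 <= self.k <= n:
            raise ConfigError(f"K must be in [1, {n}], got {self.k}")
        if self.matrix.shape != (len(self.pharmacy_ids), len(self.axis)):
            raise ValueError("matrix shape does not match ids/axis")
        if len(self.labels) != n:
            raise ValueError("labels length does not match training instances")
        m = self.matrix
        self._row_sq = np.asarray(m.multiply(m).sum(axis=1)).ravel().astype(np.int64)


def euclidean_distance(a: BacklinkVector, b: BacklinkVector) -> float:
    """Euclidean distance between two backlink vectors on the same axis."""
    if a.axis != b.axis:
        raise AxisMismatchError("backlink vectors have different referrer axes")
    diff = a.counts - b.counts
    return float(np.sqrt(np.dot(diff, diff)))


def fit_rknn(graph: ReferralGraph, labels: LabelSet, k: int, *, log1p: bool = False) -> RKNNModel:
    """Build the training matrix over the labeled pharmacies.

    The axis is the sorted union of referrers with >= 1 edge to a labeled
    pharmacy; every labeled pharmacy becomes one training row (possibly all
    zero).  Training order is sorted by identifier, though predictions do not
    depend on it.
    """
    labeled = sorted(labels.labels)
    if not labeled:
        raise FitError("no labeled pharmacies")
    axis_set: set[str] = set()
    for pid in labeled:
        axis_set.update(graph.referrers_of(pid))
    axis = tuple(sorted(axis_set))
    col = {j: idx for idx, j in enumerate(axis)}
    rows, cols, vals = [], [], []
    for r, pid in enumerate(labeled):
        for j, l_ij in graph.referrers_of(pid).items():
            rows.append(r)
            cols.append(col[j])
            vals.append(l_ij)
    matrix = sp.csr_matrix(
        (np.array(vals, dtype=np.int64), (rows, cols)),
        shape=(len(labeled), len(axis)),
        dtype=np.int64,
    )
    statuses = tuple(labels[pid] for pid in labeled)
    return RKNNModel(axis, tuple(labeled), matrix, statuses, k, log1p=log1p)


def _neighbor_order(model: RKNNModel, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of training rows sorted by (distance, identifier), plus distances."""
    if model.log1p:
        x = np.log1p(query.astype(np.float64))
        m = model.matrix.astype(np.float64)
        m.data = np.log1p(m.data)
        row_sq = np.asarray(m.multiply(m).sum(axis=1)).ravel()
        d2 = row_sq - 2.0 * (m @ x) + np.dot(x, x)
        d2 = np.maximum(d2, 0.0)
    else:
        d2 = model._row_sq - 2 * (model.matrix @ query) + np.dot(query, query)
    ids = np.asarray(model.pharmacy_ids)
    order = np.lexsort((ids, d2))
    return order, np.sqrt(d2.astype(np.float64))


def classify_rknn(graph: ReferralGraph, pharmacy: str, model: RKNNModel) -> RKNNPrediction:
    """Three-way decision for one pharmacy.

    No referral edges at all -> "unknown".  Otherwise the pharmacy's counts
    are projected onto the model axis (referrers unseen in training are
    dropped), the K nearest training pharmacies vote, and the query is
    legitimate iff R_x > 0.5.
    """
    if not graph.has_edges(pharmacy):
        return RKNNPrediction(UNKNOWN, None)
    query = graph.backlink_vector(pharmacy, model.axis).counts
    order, dist = _neighbor_order(model, query)
    top = order[: model.k]
    neighbors = [(model.pharmacy_ids[t], float(dist[t])) for t in top]
    k_safe = sum(1 for t in top if model.labels[t] == LEGITIMATE)
    result = NeighborResult(neighbors, k_safe, model.k - k_safe)
    status = LEGITIMATE if result.r_x > 0.5 else ILLICIT
    return RKNNPrediction(status, result)


def sweep_k(
    graph: ReferralGraph,
    labels: LabelSet,
    k_values: Sequence[int],
    *,
    n_folds: int = 10,
    seed: int = 0,
    unknown_policy: str = "exclude",
):
    """Cross-validate RKNN for each K with identical folds (paired comparison).

    Returns a list of (K, MetricsReport) in the order of ``k_values``.
    """
    from .evaluation import cross_validate, stratified_kfold_split

    if not k_values:
        raise ConfigError("k_values must be non-empty")
    folds = stratified_kfold_split(labels, n_folds, seed)
    min_train = min(len(labels) - len(test) for _, test in folds)
    for k in k_values:
        if not 1 <= k <= min_train:
            raise ConfigError(f"K={k} exceeds the smallest training-fold size {min_train}")
    out = []
    for k in k_values:
        report, _ = cross_validate(
            graph, labels, "rknn", k=k, n_folds=n_folds, seed=seed,
            unknown_policy=unknown_policy,
        )
        out.append((k, report))
    return out


# ---------------------------------------------------------------------------
# Serialization


def save_rknn(model: RKNNModel, path: str | Path | IO[str]) -> None:
    """Serialize as versioned JSON: axis, sparse COO triples, labels, K."""
    coo = model.matrix.tocoo()
    payload = {
        "format": "refpharm-rknn",
        "version": _FORMAT_VERSION,
        "k": model.k,
        "log1p": model.log1p,
        "axis": list(model.axis),
        "pharmacies": list(model.pharmacy_ids),
        "labels": list(model.labels),
        "entries": sorted(
            (int(r), int(c), int(v)) for r, c, v in zip(coo.row, coo.col, coo.data)
        ),
    }
    if hasattr(path, "write"):
        json.dump(payload, path, indent=1)
    else:
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_rknn(path: str | Path | IO[str]) -> RKNNModel:
    payload = json.load(path) if hasattr(path, "read") else json.loads(Path(path).read_text())
    if payload.get("format") != "refpharm-rknn":
        raise ValueError("not a refpharm RKNN model file")
    entries = payload["entries"]
    rows = [e[0] for e in entries]
    cols = [e[1] for e in entries]
    vals = [e[2] for e in entries]
    matrix = sp.csr_matrix(
        (np.array(vals, dtype=np.int64), (rows, cols)),
        shape=(len(payload["pharmacies"]), len(payload["axis"])),
        dtype=np.int64,
    )
    return RKNNModel(
        tuple(payload["axis"]),
        tuple(payload["pharmacies"]),
        matrix,
        tuple(payload["labels"]),
        int(payload["k"]),
        log1p=bool(payload["log1p"]),
    )
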