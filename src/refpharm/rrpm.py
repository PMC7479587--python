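"""Referral Rating Prediction Method (RRPM).

The method scores every referrer j by its *quality*

    M_j = (n_s_j - n_r_j) / n_j  in [-1, 1],

where n_s_j, n_r_j and n_j are the numbers of distinct legitimate, illicit
and all labeled pharmacies referrer j links to.  M_j = 1 means j refers only
to legitimate pharmacies, M_j = -1 only to illicit ones.  A query pharmacy i
then receives a *reliability score*: the backlink-weighted mean of the
qualities of its referrers,

    R_i = (sum_j l_ij * M_j) / (sum_j l_ij),

summed over the referrers whose quality is known from training.  A pharmacy
whose referrers are all unseen in training is *indeterminate* and gets
R_i = 0; a pharmacy with no referral data at all is classified "unknown".

Classification compares R_i against a threshold T learned from the training
set: illicit iff R_i < T, legitimate otherwise (the boundary R_i = T is
legitimate).  Two threshold strategies exist:

* ``conservative`` — T is the maximum training reliability score among
  illicit pharmacies, so a pharmacy predicted legitimate is very unlikely to
  be illicit (sensitivity-first screening).
* ``accuracy_max`` — T maximises training accuracy over candidate cut
  points; ties go to the larger T (again favouring sensitivity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .errors import FitError, NoReferralDataError
from .referral_graph import ILLICIT, LEGITIMATE, UNKNOWN, LabelSet, ReferralGraph

CONSERVATIVE = "conservative"
ACCURACY_MAX = "accuracy_max"

_FORMAT_VERSION = 1


@dataclass
class ReferrerSupport:
    """Training support of one referrer: counts of distinct labeled pharmacies."""

    n_safe: int    # legitimate pharmacies referred to (n_s_j)
    n_rogue: int   # illicit pharmacies referred to (n_r_j)

    @property
    def n_total(self) -> int:
        return self.n_safe + self.n_rogue


@dataclass
class ReferrerQualityMap:
    """Fitted referrer qualities M_j with their supporting counts.

    Only referrers with at least one edge to a labeled pharmacy appear;
    multiplicity l_ij does not affect M_j (counts are over distinct
    pharmacies).
    """

    quality: dict[str, float] = field(default_factory=dict)
    support: dict[str, ReferrerSupport] = field(default_factory=dict)

    def __contains__(self, referrer: str) -> bool:
        return referrer in self.quality

    def __len__(self) -> int:
        return len(self.quality)

    def __getitem__(self, referrer: str) -> float:
        return self.quality[referrer]


@dataclass
class ReliabilityResult:
    """Reliability score of one pharmacy, with audit fields.

    ``indeterminate`` is True when the pharmacy has edges but none to a
    referrer seen in training; the score is then 0 by convention.
    ``total_links`` is L_i, the total backlink count over training-known
    referrers.
    """

    score: float
    total_links: int
    indeterminate: bool = False


@dataclass
class RRPMPrediction:
    status: str                    # legitimate | illicit | unknown
    reliability: ReliabilityResult


@dataclass
class RRPMModel:
    """Fitted RRPM: referrer qualities, decision threshold and audit trail."""

    qualities: ReferrerQualityMap
    threshold: float
    strategy: str
    training_scores: dict[str, float] = field(default_factory=dict)


def fit_referrer_quality(graph: ReferralGraph, labels: LabelSet) -> ReferrerQualityMap:
    """Score every referrer with >= 1 edge to a labeled pharmacy.

    Referrers linking only to unlabeled pharmacies are omitted (no default
    quality is invented for them).  Raises :class:`FitError` when no labeled
    pharmacy has any edge.
    """
    safe, rogue = labels.safe, labels.rogue
    support: dict[str, ReferrerSupport] = {}
    for (i, j) in graph.backlinks:
        if i in safe:
            s = support.setdefault(j, ReferrerSupport(0, 0))
            s.n_safe += 1
        elif i in rogue:
            s = support.setdefault(j, ReferrerSupport(0, 0))
            s.n_rogue += 1
    if not support:
        raise FitError("empty training signal: no labeled pharmacy has referral edges")
    quality = {
        j: (s.n_safe - s.n_rogue) / s.n_total for j, s in support.items()
    }
    return ReferrerQualityMap(quality, support)


def reliability_score(
    graph: ReferralGraph, pharmacy: str, qualities: ReferrerQualityMap
) -> ReliabilityResult:
    """R_i for one pharmacy given fitted referrer qualities.

    Raises :class:`NoReferralDataError` for a pharmacy with no edges at all;
    callers map that to the "unknown" status.
    """
    row = graph.referrers_of(pharmacy)
    if not row:
        raise NoReferralDataError(f"pharmacy {pharmacy!r} has no referral data")
    weighted = 0.0
    total = 0
    for j, l_ij in row.items():
        if j in qualities:
            weighted += l_ij * qualities[j]
            total += l_ij
    if total == 0:
        return ReliabilityResult(score=0.0, total_links=0, indeterminate=True)
    return ReliabilityResult(score=weighted / total, total_links=total)


def select_threshold(
    training_scores: Mapping[str, float], labels: LabelSet, strategy: str = CONSERVATIVE
) -> float:
    """Choose the decision threshold T from training reliability scores.

    conservative: T = max R_i over illicit training pharmacies, so every
    illicit pharmacy scoring strictly below the worst illicit score is
    caught.  accuracy_max: scan candidate cut points (the unique training
    scores and the midpoints between consecutive unique scores) and keep the
    T with the highest training accuracy under the rule R_i < T -> illicit,
    breaking ties toward the larger T.
    """
    if not training_scores:
        raise FitError("no training scores")
    rogue = labels.rogue
    illicit_scores = [s for p, s in training_scores.items() if p in rogue]
    if strategy == CONSERVATIVE:
        if not illicit_scores:
            raise FitError("conservative threshold needs >= 1 illicit training pharmacy")
        return float(max(illicit_scores))
    if strategy != ACCURACY_MAX:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    safe = labels.safe
    legit_scores = [s for p, s in training_scores.items() if p in safe]
    if not illicit_scores or not legit_scores:
        raise FitError("accuracy_max threshold needs both classes in training")
    r = np.array(sorted(illicit_scores + legit_scores))
    uniq = np.unique(r)
    candidates = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]) if len(uniq) > 1 else uniq
    candidates = np.unique(candidates)
    ill = np.sort(np.array(illicit_scores))
    leg = np.sort(np.array(legit_scores))
    n = len(r)
    # R < T -> illicit: correct illicit have score < T, correct legit have score >= T
    correct = np.searchsorted(ill, candidates, side="left") + (
        len(leg) - np.searchsorted(leg, candidates, side="left")
    )
    best = correct.max()
    # ties toward the larger T (higher sensitivity)
    return float(candidates[np.nonzero(correct == best)[0][-1]])


def fit_rrpm(
    graph: ReferralGraph, labels: LabelSet, strategy: str = CONSERVATIVE
) -> RRPMModel:
    """Fit qualities and threshold on the labeled pharmacies of ``graph``.

    Labeled pharmacies without any referral edge cannot be scored and are
    left out of the threshold computation.
    """
    qualities = fit_referrer_quality(graph, labels)
    training_scores: dict[str, float] = {}
    for pid in labels.labels:
        if graph.has_edges(pid):
            training_scores[pid] = reliability_score(graph, pid, qualities).score
    threshold = select_threshold(training_scores, labels, strategy)
    return RRPMModel(qualities, threshold, strategy, training_scores)


def classify_rrpm(graph: ReferralGraph, pharmacy: str, model: RRPMModel) -> RRPMPrediction:
    """Three-way decision for one pharmacy.

    No referral data at all -> "unknown"; otherwise illicit iff R_i < T and
    legitimate otherwise (the boundary R_i = T is legitimate).  The
    reliability result is always attached for audit.
    """
    try:
        rel = reliability_score(graph, pharmacy, model.qualities)
    except NoReferralDataError:
        return RRPMPrediction(UNKNOWN, ReliabilityResult(0.0, 0, indeterminate=True))
    status = ILLICIT if rel.score < model.threshold else LEGITIMATE
    return RRPMPrediction(status, rel)


# ---------------------------------------------------------------------------
# Serialization


def save_rrpm(model: RRPMModel, path: str | Path | IO[str]) -> None:
    """Serialize the model as versioned JSON with deterministic field order."""
    payload = {
        "format": "refpharm-rrpm",
        "version": _FORMAT_VERSION,
        "strategy": model.strategy,
        "threshold": model.threshold,
        "referrers": [
            {
                "referrer": j,
                "quality": model.qualities.quality[j],
                "n_safe": model.qualities.support[j].n_safe,
                "n_rogue": model.qualities.support[j].n_rogue,
            }
            for j in sorted(model.qualities.quality)
        ],
        "training_scores": {p: model.training_scores[p] for p in sorted(model.training_scores)},
    }
    if hasattr(path, "write"):
        json.dump(payload, path, indent=1)
    else:
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_rrpm(path: str | Path | IO[str]) -> RRPMModel:
    payload = json.load(path) if hasattr(path, "read") else json.loads(Path(path).read_text())
    if payload.get("format") != "refpharm-rrpm":
        raise ValueError("not a refpharm RRPM model file")
    quality = {e["referrer"]: float(e["quality"]) for e in payload["referrers"]}
    support = {
        e["referrer"]: ReferrerSupport(int(e["n_safe"]), int(e["n_rogue"]))
        for e in payload["referrers"]
    }
    return RRPMModel(
        ReferrerQualityMap(quality, support),
        float(payload["threshold"]),
        payload["strategy"],
        {p: float(s) for p, s in payload["training_scores"].items()},
    )
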