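"""Synthetic referral-ecosystem generator.

Real backlink data for online pharmacies is proprietary, so this module
fabricates bipartite referral graphs that reproduce the structural
phenomena the classifiers exploit:

* two pharmacy classes with heavy imbalance (default 50 legitimate vs 713
  illicit, the scale of the study data);
* *good* referrers that link predominantly to legitimate pharmacies and
  cluster in groups sharing target pools (they "refer to each other's
  referred pharmacies"), versus *bad* referrers that scatter links across
  the illicit class;
* mixed purity — a good referrer still links to an illicit pharmacy with
  probability 1 - purity_good, and vice versa;
* integer backlink multiplicities >= 1 on every realised (i, j) pair and
  overwhelming sparsity.

Distributional choices (single-parameter, deliberately simple): referrer
out-degree is 1 + Poisson(mean - 1), per-pair multiplicity is geometric on
{1, 2, ...}.  Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .referral_graph import ILLICIT, LEGITIMATE, LabelSet, ReferralGraph


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic referral ecosystem.

    Defaults mirror the study scale: 763 pharmacies with the 50:713 class
    split, four scattered bad referrers for every clustered good one, high
    but imperfect purity on both sides.
    """

    n_legit: int = 50
    n_illicit: int = 713
    n_good_ref: int = 120
    n_bad_ref: int = 480
    purity_good: float = 0.95    # P(a good referrer's link targets a legitimate pharmacy)
    purity_bad: float = 0.95     # P(a bad referrer's link targets an illicit pharmacy)
    links_per_referrer: float = 8.0
    multiplicity_mean: float = 3.0
    cluster_good: bool = True
    n_good_clusters: int = 12
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_legit, self.n_illicit, self.n_good_ref, self.n_bad_ref) < 0:
            raise ConfigError("counts must be >= 0")
        if not (0.0 <= self.purity_good <= 1.0 and 0.0 <= self.purity_bad <= 1.0):
            raise ConfigError("purities must lie in [0, 1]")
        if self.links_per_referrer <= 0 or self.multiplicity_mean < 1:
            raise ConfigError("links_per_referrer must be > 0 and multiplicity_mean >= 1")
        if self.n_legit + self.n_illicit == 0 and self.n_good_ref + self.n_bad_ref > 0:
            raise ConfigError("referrers without any pharmacy to link to")
        if self.n_good_clusters < 1:
            raise ConfigError("need at least one good-referrer cluster")


def tiny_config(seed: int = 0) -> SimConfig:
    """A 20-pharmacy preset for fast tests."""
    return SimConfig(
        n_legit=8, n_illicit=12, n_good_ref=10, n_bad_ref=14,
        links_per_referrer=5.0, n_good_clusters=2, seed=seed,
    )


def _multiplicity(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with the given mean (p = 1/mean)
    return int(rng.geometric(1.0 / mean))


def _out_degree(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def generate_graph(config: SimConfig) -> tuple[ReferralGraph, LabelSet]:
    """Draw one labeled referral ecosystem.

    Pharmacy ids are L0000.../I0000..., referrer ids G000.../B000... .  Good
    referrers are assigned round-robin to clusters, each cluster owning a
    shared pool of legitimate pharmacies it preferentially refers to (when
    ``cluster_good``).  Bad referrers pick targets uniformly in the
    appropriate class.  Pharmacies may end up with zero edges; they stay
    declared (and labeled) as isolated nodes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    legit = [f"L{n:04d}" for n in range(config.n_legit)]
    illicit = [f"I{n:04d}" for n in range(config.n_illicit)]
    good = [f"G{n:03d}" for n in range(config.n_good_ref)]
    bad = [f"B{n:03d}" for n in range(config.n_bad_ref)]
    labels = LabelSet(
        {**{p: LEGITIMATE for p in legit}, **{p: ILLICIT for p in illicit}}
    )

    # Clusters partition the legitimate pharmacies into small shared pools;
    # every good referrer in a cluster spreads its links over the whole pool,
    # so pool-mates end up referred by the same group of referrers — the
    # co-referral structure the classifiers rely on.
    pools: list[list[str]] = []
    if config.cluster_good and legit:
        n_pools = min(config.n_good_clusters, len(legit))
        shuffled = list(rng.permutation(legit))
        pools = [shuffled[c::n_pools] for c in range(n_pools)]

    edges: list[tuple[str, str, int]] = []

    def _emit_clustered(referrer: str, pool: list[str], off_class: list[str], purity: float) -> None:
        degree = _out_degree(rng, config.links_per_referrer)
        n_stray = int(rng.binomial(degree, 1.0 - purity)) if off_class else 0
        cycle = list(rng.permutation(pool))
        for n in range(degree - n_stray):
            i = cycle[n % len(cycle)]
            edges.append((i, referrer, _multiplicity(rng, config.multiplicity_mean)))
        for _ in range(n_stray):
            i = off_class[int(rng.integers(len(off_class)))]
            edges.append((i, referrer, _multiplicity(rng, config.multiplicity_mean)))

    def _emit_scattered(referrer: str, primary: list[str], secondary: list[str], purity: float) -> None:
        if not primary and not secondary:
            return
        for _ in range(_out_degree(rng, config.links_per_referrer)):
            use_primary = primary and (not secondary or rng.random() < purity)
            target_pool = primary if use_primary else secondary
            i = target_pool[int(rng.integers(len(target_pool)))]
            edges.append((i, referrer, _multiplicity(rng, config.multiplicity_mean)))

    for idx, j in enumerate(good):
        if pools:
            _emit_clustered(j, pools[idx % len(pools)], illicit, config.purity_good)
        else:
            _emit_scattered(j, legit, illicit, config.purity_good)
    for j in bad:
        _emit_scattered(j, illicit, legit, config.purity_bad)

    graph = ReferralGraph.from_edges(edges, pharmacies=legit + illicit, referrers=good + bad)
    return graph, labels


def generate_query_set(
    config: SimConfig,
    graph: ReferralGraph,
    n_queries: int,
    frac_no_referral: float = 0.1,
    frac_unseen_referrers: float = 0.1,
) -> tuple[ReferralGraph, LabelSet]:
    """Emit unlabeled query pharmacies with known ground truth.

    A ``frac_no_referral`` fraction gets zero edges (both classifiers must
    answer "unknown"); a ``frac_unseen_referrers`` fraction links only to
    brand-new referrers (RRPM's reliability is indeterminate, 0); the rest
    link through the existing good/bad referrers by the same class-
    conditional mechanism as training.  Returns the input graph extended
    with the query pharmacies plus a LabelSet of their true statuses.
    """
    config.validate()
    if not (0.0 <= frac_no_referral <= 1.0 and 0.0 <= frac_unseen_referrers <= 1.0):
        raise ConfigError("fractions must lie in [0, 1]")
    if frac_no_referral + frac_unseen_referrers > 1.0 + 1e-12:
        raise ConfigError("frac_no_referral + frac_unseen_referrers must be <= 1")
    rng = np.random.default_rng([config.seed, 0x5EED])
    good = [j for j in graph.referrers if j.startswith("G")]
    bad = [j for j in graph.referrers if j.startswith("B")]
    p_illicit = (
        config.n_illicit / (config.n_legit + config.n_illicit)
        if config.n_legit + config.n_illicit
        else 0.5
    )
    n_none = int(round(frac_no_referral * n_queries))
    n_unseen = int(round(frac_unseen_referrers * n_queries))
    n_unseen = min(n_unseen, n_queries - n_none)

    truth: dict[str, str] = {}
    edges: list[tuple[str, str, int]] = []
    new_referrers: list[str] = []
    for q in range(n_queries):
        qid = f"Q{q:04d}"
        status = ILLICIT if rng.random() < p_illicit else LEGITIMATE
        truth[qid] = status
        if q < n_none:
            continue  # no referral data at all
        if q < n_none + n_unseen:
            for x in range(1 + int(rng.poisson(2.0))):
                rid = f"X{q:04d}_{x}"
                new_referrers.append(rid)
                edges.append((qid, rid, _multiplicity(rng, config.multiplicity_mean)))
            continue
        aligned, other = (bad, good) if status == ILLICIT else (good, bad)
        purity = config.purity_bad if status == ILLICIT else config.purity_good
        for _ in range(_out_degree(rng, 4.0)):
            use_aligned = aligned and (not other or rng.random() < purity)
            pool = aligned if use_aligned else other
            if not pool:
                continue
            j = pool[int(rng.integers(len(pool)))]
            edges.append((qid, j, _multiplicity(rng, config.multiplicity_mean)))

    combined = ReferralGraph.from_edges(
        list(_graph_edges(graph)) + edges,
        pharmacies=list(graph.pharmacies) + sorted(truth),
        referrers=list(graph.referrers) + new_referrers,
    )
    return combined, LabelSet(truth)


def _graph_edges(graph: ReferralGraph):
    for (i, j), count in graph.backlinks.items():
        yield i, j, count


def scaled_config(config: SimConfig, factor: float) -> SimConfig:
    """Shrink (or grow) an ecosystem keeping its proportions; for fast tests."""
    return replace(
        config,
        n_legit=max(2, int(config.n_legit * factor)),
        n_illicit=max(2, int(config.n_illicit * factor)),
        n_good_ref=max(1, int(config.n_good_ref * factor)),
        n_bad_ref=max(1, int(config.n_bad_ref * factor)),
        n_good_clusters=max(1, int(config.n_good_clusters * factor)),
    )
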