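"""Shared fixtures: a small hand-written backlink table and random-graph factories."""

import numpy as np
import pytest

import refpharm as rp

# Mirrors the demonstration layout of the backlink matrix: pharmacy p1 has
# counts (5, 0, 3, ..., 16) over referrers (r1, r2, r3, ..., r9); p2 has (9, 3, 0, ...).
DEMO_EDGES = """pharmacy,referrer,backlinks
p1,r1,5
p1,r3,3
p1,r9,16
p2,r1,9
p2,r2,3
"""

DEMO_LABELS = """pharmacy,status
p1,illicit
p2,legitimate
"""


@pytest.fixture
def demo_graph():
    return rp.read_edge_table(DEMO_EDGES)


@pytest.fixture
def demo_labels():
    return rp.read_labels(DEMO_LABELS)


@pytest.fixture
def tiny_ecosystem():
    """A 20-pharmacy synthetic ecosystem with labels."""
    return rp.generate_graph(rp.tiny_config(seed=7))


@pytest.fixture
def random_labeled_graph():
    """Factory: random sparse bipartite graph plus labels, for oracle tests."""

    def make(rng: np.random.Generator, n_pharm: int = 30, n_ref: int = 12,
             density: float = 0.2, max_count: int = 9):
        pharmacies = [f"p{n:03d}" for n in range(n_pharm)]
        referrers = [f"r{n:03d}" for n in range(n_ref)]
        edges = []
        for i in pharmacies:
            for j in referrers:
                if rng.random() < density:
                    edges.append((i, j, int(rng.integers(1, max_count + 1))))
        graph = rp.ReferralGraph.from_edges(edges, pharmacies=pharmacies, referrers=referrers)
        statuses = rng.random(n_pharm) < 0.5
        labels = rp.LabelSet({
            p: (rp.LEGITIMATE if s else rp.ILLICIT)
            for p, s in zip(pharmacies, statuses)
        })
        return graph, labels

    return make
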