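"""Bipartite pharmacy–referrer backlink structure and status labels.

The central object is :class:`ReferralGraph`: an ordered set of pharmacy
identifiers ``P`` (indexed ``i``), an ordered set of referrer identifiers
``W`` (indexed ``j``), and a sparse mapping ``(i, j) -> l_ij`` of backlink
counts.  A backlink is a hyperlink from referrer ``j`` to pharmacy ``i``;
absent pairs mean zero backlinks, and stored counts are always >= 1.

Identifiers are opaque strings (URLs, hashes, synthetic ids); no URL
normalisation is attempted here — that belongs to data collection.

On-disk formats are small delimited-text tables (comma or tab), one header
row, written deterministically (sorted) so round-trips are byte-stable.
Lines starting with ``#`` are metadata comments and are skipped on read.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import numpy as np

from .errors import ConflictError, ParseError

LEGITIMATE = "legitimate"
ILLICIT = "illicit"
UNKNOWN = "unknown"

#: status tokens accepted on input, mapped case-insensitively
_STATUS_ALIASES = {
    "legitimate": LEGITIMATE,
    "licit": LEGITIMATE,
    "safe": LEGITIMATE,
    "0": LEGITIMATE,
    "illicit": ILLICIT,
    "rogue": ILLICIT,
    "1": ILLICIT,
}

EDGE_HEADER = ("pharmacy", "referrer", "backlinks")
LABEL_HEADER = ("pharmacy", "status")


@dataclass(eq=False)
class BacklinkVector:
    """Backlink counts of one pharmacy along a fixed, ordered referrer axis.

    ``counts[k]`` is ``l_ij`` for referrer ``axis[k]``; referrers the pharmacy
    has no edge to contribute 0.  This is the coordinate vector the
    referral-KNN distance is computed over.
    """

    axis: tuple[str, ...]
    counts: np.ndarray  # int64, same length as axis

    def __post_init__(self) -> None:
        self.axis = tuple(self.axis)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != len(self.axis):
            raise ValueError("counts length must equal axis length")
        if (self.counts < 0).any():
            raise ValueError("backlink counts must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BacklinkVector):
            return NotImplemented
        return self.axis == other.axis and bool(np.array_equal(self.counts, other.counts))


@dataclass
class ReferralGraph:
    """Sparse bipartite weighted graph of backlinks from referrers to pharmacies."""

    pharmacies: tuple[str, ...] = ()
    referrers: tuple[str, ...] = ()
    backlinks: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pharmacies = tuple(self.pharmacies)
        self.referrers = tuple(self.referrers)
        if len(set(self.pharmacies)) != len(self.pharmacies):
            raise ValueError("duplicate pharmacy identifiers")
        if len(set(self.referrers)) != len(self.referrers):
            raise ValueError("duplicate referrer identifiers")
        pset, rset = set(self.pharmacies), set(self.referrers)
        for (i, j), count in self.backlinks.items():
            if i not in pset:
                raise ValueError(f"edge references undeclared pharmacy {i!r}")
            if j not in rset:
                raise ValueError(f"edge references undeclared referrer {j!r}")
            if not isinstance(count, (int, np.integer)) or count < 1:
                raise ValueError(f"backlink count for ({i!r}, {j!r}) must be >= 1")
        self._adj: dict[str, dict[str, int]] | None = None

    # -- construction ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        pharmacies: Iterable[str] = (),
        referrers: Iterable[str] = (),
    ) -> "ReferralGraph":
        """Build a graph from (pharmacy, referrer, count) triples.

        Duplicate (i, j) pairs are summed.  ``pharmacies`` / ``referrers``
        declare extra isolated nodes (no edges), e.g. pharmacies known to
        exist but with no referral data.
        """
        backlinks: dict[tuple[str, str], int] = {}
        p_order: dict[str, None] = dict.fromkeys(pharmacies)
        r_order: dict[str, None] = dict.fromkeys(referrers)
        for i, j, count in edges:
            p_order.setdefault(i)
            r_order.setdefault(j)
            backlinks[(i, j)] = backlinks.get((i, j), 0) + int(count)
        return cls(tuple(p_order), tuple(r_order), backlinks)

    # -- queries ---------------------------------------------------------

    def adjacency(self) -> Mapping[str, Mapping[str, int]]:
        """Per-pharmacy mapping referrer -> l_ij (cached)."""
        if self._adj is None:
            adj: dict[str, dict[str, int]] = {i: {} for i in self.pharmacies}
            for (i, j), count in self.backlinks.items():
                adj[i][j] = count
            self._adj = adj
        return self._adj

    def has_edges(self, pharmacy: str) -> bool:
        """True if the pharmacy has at least one backlink from any referrer."""
        return bool(self.adjacency().get(pharmacy))

    def referrers_of(self, pharmacy: str) -> Mapping[str, int]:
        """Mapping referrer -> l_ij for one pharmacy ({} if none/absent)."""
        return self.adjacency().get(pharmacy, {})

    def backlink_vector(self, pharmacy: str, axis: Iterable[str]) -> BacklinkVector:
        """Project a pharmacy's backlinks onto an ordered referrer axis.

        Position ``k`` holds ``l_{pharmacy, axis[k]}``; off-axis edges are
        dropped and a pharmacy absent from the graph yields all zeros.
        """
        axis = tuple(axis)
        row = self.referrers_of(pharmacy)
        counts = np.fromiter((row.get(j, 0) for j in axis), dtype=np.int64, count=len(axis))
        return BacklinkVector(axis, counts)

    def total_backlinks(self, pharmacy: str) -> int:
        """L_i: the total number of backlinks to a pharmacy (0 if none)."""
        return int(sum(self.referrers_of(pharmacy).values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferralGraph):
            return NotImplemented
        return (
            self.pharmacies == other.pharmacies
            and self.referrers == other.referrers
            and self.backlinks == other.backlinks
        )


@dataclass
class LabelSet:
    """Pharmacy status assignments y_i, partitioning pharmacies into the
    safe set P_s (legitimate) and the rogue set P_r (illicit)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, status in self.labels.items():
            if not pid:
                raise ValueError("empty pharmacy identifier")
            if status not in (LEGITIMATE, ILLICIT):
                raise ValueError(f"invalid status {status!r} for {pid!r}")

    @property
    def safe(self) -> frozenset[str]:
        """P_s — the legitimate pharmacies."""
        return frozenset(p for p, s in self.labels.items() if s == LEGITIMATE)

    @property
    def rogue(self) -> frozenset[str]:
        """P_r — the illicit pharmacies."""
        return frozenset(p for p, s in self.labels.items() if s == ILLICIT)

    def subset(self, ids: Iterable[str]) -> "LabelSet":
        ids = set(ids)
        return LabelSet({p: s for p, s in self.labels.items() if p in ids})

    def __contains__(self, pharmacy: str) -> bool:
        return pharmacy in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pharmacy: str) -> str:
        return self.labels[pharmacy]


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _rows(source: IO[str] | str) -> Iterator[tuple[int, list[str]]]:
    """Yield (line number, fields) from a delimited text stream.

    Accepts a file-like object or a string.  The delimiter (comma or tab) is
    sniffed from the header line; ``#`` comment lines and blank lines are
    skipped but still counted for error messages.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    delimiter: str | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if delimiter is None:
            delimiter = "\t" if "\t" in line else ","
        fields = next(csv.reader([line], delimiter=delimiter))
        yield lineno, [f.strip() for f in fields]


def read_edge_table(source: IO[str] | str) -> ReferralGraph:
    """Read a 3-column backlink edge table into a :class:`ReferralGraph`.

    Columns are ``pharmacy,referrer,backlinks`` (header required); duplicate
    (pharmacy, referrer) rows are summed.  An empty stream yields an empty
    graph.  Raises :class:`ParseError` naming the offending line on wrong
    arity, non-integer or non-positive counts.
    """
    edges: list[tuple[str, str, int]] = []
    saw_header = False
    for lineno, fields in _rows(source):
        if not saw_header:
            saw_header = True
            if [f.lower() for f in fields] != list(EDGE_HEADER):
                raise ParseError(
                    f"line {lineno}: expected header {','.join(EDGE_HEADER)!r}, "
                    f"got {','.join(fields)!r}"
                )
            continue
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        pid, rid, raw_count = fields
        if not pid or not rid:
            raise ParseError(f"line {lineno}: empty identifier")
        try:
            count = int(raw_count)
        except ValueError:
            raise ParseError(f"line {lineno}: backlink count {raw_count!r} is not an integer") from None
        if count < 1:
            raise ParseError(f"line {lineno}: backlink count must be >= 1, got {count}")
        edges.append((pid, rid, count))
    return ReferralGraph.from_edges(edges)


def write_edge_table(graph: ReferralGraph, stream: IO[str], *, header_comment: str = "") -> None:
    """Write the edge table sorted by (pharmacy, referrer) for byte-stable output.

    Isolated nodes carry no rows; serialise them separately if they matter.
    """
    if header_comment:
        for line in header_comment.splitlines():
            stream.write(f"# {line}\n")
    stream.write(",".join(EDGE_HEADER) + "\n")
    for (i, j) in sorted(graph.backlinks):
        stream.write(f"{i},{j},{graph.backlinks[(i, j)]}\n")


def read_labels(source: IO[str] | str) -> LabelSet:
    """Read a 2-column ``pharmacy,status`` table into a :class:`LabelSet`.

    Status tokens are matched case-insensitively: legitimate/licit/safe/0 and
    illicit/rogue/1.  A pharmacy listed twice with the same status is fine;
    conflicting statuses raise :class:`ConflictError`.
    """
    labels: dict[str, str] = {}
    saw_header = False
    for lineno, fields in _rows(source):
        if not saw_header:
            saw_header = True
            if [f.lower() for f in fields] != list(LABEL_HEADER):
                raise ParseError(
                    f"line {lineno}: expected header {','.join(LABEL_HEADER)!r}, "
                    f"got {','.join(fields)!r}"
                )
            continue
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected 2 fields, got {len(fields)}")
        pid, token = fields
        if not pid:
            raise ParseError(f"line {lineno}: empty pharmacy identifier")
        status = _STATUS_ALIASES.get(token.lower())
        if status is None:
            raise ParseError(f"line {lineno}: unrecognized status token {token!r}")
        if pid in labels and labels[pid] != status:
            raise ConflictError(f"line {lineno}: conflicting status for pharmacy {pid!r}")
        labels[pid] = status
    return LabelSet(labels)


def write_labels(labels: LabelSet, stream: IO[str], *, header_comment: str = "") -> None:
    """Write the label table sorted by pharmacy identifier."""
    if header_comment:
        for line in header_comment.splitlines():
            stream.write(f"# {line}\n")
    stream.write(",".join(LABEL_HEADER) + "\n")
    for pid in sorted(labels.labels):
        stream.write(f"{pid},{labels.labels[pid]}\n")
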