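"""Overlap detection between reads by shared q-mers.

Two reads are declared overlapping when they share at least ``m`` distinct
q-mers; with a sufficiently long q (default 30) almost all q-mers shared
between reads come from genuine overlaps on the same genome, so the relation
approximates "sampled from intersecting regions".  The overlap graph has one
node per read and an edge for every overlapping pair.

q-mers are collapsed with their reverse complements by default (canonical
form), making the relation invariant to the sequencing strand.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

from .io import Read, ReadSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T}.

    Raises on N or any other character: callers must pre-filter windows.
    """
    if not _ACGT.issuperset(seq):
        bad = sorted(set(seq) - _ACGT)
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class OverlapParams:
    """Parameters of the overlap relation.

    q : q-mer length (default 30).
    m : minimum number of shared q-mers, floored at 1 (default 5 for short
        reads; 45 is the long-read preset).
    canonical : collapse q-mers with their reverse complements so the
        relation ignores sequencing strand.
    """

    q: int = 30
    m: int = 5
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.m < 0:
            raise ValueError("m must be >= 0")

    @property
    def threshold(self) -> int:
        # m=0 would make every pair overlap; floor at one shared q-mer.
        return max(self.m, 1)


def extract_qmers(read: Read | str, q: int, canonical: bool = True) -> set[str]:
    """Distinct q-length windows of a read, skipping windows containing N.

    Returns the empty set when the read is shorter than q.
    """
    seq = read.seq if isinstance(read, Read) else read
    out: set[str] = set()
    for i in range(len(seq) - q + 1):
        w = seq[i : i + q]
        if "N" in w:
            continue
        out.add(canonical_form(w) if canonical else w)
    return out


def shared_qmer_count(r: Read | str, s: Read | str, params: OverlapParams) -> int:
    """Number of distinct q-mers present in both reads."""
    a = extract_qmers(r, params.q, params.canonical)
    b = extract_qmers(s, params.q, params.canonical)
    return len(a & b)


def overlaps(r: Read | str, s: Read | str, params: OverlapParams) -> bool:
    """True iff the reads share at least max(m, 1) distinct q-mers."""
    return shared_qmer_count(r, s, params) >= params.threshold


class OverlapGraph:
    """Undirected graph over read indices; edge = overlapping pair.

    Edge keys are (u, v) with u < v and map to the shared q-mer count.
    """

    def __init__(self, n_nodes: int, edge_counts: Mapping[tuple[int, int], int]):
        self.n_nodes = int(n_nodes)
        self._counts: dict[tuple[int, int], int] = {}
        adjacency: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for (u, v), c in edge_counts.items():
            if u == v:
                raise ValueError("self-edges are not allowed")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range")
            key = (u, v) if u < v else (v, u)
            self._counts[key] = int(c)
            adjacency[u].add(v)
            adjacency[v].add(u)
        self._adj_sets = adjacency
        self._adj_sorted = [tuple(sorted(s)) for s in adjacency]

    @property
    def n_edges(self) -> int:
        return len(self._counts)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._adj_sets[u]

    def neighbors(self, u: int) -> tuple[int, ...]:
        """Neighbors of u in ascending index order (deterministic)."""
        return self._adj_sorted[u]

    def adjacency_set(self, u: int) -> set[int]:
        return self._adj_sets[u]

    def degree(self, u: int) -> int:
        return len(self._adj_sets[u])

    def shared_count(self, u: int, v: int) -> int:
        key = (u, v) if u < v else (v, u)
        return self._counts[key]

    def edges(self) -> list[tuple[int, int, int]]:
        """Sorted edge list as (u, v, shared_count) with u < v."""
        return [(u, v, self._counts[(u, v)]) for u, v in sorted(self._counts)]

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, c in self.edges():
                fh.write(f"{u}\t{v}\t{c}\n")


def build_overlap_graph(reads: ReadSet | Iterable[Read], params: OverlapParams) -> OverlapGraph:
    """Build the read overlap graph via a q-mer posting-list index.

    Equivalent to the all-pairs definition (``overlaps`` on every pair) but
    only pairs that share at least one q-mer are ever touched.
    """
    read_list = list(reads)
    qmer_sets = [extract_qmers(r, params.q, params.canonical) for r in read_list]
    index: dict[str, list[int]] = defaultdict(list)
    for i, qs in enumerate(qmer_sets):
        for w in qs:
            index[w].append(i)
    pair_counts: Counter[tuple[int, int]] = Counter()
    for postings in index.values():
        if len(postings) < 2:
            continue
        for pair in combinations(postings, 2):
            pair_counts[pair] += 1
    thr = params.threshold
    edges = {p: c for p, c in pair_counts.items() if c >= thr}
    return OverlapGraph(len(read_list), edges)
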