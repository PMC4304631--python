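"""Phase 1: greedy grouping of the overlap graph with simultaneous seed
construction.

Groups are grown breadth-first from a random start node.  Each admitted node
joins the group's seed when it is not adjacent (in the overlap graph) to any
current seed member, so the seed is an independent set: a collection of
mutually non-overlapping reads whose combined sequence approximates a
contiguous sample of the underlying genome.  Growth stops once the seed's
total length exceeds ``s_max`` base pairs — larger seeds gain little
compositional information and increase the chance of absorbing reads from a
different genome — or when the frontier is exhausted.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .io import ReadSet
from .overlap import OverlapGraph

#: Default seed size cap in base pairs.
DEFAULT_S_MAX = 9000


@dataclass(frozen=True)
class Group:
    """A phase-1 read group: members partitioned into seed and non-seed.

    ``members`` preserves admission order; ``seed`` is an independent set of
    the overlap graph and is nonempty whenever ``members`` is.
    """

    index: int
    members: tuple[int, ...]
    seed: tuple[int, ...]
    nonseed: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.seed) | set(self.nonseed) != set(self.members):
            raise ValueError("seed and nonseed must partition members")
        if set(self.seed) & set(self.nonseed):
            raise ValueError("seed and nonseed overlap")
        if self.members and not self.seed:
            raise ValueError("nonempty group must have a nonempty seed")


def seed_size_bp(group: Group, reads: ReadSet) -> int:
    """Total length in bp of the group's seed reads."""
    return sum(reads[i].length for i in group.seed)


def build_groups(
    graph: OverlapGraph,
    reads: ReadSet,
    s_max: int = DEFAULT_S_MAX,
    rng: int | np.random.Generator | None = 0,
) -> list[Group]:
    """Partition all reads into groups by the greedy seed-growing heuristic.

    Parameters
    ----------
    graph : overlap graph over the reads (node i = read i).
    reads : the reads, used for seed length accounting.
    s_max : seed size cap in base pairs; once a seed admission pushes the
        seed past this, the group stops growing and un-admitted frontier
        nodes return to the pool for later groups.
    rng : integer seed or ``numpy.random.Generator`` (or any object with an
        ``integers`` method); drives only the choice of start nodes.

    Notes
    -----
    The frontier is expanded first-in-first-out with neighbor pushes in
    ascending index order, so runs are reproducible given the seed.  Seed
    admission tests adjacency against current seed members only.  Isolated
    nodes become singleton groups.
    """
    n = graph.n_nodes
    if n != len(reads):
        raise ValueError(
            f"graph has {n} nodes but read set has {len(reads)} reads"
        )
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    if not hasattr(rng, "integers"):
        rng = np.random.default_rng(rng)

    assigned = bytearray(n)
    n_left = n
    groups: list[Group] = []
    while n_left:
        remaining = [v for v in range(n) if not assigned[v]]
        start = remaining[int(rng.integers(len(remaining)))]
        assigned[start] = 1
        n_left -= 1
        members = [start]
        seed = [start]
        seed_set = {start}
        nonseed: list[int] = []
        seed_bp = reads[start].length
        capped = seed_bp > s_max

        frontier: deque[int] = deque()
        queued: set[int] = set()

        def push_neighbors(w: int) -> None:
            for x in graph.neighbors(w):
                if not assigned[x] and x not in queued:
                    queued.add(x)
                    frontier.append(x)

        if not capped:
            push_neighbors(start)
        while frontier and not capped:
            u = frontier.popleft()
            queued.discard(u)
            if assigned[u]:
                continue
            assigned[u] = 1
            n_left -= 1
            members.append(u)
            if graph.adjacency_set(u).isdisjoint(seed_set):
                seed.append(u)
                seed_set.add(u)
                seed_bp += reads[u].length
                if seed_bp > s_max:
                    capped = True
            else:
                nonseed.append(u)
            if not capped:
                push_neighbors(u)

        groups.append(
            Group(len(groups), tuple(members), tuple(seed), tuple(nonseed))
        )
    return groups


def write_groups(groups: list[Group], reads: ReadSet, path) -> None:
    """Dump groups as TSV rows (read_id, group_index, in_seed)."""
    with open(path, "w") as fh:
        for g in groups:
            seed_set = set(g.seed)
            for i in g.members:
                fh.write(f"{reads[i].id}\t{g.index}\t{int(i in seed_set)}\n")
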