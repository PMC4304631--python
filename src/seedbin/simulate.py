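"""Synthetic multi-species read sets with known ground truth.

Genomes are sampled from per-species Markov chains over {A,C,G,T} (order 2
by default): distinct transition models stand in for phylogenetic distance,
with larger model divergence emulating more distantly related organisms.
Reads are sampled uniformly along a genome, from either strand, with an
optional per-base substitution error (default 1%); each read records its
species, source genome and 0-based half-open coordinates, so true overlap —
same genome and intersecting intervals — is known exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grouping import Group
from .io import Read, ReadSet, ReadTruth
from .overlap import reverse_complement

_BASES = "ACGT"


def random_markov(
    order: int = 2,
    rng: int | np.random.Generator | None = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """Random transition matrix with Dirichlet(alpha) rows, shape
    (4**order, 4).  Small alpha gives skewed, composition-rich models."""
    rng = np.random.default_rng(rng)
    return rng.dirichlet([alpha] * 4, size=4**order)


def markov_from_base_weights(
    base_weights: Sequence[float],
    order: int = 2,
    rng: int | np.random.Generator | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Transition matrix whose rows all target the given base weights,
    optionally log-normally jittered per row (context dependence)."""
    w = np.asarray(base_weights, dtype=float)
    if w.shape != (4,) or (w <= 0).any():
        raise ValueError("base_weights must be 4 positive values")
    w = w / w.sum()
    rows = np.tile(w, (4**order, 1))
    if jitter > 0:
        rng = np.random.default_rng(rng)
        rows = rows * rng.lognormal(0.0, jitter, size=rows.shape)
    return rows / rows.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: genome length, a Markov composition model and an
    abundance weight controlling its share of the reads."""

    label: str
    genome_length: int
    transition: np.ndarray = field(repr=False)
    order: int = 2
    abundance_weight: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (4**self.order, 4):
            raise ValueError(
                f"transition must have shape ({4 ** self.order}, 4) "
                f"for order {self.order}, got {t.shape}"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition rows must be probabilities summing to 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be positive")
        object.__setattr__(self, "transition", t)


def divergent_species_pair(
    genome_length: int,
    labels: tuple[str, str] = ("sp1", "sp2"),
    rng: int | np.random.Generator | None = 0,
    gc: tuple[float, float] = (0.72, 0.28),
    jitter: float = 0.25,
    order: int = 2,
    abundance_weights: tuple[float, float] = (1.0, 1.0),
) -> tuple[SpeciesSpec, SpeciesSpec]:
    """Two species with strongly divergent composition (GC-rich vs AT-rich
    with jittered context dependence), emulating a large phylogenetic
    distance."""
    rng = np.random.default_rng(rng)
    specs = []
    for label, g, w in zip(labels, gc, abundance_weights):
        weights = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
        t = markov_from_base_weights(weights, order=order, rng=rng, jitter=jitter)
        specs.append(
            SpeciesSpec(
                label=label,
                genome_length=genome_length,
                transition=t,
                order=order,
                abundance_weight=w,
            )
        )
    return specs[0], specs[1]


def generate_genome(
    spec: SpeciesSpec, rng: int | np.random.Generator | None = None
) -> str:
    """Sample a genome string of exactly ``spec.genome_length`` bases from
    the species' Markov model."""
    rng = np.random.default_rng(rng)
    L = spec.genome_length
    order = spec.order
    cum = np.cumsum(spec.transition, axis=1)
    us = rng.random(L)
    out = np.empty(L, dtype=np.int64)
    ctx = 0
    if order == 0:
        for i in range(L):
            out[i] = np.searchsorted(cum[0], us[i], side="right")
    else:
        # Warm-up: the first `order` bases extend a context drawn uniformly.
        ctx = int(rng.integers(4**order))
        mask = 4**order
        for i in range(L):
            b = int(np.searchsorted(cum[ctx], us[i], side="right"))
            out[i] = b
            ctx = (ctx * 4 + b) % mask
    out = np.minimum(out, 3)  # guard against u == 1.0 edge
    return "".join(_BASES[b] for b in out)


def _substitute(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = {ord(b): i for i, b in enumerate(_BASES)}
    idx = np.array([lut[c] for c in arr], dtype=np.int64)
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx[hit] = (idx[hit] + shift) % 4
    return "".join(_BASES[i] for i in idx)


def sample_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    rng: int | np.random.Generator | None = None,
    *,
    species_label: str,
    genome_id: str | None = None,
    error_rate: float = 0.01,
    paired: bool = False,
    fragment_length: int | None = None,
    id_prefix: str | None = None,
) -> list[Read]:
    """Sample reads uniformly from a genome, both strands, with substitution
    errors.

    Truth intervals are genome coordinates regardless of strand.  In paired
    mode each of ``n_reads`` fragments yields two reads (ids suffixed /1
    and /2), the second from the reverse strand of the fragment's far end.
    """
    rng = np.random.default_rng(rng)
    G = len(genome)
    L = read_length
    if L > G:
        raise ValueError(f"read_length {L} exceeds genome length {G}")
    genome_id = genome_id if genome_id is not None else species_label
    prefix = id_prefix if id_prefix is not None else species_label
    reads: list[Read] = []
    if paired:
        F = fragment_length if fragment_length is not None else min(3 * L, G)
        if F < L or F > G:
            raise ValueError(f"fragment_length {F} incompatible with L={L}, G={G}")
        for i in range(n_reads):
            fs = int(rng.integers(0, G - F + 1))
            left = genome[fs : fs + L]
            right = reverse_complement(genome[fs + F - L : fs + F])
            for suffix, seq, start in (
                ("1", left, fs),
                ("2", right, fs + F - L),
            ):
                seq = _substitute(seq, error_rate, rng)
                reads.append(
                    Read(
                        id=f"{prefix}_{i:06d}/{suffix}",
                        seq=seq,
                        truth=ReadTruth(species_label, genome_id, start, start + L),
                    )
                )
    else:
        for i in range(n_reads):
            s = int(rng.integers(0, G - L + 1))
            seq = genome[s : s + L]
            if rng.integers(2):
                seq = reverse_complement(seq)
            seq = _substitute(seq, error_rate, rng)
            reads.append(
                Read(
                    id=f"{prefix}_{i:06d}",
                    seq=seq,
                    truth=ReadTruth(species_label, genome_id, s, s + L),
                )
            )
    return reads


@dataclass
class SimulationSpec:
    """A full multi-species simulation.

    Exactly one of ``n_reads`` (total count, split by abundance weights
    using largest-remainder apportionment) or ``coverage`` (per-species
    fold coverage; count = round(c * genome_length / read_length)) must be
    given.  ``n_reads`` counts fragments in paired mode (2 reads each).
    """

    species: list[SpeciesSpec]
    read_length: int = 80
    n_reads: int | None = None
    coverage: float | None = None
    error_rate: float = 0.01
    paired: bool = False
    fragment_length: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if (self.n_reads is None) == (self.coverage is None):
            raise ValueError("give exactly one of n_reads or coverage")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")


def _apportion(total: int, weights: Sequence[float]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    quotas = total * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    for j in order[:remainder]:
        counts[j] += 1
    return counts.tolist()


def simulate(spec: SimulationSpec) -> tuple[ReadSet, dict[str, str]]:
    """Run a simulation: returns the read set (with truth) and the genomes
    keyed by species label."""
    rng = np.random.default_rng(spec.rng_seed)
    genomes = {sp.label: generate_genome(sp, rng) for sp in spec.species}
    if spec.n_reads is not None:
        counts = _apportion(
            spec.n_reads, [sp.abundance_weight for sp in spec.species]
        )
    else:
        counts = [
            round(spec.coverage * sp.genome_length / spec.read_length)
            for sp in spec.species
        ]
    all_reads: list[Read] = []
    for sp, c in zip(spec.species, counts):
        all_reads.extend(
            sample_reads(
                genomes[sp.label],
                c,
                spec.read_length,
                rng,
                species_label=sp.label,
                error_rate=spec.error_rate,
                paired=spec.paired,
                fragment_length=spec.fragment_length,
            )
        )
    return ReadSet(all_reads), genomes


def true_overlap(r: Read, s: Read) -> bool:
    """True iff both reads come from the same genome and their sampled
    intervals intersect."""
    if r.truth is None or s.truth is None:
        raise ValueError("both reads must carry truth")
    if r.truth.genome_id != s.truth.genome_id:
        return False
    return r.truth.start < s.truth.end and s.truth.start < r.truth.end


def grouping_precision(
    groups: Sequence[Group],
    reads: ReadSet,
    truth: dict[str, str] | None = None,
) -> float:
    """Read-weighted fraction of reads whose group's majority species equals
    their own species.

    Species labels come from each read's truth record, or from an explicit
    read_id -> species mapping.
    """

    def label_of(i: int) -> str:
        r = reads[i]
        if truth is not None:
            return truth[r.id]
        if r.truth is None:
            raise ValueError(f"read {r.id!r} carries no truth")
        return r.truth.species_label

    total = 0
    correct = 0
    for g in groups:
        tally: dict[str, int] = {}
        for i in g.members:
            lab = label_of(i)
            tally[lab] = tally.get(lab, 0) + 1
        if not tally:
            continue
        majority = max(tally.values())
        total += sum(tally.values())
        correct += majority
    if total == 0:
        raise ValueError("no reads in groups")
    return correct / total


def sample_nonoverlapping_reads(
    genome: str,
    n_reads: int,
    read_length: int,
    rng: int | np.random.Generator | None = None,
    *,
    species_label: str,
    genome_id: str | None = None,
    id_prefix: str | None = None,
) -> list[Read]:
    """Sample error-free reads at pairwise-disjoint genome intervals (for
    building reference groups of truly non-overlapping reads)."""
    rng = np.random.default_rng(rng)
    G, L = len(genome), read_length
    if n_reads * L > G:
        raise ValueError("genome too short for that many disjoint reads")
    genome_id = genome_id if genome_id is not None else species_label
    prefix = id_prefix if id_prefix is not None else species_label
    candidates = rng.permutation(G - L + 1)
    chosen: list[int] = []
    for s in candidates:
        s = int(s)
        if all(abs(s - t) >= L for t in chosen):
            chosen.append(s)
            if len(chosen) == n_reads:
                break
    if len(chosen) < n_reads:
        raise ValueError("could not place enough disjoint reads")
    return [
        Read(
            id=f"{prefix}_{i:06d}",
            seq=genome[s : s + L],
            truth=ReadTruth(species_label, genome_id, s, s + L),
        )
        for i, s in enumerate(chosen)
    ]
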