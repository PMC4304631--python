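"""Genomic signatures: normalised, strand-collapsed l-mer frequency vectors.

The l-mer frequency profile of a DNA sample is species-characteristic, and
it is preserved even when the sample is a modest collection (a few kilobase
pairs) of short, mutually non-overlapping reads.  This module computes the
profile of any read collection — in the pipeline, of each group's seed.

Each window is counted once under its canonical class (the lexicographic
minimum of the l-mer and its reverse complement), so profiles do not depend
on which strand the reads were sequenced from.  Merging each l-mer with its
reverse complement shrinks the vector from 4^l entries to 4^l/2 for odd l
and (4^l + 4^(l/2))/2 for even l (palindromic l-mers are their own
complement); for the default l=4 the vector has 136 entries.  Counts are
normalised by the total number of valid windows, Σ_j (|r_j| − l + 1), so
groups of different sizes are comparable.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import Read
from .overlap import canonical_form

DEFAULT_L = 4


def dim(l: int) -> int:
    """Number of canonical l-mer classes: 4^l/2 for odd l,
    (4^l + 4^(l/2))/2 for even l."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if l % 2:
        return 4**l // 2
    return (4**l + 4 ** (l // 2)) // 2


@lru_cache(maxsize=None)
def canonical_lmers(l: int) -> tuple[str, ...]:
    """All canonical l-mers in lexicographic order (the coordinate system of
    the signature vector)."""
    if l < 1:
        raise ValueError("l must be >= 1")
    words = ("".join(p) for p in itertools.product("ACGT", repeat=l))
    return tuple(sorted({canonical_form(w) for w in words}))


@lru_cache(maxsize=None)
def _full_index(l: int) -> dict[str, int]:
    # Every l-mer (not just canonical) -> index of its canonical class.
    ranks = {w: i for i, w in enumerate(canonical_lmers(l))}
    return {
        "".join(p): ranks[canonical_form("".join(p))]
        for p in itertools.product("ACGT", repeat=l)
    }


def lmer_index(lmer: str) -> int:
    """Stable index of an l-mer's canonical class in [0, dim(l))."""
    idx = _full_index(len(lmer))
    try:
        return idx[lmer]
    except KeyError:
        raise ValueError(f"invalid l-mer {lmer!r}") from None


@dataclass(frozen=True)
class SignatureVector:
    """Normalised l-mer frequency vector.

    ``values`` sums to 1 when ``total_lmers`` > 0 and is all-zero otherwise.
    """

    l: int
    values: np.ndarray = field(repr=False)
    total_lmers: int

    def __post_init__(self) -> None:
        if len(self.values) != dim(self.l):
            raise ValueError(
                f"vector length {len(self.values)} != dim({self.l})"
            )


def count_lmers(
    reads: Iterable[Read | str], l: int
) -> tuple[np.ndarray, int]:
    """Count canonical l-mer classes over all windows of all reads.

    Windows containing N are skipped and excluded from the total.  Returns
    (counts, total) with total == sum of counts.
    """
    idx = _full_index(l)
    counts = np.zeros(dim(l), dtype=np.int64)
    total = 0
    for r in reads:
        seq = r.seq if isinstance(r, Read) else r
        for i in range(len(seq) - l + 1):
            w = seq[i : i + l]
            j = idx.get(w)
            if j is not None:
                counts[j] += 1
                total += 1
    return counts, total


def signature(reads: Iterable[Read | str], l: int = DEFAULT_L) -> SignatureVector:
    """Normalised signature of a read collection (all-zero if no valid
    windows)."""
    counts, total = count_lmers(reads, l)
    if total == 0:
        values = np.zeros(dim(l))
    else:
        values = counts / total
    return SignatureVector(l=l, values=values, total_lmers=total)


def euclidean_distance(
    a: SignatureVector | Sequence[float], b: SignatureVector | Sequence[float]
) -> float:
    """Euclidean distance between two signature vectors."""
    va = a.values if isinstance(a, SignatureVector) else np.asarray(a, float)
    vb = b.values if isinstance(b, SignatureVector) else np.asarray(b, float)
    if isinstance(a, SignatureVector) and isinstance(b, SignatureVector):
        if a.l != b.l:
            raise ValueError(f"l mismatch: {a.l} != {b.l}")
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    return float(np.linalg.norm(va - vb))


def write_signatures(
    signatures: Sequence[SignatureVector], path: str | Path
) -> None:
    """Dump signatures as TSV: group_index then one frequency column per
    canonical l-mer (header row names the l-mers in index order)."""
    if not signatures:
        raise ValueError("no signatures to write")
    l = signatures[0].l
    header = "group_index\t" + "\t".join(canonical_lmers(l))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, sig in enumerate(signatures):
            row = "\t".join(format(v, ".10g") for v in sig.values)
            fh.write(f"{i}\t{row}\n")
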