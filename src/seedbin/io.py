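"""Read and table I/O.

Sequences come in as FASTA or FASTQ (optionally gzipped); qualities are
discarded because the binning algorithm uses only base identity.  Characters
outside {A,C,G,T} are normalised to N at parse time; downstream k-mer
extraction skips windows containing N.

Assignment and truth tables are plain headerless TSV so runs are
byte-reproducible.
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

#: Sentinel cluster id for reads left out of any cluster.
UNASSIGNED = -1

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth provenance of a read: species, source genome and the
    0-based half-open interval it was sampled from."""

    species_label: str
    genome_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid truth interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Read:
    """A sequencing read: unique id, uppercase sequence over {A,C,G,T,N},
    and optional ground truth."""

    id: str
    seq: str
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"read {self.id!r} contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class ReadSet:
    """Ordered collection of reads with unique ids and stable iteration
    order."""

    def __init__(self, reads: Iterable[Read]):
        self._reads: list[Read] = list(reads)
        seen: set[str] = set()
        for r in self._reads:
            if r.id in seen:
                raise ValueError(f"duplicate read id {r.id!r}")
            seen.add(r.id)

    @property
    def n(self) -> int:
        return len(self._reads)

    def __len__(self) -> int:
        return len(self._reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self._reads)

    def __getitem__(self, i: int) -> Read:
        return self._reads[i]

    def ids(self) -> list[str]:
        return [r.id for r in self._reads]

    def __repr__(self) -> str:
        return f"ReadSet(n={self.n})"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, format: str = "auto") -> ReadSet:
    """Parse a FASTA/FASTQ file into a :class:`ReadSet`.

    Sequences are uppercased and non-ACGT characters mapped to N; FASTQ
    quality strings are discarded.  ``format='auto'`` guesses from the file
    extension, falling back to sniffing the first character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {format!r}")
    reads: list[Read] = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                seq = _NON_ACGT.sub("N", str(rec.seq).upper())
                reads.append(Read(rec.id, seq))
        except ValueError as exc:
            raise ValueError(
                f"malformed {format} record at index {len(reads)} "
                f"in {path}: {exc}"
            ) from exc
    return ReadSet(reads)


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as unwrapped FASTA (one header line, one sequence line)."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")


class AssignmentTable:
    """Read id -> cluster id mapping in input read order.

    Cluster ids are non-negative integers, or :data:`UNASSIGNED` (-1) for
    reads left out of every cluster.
    """

    def __init__(self, pairs: Iterable[tuple[str, int]]):
        self._map: dict[str, int] = {}
        for rid, cid in pairs:
            if rid in self._map:
                raise ValueError(f"duplicate read id {rid!r} in assignment")
            self._map[rid] = int(cid)

    def __getitem__(self, rid: str) -> int:
        return self._map[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._map.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssignmentTable):
            return NotImplemented
        return list(self._map.items()) == list(other._map.items())

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self._map.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes


def write_assignments(table: AssignmentTable, path: str | Path) -> None:
    """Write an assignment table as 2-column TSV (read_id, cluster_id)."""
    with _open_text(path, "wt") as fh:
        for rid, cid in table.items():
            fh.write(f"{rid}\t{cid}\n")


def read_assignments(path: str | Path) -> AssignmentTable:
    pairs: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0], int(fields[1])))
    return AssignmentTable(pairs)


def read_truth(path: str | Path) -> dict[str, str]:
    """Read a truth TSV mapping read_id -> species_label.

    Only the first two columns are used, so files carrying extra provenance
    columns (genome id, coordinates) are accepted.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            rid, label = fields[0], fields[1]
            if rid in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate read id {rid!r}")
            mapping[rid] = label
    return mapping


def write_truth(reads: Iterable[Read], path: str | Path) -> None:
    """Write truth TSV rows (read_id, species, genome, start, end) for reads
    that carry ground truth."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            if r.truth is None:
                raise ValueError(f"read {r.id!r} carries no truth")
            t = r.truth
            fh.write(
                f"{r.id}\t{t.species_label}\t{t.genome_id}\t{t.start}\t{t.end}\n"
            )
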