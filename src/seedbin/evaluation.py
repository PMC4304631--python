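"""Binning performance metrics: precision, recall and F-measure.

With A_ij the number of reads from species j assigned to cluster i,

    precision = sum_i max_j A_ij / sum_ij A_ij
    recall    = sum_j max_i A_ij / (sum_ij A_ij + #unassigned)
    F-measure = 2 / (1/precision + 1/recall)

Precision measures cluster purity; recall measures species cohesion and is
additionally penalised by reads left unassigned; the F-measure is their
harmonic mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import UNASSIGNED, AssignmentTable


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x m tally: a[i, j] = reads from species j in cluster i, plus the
    count of unassigned reads."""

    a: np.ndarray
    unassigned: int
    cluster_ids: tuple[int, ...]
    species_labels: tuple[str, ...]


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f_measure: float

    def as_percent_lines(self) -> list[str]:
        return [
            f"precision\t{100 * self.precision:.2f}%",
            f"recall\t{100 * self.recall:.2f}%",
            f"F-measure\t{100 * self.f_measure:.2f}%",
        ]


def confusion(table: AssignmentTable, truth: dict[str, str]) -> ConfusionMatrix:
    """Tally the confusion matrix of an assignment against species truth.

    Every read in the table must carry a truth label; rows assigned
    :data:`UNASSIGNED` are counted separately.
    """
    for rid in table:
        if rid not in truth:
            raise ValueError(f"read {rid!r} has no truth label")
    cluster_ids = sorted({c for _, c in table.items() if c != UNASSIGNED})
    species = sorted({truth[rid] for rid in table})
    ci = {c: i for i, c in enumerate(cluster_ids)}
    sj = {s: j for j, s in enumerate(species)}
    a = np.zeros((len(cluster_ids), len(species)), dtype=np.int64)
    unassigned = 0
    for rid, c in table.items():
        if c == UNASSIGNED:
            unassigned += 1
        else:
            a[ci[c], sj[truth[rid]]] += 1
    return ConfusionMatrix(
        a=a,
        unassigned=unassigned,
        cluster_ids=tuple(cluster_ids),
        species_labels=tuple(species),
    )


def precision(cm: ConfusionMatrix) -> float:
    total = int(cm.a.sum())
    if total == 0:
        raise ValueError("precision undefined: no assigned reads")
    return float(cm.a.max(axis=1).sum() / total)


def recall(cm: ConfusionMatrix) -> float:
    denom = int(cm.a.sum()) + cm.unassigned
    if denom == 0:
        raise ValueError("recall undefined: no reads")
    if cm.a.size == 0:
        return 0.0
    return float(cm.a.max(axis=0).sum() / denom)


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when either is 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p == 0 or r == 0:
        return 0.0
    return 2 / (1 / p + 1 / r)


def evaluate(table: AssignmentTable, truth: dict[str, str]) -> EvalReport:
    """Full report for an assignment against ground truth."""
    cm = confusion(table, truth)
    p = precision(cm)
    r = recall(cm)
    return EvalReport(precision=p, recall=r, f_measure=f_measure(p, r))
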