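"""Mismatch-tolerant assignment of cleaned reads to mature miRNAs.

Alignment model: reads are anchored at the reference 5' end (miRNA 5'
ends are biologically homogeneous and editing detection needs positional
fidelity); the read and reference are compared over the shorter of the
two lengths, with a bounded 3' length difference absorbing the dominant
isomiR mode. No indels. A read is assigned to the unique reference with
the fewest mismatches within ``max_mm``; ties between distinct miRNAs
are ambiguous and excluded from counting so that editing denominators
stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MirnaReference, READ_ALPHABET, SampleDesign, write_tsv
from .readproc import UniqueReadTable

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Mismatch:
    """A read/reference disagreement at a 1-based reference position."""

    position: int
    ref_base: str
    read_base: str

    def __str__(self) -> str:
        return f"{self.position}:{self.ref_base}>{self.read_base}"


@dataclass(frozen=True)
class ReadAssignment:
    sequence: str
    status: str  # assigned | ambiguous | unassigned
    mirna_id: str | None = None
    mismatches: tuple[Mismatch, ...] = ()
    count: int = 1

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)


def _compare(read: str, ref: str) -> tuple[int, tuple[Mismatch, ...]]:
    """Mismatches over the 5'-anchored overlap; N counts as a mismatch."""
    n = min(len(read), len(ref))
    mms = tuple(
        Mismatch(i + 1, ref[i], read[i])
        for i in range(n)
        if read[i] != ref[i]
    )
    return len(mms), mms


def align_read(
    sequence: str,
    reference: MirnaReference,
    max_mm: int = 2,
    max_3prime_slack: int = 2,
) -> ReadAssignment:
    """Assign one insert sequence to its best-matching mature miRNA.

    Candidates are references whose length differs from the read by at
    most ``max_3prime_slack``; the best candidate is the one with the
    fewest mismatches. A unique best within ``max_mm`` is assigned; a
    tie between distinct miRNAs is ambiguous; no candidate within
    ``max_mm`` is unassigned.
    """
    if not set(sequence) <= READ_ALPHABET:
        bad = sorted(set(sequence) - READ_ALPHABET)
        raise ValueError(f"non-ACGTN characters in read: {bad}")
    best_mm = max_mm + 1
    best: list[tuple[str, tuple[Mismatch, ...]]] = []
    for mid, ref in reference:
        if abs(len(sequence) - len(ref)) > max_3prime_slack:
            continue
        n_mm, mms = _compare(sequence, ref)
        if n_mm < best_mm:
            best_mm = n_mm
            best = [(mid, mms)]
        elif n_mm == best_mm:
            best.append((mid, mms))
    if best_mm > max_mm or not best:
        return ReadAssignment(sequence, UNASSIGNED)
    if len(best) > 1:
        return ReadAssignment(sequence, AMBIGUOUS)
    mid, mms = best[0]
    return ReadAssignment(sequence, ASSIGNED, mirna_id=mid, mismatches=mms)


@dataclass(frozen=True)
class AssignmentSummary:
    """Read-weighted totals; assigned + ambiguous + unassigned = input."""

    sample_id: str
    assigned: int
    ambiguous: int
    unassigned: int

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned


def assign_sample(
    table: UniqueReadTable,
    reference: MirnaReference,
    max_mm: int = 2,
    max_3prime_slack: int = 2,
) -> tuple[list[ReadAssignment], AssignmentSummary]:
    """Align every unique sequence of a sample, weighting by its count."""
    assignments: list[ReadAssignment] = []
    totals = {ASSIGNED: 0, AMBIGUOUS: 0, UNASSIGNED: 0}
    for seq, count in zip(table.table["sequence"], table.table["count"]):
        a = align_read(seq, reference, max_mm, max_3prime_slack)
        a = ReadAssignment(
            a.sequence, a.status, a.mirna_id, a.mismatches, int(count)
        )
        assignments.append(a)
        totals[a.status] += int(count)
    summary = AssignmentSummary(
        table.sample_id,
        assigned=totals[ASSIGNED],
        ambiguous=totals[AMBIGUOUS],
        unassigned=totals[UNASSIGNED],
    )
    return assignments, summary


def build_count_matrix(
    assignments_by_sample: Mapping[str, Sequence[ReadAssignment]],
    design: SampleDesign,
    reference: MirnaReference,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA x sample raw count matrix plus an excluded-reads side table.

    Ambiguous and unassigned reads are not counted; their totals are
    returned in the side table so conservation is checkable per sample.
    """
    unknown = set(assignments_by_sample) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    samples = [s for s in design.sample_ids if s in assignments_by_sample]
    matrix = pd.DataFrame(0, index=list(reference.ids), columns=samples)
    side_rows = []
    for sid in samples:
        ambiguous = unassigned = 0
        for a in assignments_by_sample[sid]:
            if a.status == ASSIGNED:
                matrix.at[a.mirna_id, sid] += a.count
            elif a.status == AMBIGUOUS:
                ambiguous += a.count
            else:
                unassigned += a.count
        side_rows.append(
            {"sample_id": sid, "ambiguous": ambiguous, "unassigned": unassigned}
        )
    side = pd.DataFrame(side_rows, columns=["sample_id", "ambiguous", "unassigned"])
    return matrix, side


def assignments_to_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    """Detail table: sequence, status, miRNA, count, "pos:ref>alt;..."."""
    rows = [
        {
            "sequence": a.sequence,
            "status": a.status,
            "mirna_id": a.mirna_id or "",
            "count": a.count,
            "n_mismatch": a.n_mismatch,
            "mismatches": ";".join(str(m) for m in a.mismatches),
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=["sequence", "status", "mirna_id", "count", "n_mismatch", "mismatches"],
    )
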