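"""Raw-read cleaning (adapter, quality, length) and unique-read collapsing.

Small-RNA reads are longer than the mature miRNA they contain, so each
raw read is insert + 3' adapter (+ downstream bases). Cleaning locates
the adapter, trims it, and keeps inserts that look like mature miRNAs:
17-24 nt, no (by default) ambiguous bases, adequate mean base quality.
Reads in which the adapter cannot be located are dropped because the
insert boundary is then unknown.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MIN_MIRNA_LEN, MAX_MIRNA_LEN, ReadSet, write_tsv

ADAPTER_SEED_LEN = 8  # exact-match prefix used to locate the adapter


@dataclass(frozen=True)
class CleanStats:
    """Per-sample read-cleaning accounting; categories partition the input."""

    sample_id: str
    total: int
    no_adapter: int
    bad_length: int
    too_many_n: int
    low_quality: int
    passed: int

    def as_row(self) -> dict:
        return self.__dict__.copy()


def clean_reads(
    reads: ReadSet,
    adapter: str,
    min_len: int = MIN_MIRNA_LEN,
    max_len: int = MAX_MIRNA_LEN,
    max_fraction_n: float = 0.0,
    min_mean_quality: float = 20.0,
) -> tuple[ReadSet, CleanStats]:
    """Trim the 3' adapter and apply length / N / quality filters.

    The adapter is located by the leftmost exact occurrence of its first
    8 nt; everything from that point on is trimmed. Filters are applied
    to the insert. Reads without an adapter hit are dropped.
    """
    if not adapter:
        raise ValueError("adapter must be a non-empty DNA string")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    seed = adapter[: ADAPTER_SEED_LEN]
    has_qual = reads.qualities is not None

    kept_seqs: list[str] = []
    kept_quals: list[str] = []
    no_adapter = bad_length = too_many_n = low_quality = 0
    for i, seq in enumerate(reads.sequences):
        pos = seq.find(seed)
        if pos < 0:
            no_adapter += 1
            continue
        insert = seq[:pos]
        if not (min_len <= len(insert) <= max_len):
            bad_length += 1
            continue
        if insert.count("N") > max_fraction_n * len(insert):
            too_many_n += 1
            continue
        if has_qual:
            qual = reads.qualities[i][:pos]
            mean_q = np.mean([ord(c) - 33 for c in qual]) if qual else 0.0
            if mean_q < min_mean_quality:
                low_quality += 1
                continue
            kept_quals.append(qual)
        kept_seqs.append(insert)

    stats = CleanStats(
        sample_id=reads.sample_id,
        total=len(reads),
        no_adapter=no_adapter,
        bad_length=bad_length,
        too_many_n=too_many_n,
        low_quality=low_quality,
        passed=len(kept_seqs),
    )
    cleaned = ReadSet(
        reads.sample_id, kept_seqs, kept_quals if has_qual else None
    )
    return cleaned, stats


@dataclass(frozen=True)
class UniqueReadTable:
    """Distinct insert sequences of one sample with their read counts.

    Rows are sorted by descending count, then lexicographically by
    sequence; counts sum to the number of surviving reads.
    """

    sample_id: str
    table: pd.DataFrame  # columns: sequence, count

    @property
    def total_reads(self) -> int:
        return int(self.table["count"].sum())

    def to_tsv(self, path) -> None:
        write_tsv(self.table, path)

    @classmethod
    def from_tsv(cls, path, sample_id: str) -> "UniqueReadTable":
        return cls(sample_id, pd.read_csv(path, sep="\t"))


def collapse_reads(reads: ReadSet) -> UniqueReadTable:
    """Collapse cleaned reads into a unique-sequence count table."""
    counts = Counter(reads.sequences)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["sequence", "count"])
    return UniqueReadTable(reads.sample_id, df)
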