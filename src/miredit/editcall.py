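"""Per-position mismatch profiles, A>G editing-site calls and summaries.

An edited miRNA is detected from the reads assigned to it: every read
contributes its observed base at each reference position it covers, and
a site is called when the alternative-base fraction clearly exceeds what
the sequencing error rate explains. A>G calls (the ADAR-consistent
signature, inosine read as G) are flagged, as is the seed region
(positions 2-7), where a substitution can redirect target recognition.

The study-level summary keeps only abundant miRNAs (mean normalized
count across the dataset strictly greater than 3000 reads) and reports,
per sex x age group, each retained miRNA's edited-read count, its
percent of that miRNA's reads, and its share of all edited reads (the
"doughnut" share), plus the six most-edited miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MirnaReference, in_seed, write_tsv
from .mirmap import ASSIGNED, ReadAssignment

PROFILE_BASES = ("A", "C", "G", "T", "N")

DEFAULT_MIN_AVG_READS = 3000.0  # strict > cut-off on mean normalized count
DEFAULT_TOP_N = 6


@dataclass(frozen=True)
class MismatchProfile:
    """Per-position observed-base counts over reads assigned to one miRNA.

    ``counts`` is indexed by 1-based reference position with one column
    per base in ``PROFILE_BASES``; row sums equal the coverage at that
    position (reads whose 5'-anchored overlap reaches it).
    """

    mirna_id: str
    ref_seq: str
    counts: pd.DataFrame

    @property
    def coverage(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total_reads(self) -> int:
        """Reads assigned to this miRNA (= coverage at position 1)."""
        return int(self.counts.iloc[0].sum()) if len(self.counts) else 0


def mismatch_profile(
    assignments: Iterable[ReadAssignment],
    mirna_id: str,
    reference: MirnaReference,
) -> MismatchProfile:
    """Tally observed bases per reference position for one miRNA.

    Each assigned read contributes the reference base at every covered
    position except where its mismatch record says otherwise; positions
    beyond a short read's 3' end are uncovered.
    """
    ref = reference.sequence(mirna_id)  # KeyError on unknown id
    L = len(ref)
    base_col = {b: i for i, b in enumerate(PROFILE_BASES)}
    counts = np.zeros((L, len(PROFILE_BASES)), dtype=np.int64)
    ref_cols = np.array([base_col[b] for b in ref])
    # coverage increments per overlap length, applied as a suffix sum
    cov_by_len = np.zeros(L + 1, dtype=np.int64)
    for a in assignments:
        if a.status != ASSIGNED or a.mirna_id != mirna_id:
            continue
        covered = min(len(a.sequence), L)
        cov_by_len[covered] += a.count
        for m in a.mismatches:
            counts[m.position - 1, base_col[m.read_base]] += a.count
            counts[m.position - 1, ref_cols[m.position - 1]] -= a.count
    coverage = np.cumsum(cov_by_len[::-1])[::-1][1:]  # reads covering pos p
    counts[np.arange(L), ref_cols] += coverage
    df = pd.DataFrame(
        counts, index=pd.RangeIndex(1, L + 1, name="position"),
        columns=list(PROFILE_BASES),
    )
    return MismatchProfile(mirna_id, ref, df)


@dataclass(frozen=True)
class EditingCall:
    """One called substitution site on a miRNA."""

    mirna_id: str
    position: int
    ref_base: str
    alt_base: str
    edited_reads: int
    total_reads: int  # coverage at the position
    fraction: float
    is_a_to_g: bool
    in_seed: bool


def call_editing_sites(
    profile: MismatchProfile,
    error_rate: float,
    min_fraction_factor: float = 3.0,
    min_edited_reads: int = 5,
) -> list[EditingCall]:
    """Call substitution sites whose signal exceeds the error model.

    A site is called when the alternative-base fraction is strictly
    greater than ``min_fraction_factor * error_rate`` and at least
    ``min_edited_reads`` reads carry the alternative base. All
    alternative bases are reported; ``is_a_to_g`` flags the
    ADAR-consistent subset.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    calls: list[EditingCall] = []
    cov = profile.coverage
    for pos in profile.counts.index:
        total = int(cov.at[pos])
        if total == 0:
            continue
        ref_base = profile.ref_seq[pos - 1]
        for alt in "ACGT":
            if alt == ref_base:
                continue
            n_alt = int(profile.counts.at[pos, alt])
            if n_alt < min_edited_reads:
                continue
            frac = n_alt / total
            if frac > min_fraction_factor * error_rate:
                calls.append(
                    EditingCall(
                        mirna_id=profile.mirna_id,
                        position=int(pos),
                        ref_base=ref_base,
                        alt_base=alt,
                        edited_reads=n_alt,
                        total_reads=total,
                        fraction=frac,
                        is_a_to_g=(ref_base == "A" and alt == "G"),
                        in_seed=in_seed(int(pos)),
                    )
                )
    return calls


def calls_to_frame(calls: Iterable[EditingCall]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": c.mirna_id,
            "position": c.position,
            "substitution": f"{c.ref_base}>{c.alt_base}",
            "edited_reads": c.edited_reads,
            "total_reads": c.total_reads,
            "fraction": c.fraction,
            "is_a_to_g": c.is_a_to_g,
            "in_seed": c.in_seed,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "position", "substitution", "edited_reads",
            "total_reads", "fraction", "is_a_to_g", "in_seed",
        ],
    )


@dataclass(frozen=True)
class EditedSummary:
    """Edited-miRNA summary for one sex x age group.

    ``table`` columns: mirna_id, edited_read_count,
    percent_of_mirna_reads (100 x edited / reads of that miRNA) and
    doughnut_share (100 x edited / all edited reads among retained
    miRNAs, the doughnut-chart slice). ``top`` lists up to six miRNAs by
    descending edited-read count, ties broken lexicographically.
    """

    group: str
    table: pd.DataFrame
    top: tuple[str, ...]


def summarize_edited(
    calls_by_mirna: Mapping[str, Sequence[EditingCall]],
    assignments: Iterable[ReadAssignment],
    norm_matrix: pd.DataFrame,
    group: str,
    min_avg_reads: float = DEFAULT_MIN_AVG_READS,
    top_n: int = DEFAULT_TOP_N,
) -> EditedSummary:
    """Group-level edited-miRNA summary under the abundance cut-off.

    Retains miRNAs whose mean normalized count across ALL samples of the
    dataset is strictly greater than ``min_avg_reads`` and that have at
    least one called site. ``assignments`` are the (pooled) group reads;
    an edited read is one that carries the alternative base of a called
    site.
    """
    if norm_matrix.shape[1] == 0:
        raise ValueError("empty group: no samples in the count matrix")
    mean_counts = norm_matrix.mean(axis=1)
    retained = [
        m
        for m in sorted(calls_by_mirna)
        if calls_by_mirna[m]
        and m in mean_counts.index
        and mean_counts.at[m] > min_avg_reads
    ]
    called_sites = {
        m: {(c.position, c.alt_base) for c in calls_by_mirna[m]}
        for m in retained
    }
    edited = {m: 0 for m in retained}
    totals = {m: 0 for m in retained}
    for a in assignments:
        if a.status != ASSIGNED or a.mirna_id not in called_sites:
            continue
        totals[a.mirna_id] += a.count
        if any(
            (m.position, m.read_base) in called_sites[a.mirna_id]
            for m in a.mismatches
        ):
            edited[a.mirna_id] += a.count
    total_edited = sum(edited.values())
    rows = []
    for m in retained:
        rows.append(
            {
                "mirna_id": m,
                "edited_read_count": edited[m],
                "percent_of_mirna_reads": (
                    100.0 * edited[m] / totals[m] if totals[m] else 0.0
                ),
                "doughnut_share": (
                    100.0 * edited[m] / total_edited if total_edited else 0.0
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "edited_read_count",
            "percent_of_mirna_reads", "doughnut_share",
        ],
    )
    order = sorted(retained, key=lambda m: (-edited[m], m))
    return EditedSummary(group=group, table=table, top=tuple(order[:top_n]))
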