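"""Mismatch profiles, editing-site calling and edited-miRNA summaries."""

import numpy as np
import pandas as pd
import pytest

from miredit import (
    MirnaReference,
    ReadSet,
    call_editing_sites,
    collapse_reads,
    mismatch_profile,
    summarize_edited,
)
from miredit.editcall import EditingCall
from miredit.mirmap import assign_sample

REF = MirnaReference.from_pairs([("mirX", "TGAGGTAGTAGGTTGTATAGTT")])
SEQ = REF.sequences[0]  # A at positions 3, 7, 10, 17, 19


def _assignments(reads):
    asg, _ = assign_sample(collapse_reads(ReadSet("s", reads)), REF)
    return asg


def _mutate(seq, pos, base):
    return seq[: pos - 1] + base + seq[pos:]


class TestMismatchProfile:
    def test_exact_reads_give_pure_reference_columns(self):
        prof = mismatch_profile(_assignments([SEQ] * 100), "mirX", REF)
        for pos in prof.counts.index:
            ref_base = SEQ[pos - 1]
            assert prof.counts.at[pos, ref_base] == 100
            assert prof.counts.loc[pos].sum() == 100

    def test_mismatch_bookkeeping(self):
        reads = [SEQ] * 70 + [_mutate(SEQ, 10, "G")] * 30
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        assert prof.counts.at[10, "A"] == 70
        assert prof.counts.at[10, "G"] == 30

    def test_short_reads_leave_3prime_uncovered(self):
        reads = [SEQ[:20]] * 10  # 3' trimmed by 2 nt
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        assert prof.coverage.at[20] == 10
        assert prof.coverage.at[21] == 0
        assert prof.coverage.at[22] == 0

    def test_unknown_mirna_fails(self):
        with pytest.raises(KeyError):
            mismatch_profile([], "nope", REF)


class TestCallEditingSites:
    def test_clean_profile_yields_no_calls(self):
        prof = mismatch_profile(_assignments([SEQ] * 1000), "mirX", REF)
        assert call_editing_sites(prof, error_rate=0.0) == []

    def test_planted_a_to_g_called_with_fraction(self, rng):
        n, frac, pos = 10_000, 0.3, 10
        edited = int(round(n * frac))
        reads = [SEQ] * (n - edited) + [_mutate(SEQ, pos, "G")] * edited
        # sprinkle of sequencing error elsewhere, below threshold
        reads[0] = _mutate(SEQ, 14, "A")
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        calls = call_editing_sites(prof, error_rate=0.001)
        a2g = [c for c in calls if c.is_a_to_g]
        assert len(a2g) == 1
        call = a2g[0]
        assert call.position == pos
        assert call.fraction == pytest.approx(frac, abs=0.03)

    def test_non_a_to_g_variant_flagged_false(self):
        reads = [SEQ] * 80 + [_mutate(SEQ, 2, "T")] * 20  # G>T at position 2
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        calls = call_editing_sites(prof, error_rate=0.0)
        assert len(calls) == 1
        assert calls[0].is_a_to_g is False
        assert calls[0].in_seed is True

    def test_calls_monotone_in_min_edited_reads(self):
        reads = [SEQ] * 90 + [_mutate(SEQ, 10, "G")] * 6 + [_mutate(SEQ, 17, "G")] * 12
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        loose = call_editing_sites(prof, 0.0, min_edited_reads=5)
        tight = call_editing_sites(prof, 0.0, min_edited_reads=10)
        assert len(tight) <= len(loose)
        assert {(c.position, c.alt_base) for c in tight} <= {
            (c.position, c.alt_base) for c in loose
        }

    def test_fraction_threshold_is_strict(self):
        # 30/10000 = 3 x error exactly: strict > excludes it
        reads = [SEQ] * 9970 + [_mutate(SEQ, 10, "G")] * 30
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        assert call_editing_sites(prof, error_rate=0.001) == []
        reads = [SEQ] * 9969 + [_mutate(SEQ, 10, "G")] * 31
        prof = mismatch_profile(_assignments(reads), "mirX", REF)
        assert len(call_editing_sites(prof, error_rate=0.001)) == 1

    def test_invalid_error_rate(self):
        prof = mismatch_profile(_assignments([SEQ]), "mirX", REF)
        with pytest.raises(ValueError):
            call_editing_sites(prof, error_rate=0.2)

    def test_seed_flag_boundaries(self):
        # positions 1 and 8 are non-seed; 2 and 7 are seed
        for pos, expected in [(1, False), (2, True), (7, True), (8, False)]:
            alt = "C" if SEQ[pos - 1] != "C" else "T"
            reads = [SEQ] * 80 + [_mutate(SEQ, pos, alt)] * 20
            prof = mismatch_profile(_assignments(reads), "mirX", REF)
            (call,) = call_editing_sites(prof, 0.0)
            assert call.in_seed is expected, f"position {pos}"


def _call(mid, pos=9, alt="G", edited=30, total=100):
    return EditingCall(
        mirna_id=mid, position=pos, ref_base="A", alt_base=alt,
        edited_reads=edited, total_reads=total, fraction=edited / total,
        is_a_to_g=True, in_seed=False,
    )


def _norm_matrix(means: dict[str, float], n_samples: int = 4) -> pd.DataFrame:
    return pd.DataFrame(
        {f"s{j}": pd.Series(means) for j in range(n_samples)}
    )


class TestSummarizeEdited:
    def _assignments_for(self, frac_by_mirna, ref, depth=1000):
        reads = []
        for mid, frac in frac_by_mirna.items():
            seq = ref.sequence(mid)
            pos = seq.index("A") + 1
            n_e = int(round(depth * frac))
            reads += [seq] * (depth - n_e) + [_mutate(seq, pos, "G")] * n_e
        asg, _ = assign_sample(collapse_reads(ReadSet("s", reads)), ref)
        return asg

    def test_mean_count_cutoff_is_strict_at_3000(self):
        ref = MirnaReference.from_pairs(
            [("a", SEQ), ("b", "CATTCCGTCGACCCTGAGTC")]
        )
        asg = self._assignments_for({"a": 0.2, "b": 0.2}, ref)
        calls = {
            m: call_editing_sites(mismatch_profile(asg, m, ref), 0.0)
            for m in ("a", "b")
        }
        norm = _norm_matrix({"a": 2999.5, "b": 3000.5})
        summary = summarize_edited(calls, asg, norm, group="M_3")
        assert summary.table["mirna_id"].tolist() == ["b"]

    def test_single_retained_mirna_gets_full_doughnut(self):
        asg = self._assignments_for({"mirX": 0.3}, REF)
        calls = {"mirX": call_editing_sites(mismatch_profile(asg, "mirX", REF), 0.0)}
        summary = summarize_edited(calls, asg, _norm_matrix({"mirX": 5000.0}), "M_3")
        assert summary.table["doughnut_share"].tolist() == [100.0]
        assert summary.top == ("mirX",)

    def test_doughnut_shares_sum_to_100(self, reference):
        frac = {m: f for m, f in zip(reference.ids[:5], (0.3, 0.2, 0.15, 0.1, 0.05))}
        asg = self._assignments_for(frac, reference)
        calls = {
            m: call_editing_sites(mismatch_profile(asg, m, reference), 0.0)
            for m in frac
        }
        norm = _norm_matrix({m: 5000.0 for m in reference.ids})
        summary = summarize_edited(calls, asg, norm, "F_30")
        assert summary.table["doughnut_share"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_percent_of_mirna_reads(self):
        asg = self._assignments_for({"mirX": 0.25}, REF, depth=400)
        calls = {"mirX": call_editing_sites(mismatch_profile(asg, "mirX", REF), 0.0)}
        summary = summarize_edited(calls, asg, _norm_matrix({"mirX": 4000.0}), "M_3")
        assert summary.table["percent_of_mirna_reads"].iloc[0] == pytest.approx(25.0)

    def test_top_list_ordered_with_lexicographic_ties(self):
        asg = []
        calls = {
            "m_b": [_call("m_b", edited=50)],
            "m_a": [_call("m_a", edited=50)],
            "m_c": [_call("m_c", edited=80)],
        }
        norm = _norm_matrix({"m_a": 4000.0, "m_b": 4000.0, "m_c": 4000.0})
        summary = summarize_edited(calls, asg, norm, "M_3")
        # edited counts come from the assignments (empty here) so all tie at 0
        assert summary.top == ("m_a", "m_b", "m_c")

    def test_empty_group_fails(self):
        with pytest.raises(ValueError, match="empty group"):
            summarize_edited({}, [], pd.DataFrame(index=["m"]), "M_3")
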