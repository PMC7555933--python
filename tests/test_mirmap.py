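"""5'-anchored mismatch-tolerant read assignment and the count matrix."""

import numpy as np
import pytest

from miredit import (
    MirnaReference,
    ReadSet,
    align_read,
    assign_sample,
    build_count_matrix,
    collapse_reads,
)
from miredit.mirmap import AMBIGUOUS, ASSIGNED, UNASSIGNED, Mismatch


def brute_force_align(sequence, reference, max_mm=2, max_3prime_slack=2):
    """Independent oracle: exhaustive scan over all (miRNA, overlap)."""
    candidates = []
    for mid, ref in reference:
        if abs(len(sequence) - len(ref)) > max_3prime_slack:
            continue
        n = min(len(sequence), len(ref))
        mm = [i + 1 for i in range(n) if sequence[i] != ref[i]]
        candidates.append((len(mm), mid, mm))
    if not candidates:
        return (UNASSIGNED, None)
    best = min(c[0] for c in candidates)
    winners = [c for c in candidates if c[0] == best]
    if best > max_mm:
        return (UNASSIGNED, None)
    if len(winners) > 1:
        return (AMBIGUOUS, None)
    return (ASSIGNED, winners[0][1])


def _mutate(seq, pos, base):
    return seq[: pos - 1] + base + seq[pos:]


class TestAlignRead:
    def test_identity(self, reference):
        mid, seq = reference.ids[0], reference.sequences[0]
        a = align_read(seq, reference)
        assert a.status == ASSIGNED and a.mirna_id == mid
        assert a.n_mismatch == 0

    def test_single_substitution_recorded_at_its_position(self, reference):
        mid, seq = reference.ids[2], reference.sequences[2]
        pos = 10
        alt = "G" if seq[pos - 1] != "G" else "C"
        a = align_read(_mutate(seq, pos, alt), reference)
        assert a.status == ASSIGNED and a.mirna_id == mid
        assert a.mismatches == (Mismatch(pos, seq[pos - 1], alt),)

    def test_equidistant_read_is_ambiguous(self):
        # two references each one mismatch from the read
        read = "ACGTACGTACGTACGTACGT"
        ref = MirnaReference.from_pairs(
            [("m1", _mutate(read, 3, "T")), ("m2", _mutate(read, 18, "A"))]
        )
        assert align_read(read, ref).status == AMBIGUOUS

    def test_too_many_mismatches_unassigned(self, reference):
        seq = reference.sequences[0]
        bad = seq
        for pos in (2, 8, 14):
            bad = _mutate(bad, pos, "G" if bad[pos - 1] != "G" else "C")
        assert align_read(bad, reference, max_mm=2).status == UNASSIGNED

    def test_length_slack_rule(self):
        ref = MirnaReference.from_pairs([("m1", "ACGTACGTACGTACGTACGTAC")])  # 22 nt
        assert align_read("ACGTACGTACGTACGTACGT", ref).status == ASSIGNED  # 20 nt
        assert (
            align_read("ACGTACGTACGTACGTACG", ref, max_3prime_slack=2).status
            == UNASSIGNED
        )  # 19 nt: |diff| = 3

    def test_n_counts_as_mismatch(self, reference):
        seq = reference.sequences[0]
        a = align_read(_mutate(_mutate(seq, 1, "N"), 2, "N"), reference)
        assert a.status == ASSIGNED and a.n_mismatch == 2
        b = align_read(
            _mutate(_mutate(_mutate(seq, 1, "N"), 2, "N"), 3, "N"), reference
        )
        assert b.status == UNASSIGNED

    def test_invalid_characters_rejected(self, reference):
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_read("ACGU" * 5, reference)

    def test_matches_brute_force_oracle_on_random_reads(self, reference, rng):
        bases = np.array(list("ACGT"))
        refs = list(reference.sequences)
        for _ in range(1000):
            if rng.random() < 0.7:
                seq = refs[rng.integers(len(refs))]
                # random number of substitutions 0-3, random 3' trim
                for _ in range(rng.integers(0, 4)):
                    p = int(rng.integers(len(seq)))
                    seq = seq[:p] + str(bases[rng.integers(4)]) + seq[p + 1:]
                seq = seq[: len(seq) - int(rng.integers(0, 3))]
                if len(seq) < 17:
                    continue
            else:
                seq = "".join(bases[rng.integers(4)] for _ in range(int(rng.integers(17, 25))))
            got = align_read(seq, reference)
            status, mid = brute_force_align(seq, reference)
            assert got.status == status
            if status == ASSIGNED:
                assert got.mirna_id == mid


class TestAssignSample:
    def test_all_exact_table(self, reference):
        reads = [s for s in reference.sequences for _ in range(3)]
        table = collapse_reads(ReadSet("s", reads))
        _, summary = assign_sample(table, reference)
        assert summary.ambiguous == 0 and summary.unassigned == 0
        assert summary.assigned == len(reads)

    def test_over_threshold_sequence_counted_unassigned(self, reference):
        seq = reference.sequences[0]
        bad = seq
        for pos in (3, 9, 15):
            bad = _mutate(bad, pos, "G" if bad[pos - 1] != "G" else "C")
        table = collapse_reads(ReadSet("s", [bad] * 7))
        _, summary = assign_sample(table, reference, max_mm=2)
        assert summary.unassigned == 7

    def test_conservation_on_simulated_sample(self, reference, design, truth):
        from miredit import clean_reads, simulate_sample_reads
        from miredit.simulate import DEFAULT_ADAPTER

        rs = simulate_sample_reads(truth, reference, "M_15_r1", design, depth=20_000)
        cleaned, _ = clean_reads(rs, DEFAULT_ADAPTER)
        table = collapse_reads(cleaned)
        _, summary = assign_sample(table, reference)
        assert summary.total == table.total_reads
        # error 0.001 on a ~20 nt insert: nearly everything maps
        assert summary.assigned / summary.total >= 0.99


class TestCountMatrix:
    def test_single_sample_single_mirna(self, reference):
        from miredit.core import SampleDesign

        design = SampleDesign.from_rows([("s1", "M", 3, 1)])
        seq = reference.sequences[0]
        table = collapse_reads(ReadSet("s1", [seq] * 100))
        asg, _ = assign_sample(table, reference)
        matrix, side = build_count_matrix({"s1": asg}, design, reference)
        assert matrix.at[reference.ids[0], "s1"] == 100
        assert matrix["s1"].sum() == 100
        assert side["ambiguous"].sum() == 0

    def test_column_sums_equal_assigned_totals(self, reference, design, truth):
        from miredit import clean_reads, simulate_sample_reads
        from miredit.simulate import DEFAULT_ADAPTER

        assignments, summaries = {}, {}
        for sid in ["M_3_r1", "M_3_r2"]:
            rs = simulate_sample_reads(truth, reference, sid, design, depth=5000)
            cleaned, _ = clean_reads(rs, DEFAULT_ADAPTER)
            asg, summary = assign_sample(collapse_reads(cleaned), reference)
            assignments[sid] = asg
            summaries[sid] = summary
        matrix, _ = build_count_matrix(assignments, design, reference)
        for sid in assignments:
            assert matrix[sid].sum() == summaries[sid].assigned

    def test_sample_not_in_design_fails(self, reference, design):
        with pytest.raises(ValueError, match="not in design"):
            build_count_matrix({"ghost": []}, design, reference)

    def test_planted_abundances_recovered(self, reference, design):
        """No DE, no editing: count shares track planted baseline shares."""
        import pandas as pd

        from miredit import clean_reads, simulate_sample_reads
        from miredit.simulate import DEFAULT_ADAPTER, SimulationTruth

        rng = np.random.default_rng(7)
        baseline = {m: float(b) for m, b in zip(reference.ids, rng.uniform(1, 10, len(reference)))}
        groups = [f"{s}_{a}" for s, a in design.groups()]
        truth = SimulationTruth(
            baseline=baseline,
            effects=pd.DataFrame(0.0, index=list(reference.ids), columns=groups),
            editing_sites=(),
            dispersion=1e6,  # near-Poisson so multinomial bounds apply
            error_rate=0.0,
            adapter=DEFAULT_ADAPTER,
            read_length=50,
            master_seed=17,
        )
        depth = 100_000
        rs = simulate_sample_reads(truth, reference, "M_3_r1", design, depth=depth)
        cleaned, _ = clean_reads(rs, DEFAULT_ADAPTER)
        asg, summary = assign_sample(collapse_reads(cleaned), reference)
        design1 = type(design).from_rows([("M_3_r1", "M", 3, 1)])
        matrix, _ = build_count_matrix({"M_3_r1": asg}, design1, reference)
        shares = matrix["M_3_r1"] / matrix["M_3_r1"].sum()
        total_b = sum(baseline.values())
        for mid in reference.ids:
            p = baseline[mid] / total_b
            se = np.sqrt(p * (1 - p) / summary.assigned)
            assert abs(shares[mid] - p) < 3 * se + 1e-3
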