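"""Two-phase change quantification against exhaustive DP oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowaudit._align import align
from flowaudit.change_quant import (
    AlignParams,
    ChangeRecord,
    accordion_report,
    length_summary,
    positional_profile,
    quantify_pair,
    quantify_set,
)
from flowaudit.synthetic import accordion_cohort, apply_edits, random_sequence, simulate_stage_pair
from oracles import gotoh_score, score_alignment

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestAlignerOptimality:
    @given(SEQ, SEQ)
    @settings(max_examples=300, deadline=None)
    def test_global_score_equals_exhaustive_dp(self, a, b):
        for open_, ext in ((-10.0, -1.0), (-100.0, -1.0), (-1.0, -1.0)):
            got = align(a, b, gap_open=open_, gap_extend=ext)
            want = gotoh_score(a, b, gap_open=open_, gap_extend=ext)
            assert got.score == pytest.approx(want)
            # the traced path achieves the reported score
            assert score_alignment(got, gap_open=open_, gap_extend=ext) == pytest.approx(want)

    @given(SEQ, SEQ)
    @settings(max_examples=300, deadline=None)
    def test_overlap_score_equals_exhaustive_dp(self, a, b):
        got = align(a, b, gap_open=-10.0, gap_extend=-1.0, free_head=True, free_tail=True)
        want = gotoh_score(a, b, gap_open=-10.0, gap_extend=-1.0, free_head=True, free_tail=True)
        assert got.score == pytest.approx(want)

    @given(SEQ, SEQ)
    @settings(max_examples=200, deadline=None)
    def test_global_score_matches_biopython(self, a, b):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        got = align(a, b, gap_open=-10.0, gap_extend=-1.0)
        assert got.score == pytest.approx(aligner.score(a, b))


class TestQuantifyPair:
    def test_identity_is_all_zero(self):
        rec = quantify_pair("ACGTACGTAC", "ACGTACGTAC")
        assert (rec.gap3, rec.subs, rec.ins_bp, rec.del_bp) == (0, 0, 0, 0)

    def test_truncation_is_pure_negative_gap3(self):
        rng = np.random.default_rng(0)
        ref = random_sequence(rng, 500)
        rec = quantify_pair(ref[: 500 - 311], ref)
        assert rec.gap3 == -311
        assert rec.total == 0

    def test_extension_is_pure_positive_gap3(self):
        rng = np.random.default_rng(1)
        ref = random_sequence(rng, 300)
        rec = quantify_pair(ref + random_sequence(rng, 40), ref)
        assert rec.gap3 == 40
        assert rec.total == 0

    def test_insert_block_and_mismatch(self):
        rng = np.random.default_rng(2)
        ref = random_sequence(rng, 200)
        query, truth = apply_edits(ref, rng, n_sub=1, n_ins=1, ins_len=3)
        rec = quantify_pair(query, ref)
        assert rec.subs == 1
        assert rec.ins_bp == 3 and rec.ins_events == 1
        assert rec.del_bp == 0

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            quantify_pair("", "ACGT")

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_gap3_antisymmetry(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        b = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        assert quantify_pair(a, b).gap3 == -quantify_pair(b, a).gap3

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_events_bounded_by_bp(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        b = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        rec = quantify_pair(a, b)
        assert rec.ins_events <= rec.ins_bp
        assert rec.del_events <= rec.del_bp

    def test_iupac_tolerance_never_increases_counts(self):
        rng = np.random.default_rng(5)
        plain = AlignParams()
        tolerant = AlignParams(iupac_tolerant=True)
        for _ in range(30):
            ref = random_sequence(rng, 80)
            query, _ = apply_edits(ref, rng, n_sub=1)
            # replace one query base by a degenerate code containing it
            pos = int(rng.integers(len(query)))
            code = {"A": "M", "C": "M", "G": "R", "T": "Y"}[query[pos]]
            degen = query[:pos] + code + query[pos + 1 :]
            base_rec = quantify_pair(query, ref, tolerant)
            degen_rec = quantify_pair(degen, ref, tolerant)
            assert degen_rec.subs <= base_rec.subs
            assert degen_rec.total <= base_rec.total
            # the plain comparison sees the primer's M as a change,
            # the tolerant one does not
            code20 = {"A": "M", "C": "M", "G": "R", "T": "Y"}[ref[20]]
            m_ref = ref[:20] + code20 + ref[21:]
            assert quantify_pair(ref, m_ref, tolerant).total == 0
            assert quantify_pair(ref, m_ref, plain).subs == 1


class TestQuantifySet:
    def test_identical_files_all_zero(self):
        reads = {"a": "ACGTACGT", "b": "TTGGCCAA"}
        table = quantify_set(reads, reads)
        assert len(table) == 2
        assert table.summary().iloc[0]["total_changes"] == 0

    def test_missing_query_id_raises(self):
        with pytest.raises(KeyError, match="missing"):
            quantify_set({"a": "ACGT"}, {"b": "ACGT"})

    def test_ref_only_ids_reported_eliminated(self):
        table = quantify_set({"a": "ACGT"}, {"a": "ACGT", "gone": "ACGT"})
        assert table.eliminated == ["gone"]

    def test_totals_match_injected_truth(self):
        query, ref, truth = simulate_stage_pair(n_reads=80, seed=17, max_trunc3=50)
        table = quantify_set(query, ref)
        frame = table.to_frame().set_index("read_id")
        t = truth.set_index("read_id")
        for col in ("subs", "ins_bp", "del_bp", "ins_events", "del_events", "gap3"):
            assert (frame[col] == t[col]).all(), col
        assert table.summary().iloc[0]["total_changes"] == int(
            (t.subs + t.ins_bp + t.del_bp).sum()
        )

    def test_aggregate_is_column_sum(self):
        query, ref, _ = simulate_stage_pair(n_reads=30, seed=3)
        table = quantify_set(query, ref)
        frame = table.to_frame()
        summary = table.summary().iloc[0]
        assert summary["substitutions"] == frame["subs"].sum()
        assert summary["insertions"] == frame["ins_bp"].sum()
        assert summary["deletions"] == frame["del_bp"].sum()
        assert summary["mean_gap3"] == pytest.approx(frame["gap3"].mean())


class TestAccordion:
    def test_all_zero_inputs_no_accordion(self):
        reads = {"a": "ACGTACGTACGT"}
        t = quantify_set(reads, reads)
        report = accordion_report(t, t, t)
        assert not report["accordion"].any()
        assert (report["excess"] == 0).all()

    def test_forced_three_substitution_excess(self):
        # the 3 bases removed by stage 1 (CGT) are re-added by stage 2
        # as TTC, differing at every position
        s0 = {"r": "ACGTACGT"}
        s1 = {"r": "ACGTA"}
        s2 = {"r": "ACGTATTC"}
        report = accordion_report(
            quantify_set(s1, s0), quantify_set(s2, s1), quantify_set(s2, s0)
        ).set_index("category")
        assert report.loc["total_changes", "step_sum"] == 0
        assert report.loc["total_changes", "net"] == 3
        assert report.loc["total_changes", "excess"] == 3
        assert report.loc["total_changes", "accordion"]

    def test_cohort_excess_equals_tail_mismatches(self):
        s0, s1, s2, truth = accordion_cohort(n_reads=30, seed=8)
        t01 = quantify_set(s1, s0)
        t12 = quantify_set(s2, s1)
        t02 = quantify_set(s2, s0)
        report = accordion_report(t01, t12, t02).set_index("category")
        assert report.loc["total_changes", "excess"] == truth["tail_mismatches"].sum()
        assert report.loc["total_changes", "accordion"]

    def test_mismatched_read_sets_rejected(self):
        ta = quantify_set({"a": "ACGT"}, {"a": "ACGT"})
        tb = quantify_set({"b": "ACGT"}, {"b": "ACGT"})
        with pytest.raises(ValueError, match="identical read sets"):
            accordion_report(ta, ta, tb)


class TestPositionalProfile:
    def test_zero_change_set_is_empty(self):
        reads = {"a": "ACGTACGT"}
        table = quantify_set(reads, reads, keep_alignments=True)
        assert len(positional_profile(table.records)) == 0

    def test_single_substitution_at_position_42(self):
        rng = np.random.default_rng(11)
        ref = random_sequence(rng, 100)
        query = ref[:41] + ("A" if ref[41] != "A" else "C") + ref[42:]
        rec = quantify_pair(query, ref, keep_alignment=True)
        profile = positional_profile([rec])
        assert profile["position"].tolist() == [42]
        assert profile["substitutions"].tolist() == [1]

    def test_accordion_changes_sit_beyond_truncation_points(self):
        s0, _, s2, truth = accordion_cohort(n_reads=30, seed=8)
        table = quantify_set(s2, s0, keep_alignments=True)
        profile = positional_profile(table.records)
        assert profile["position"].min() > truth["trunc_point"].min() - 2

    def test_requires_alignments(self):
        rec = ChangeRecord("x", 0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError, match="alignment"):
            positional_profile([rec])


class TestLengthSummary:
    def test_empty_stage_zero_curve(self):
        summary, hist = length_summary({"s0": {}})
        assert summary.iloc[0]["total_bases"] == 0
        assert len(hist) == 0

    def test_total_is_area_under_curve(self):
        reads = {f"r{i}": "A" * 400 for i in range(10)}
        summary, hist = length_summary({"s0": reads})
        assert summary.iloc[0]["total_bases"] == 4000
        assert hist.iloc[0]["count"] == 10

    def test_truncated_stage_loses_information(self):
        s0, s1, _, _ = accordion_cohort(n_reads=20, seed=2)
        summary, _ = length_summary({"s0": s0, "s1": s1})
        by_stage = summary.set_index("stage")["total_bases"]
        assert by_stage["s1"] < by_stage["s0"]
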