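"""Merging, alignment, HDR gating and counting."""

import functools
import itertools

import numpy as np
import pandas as pd
import pytest

from sgekit.caller import (
    AlignScoring,
    FastqRead,
    _revcomp,
    align_global,
    call_sample,
    classify_read,
    compute_editing_summary,
    compute_indel_spectrum,
    count_variants,
    merge_pairs,
)
from sgekit.tables import CountTable, indel_row


def oracle_score(read: str, ref: str, scoring: AlignScoring) -> int:
    """Independent NW oracle: plain memoized recursion, no DP matrix."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        options = []
        if i > 0 and j > 0:
            sub = scoring.match if read[i - 1] == ref[j - 1] else scoring.mismatch
            options.append(best(i - 1, j - 1) + sub)
        if i > 0:
            options.append(best(i - 1, j) + scoring.gap)
        if j > 0:
            options.append(best(i, j - 1) + scoring.gap)
        return max(options)

    return best(len(read), len(ref))


class TestAlignGlobal:
    def test_identical_sequences(self):
        aln = align_global("ACGTACGT", "ACGTACGT")
        assert aln.score == 16 and "-" not in aln.aligned_read

    def test_single_deletion_documented_scoring(self):
        # with the classic 2/-1/-2 parameters: 3 matches + 1 gap = 4
        aln = align_global("AGT", "ACGT", AlignScoring(2, -1, -2))
        assert aln.score == 4
        assert aln.aligned_read.count("-") == 1

    def test_matches_oracle_small_alphabet(self):
        scoring = AlignScoring()
        seqs = ["".join(p) for n in (1, 2, 3, 4)
                for p in itertools.product("AC", repeat=n)]
        for a in seqs:
            for b in seqs:
                assert align_global(a, b, scoring).score == oracle_score(a, b, scoring)

    def test_aligned_pair_is_consistent(self):
        aln = align_global("ACCTGAC", "ACGTAC")
        assert aln.aligned_read.replace("-", "") == "ACCTGAC"
        assert aln.aligned_ref.replace("-", "") == "ACGTAC"
        assert len(aln.aligned_read) == len(aln.aligned_ref)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")
        with pytest.raises(ValueError):
            align_global("ACXG", "ACGT")


class TestMergePairs:
    def test_offset_100mers_merge_to_150(self):
        rng = np.random.default_rng(0)
        frag = "".join(rng.choice(list("ACGT"), 150))
        r1 = FastqRead("p", frag[:100], (30,) * 100)
        r2 = FastqRead("p", _revcomp(frag[50:]), (30,) * 100)
        merged, dropped = merge_pairs([r1], [r2], min_overlap=20)
        assert dropped == 0
        assert merged[0].seq == frag and len(merged[0].seq) == 150

    def test_below_min_overlap_dropped(self):
        r1 = FastqRead("p", "ACGTACGTAC", (30,) * 10)
        r2 = FastqRead("p", _revcomp("TTTTTTTTTT"), (30,) * 10)
        merged, dropped = merge_pairs([r1], [r2], min_overlap=4,
                                      max_mismatch_frac=0.0)
        assert merged == [] and dropped == 1

    def test_disagreement_resolved_by_quality(self):
        rng = np.random.default_rng(1)
        frag = "".join(rng.choice(list("ACGT"), 80))
        # mate 1 carries an error in the overlap at low quality
        err_pos = 45
        wrong = "A" if frag[err_pos] != "A" else "C"
        seq1 = frag[:err_pos] + wrong + frag[err_pos + 1:60]
        q1 = [30] * 60
        q1[err_pos] = 5
        r1 = FastqRead("p", seq1, tuple(q1))
        r2 = FastqRead("p", _revcomp(frag[20:]), (30,) * 60)
        merged, _ = merge_pairs([r1], [r2], min_overlap=20)
        assert merged[0].seq == frag  # mate-2 base retained

    def test_unpaired_raises(self):
        r = FastqRead("a", "ACGT", (30,) * 4)
        with pytest.raises(ValueError):
            merge_pairs([r], [])


class TestClassifyRead:
    def test_reference_read_is_wt(self, toy_design):
        aln = align_global(toy_design.reference_seq, toy_design.reference_seq)
        assert classify_read(aln, toy_design).category == "WT"

    def test_marker_plus_codon_swap_is_hdr_variant(self, toy_design):
        from sgekit.design import CdnaPosition, make_variant_key

        key = make_variant_key(
            toy_design,
            [(CdnaPosition(169), "T", "G"), (CdnaPosition(170), "A", "A"),
             (CdnaPosition(171), "C", "T")],
        )
        read = toy_design.apply_edits(key.edits, with_marker=True)
        cls = classify_read(align_global(read, toy_design.reference_seq), toy_design)
        assert cls.category == "HDR_variant"
        assert cls.variant.hgvs_c == key.hgvs_c

    def test_marker_only_read_maps_to_wt_codon_key(self, toy_design):
        read = toy_design.apply_edits(with_marker=True)
        cls = classify_read(align_global(read, toy_design.reference_seq), toy_design)
        assert cls.category == "HDR_variant"
        assert cls.variant.is_marker_only

    def test_marker_plus_indel_is_indel_not_hdr(self, toy_design):
        ref = toy_design.reference_seq
        cut = toy_design.cut_sites[0]
        read = toy_design.apply_edits(with_marker=True)
        read = read[:cut] + read[cut + 1:]  # 1-bp deletion at the cut
        cls = classify_read(align_global(read, ref), toy_design)
        assert cls.category == "indel"
        assert cls.indel[0] == -1

    def test_read_with_n_rejected(self, toy_design):
        ref = toy_design.reference_seq
        read = "N" + ref[1:]
        cls = classify_read(align_global(read, ref), toy_design)
        assert cls.category == "rejected_N"

    def test_substitution_outside_target_rejected(self, toy_design):
        read = list(toy_design.apply_edits(with_marker=True))
        read[2] = "A" if read[2] != "A" else "C"  # stray upstream change
        cls = classify_read(align_global("".join(read), toy_design.reference_seq),
                            toy_design)
        assert cls.category == "rejected_other"

    def test_categories_partition_reads(self, toy_design):
        reads = [
            toy_design.reference_seq,
            toy_design.apply_edits(with_marker=True),
            "N" + toy_design.reference_seq[1:],
        ]
        cls, failures = call_sample(reads, toy_design)
        assert failures == 0 and len(cls) == len(reads)
        assert [c.category for c in cls] == ["WT", "HDR_variant", "rejected_N"]


class TestCounting:
    def test_counts_aggregate_and_totals_conserve(self, toy_design):
        reads = [toy_design.reference_seq] * 3 + \
            [toy_design.apply_edits(with_marker=True)] * 10
        cls, _ = call_sample(reads, toy_design)
        table = count_variants({"d3_pre_r1": cls})
        assert table.counts.loc["WT", "d3_pre_r1"] == 3
        assert table.counts.loc["c.=", "d3_pre_r1"] == 10
        assert table.totals["d3_pre_r1"] == 13

    def test_editing_summary_fractions(self):
        counts = pd.DataFrame({"s1": [10_000, 985_000, 5_000]},
                              index=["c.=", "WT", indel_row(-1, 0)])
        table = CountTable(counts, pd.Series({"s1": 1_000_000}))
        summary = compute_editing_summary(table)
        assert summary.loc["s1", "pct_hdr"] == pytest.approx(1.0)
        assert summary.loc["s1", "pct_indel"] == pytest.approx(0.5)

    def test_all_wt_sample_has_zero_editing(self, toy_design):
        cls, _ = call_sample([toy_design.reference_seq] * 5, toy_design)
        table = count_variants({"s": cls})
        summary = compute_editing_summary(table)
        assert summary.loc["s", "pct_hdr"] == 0.0
        assert summary.loc["s", "pct_indel"] == 0.0


class TestIndelSpectrum:
    def test_single_allele_mass_at_cut(self):
        counts = pd.DataFrame(
            {"s1": [900, 100], "s2": [950, 50]},
            index=["WT", indel_row(-1, 0)],
        )
        table = CountTable(counts, pd.Series({"s1": 1000, "s2": 1000}))
        spec = compute_indel_spectrum(table)
        assert spec.by_position.index.tolist() == [0]
        assert spec.by_size.loc[-1, "s1"] == pytest.approx(0.1)

    def test_equal_frequencies_zero_zscores(self):
        counts = pd.DataFrame(
            {"s1": [900, 100], "s2": [1800, 200]},
            index=["WT", indel_row(-2, 1)],
        )
        table = CountTable(counts, pd.Series({"s1": 1000, "s2": 2000}))
        spec = compute_indel_spectrum(table)
        assert (spec.z_by_size.to_numpy() == 0).all()

    def test_no_indel_rows_raises(self):
        table = CountTable(pd.DataFrame({"s1": [10]}, index=["WT"]),
                           pd.Series({"s1": 10}))
        with pytest.raises(ValueError):
            compute_indel_spectrum(table)
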