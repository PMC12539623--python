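"""Allele assignment, binomial allelic score, and merging semantics."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from aselink.io import SnpIndex
from aselink.quant import (
    QuantParams,
    ReadAlleleCall,
    allelic_score,
    assign_read_allele,
    binomial_pvalue,
    merge_replicates,
    merge_strands,
    quantify_sample,
)
from aselink.records import AnnotationRecord, PhasedSNP
from conftest import SAM_HEADER, locus_row, locus_table, read_seq, sam_line


def exact_minlike_pvalue(a1: int, a2: int) -> Fraction:
    """Independent oracle: exact minimum-likelihood two-sided binomial p.

    Enumerates all outcomes of n tosses and sums the probabilities of those
    no more likely than the observed one, in exact rational arithmetic.
    """
    n = a1 + a2
    obs = math.comb(n, a1)
    favourable = sum(math.comb(n, k) for k in range(n + 1) if math.comb(n, k) <= obs)
    return Fraction(favourable, 2**n)


class TestAllelicScore:
    def test_balanced_counts_score_zero(self):
        assert allelic_score(5, 5) == 0.0
        assert binomial_pvalue(5, 5) == 1.0

    def test_fully_imbalanced_examples(self):
        # (10, 0): p = 2 * 0.5**10, AS = +2.70927
        assert binomial_pvalue(10, 0) == pytest.approx(1.953125e-3, abs=1e-12)
        assert allelic_score(10, 0) == pytest.approx(2.70927, abs=1e-5)
        # (0, 20): sign follows the deficient allele 1
        assert allelic_score(0, 20) == pytest.approx(-5.71957, abs=1e-5)

    def test_exhaustive_enumeration_oracle_small_n(self):
        for n in range(1, 16):
            for a1 in range(n + 1):
                expected = float(exact_minlike_pvalue(a1, n - a1))
                assert binomial_pvalue(a1, n - a1) == pytest.approx(expected, abs=1e-9)

    def test_matches_scipy_binomtest(self):
        for a1, a2 in [(7, 3), (100, 40), (1, 12), (500, 400)]:
            expected = binomtest(a1, a1 + a2, 0.5).pvalue
            assert binomial_pvalue(a1, a2) == pytest.approx(expected, rel=1e-9)

    def test_extreme_counts_finite_in_log_space(self):
        score = allelic_score(10**6, 0)
        assert math.isfinite(score)
        # -log10(2 * 0.5**1e6) = 1e6*log10(2) - log10(2)
        assert score == pytest.approx((10**6 - 1) * math.log10(2), rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allelic_score(0, 0)

    def test_score_magnitude_increases_with_depth_at_fixed_ar(self):
        # AR fixed at 0.8; |AS| strictly increasing on the grid
        mags = [abs(allelic_score(4 * k, k)) for k in range(1, 30)]
        assert all(b > a for a, b in zip(mags, mags[1:]))

    @given(st.integers(0, 300), st.integers(1, 300))
    @settings(max_examples=200)
    def test_ar_monotone_in_allele1_reads(self, a1, a2):
        ar_before = a1 / (a1 + a2)
        ar_after = (a1 + 1) / (a1 + 1 + a2)
        assert ar_after >= ar_before

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200)
    def test_sign_convention(self, a1, a2):
        if a1 + a2 == 0:
            return
        score = allelic_score(a1, a2)
        ar = a1 / (a1 + a2)
        if ar > 0.5:
            assert score >= 0
        elif ar < 0.5:
            assert score <= 0
        else:
            assert score == 0.0


# ---------------------------------------------------------------------------
# read -> allele assignment
# ---------------------------------------------------------------------------

def _segment(start: int, bases: dict[int, str], cigar: str | None = None):
    header = pysam.AlignmentHeader.from_text(SAM_HEADER)
    length = 50
    line = sam_line("r0", start, read_seq(start, length, bases), cigar=cigar).rstrip("\n")
    return pysam.AlignedSegment.fromstring(line, header)


class TestAssignReadAllele:
    snps = SnpIndex([PhasedSNP("chr1", 199, "C", "T"), PhasedSNP("chr1", 210, "A", "G")])

    def test_single_snp_allele1(self):
        call = assign_read_allele(_segment(150, {199: "C"}), self.snps)
        assert call.call == "allele1" and call.n_snps_covered == 1

    def test_two_snp_tie_is_conflict(self):
        call = assign_read_allele(_segment(180, {199: "C", 210: "G"}), self.snps)
        assert call.call == "conflict" and call.n_snps_covered == 2

    def test_third_allele_unassigned(self):
        call = assign_read_allele(_segment(150, {199: "G"}), self.snps)
        assert call.call == "unassigned"

    def test_majority_wins_over_mismatch(self):
        call = assign_read_allele(_segment(180, {199: "T", 210: "G"}), self.snps)
        assert call.call == "allele2"

    def test_deletion_skips_snp(self):
        # 19M2D31M starting at 182: deletion covers refs 201..202, SNP 210
        # is at query offset 210-182-2; SNP 199 at offset 17
        seg = _segment(182, {199: "C"}, cigar="19M2D31M")
        call = assign_read_allele(seg, self.snps)
        # base under 210 is filler N -> vote None; only SNP199 votes
        assert call.call == "allele1"

    def test_unsupported_cigar_rejected(self):
        seg = _segment(180, {199: "C"}, cigar="25M2P25M")
        with pytest.raises(ValueError, match="CIGAR"):
            assign_read_allele(seg, self.snps)


# ---------------------------------------------------------------------------
# per-sample quantification
# ---------------------------------------------------------------------------

class TestQuantifySample:
    def test_planted_counts_recovered(self, planted_sam):
        df = quantify_sample(
            planted_sam["sam"],
            planted_sam["annotation"],
            planted_sam["snps"],
            QuantParams(),
        )
        row = df.iloc[0]
        exp = planted_sam["expected"]
        assert (row["a1_reads"], row["a2_reads"]) == (exp["a1"], exp["a2"])
        assert row["total_reads"] == exp["total"]
        assert row["allelic_ratio"] == pytest.approx(exp["a1"] / exp["total"])
        assert row["n_snps"] == 2

    def test_read_conservation_tally(self, planted_sam):
        df = quantify_sample(
            planted_sam["sam"],
            planted_sam["annotation"],
            planted_sam["snps"],
            QuantParams(),
        )
        tally = df.attrs["read_tally"]["GeneA"]
        parts = (
            tally["a1"] + tally["a2"] + tally["conflict"] + tally["unassigned"]
            + tally["no_snp"] + tally["snp_filtered"]
        )
        assert parts == tally["overlapping_total"] == planted_sam["expected"]["n_reads"]

    def test_per_snp_minimum_discards_reads(self, planted_sam):
        # SNP at 210 carries 6 assigned reads; min 7 drops it and its reads
        df = quantify_sample(
            planted_sam["sam"],
            planted_sam["annotation"],
            planted_sam["snps"],
            QuantParams(min_reads_per_snp=7),
        )
        row = df.iloc[0]
        assert (row["a1_reads"], row["a2_reads"], row["n_snps"]) == (8, 4, 1)
        assert df.attrs["read_tally"]["GeneA"]["snp_filtered"] == 6

    def test_zero_read_locus_blank_ar(self, planted_sam):
        annotation = planted_sam["annotation"] + [
            AnnotationRecord("chr1", 50_000, 51_000, "Empty", 0.0, "+", "pcGene")
        ]
        df = quantify_sample(
            planted_sam["sam"], annotation, planted_sam["snps"], QuantParams()
        )
        row = df.set_index("locus_name").loc["Empty"]
        assert row["total_reads"] == 0
        assert math.isnan(row["allelic_ratio"]) and math.isnan(row["allelic_score"])

    def test_excluded_chromosome_dropped(self, planted_sam):
        df = quantify_sample(
            planted_sam["sam"],
            planted_sam["annotation"],
            planted_sam["snps"],
            QuantParams(excluded_chroms=frozenset({"chr1"})),
        )
        assert len(df) == 0

    def test_stranded_orientation_gates_loci(self, planted_sam):
        # all fixture reads are forward; a minus-strand locus gets nothing
        # under the forward library but everything under reverse
        minus = [
            AnnotationRecord("chr1", 100, 500, "GeneA", 0.0, "-", "pcGene")
        ]
        fwd = quantify_sample(
            planted_sam["sam"], minus, planted_sam["snps"],
            QuantParams(library_orientation="forward"),
        )
        rev = quantify_sample(
            planted_sam["sam"], minus, planted_sam["snps"],
            QuantParams(library_orientation="reverse"),
        )
        assert fwd.iloc[0]["total_reads"] == 0
        assert rev.iloc[0]["total_reads"] == 18

    def test_empty_annotation_rejected(self, planted_sam):
        with pytest.raises(ValueError, match="annotation"):
            quantify_sample(planted_sam["sam"], [], planted_sam["snps"], QuantParams())


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMergeStrands:
    def test_concatenates_partition(self):
        fwd = locus_table([locus_row(f"F{i}") for i in range(10)])
        rev = locus_table([locus_row(f"R{i}", strand="-") for i in range(12)])
        assert len(merge_strands(fwd, rev)) == 22

    def test_shared_locus_rejected(self):
        t = locus_table([locus_row("A")])
        with pytest.raises(ValueError, match="A"):
            merge_strands(t, t)

    def test_empty_reverse_identity(self):
        fwd = locus_table([locus_row("A"), locus_row("B", start=2000, end=3000)])
        rev = locus_table([])
        merged = merge_strands(fwd, rev)
        pd.testing.assert_frame_equal(merged, fwd)


class TestMergeReplicates:
    def _reps(self, specs):
        """specs: per replicate, (a1, a2) for a single locus."""
        return [locus_table([locus_row("A", a1=a1, a2=a2)]) for a1, a2 in specs]

    def test_median_ar_and_reads(self):
        reps = self._reps([(8, 2), (9, 1), (10, 0)])  # ARs 0.8, 0.9, 1.0
        merged = merge_replicates(reps, "all_samples", min_total_reads=10)
        assert merged.iloc[0]["allelic_ratio"] == pytest.approx(0.9)
        assert merged.iloc[0]["total_reads"] == 10

    def test_min_score_rule_with_median_sign(self):
        reps = self._reps([(8, 2), (20, 1), (30, 0)])
        merged = merge_replicates(reps, "all_samples", min_total_reads=10)
        expected = min(abs(allelic_score(a, b)) for a, b in [(8, 2), (20, 1), (30, 0)])
        assert merged.iloc[0]["allelic_score"] == pytest.approx(expected)
        assert merged.iloc[0]["allelic_score"] > 0

    def test_all_samples_rule_drops_one_shallow_replicate(self):
        reps = self._reps([(10, 9), (15, 10), (20, 10)])  # totals 19, 25, 30
        merged = merge_replicates(reps, "all_samples", min_total_reads=20)
        assert len(merged) == 0

    def test_any_sample_rule_keeps_it(self):
        reps = self._reps([(10, 9), (15, 10), (20, 10)])
        merged = merge_replicates(reps, "any_sample", min_total_reads=20)
        assert len(merged) == 1

    def test_zero_tables_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([], "all_samples")

    @given(st.integers(1, 60))
    @settings(max_examples=40)
    def test_raising_cutoff_never_adds_loci(self, cutoff):
        rng = np.random.default_rng(42)
        reps = [
            locus_table(
                [
                    locus_row(f"L{i}", a1=int(rng.integers(0, 30)), a2=int(rng.integers(0, 30)))
                    for i in range(15)
                ]
            )
            for _ in range(3)
        ]
        lo = merge_replicates(reps, "all_samples", min_total_reads=cutoff)
        hi = merge_replicates(reps, "all_samples", min_total_reads=cutoff + 5)
        assert set(hi["locus_name"]).issubset(set(lo["locus_name"]))
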