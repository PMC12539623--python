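"""eQTL confirmation, GWAS intersection, TADs, consistency, saturation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from aselink.integrate import (
    CONFIRMED_OTHER_TISSUE,
    CONFIRMED_SAME_TISSUE,
    ENHANCER_COOCCURRING,
    GWAS_BOTH,
    GWAS_NCRNA_ONLY,
    GWAS_NONE,
    GWAS_PCGENE_ONLY,
    NCRNA_CANDIDATE,
    UNCLASSIFIED,
    UNCONFIRMED,
    confirm_with_eqtl,
    enhancer_cooccurrence,
    evaluate_against_truth,
    intersect_gwas,
    mechanism_bias_test,
    mechanism_consistency,
    saturation_curve,
    sharing_across_groups,
    tad_colocalization,
)
from aselink.link import LinkParams, link_loci
from aselink.records import (
    ENHANCING,
    REPRESSIVE,
    EqtlRecord,
    GwasVariant,
    LinkageKey,
    TadInterval,
)
from conftest import locus_row, locus_table


def _one_linkage(src_start=4000, src_end=6000, tgt_start=50_000, tgt_end=60_000):
    table = locus_table(
        [
            locus_row("NC1", start=src_start, end=src_end, a1=18, a2=2, biotype="ncRNA"),
            locus_row("GENE1", start=tgt_start, end=tgt_end, a1=17, a2=3, biotype="pcGene"),
        ]
    )
    (link,) = link_loci(table, LinkParams(biotype_filter=("ncRNA", "pcGene")))
    return link


class TestConfirmWithEqtl:
    def test_same_tissue_confirmation(self):
        link = _one_linkage()
        eqtls = [EqtlRecord("chr1", 5000, "GENE1", "liver")]
        assert confirm_with_eqtl([link], eqtls, "liver") == [CONFIRMED_SAME_TISSUE]

    def test_other_tissue_confirmation(self):
        link = _one_linkage()
        eqtls = [EqtlRecord("chr1", 5000, "GENE1", "brain")]
        assert confirm_with_eqtl([link], eqtls, "liver") == [CONFIRMED_OTHER_TISSUE]

    def test_wrong_target_unconfirmed(self):
        link = _one_linkage()
        eqtls = [EqtlRecord("chr1", 5000, "GENE2", "liver")]
        assert confirm_with_eqtl([link], eqtls, "liver") == [UNCONFIRMED]

    def test_eqtl_in_target_body_not_enough(self):
        link = _one_linkage()
        eqtls = [EqtlRecord("chr1", 55_000, "GENE1", "liver")]
        assert confirm_with_eqtl([link], eqtls, "liver") == [UNCONFIRMED]

    def test_adding_eqtls_never_unconfirms(self):
        link = _one_linkage()
        base = [EqtlRecord("chr1", 5000, "GENE1", "brain")]
        extra = base + [EqtlRecord("chr1", 5500, "GENE2", "liver")]
        order = {UNCONFIRMED: 0, CONFIRMED_OTHER_TISSUE: 1, CONFIRMED_SAME_TISSUE: 2}
        before = confirm_with_eqtl([link], base, "liver")[0]
        after = confirm_with_eqtl([link], extra, "liver")[0]
        assert order[after] >= order[before]


class TestIntersectGwas:
    def test_threshold_is_strict(self):
        link = _one_linkage()
        at_threshold = [GwasVariant("rs1", "chr1", 5000, 5e-8, "t")]
        (hit,) = intersect_gwas([link], at_threshold)
        assert hit.category == GWAS_NONE

    def test_categories(self):
        link = _one_linkage()
        cases = [
            ([GwasVariant("rs1", "chr1", 5000, 1e-9, "t")], GWAS_NCRNA_ONLY),
            ([GwasVariant("rs1", "chr1", 55_000, 1e-9, "t")], GWAS_PCGENE_ONLY),
            (
                [
                    GwasVariant("rs1", "chr1", 5000, 1e-9, "t"),
                    GwasVariant("rs2", "chr1", 55_000, 1e-9, "t"),
                ],
                GWAS_BOTH,
            ),
            ([], GWAS_NONE),
        ]
        for variants, expected in cases:
            (hit,) = intersect_gwas([link], variants)
            assert hit.category == expected

    def test_categories_partition_linkage_set(self):
        rng = np.random.default_rng(5)
        links = [
            _one_linkage(
                src_start=int(s), src_end=int(s) + 2000,
                tgt_start=int(s) + 10_000, tgt_end=int(s) + 12_000,
            )
            for s in rng.integers(0, 1_000_000, size=10)
        ]
        variants = [
            GwasVariant(f"rs{i}", "chr1", int(p), 1e-9, "t")
            for i, p in enumerate(rng.integers(0, 1_100_000, size=50))
        ]
        hits = intersect_gwas(links, variants)
        assert len(hits) == len(links)  # every linkage categorized exactly once


class TestTadColocalization:
    def test_containment_rules(self):
        link = _one_linkage()
        inside = [TadInterval("chr1", 0, 1_000_000)]
        flags, fraction = tad_colocalization([link], inside)
        assert flags == [True] and fraction == 1.0
        adjacent = [TadInterval("chr1", 0, 10_000), TadInterval("chr1", 10_000, 1_000_000)]
        flags, _ = tad_colocalization([link], adjacent)
        assert flags == [False]
        straddle = [TadInterval("chr1", 0, 55_000), TadInterval("chr1", 55_000, 1_000_000)]
        flags, _ = tad_colocalization([link], straddle)
        assert flags == [False]  # target straddles the boundary

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            tad_colocalization(
                [], [TadInterval("chr1", 0, 100), TadInterval("chr1", 50, 200)]
            )


class TestEnhancerCooccurrence:
    def _peak_link(self, target_name, mechanism):
        a1, a2 = (18, 2) if mechanism == ENHANCING else (2, 18)
        table = locus_table(
            [
                locus_row("peak1", start=0, end=500, a1=18, a2=2, biotype="peak"),
                locus_row(target_name, start=2_000, end=4_000, a1=a1, a2=a2),
            ]
        )
        (link,) = link_loci(table, LinkParams(biotype_filter=("peak", None)))
        return link

    def test_peak_linked_to_target_gene(self):
        pair = _one_linkage()
        enh = self._peak_link("GENE1", ENHANCING)
        assert enhancer_cooccurrence([pair], [enh]) == [ENHANCER_COOCCURRING]

    def test_no_peak_links(self):
        pair = _one_linkage()
        assert enhancer_cooccurrence([pair], []) == [NCRNA_CANDIDATE]

    def test_repressive_peak_link_ignored(self):
        pair = _one_linkage()
        rep = self._peak_link("GENE1", REPRESSIVE)
        assert enhancer_cooccurrence([pair], [rep]) == [NCRNA_CANDIDATE]


class TestMechanismConsistency:
    def _calls(self, n_enh, n_rep, key=LinkageKey("nc", "pc")):
        return [(key, ENHANCING)] * n_enh + [(key, REPRESSIVE)] * n_rep

    def test_three_of_four_enhancing(self):
        (res,) = mechanism_consistency(self._calls(3, 1))
        assert res.call == ENHANCING and res.fraction_enhancing == 0.75

    def test_even_split_unclassified(self):
        (res,) = mechanism_consistency(self._calls(2, 2))
        assert res.call == UNCLASSIFIED

    def test_all_repressive(self):
        (res,) = mechanism_consistency(self._calls(0, 5))
        assert res.call == REPRESSIVE and res.fraction_enhancing == 0.0

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(11)
        calls = []
        for k in range(10):
            key = LinkageKey(f"nc{k}", f"pc{k}")
            for _ in range(int(rng.integers(1, 8))):
                calls.append(
                    (key, ENHANCING if rng.random() < 0.5 else REPRESSIVE)
                )
        swapped = [
            (key, REPRESSIVE if m == ENHANCING else ENHANCING) for key, m in calls
        ]
        for a, b in zip(mechanism_consistency(calls), mechanism_consistency(swapped)):
            assert a.fraction_enhancing == pytest.approx(1.0 - b.fraction_enhancing)
            flip = {ENHANCING: REPRESSIVE, REPRESSIVE: ENHANCING, UNCLASSIFIED: UNCLASSIFIED}
            assert flip[a.call] == b.call


def test_mechanism_bias_test_validates_inputs():
    assert mechanism_bias_test(3, 4) == pytest.approx(5 / 16)
    with pytest.raises(ValueError):
        mechanism_bias_test(5, 4)


class TestSaturationCurve:
    def test_identical_samples_flat_sd_zero(self):
        keys = {LinkageKey(f"n{i}", f"p{i}") for i in range(5)}
        curve = saturation_curve([keys, set(keys), set(keys)], iterations=50, seed=0)
        assert list(curve["mean"]) == [5.0, 5.0, 5.0]
        assert list(curve["sd"]) == [0.0, 0.0, 0.0]

    def test_disjoint_sets_union_arithmetic(self):
        sets = [
            {LinkageKey(f"a{i}", "x") for i in range(2)},
            {LinkageKey(f"b{i}", "x") for i in range(3)},
            {LinkageKey(f"c{i}", "x") for i in range(4)},
        ]
        curve = saturation_curve(sets, iterations=20, seed=0)
        final = curve.iloc[-1]
        assert final["mean"] == 9.0 and final["sd"] == 0.0

    def test_mean_nondecreasing_over_seeds(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            sets = [
                {
                    LinkageKey(f"n{k}", f"p{k}")
                    for k in rng.integers(0, 30, size=rng.integers(1, 15))
                }
                for _ in range(5)
            ]
            curve = saturation_curve(sets, iterations=60, seed=seed)
            means = list(curve["mean"])
            assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve([{LinkageKey("a", "b")}], iterations=0, seed=0)


class TestSharing:
    def test_specific_and_shared(self):
        tagged = [
            ("liver", LinkageKey("a", "b")),
            ("brain", LinkageKey("a", "b")),
            ("heart", LinkageKey("a", "b")),
            ("liver", LinkageKey("c", "d")),
        ]
        summary = sharing_across_groups(tagged)
        assert summary.per_key_groups[LinkageKey("a", "b")] == 3
        assert summary.histogram == {1: 1, 3: 1}
        assert summary.specific_fraction == pytest.approx(0.5)

    def test_all_shared_specific_fraction_zero(self):
        tagged = [
            (g, LinkageKey("a", "b")) for g in ("t1", "t2", "t3")
        ] + [(g, LinkageKey("c", "d")) for g in ("t1", "t2", "t3")]
        assert sharing_across_groups(tagged).specific_fraction == 0.0


class TestEvaluateAgainstTruth:
    def test_partial_overlap(self):
        pred = {LinkageKey("A", "B"), LinkageKey("A", "C")}
        truth = {LinkageKey("A", "B")}
        assert evaluate_against_truth(pred, truth) == (0.5, 1.0)

    def test_identity(self):
        keys = {LinkageKey("A", "B")}
        assert evaluate_against_truth(keys, keys) == (1.0, 1.0)

    def test_empty_prediction_convention(self):
        assert evaluate_against_truth(set(), {LinkageKey("A", "B")}) == (1.0, 0.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_against_truth({LinkageKey("A", "B")}, set())
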