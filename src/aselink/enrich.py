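"""Proximity enrichment and linkage-distance characterisation.

The enrichment question: are allele-specific ncRNAs found near
allele-specific protein-coding genes more often than near biallelic ones?
For each group (tissue or sample) the fraction of allelic ncRNAs with at
least one allelic / biallelic pcGene within a genomic window is computed,
and the paired percentages across groups are compared with a Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .link import LinkParams, filter_allele_specific
from .records import BIOTYPE_NCRNA, BIOTYPE_PCGENE, Linkage, interval_gap

SHARED_PROMOTER = "shared_promoter"
OVERLAPPING = "overlapping"
DISTANT = "distant"


@dataclass(frozen=True)
class EnrichmentResult:
    """Proximity percentages for one group.

    Percentages are undefined (NaN, ``defined=False``) when the group has
    no allele-specific ncRNA at all.
    """

    window_bp: float
    pct_near_allelic: float
    pct_near_biallelic: float
    n_allelic_ncrna: int
    group_label: str | None = None

    @property
    def defined(self) -> bool:
        return self.n_allelic_ncrna > 0


def proximity_enrichment(
    table: pd.DataFrame,
    params: LinkParams = LinkParams(),
    window_bp: float | None = None,
    group_label: str | None = None,
    denominator: str = "ncRNA",
) -> EnrichmentResult:
    """Percentage of allelic ncRNAs near allelic vs biallelic pcGenes.

    "Near" means an interval gap <= ``window_bp`` (overlap counts, distance
    0) on the same chromosome. *Biallelic* means informative (total reads
    >= the filter minimum) but not allele-specific. With
    ``denominator="pcGene"`` the roles are swapped: the fraction of allelic
    / biallelic pcGenes with >= 1 allelic ncRNA nearby.
    """
    if window_bp is None:
        window_bp = params.window_bp
    if denominator not in ("ncRNA", "pcGene"):
        raise ValueError(f"unknown denominator {denominator!r}")
    allelic = filter_allele_specific(table, params)
    allelic_names = set(allelic["locus_name"])
    informative = table.loc[
        table["allelic_ratio"].notna()
        & (table["total_reads"] >= params.min_total_reads)
    ]
    biallelic = informative.loc[~informative["locus_name"].isin(allelic_names)]

    allelic_nc = allelic.loc[allelic["biotype"] == BIOTYPE_NCRNA]
    allelic_pc = allelic.loc[allelic["biotype"] == BIOTYPE_PCGENE]
    biallelic_pc = biallelic.loc[biallelic["biotype"] == BIOTYPE_PCGENE]
    biallelic_nc = biallelic.loc[biallelic["biotype"] == BIOTYPE_NCRNA]

    if denominator == "ncRNA":
        denom, near_a, near_b = allelic_nc, allelic_pc, biallelic_pc
    else:
        denom, near_a, near_b = allelic_pc, allelic_nc, biallelic_nc

    n = len(denom)
    if n == 0:
        return EnrichmentResult(window_bp, math.nan, math.nan, 0, group_label)

    def pct_with_neighbor(candidates: pd.DataFrame) -> float:
        count = 0
        for _, row in denom.iterrows():
            near = candidates.loc[candidates["chrom"] == row["chrom"]]
            for _, other in near.iterrows():
                if other["locus_name"] == row["locus_name"]:
                    continue
                gap = interval_gap(
                    int(row["start"]),
                    int(row["end"]),
                    int(other["start"]),
                    int(other["end"]),
                )
                if gap <= window_bp:
                    count += 1
                    break
        return 100.0 * count / n

    n_allelic = len(allelic_nc) if denominator == "ncRNA" else len(allelic_pc)
    return EnrichmentResult(
        window_bp=window_bp,
        pct_near_allelic=pct_with_neighbor(near_a),
        pct_near_biallelic=pct_with_neighbor(near_b),
        n_allelic_ncrna=n_allelic,
        group_label=group_label,
    )


@dataclass(frozen=True)
class EnrichmentComparison:
    pvalue: float
    statistic: float
    degenerate: bool = False


def compare_enrichment(
    group_a: Sequence[float | EnrichmentResult],
    group_b: Sequence[float | EnrichmentResult],
    paired: bool = True,
) -> EnrichmentComparison:
    """Two-sided Wilcoxon comparison of two sets of enrichment percentages.

    Paired (the default, one allelic/biallelic pair per group) uses the
    signed-rank test; unpaired uses the rank-sum test. An all-zero paired
    difference vector is degenerate and reported as p = 1.
    """
    a = np.asarray([_pct(x) for x in group_a], dtype=float)
    b = np.asarray([_pct(x) for x in group_b], dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        if len(a) < 3:
            raise ValueError("paired Wilcoxon requires >= 3 observation pairs")
        if np.all(a == b):
            return EnrichmentComparison(pvalue=1.0, statistic=0.0, degenerate=True)
        stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        return EnrichmentComparison(pvalue=float(p), statistic=float(stat))
    if len(a) < 1 or len(b) < 1:
        raise ValueError("rank-sum comparison requires non-empty groups")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return EnrichmentComparison(pvalue=float(p), statistic=float(stat))


def _pct(x: float | EnrichmentResult) -> float:
    if isinstance(x, EnrichmentResult):
        return x.pct_near_allelic
    return float(x)


def distance_profile(linkages: Sequence[Linkage]) -> pd.DataFrame:
    """Per-linkage TSS distance and a mutually exclusive distance category.

    Priority order: *shared_promoter* (TSSs within +/-2 kb), then
    *overlapping* (intersecting gene bodies), then *distant*.
    """
    rows = []
    for l in linkages:
        if l.tss_distance_bp <= 2000:
            category = SHARED_PROMOTER
        elif not (
            l.source_end <= l.target_start or l.target_end <= l.source_start
        ):
            category = OVERLAPPING
        else:
            category = DISTANT
        rows.append(
            {
                "source_name": l.source_name,
                "target_name": l.target_name,
                "mechanism": l.mechanism,
                "tss_distance_bp": l.tss_distance_bp,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["source_name", "target_name", "mechanism", "tss_distance_bp", "category"],
    )
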