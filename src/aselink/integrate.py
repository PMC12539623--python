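"""Downstream annotation and cohort analyses for predicted linkages.

Covers confirmation against eQTL tables (an eQTL inside the source ncRNA
locus that regulates the predicted target), intersection with genome-wide
significant GWAS variants, TAD co-localization, enhancer co-occurrence,
cross-sample mechanism consistency, discovery saturation curves, sharing
across groups, and precision/recall against a planted truth set.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .records import (
    ENHANCING,
    REPRESSIVE,
    EqtlRecord,
    GwasVariant,
    Linkage,
    LinkageKey,
    TadInterval,
)

CONFIRMED_SAME_TISSUE = "confirmed_same_tissue"
CONFIRMED_OTHER_TISSUE = "confirmed_other_tissue"
UNCONFIRMED = "unconfirmed"

GWAS_NCRNA_ONLY = "ncRNA_only"
GWAS_PCGENE_ONLY = "pcGene_only"
GWAS_BOTH = "both"
GWAS_NONE = "none"

GENOME_WIDE_SIGNIFICANCE = 5e-8


# ---------------------------------------------------------------------------
# eQTL confirmation
# ---------------------------------------------------------------------------

def confirm_with_eqtl(
    linkages: Sequence[Linkage],
    eqtls: Iterable[EqtlRecord],
    linkage_tissue: str | None = None,
) -> list[str]:
    """Per-linkage eQTL confirmation status.

    A linkage is confirmed when at least one eQTL position falls inside the
    source (ncRNA) locus interval *and* that eQTL's target gene equals the
    linkage's predicted target. Same-tissue confirmation (eQTL tissue ==
    ``linkage_tissue``) takes precedence over other-tissue.
    """
    by_chrom: dict[str, list[EqtlRecord]] = defaultdict(list)
    for e in eqtls:
        by_chrom[e.chrom].append(e)
    statuses = []
    for l in linkages:
        status = UNCONFIRMED
        for e in by_chrom.get(l.chrom, ()):
            if not (l.source_start <= e.pos < l.source_end):
                continue
            if e.target_gene != l.target_name:
                continue
            if linkage_tissue is not None and e.tissue == linkage_tissue:
                status = CONFIRMED_SAME_TISSUE
                break
            status = CONFIRMED_OTHER_TISSUE
        statuses.append(status)
    return statuses


def eqtl_confirmation_rates(statuses: Sequence[str]) -> dict[str, float]:
    """Summary fractions; the same-tissue rate is reported against both the
    full linkage set and the confirmed subset (the denominator is ambiguous
    in general use, so both are emitted)."""
    n = len(statuses)
    n_same = statuses.count(CONFIRMED_SAME_TISSUE)
    n_other = statuses.count(CONFIRMED_OTHER_TISSUE)
    n_confirmed = n_same + n_other
    return {
        "fraction_confirmed": n_confirmed / n if n else float("nan"),
        "fraction_same_tissue_of_all": n_same / n if n else float("nan"),
        "fraction_same_tissue_of_confirmed": (
            n_same / n_confirmed if n_confirmed else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# GWAS intersection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GwasIntersection:
    key: LinkageKey
    category: str
    ncrna_variants: tuple[str, ...]
    pcgene_variants: tuple[str, ...]


def intersect_gwas(
    linkages: Sequence[Linkage],
    variants: Iterable[GwasVariant],
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> list[GwasIntersection]:
    """Assign each linkage a category from genome-wide significant variants.

    Only variants with ``pvalue < p_threshold`` (strict) are considered;
    containment uses the full gene-body intervals of both partners.
    """
    significant = [v for v in variants if v.pvalue < p_threshold]
    by_chrom: dict[str, list[GwasVariant]] = defaultdict(list)
    for v in significant:
        by_chrom[v.chrom].append(v)
    results = []
    for l in linkages:
        in_src = tuple(
            v.rsid
            for v in by_chrom.get(l.chrom, ())
            if l.source_start <= v.pos < l.source_end
        )
        in_tgt = tuple(
            v.rsid
            for v in by_chrom.get(l.chrom, ())
            if l.target_start <= v.pos < l.target_end
        )
        if in_src and in_tgt:
            category = GWAS_BOTH
        elif in_src:
            category = GWAS_NCRNA_ONLY
        elif in_tgt:
            category = GWAS_PCGENE_ONLY
        else:
            category = GWAS_NONE
        results.append(GwasIntersection(l.key, category, in_src, in_tgt))
    return results


# ---------------------------------------------------------------------------
# TAD co-localization
# ---------------------------------------------------------------------------

def tad_colocalization(
    linkages: Sequence[Linkage], tads: Sequence[TadInterval]
) -> tuple[list[bool], float]:
    """Flag linkages whose two loci lie fully inside one common TAD.

    TADs must be non-overlapping within each chromosome; a locus straddling
    a TAD boundary is not contained.
    """
    by_chrom: dict[str, list[TadInterval]] = defaultdict(list)
    for t in tads:
        by_chrom[t.chrom].append(t)
    for chrom, intervals in by_chrom.items():
        intervals.sort(key=lambda t: t.start)
        for prev, curr in zip(intervals, intervals[1:]):
            if curr.start < prev.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: "
                    f"[{prev.start},{prev.end}) and [{curr.start},{curr.end})"
                )
    flags = []
    for l in linkages:
        flags.append(
            any(
                t.contains(l.source_start, l.source_end)
                and t.contains(l.target_start, l.target_end)
                for t in by_chrom.get(l.chrom, ())
            )
        )
    fraction = sum(flags) / len(flags) if flags else float("nan")
    return flags, fraction


# ---------------------------------------------------------------------------
# enhancer co-occurrence
# ---------------------------------------------------------------------------

ENHANCER_COOCCURRING = "enhancer_cooccurring"
NCRNA_CANDIDATE = "ncRNA_candidate"


def enhancer_cooccurrence(
    gene_linkages: Sequence[Linkage],
    enhancer_linkages: Sequence[Linkage],
) -> list[str]:
    """Label each ncRNA->pcGene pair by nearby allelic enhancer support.

    Only *enhancing* peak->gene linkages count as enhancer support; a pair
    is ``enhancer_cooccurring`` when such a peak linkage targets either of
    its members, and otherwise an ``ncRNA_candidate`` (a putative
    RNA-mediated effect).
    """
    enhancer_targets = {
        e.target_name for e in enhancer_linkages if e.mechanism == ENHANCING
    }
    return [
        ENHANCER_COOCCURRING
        if (l.source_name in enhancer_targets or l.target_name in enhancer_targets)
        else NCRNA_CANDIDATE
        for l in gene_linkages
    ]


# ---------------------------------------------------------------------------
# mechanism consistency across samples
# ---------------------------------------------------------------------------

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ConsistencyResult:
    key: LinkageKey
    n_samples: int
    n_enhancing: int
    call: str

    @property
    def fraction_enhancing(self) -> float:
        return self.n_enhancing / self.n_samples


def mechanism_consistency(
    calls: Iterable[tuple[LinkageKey, str]],
    cutoff: float = 0.75,
) -> list[ConsistencyResult]:
    """Classify recurrent linkages by the consistency of their mechanism.

    A linkage seen in several samples is called *enhancing* when the
    enhancing fraction reaches ``cutoff`` (>= 75% by default), *repressive*
    when the repressive fraction does, else *unclassified* (the behaviour
    of genuinely inconsistent loci such as hyper-polymorphic gene clusters).
    """
    per_key: dict[LinkageKey, list[str]] = defaultdict(list)
    for key, mechanism in calls:
        if mechanism not in (ENHANCING, REPRESSIVE):
            raise ValueError(f"invalid mechanism {mechanism!r}")
        per_key[key].append(mechanism)
    results = []
    for key in sorted(per_key):
        mechanisms = per_key[key]
        n = len(mechanisms)
        n_enh = sum(1 for m in mechanisms if m == ENHANCING)
        fraction = n_enh / n
        if fraction >= cutoff:
            call = ENHANCING
        elif 1.0 - fraction >= cutoff:
            call = REPRESSIVE
        else:
            call = UNCLASSIFIED
        results.append(ConsistencyResult(key, n, n_enh, call))
    return results


def mechanism_bias_test(
    n_enhancing: int, n_total: int, alternative: str = "greater"
) -> float:
    """Exact binomial test of an excess of enhancing over repressive calls.

    Tests ``n_enhancing`` of ``n_total`` mechanism calls against a balanced
    0.5 null; the default one-sided "greater" alternative asks whether
    enhancing linkages are over-represented.
    """
    if not (0 <= n_enhancing <= n_total) or n_total < 1:
        raise ValueError("need 0 <= n_enhancing <= n_total and n_total >= 1")
    return float(binomtest(n_enhancing, n_total, 0.5, alternative=alternative).pvalue)


# ---------------------------------------------------------------------------
# saturation and sharing
# ---------------------------------------------------------------------------

def saturation_curve(
    per_sample_linkage_sets: Sequence[set[LinkageKey] | frozenset],
    iterations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected unique linkages as a function of cohort size.

    For each n in 1..N, draws ``iterations`` random n-subsets of samples
    without replacement and records the union size of their linkage keys;
    n = N uses the full union exactly (sd 0). Returns columns
    ``n, mean, sd``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_samples = len(per_sample_linkage_sets)
    if n_samples < 1:
        raise ValueError("at least one sample required")
    sets = [frozenset(s) for s in per_sample_linkage_sets]
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, n_samples + 1):
        if n == n_samples:
            union = len(frozenset().union(*sets))
            rows.append({"n": n, "mean": float(union), "sd": 0.0})
            continue
        sizes = np.empty(iterations)
        for it in range(iterations):
            idx = rng.choice(n_samples, size=n, replace=False)
            sizes[it] = len(frozenset().union(*(sets[i] for i in idx)))
        rows.append({"n": n, "mean": float(sizes.mean()), "sd": float(sizes.std())})
    return pd.DataFrame(rows, columns=["n", "mean", "sd"])


@dataclass(frozen=True)
class SharingSummary:
    per_key_groups: Mapping[LinkageKey, int]
    histogram: Mapping[int, int]
    specific_fraction: float


def sharing_across_groups(
    tagged_linkages: Iterable[tuple[str, LinkageKey]],
) -> SharingSummary:
    """How many groups (tissues) each linkage key appears in.

    A key is counted once per group; the *specific* fraction is the share
    of keys seen in exactly one group.
    """
    groups_per_key: dict[LinkageKey, set[str]] = defaultdict(set)
    for group, key in tagged_linkages:
        groups_per_key[key].add(group)
    counts = {key: len(groups) for key, groups in groups_per_key.items()}
    histogram = dict(sorted(Counter(counts.values()).items()))
    n_keys = len(counts)
    specific = (
        sum(1 for c in counts.values() if c == 1) / n_keys if n_keys else float("nan")
    )
    return SharingSummary(counts, histogram, specific)


# ---------------------------------------------------------------------------
# truth-set evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(
    predicted: Iterable[LinkageKey], truth: Iterable[LinkageKey]
) -> tuple[float, float]:
    """Precision and recall of predicted linkage keys against a truth set.

    An empty prediction set has precision 1.0 by convention (nothing wrong
    was asserted); an empty truth set is an error.
    """
    pred = set(predicted)
    true = set(truth)
    if not true:
        raise ValueError("truth set must be non-empty")
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(true)
    return precision, recall
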