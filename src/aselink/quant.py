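"""Allele-specific expression quantification from phased-SNP-overlapping reads.

For every annotated locus in one sample this module counts the aligned reads
assignable to each haplotype via the phased SNPs the read covers, and reports

* the allelic ratio ``AR = a1 / (a1 + a2)`` (undefined at zero reads), and
* the signed allelic score ``AS = sign(AR - 0.5) * (-log10 p)`` where ``p``
  is the two-sided exact binomial p-value of the allele counts against a
  balanced 0.5 null (minimum-likelihood tail definition, computed in log
  space so it stays finite and accurate for counts well beyond 10**6).

Reads are the counting unit: a read covering several SNPs casts one vote
per SNP and is assigned by majority, with ties recorded as ``conflict`` and
third-allele bases as ``unassigned``; neither contributes to the counts but
both are tallied for the run log. SNPs attracting fewer than
``min_reads_per_snp`` assigned reads within a locus are dropped together
with reads supported only by them.
"""

from __future__ import annotations

import bisect as _bisect
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.special import gammaln
from scipy.stats import binom

from .io import LOCUS_TABLE_COLUMNS, RunLog, SnpIndex
from .records import AnnotationRecord, PhasedSNP

_LN10 = math.log(10.0)
_SUPPORTED_CIGAR_OPS = {0, 1, 2, 3, 4, 5, 7, 8}  # M I D N S H = X

def _log_binom_cdf_half(m: int, n: int) -> float:
    """Natural-log CDF of Binomial(n, 0.5) at m, robust to extreme tails.

    scipy's logcdf underflows to -inf when the CDF is below the smallest
    normal double; in that regime the tail is summed directly from log
    probability masses.
    """
    logcdf = float(binom.logcdf(m, n, 0.5))
    if math.isfinite(logcdf):
        return logcdf
    log_half = math.log(0.5)
    total = -math.inf
    for k in range(m + 1):
        logpmf = (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) + n * log_half
        )
        total = np.logaddexp(total, logpmf)
    return float(total)


CALL_ALLELE1 = "allele1"
CALL_ALLELE2 = "allele2"
CALL_CONFLICT = "conflict"
CALL_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadAlleleCall:
    read_id: str
    locus_name: str | None
    call: str
    n_snps_covered: int


@dataclass(frozen=True)
class QuantParams:
    """Quantification parameters.

    ``library_orientation``: "forward" means the read strand equals the
    transcript strand, "reverse" the opposite (e.g. Illumina stranded mRNA
    ligation kits), "unstranded" ignores strand. ``excluded_chroms`` drops
    whole chromosomes (e.g. ``{"chrX"}`` to avoid skewed X-inactivation in
    mouse crosses).
    """

    min_reads_per_snp: int = 1
    min_total_reads: int = 20
    library_orientation: str = "unstranded"
    excluded_chroms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_reads_per_snp < 1:
            raise ValueError("min_reads_per_snp must be >= 1")
        if self.min_total_reads < 1:
            raise ValueError("min_total_reads must be >= 1")
        if self.library_orientation not in ("forward", "reverse", "unstranded"):
            raise ValueError(
                f"invalid library_orientation {self.library_orientation!r}"
            )


MOUSE_EXCLUDED_CHROMS = frozenset({"chrX"})


# ---------------------------------------------------------------------------
# allelic score
# ---------------------------------------------------------------------------

def binomial_pvalue(a1: int, a2: int) -> float:
    """Two-sided exact binomial p-value of (a1, a2) against p = 0.5.

    Uses the minimum-likelihood tail: the sum of probabilities of all
    outcomes no more likely than the observed one. Under the symmetric 0.5
    null this equals ``min(1, 2 * P(X <= min(a1, a2)))``, which is evaluated
    through the log-CDF so extreme counts do not underflow.
    """
    n = a1 + a2
    if n < 1:
        raise ValueError("binomial_pvalue requires a1 + a2 >= 1")
    if a1 == a2:
        return 1.0
    m = min(a1, a2)
    logp = math.log(2.0) + _log_binom_cdf_half(m, n)
    return float(math.exp(min(logp, 0.0)))


def allelic_score(a1: int, a2: int) -> float:
    """Signed allelic score: sign(AR - 0.5) * (-log10 of the binomial p).

    Computed in log space: for counts like (10**6, 0) the magnitude is the
    exact ``-log10(2 * 0.5**n)`` rather than an overflow to infinity.
    """
    n = a1 + a2
    if n < 1:
        raise ValueError("allelic_score requires a1 + a2 >= 1")
    if a1 == a2:
        return 0.0
    m = min(a1, a2)
    log10p = (math.log(2.0) + _log_binom_cdf_half(m, n)) / _LN10
    magnitude = max(0.0, -log10p)
    return magnitude if a1 > a2 else -magnitude


# ---------------------------------------------------------------------------
# read -> allele assignment
# ---------------------------------------------------------------------------

def _read_snp_votes(
    read: pysam.AlignedSegment, snps: SnpIndex
) -> list[tuple[int, int | None]]:
    """(position, vote) per covered SNP; vote is 1, 2 or None (third allele).

    Only aligned (match/mismatch) bases can cover a SNP; inserted and
    soft-clipped bases have no reference coordinate and are skipped by
    construction.
    """
    if read.cigartuples is None:
        raise ValueError(f"read {read.query_name!r} has no CIGAR")
    for op, _ in read.cigartuples:
        if op not in _SUPPORTED_CIGAR_OPS:
            raise ValueError(
                f"read {read.query_name!r}: unsupported CIGAR op code {op}"
            )
    seq = read.query_sequence
    if seq is None:
        raise ValueError(f"read {read.query_name!r} has no query sequence")
    chrom = read.reference_name
    votes: list[tuple[int, int | None]] = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        snp = snps.get(chrom, rpos)
        if snp is None:
            continue
        base = seq[qpos].upper()
        if base == snp.allele1_base:
            votes.append((rpos, 1))
        elif base == snp.allele2_base:
            votes.append((rpos, 2))
        else:
            votes.append((rpos, None))
    return votes


def _majority_call(votes: Sequence[tuple[int, int | None]]) -> str:
    n1 = sum(1 for _, v in votes if v == 1)
    n2 = sum(1 for _, v in votes if v == 2)
    if n1 == 0 and n2 == 0:
        return CALL_UNASSIGNED
    if n1 > n2:
        return CALL_ALLELE1
    if n2 > n1:
        return CALL_ALLELE2
    return CALL_CONFLICT


def assign_read_allele(read: pysam.AlignedSegment, snps: SnpIndex) -> ReadAlleleCall:
    """Assign one aligned read to a haplotype by majority vote over its SNPs.

    Reads covering no SNP return a call with ``n_snps_covered == 0`` and an
    ``unassigned`` state; callers ignore them.
    """
    if read.is_unmapped:
        raise ValueError(f"read {read.query_name!r} is unmapped")
    votes = _read_snp_votes(read, snps)
    return ReadAlleleCall(
        read_id=read.query_name,
        locus_name=None,
        call=_majority_call(votes) if votes else CALL_UNASSIGNED,
        n_snps_covered=len(votes),
    )


# ---------------------------------------------------------------------------
# per-sample quantification
# ---------------------------------------------------------------------------

def _read_transcript_strand(read: pysam.AlignedSegment, orientation: str) -> str | None:
    if orientation == "unstranded":
        return None
    strand = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        strand = "-" if strand == "+" else "+"
    if orientation == "reverse":
        strand = "-" if strand == "+" else "+"
    return strand


def quantify_sample(
    alignments: str | Path | pysam.AlignmentFile,
    annotation: Sequence[AnnotationRecord],
    snps: SnpIndex,
    params: QuantParams = QuantParams(),
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Quantify allele-specific expression for every annotated locus.

    Returns a locus table (one row per locus surviving chromosome
    exclusion) with AR/AS computed whenever at least one read was assigned;
    zero-read loci keep blank (NaN) AR/AS. A per-locus read tally — assigned,
    conflicting, unassigned, SNP-less and SNP-filtered reads — is attached
    as ``df.attrs["read_tally"]`` and written to the run log; it conserves
    every considered read.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    loci = [a for a in annotation if a.chrom not in params.excluded_chroms]
    n_excluded = len(annotation) - len(loci)

    by_chrom: dict[str, list[AnnotationRecord]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for entries in by_chrom.values():
        entries.sort(key=lambda a: a.start)
    starts_by_chrom = {c: [a.start for a in entries] for c, entries in by_chrom.items()}
    max_len_by_chrom = {
        c: max(a.length for a in entries) for c, entries in by_chrom.items()
    }

    locus_snps: dict[str, list[int]] = {
        a.name: [s.pos for s in snps.in_interval(a.chrom, a.start, a.end)] for a in loci
    }
    # per locus: list of (call, covered in-locus SNP positions with a 1/2 vote)
    per_locus_reads: dict[str, list[tuple[str, tuple[int, ...]]]] = {
        a.name: [] for a in loci
    }

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        if own_handle
        else alignments
    )
    try:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            entries = by_chrom.get(chrom)
            if not entries:
                continue
            transcript_strand = _read_transcript_strand(
                read, params.library_orientation
            )
            votes = None
            r_start, r_end = read.reference_start, read.reference_end
            # candidate loci: start < r_end and end > r_start
            hi = _bisect.bisect_left(starts_by_chrom[chrom], r_end)
            lo = _bisect.bisect_left(
                starts_by_chrom[chrom], r_start - max_len_by_chrom[chrom]
            )
            for locus in entries[lo:hi]:
                if locus.end <= r_start or locus.start >= r_end:
                    continue
                if (
                    transcript_strand is not None
                    and locus.strand in ("+", "-")
                    and locus.strand != transcript_strand
                ):
                    continue
                if votes is None:
                    votes = _read_snp_votes(read, snps)
                in_locus = [
                    (pos, v) for pos, v in votes if locus.start <= pos < locus.end
                ]
                if not in_locus:
                    per_locus_reads[locus.name].append(("no_snp", ()))
                    continue
                call = _majority_call(in_locus)
                assigned_positions = tuple(
                    pos for pos, v in in_locus if v is not None
                ) if call in (CALL_ALLELE1, CALL_ALLELE2) else ()
                per_locus_reads[locus.name].append((call, assigned_positions))
    finally:
        if own_handle:
            af.close()

    rows = []
    tally: dict[str, dict[str, int]] = {}
    for locus in loci:
        reads = per_locus_reads[locus.name]
        counts = {
            "a1": 0,
            "a2": 0,
            "conflict": 0,
            "unassigned": 0,
            "no_snp": 0,
            "snp_filtered": 0,
        }
        snp_support: dict[int, int] = {p: 0 for p in locus_snps[locus.name]}
        for call, positions in reads:
            if call in (CALL_ALLELE1, CALL_ALLELE2):
                for pos in positions:
                    snp_support[pos] += 1
        kept_snps = {
            p for p, n in snp_support.items() if n >= params.min_reads_per_snp
        }
        for call, positions in reads:
            if call == CALL_ALLELE1 or call == CALL_ALLELE2:
                if any(p in kept_snps for p in positions):
                    counts["a1" if call == CALL_ALLELE1 else "a2"] += 1
                else:
                    counts["snp_filtered"] += 1
            elif call == CALL_CONFLICT:
                counts["conflict"] += 1
            elif call == CALL_UNASSIGNED:
                counts["unassigned"] += 1
            else:  # no_snp sentinel
                counts["no_snp"] += 1
        counts["overlapping_total"] = len(reads)
        tally[locus.name] = counts
        a1, a2 = counts["a1"], counts["a2"]
        total = a1 + a2
        ar = a1 / total if total > 0 else math.nan
        score = allelic_score(a1, a2) if total > 0 else math.nan
        rows.append(
            {
                "locus_name": locus.name,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "strand": locus.strand,
                "biotype": locus.biotype,
                "total_reads": float(total),
                "a1_reads": a1,
                "a2_reads": a2,
                "n_snps": len(kept_snps),
                "allelic_ratio": ar,
                "allelic_score": score,
            }
        )

    df = pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS)
    df.attrs["read_tally"] = tally
    if log is not None:
        log.add_params(
            {
                "min_reads_per_snp": params.min_reads_per_snp,
                "library_orientation": params.library_orientation,
                "excluded_chroms": sorted(params.excluded_chroms),
            }
        )
        log.add(f"{len(annotation)} loci in annotation")
        log.add(f"{n_excluded} loci dropped on excluded chromosomes")
        total_conflict = sum(t["conflict"] for t in tally.values())
        total_unassigned = sum(t["unassigned"] for t in tally.values())
        total_filtered = sum(t["snp_filtered"] for t in tally.values())
        log.add(f"{total_conflict} conflicting reads excluded")
        log.add(f"{total_unassigned} unassigned (third-allele) reads excluded")
        log.add(f"{total_filtered} reads dropped by the per-SNP read minimum")
    return df


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_strands(table_fwd: pd.DataFrame, table_rev: pd.DataFrame) -> pd.DataFrame:
    """Concatenate the per-strand tables of one sample.

    The two runs must partition the annotation: a locus present in both is
    an error.
    """
    shared = set(table_fwd["locus_name"]) & set(table_rev["locus_name"])
    if shared:
        raise ValueError(
            f"loci present in both strand tables: {', '.join(sorted(shared)[:5])}"
        )
    parts = [t for t in (table_fwd, table_rev) if len(t) > 0]
    if not parts:
        return table_fwd.copy()
    if len(parts) == 1:
        return parts[0].reset_index(drop=True)[LOCUS_TABLE_COLUMNS]
    merged = pd.concat(parts, ignore_index=True)
    return merged[LOCUS_TABLE_COLUMNS]


def merge_replicates(
    tables: Sequence[pd.DataFrame],
    informative_rule: str = "all_samples",
    min_total_reads: int = 20,
    log: RunLog | None = None,
) -> pd.DataFrame:
    """Merge replicate locus tables into one robust consensus table.

    A locus is kept when its total reads reach ``min_total_reads`` in every
    replicate (``all_samples``, the inbred-cross rule) or in at least one
    (``any_sample``, the outbred-cohort rule). Merged total reads and AR are
    medians across replicates; the merged score magnitude is the minimum
    |AS| (the most conservative replicate) signed by the median-AR side.
    Replicates whose score sign disagrees with that side are counted in the
    log.
    """
    if len(tables) == 0:
        raise ValueError("merge_replicates requires at least one table")
    if informative_rule not in ("all_samples", "any_sample"):
        raise ValueError(f"unknown informative rule {informative_rule!r}")
    names = list(tables[0]["locus_name"])
    name_set = set(names)
    for i, t in enumerate(tables[1:], start=2):
        if set(t["locus_name"]) != name_set:
            raise ValueError(f"replicate {i} has a different locus set")
    indexed = [t.set_index("locus_name") for t in tables]

    rows = []
    n_discordant = 0
    for name in names:
        reps = [t.loc[name] for t in indexed]
        totals = np.array([r["total_reads"] for r in reps], dtype=float)
        informative = totals >= min_total_reads
        keep = informative.all() if informative_rule == "all_samples" else informative.any()
        if not keep:
            continue
        ars = np.array([r["allelic_ratio"] for r in reps], dtype=float)
        scores = np.array([r["allelic_score"] for r in reps], dtype=float)
        defined = ~np.isnan(ars)
        med_total = float(np.median(totals))
        med_ar = float(np.median(ars[defined]))
        min_abs_score = float(np.min(np.abs(scores[defined])))
        if med_ar > 0.5:
            sign = 1.0
        elif med_ar < 0.5:
            sign = -1.0
        else:
            sign = 0.0
        merged_score = sign * min_abs_score
        n_discordant += int(
            np.sum(np.sign(scores[defined]) * sign < 0)
        )
        first = reps[0]
        rows.append(
            {
                "locus_name": name,
                "chrom": first["chrom"],
                "start": int(first["start"]),
                "end": int(first["end"]),
                "strand": first["strand"],
                "biotype": first["biotype"],
                "total_reads": med_total,
                "a1_reads": int(np.median([r["a1_reads"] for r in reps])),
                "a2_reads": int(np.median([r["a2_reads"] for r in reps])),
                "n_snps": int(np.median([r["n_snps"] for r in reps])),
                "allelic_ratio": med_ar,
                "allelic_score": merged_score,
            }
        )
    if log is not None:
        log.add(f"{len(tables)} replicates merged under rule {informative_rule}")
        log.add(f"{len(rows)} of {len(names)} loci informative")
        log.add(f"{n_discordant} replicate scores discordant with the median-AR sign")
    return pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS)
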