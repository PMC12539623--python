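"""Shared domain types.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), the convention of BED and of pysam. Conversion to the
1-based, fully-closed display convention of genome browsers is provided by
:func:`to_display_coords` / :func:`from_display_coords` and is an exact
round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

NUCLEOTIDES = frozenset("ACGT")

#: Biotype labels with special meaning to the linker; anything else is "other".
BIOTYPE_NCRNA = "ncRNA"
BIOTYPE_PCGENE = "pcGene"
BIOTYPE_PEAK = "peak"
BIOTYPE_OTHER = "other"

KNOWN_BIOTYPES = (BIOTYPE_NCRNA, BIOTYPE_PCGENE, BIOTYPE_PEAK, BIOTYPE_OTHER)

ENHANCING = "enhancing"
REPRESSIVE = "repressive"


@dataclass(frozen=True)
class AnnotationRecord:
    """One BED6 locus plus a biotype tag.

    The transcription start site (``tss``) is the ``start`` coordinate for
    loci on the plus (or unknown) strand and ``end - 1`` for the minus
    strand, so it always lies inside ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    biotype: str = BIOTYPE_OTHER

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"locus {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"locus {self.name!r}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand in ("+", ".") else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PhasedSNP:
    """A single-base phased heterozygous variant.

    ``allele1_base`` belongs to haplotype 1 (the allele whose read fraction
    is the allelic ratio), ``allele2_base`` to haplotype 2.
    """

    chrom: str
    pos: int
    allele1_base: str
    allele2_base: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP position must be >= 0, got {self.pos}")
        for base in (self.allele1_base, self.allele2_base):
            if base not in NUCLEOTIDES:
                raise ValueError(f"invalid SNP base {base!r}")
        if self.allele1_base == self.allele2_base:
            raise ValueError(
                f"SNP at {self.chrom}:{self.pos} has identical alleles "
                f"{self.allele1_base!r}"
            )


@dataclass(frozen=True)
class Linkage:
    """An ordered pair of allele-specific loci with mechanism and score.

    ``delta_ar`` is the signed difference of centered allelic-ratio
    magnitudes, |AR_source - 0.5| - |AR_target - 0.5|; ``linkage_score`` is
    log10(min(|AS_source|, |AS_target|) + 1) * (1 - |delta_ar|). Both the
    score and the mechanism call are symmetric in source and target.
    """

    chrom: str
    source_name: str
    source_start: int
    source_end: int
    source_strand: str
    source_biotype: str
    source_ar: float
    source_score: float
    target_name: str
    target_start: int
    target_end: int
    target_strand: str
    target_biotype: str
    target_ar: float
    target_score: float
    mechanism: str
    delta_ar: float
    linkage_score: float
    distance_bp: int
    tss_distance_bp: int

    def __post_init__(self) -> None:
        if self.mechanism not in (ENHANCING, REPRESSIVE):
            raise ValueError(f"invalid mechanism {self.mechanism!r}")
        if self.linkage_score < 0:
            raise ValueError("linkage score must be >= 0")
        if self.source_name == self.target_name:
            raise ValueError("self-linkage forbidden")

    @property
    def key(self) -> "LinkageKey":
        return LinkageKey(self.source_name, self.target_name)

    def intervals_overlap(self) -> bool:
        return self.distance_bp == 0 and not (
            self.source_end <= self.target_start or self.target_end <= self.source_start
        )


class LinkageKey(NamedTuple):
    """Identity of a linkage across samples: the gene-id pair only.

    Mechanism is deliberately not part of the identity; whether the same
    pair is called enhancing or repressive may vary per sample and is what
    the consistency analysis measures.
    """

    source_gene_id: str
    target_gene_id: str


@dataclass(frozen=True)
class EqtlRecord:
    chrom: str
    pos: int
    target_gene: str
    tissue: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("eQTL position must be >= 0")


@dataclass(frozen=True)
class GwasVariant:
    rsid: str
    chrom: str
    pos: int
    pvalue: float
    trait: str

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"GWAS p-value must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class TadInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid TAD interval [{self.start}, {self.end})")

    def contains(self, start: int, end: int, chrom: str | None = None) -> bool:
        """Full containment of ``[start, end)`` (the TAD co-localization rule)."""
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= start and end <= self.end


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Minimum gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, max(start1, start2) - min(end1, end2))


def to_display_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based fully-closed browser coordinates."""
    return start + 1, end


def from_display_coords(first: int, last: int) -> tuple[int, int]:
    """Inverse of :func:`to_display_coords`."""
    return first - 1, last
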