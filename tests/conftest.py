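"""Shared fixtures: a hand-built SAM alignment with known allele counts,
small annotation/SNP files, and locus-table builders."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import settings

from aselink.io import LOCUS_TABLE_COLUMNS, SnpIndex
from aselink.quant import allelic_score
from aselink.records import AnnotationRecord, PhasedSNP

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(name: str, start: int, seq: str, flag: int = 0, cigar: str | None = None) -> str:
    cigar = cigar or f"{len(seq)}M"
    return (
        f"{name}\t{flag}\tchr1\t{start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
    )


def read_seq(start: int, length: int, bases: dict[int, str]) -> str:
    """Sequence of 'N' filler with specified bases at reference positions."""
    seq = ["N"] * length
    for pos, base in bases.items():
        assert start <= pos < start + length
        seq[pos - start] = base
    return "".join(seq)


@pytest.fixture
def planted_sam(tmp_path):
    """One locus, two phased SNPs, 20 planted reads.

    12 allele-1 reads (8 via SNP at 199 C/T, 4 via SNP at 210 A/G),
    6 allele-2 reads (4 via 199, 2 via 210), 1 conflicting read voting both
    ways, 1 unassigned read with a third allele. Expected counts:
    a1 = 12, a2 = 6, total = 18.
    """
    snps = SnpIndex(
        [PhasedSNP("chr1", 199, "C", "T"), PhasedSNP("chr1", 210, "A", "G")]
    )
    annotation = [
        AnnotationRecord("chr1", 100, 500, "GeneA", 0.0, "+", "pcGene")
    ]
    lines = [SAM_HEADER]
    i = 0

    def add(start, bases):
        nonlocal i
        lines.append(sam_line(f"r{i:02d}", start, read_seq(start, 50, bases)))
        i += 1

    for _ in range(8):
        add(150, {199: "C"})  # covers 199 only
    for _ in range(4):
        add(205, {210: "A"})  # covers 210 only
    for _ in range(4):
        add(150, {199: "T"})
    for _ in range(2):
        add(205, {210: "G"})
    add(170, {199: "C", 210: "G"})  # one vote per allele -> conflict
    add(150, {199: "G"})  # third allele -> unassigned

    path = tmp_path / "planted.sam"
    path.write_text("".join(lines))
    return {
        "sam": path,
        "annotation": annotation,
        "snps": snps,
        "expected": {"a1": 12, "a2": 6, "total": 18, "n_reads": 20},
    }


def locus_row(
    name: str,
    chrom: str = "chr1",
    start: int = 0,
    end: int = 1000,
    strand: str = "+",
    biotype: str = "pcGene",
    a1: int = 10,
    a2: int = 10,
    n_snps: int = 1,
) -> dict:
    total = a1 + a2
    return {
        "locus_name": name,
        "chrom": chrom,
        "start": start,
        "end": end,
        "strand": strand,
        "biotype": biotype,
        "total_reads": float(total),
        "a1_reads": a1,
        "a2_reads": a2,
        "n_snps": n_snps,
        "allelic_ratio": a1 / total if total else math.nan,
        "allelic_score": allelic_score(a1, a2) if total else math.nan,
    }


def locus_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS)
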