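"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* BED6 locus annotation (+ optional two-column biotype sidecar),
* BED4 phased SNPs with an ``A1/A2`` allele string in the name column
  (haplotype-1 base first),
* the locus-table TSV produced by the quantifier (fixed 12-column schema),
* ranked linkage outputs: TSV table, BEDPE and BED browser tracks with the
  green/red mechanism colour convention, and a plain-text run log.

SAM alignments are consumed directly with pysam in :mod:`aselink.quant`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    BIOTYPE_OTHER,
    ENHANCING,
    AnnotationRecord,
    EqtlRecord,
    GwasVariant,
    Linkage,
    PhasedSNP,
    TadInterval,
)

#: Exact column set and order of the locus table dialect.
LOCUS_TABLE_COLUMNS = [
    "locus_name",
    "chrom",
    "start",
    "end",
    "strand",
    "biotype",
    "total_reads",
    "a1_reads",
    "a2_reads",
    "n_snps",
    "allelic_ratio",
    "allelic_score",
]

RGB_ENHANCING = "0,128,0"
RGB_REPRESSIVE = "255,0,0"


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# annotation (BED6)
# ---------------------------------------------------------------------------

def parse_annotation(
    path: str | Path,
    biotype_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[AnnotationRecord]:
    """Read a BED6 annotation file into validated records.

    ``biotype_map`` assigns a biotype per locus name, either as a mapping or
    as a callable (e.g. a name-prefix rule); unmapped names default to
    ``"other"``. Duplicate locus names are rejected.
    """
    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 6:
            raise FormatError(
                f"{path}: line {lineno}: expected 6 BED columns, got {len(fields)}"
            )
        chrom, start_s, end_s, name, score_s, strand = fields
        try:
            start, end = int(start_s), int(end_s)
            score = float(score_s)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric field: {exc}") from None
        if name in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate locus name {name!r}")
        seen.add(name)
        try:
            record = AnnotationRecord(
                chrom=chrom,
                start=start,
                end=end,
                name=name,
                score=score,
                strand=strand,
                biotype=_lookup_biotype(name, biotype_map),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        records.append(record)
    return records


def _lookup_biotype(
    name: str, biotype_map: Mapping[str, str] | Callable[[str], str] | None
) -> str:
    if biotype_map is None:
        return BIOTYPE_OTHER
    if callable(biotype_map):
        return biotype_map(name) or BIOTYPE_OTHER
    return biotype_map.get(name, BIOTYPE_OTHER)


def biotype_from_prefix(prefixes: Mapping[str, str]) -> Callable[[str], str]:
    """Name-prefix biotype rule, e.g. ``{"nc": "ncRNA", "pc": "pcGene"}``."""

    def rule(name: str) -> str:
        for prefix, biotype in prefixes.items():
            if name.startswith(prefix):
                return biotype
        return BIOTYPE_OTHER

    return rule


def read_biotype_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV sidecar: locus name -> biotype."""
    mapping: dict[str, str] = {}
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
            )
        mapping[fields[0]] = fields[1]
    return mapping


def write_annotation(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


def write_biotype_map(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.name}\t{r.biotype}\n")


# ---------------------------------------------------------------------------
# phased SNPs (BED4)
# ---------------------------------------------------------------------------

class SnpIndex:
    """Phased SNPs indexed for point lookup and interval queries."""

    def __init__(self, snps: Iterable[PhasedSNP]):
        self._by_pos: dict[tuple[str, int], PhasedSNP] = {}
        self._positions: dict[str, list[int]] = {}
        for snp in snps:
            key = (snp.chrom, snp.pos)
            if key in self._by_pos:
                raise FormatError(f"duplicate SNP at {snp.chrom}:{snp.pos}")
            self._by_pos[key] = snp
        chroms: dict[str, list[int]] = {}
        for chrom, pos in self._by_pos:
            chroms.setdefault(chrom, []).append(pos)
        self._positions = {c: sorted(p) for c, p in chroms.items()}

    def __len__(self) -> int:
        return len(self._by_pos)

    def __iter__(self):
        return iter(self._by_pos.values())

    def get(self, chrom: str, pos: int) -> PhasedSNP | None:
        return self._by_pos.get((chrom, pos))

    def in_interval(self, chrom: str, start: int, end: int) -> list[PhasedSNP]:
        """All SNPs with ``start <= pos < end`` on ``chrom``, sorted."""
        positions = self._positions.get(chrom, [])
        lo = bisect.bisect_left(positions, start)
        hi = bisect.bisect_left(positions, end)
        return [self._by_pos[(chrom, p)] for p in positions[lo:hi]]


def parse_snps(path: str | Path) -> SnpIndex:
    """Read a BED4 phased-SNP file (name column ``A1/A2``, width-1 intervals)."""
    snps: list[PhasedSNP] = []
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 4:
            raise FormatError(
                f"{path}: line {lineno}: expected 4 BED columns, got {len(fields)}"
            )
        chrom, start_s, end_s, alleles = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric coordinate") from None
        if end != start + 1:
            raise FormatError(
                f"{path}: line {lineno}: SNP interval must have width 1, "
                f"got [{start}, {end})"
            )
        parts = alleles.split("/")
        if len(parts) != 2 or not all(len(p) == 1 for p in parts):
            raise FormatError(
                f"{path}: line {lineno}: malformed allele string {alleles!r} "
                "(expected 'X/Y')"
            )
        try:
            snps.append(PhasedSNP(chrom, start, parts[0].upper(), parts[1].upper()))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return SnpIndex(snps)


def write_snps(snps: Iterable[PhasedSNP], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.allele1_base}/{s.allele2_base}\n")


# ---------------------------------------------------------------------------
# locus tables
# ---------------------------------------------------------------------------

def read_locus_table(path: str | Path) -> pd.DataFrame:
    """Read a locus-table TSV, validating the fixed column schema."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "locus_name": str})
    missing = [c for c in LOCUS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: locus table missing column(s): {', '.join(missing)}")
    df = df[LOCUS_TABLE_COLUMNS].copy()
    for col in ("start", "end", "a1_reads", "a2_reads", "n_snps"):
        df[col] = df[col].astype(np.int64)
    for col in ("total_reads", "allelic_ratio", "allelic_score"):
        df[col] = df[col].astype(float)
    return df


def write_locus_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a locus table; blank cells for undefined AR/AS (zero-read loci)."""
    missing = [c for c in LOCUS_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"locus table missing column(s): {', '.join(missing)}")
    out = table[LOCUS_TABLE_COLUMNS]
    # no float_format: pandas emits shortest-exact reprs, so read/write is
    # an identity on finite values and blank cells round-trip as NaN
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eQTL / GWAS / TAD tables
# ---------------------------------------------------------------------------

def read_eqtl_table(path: str | Path) -> list[EqtlRecord]:
    """4-column TSV with header: chrom, pos, target_gene, tissue."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "target_gene": str, "tissue": str})
    _require_columns(df, ["chrom", "pos", "target_gene", "tissue"], path)
    return [
        EqtlRecord(r.chrom, int(r.pos), r.target_gene, r.tissue)
        for r in df.itertuples(index=False)
    ]


def write_eqtl_table(eqtls: Iterable[EqtlRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(e.chrom, e.pos, e.target_gene, e.tissue) for e in eqtls],
        columns=["chrom", "pos", "target_gene", "tissue"],
    ).to_csv(path, sep="\t", index=False)


def read_gwas_table(path: str | Path) -> list[GwasVariant]:
    """5-column TSV with header: rsid, chrom, pos, pvalue, trait."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "trait": str})
    _require_columns(df, ["rsid", "chrom", "pos", "pvalue", "trait"], path)
    return [
        GwasVariant(r.rsid, r.chrom, int(r.pos), float(r.pvalue), r.trait)
        for r in df.itertuples(index=False)
    ]


def write_gwas_table(variants: Iterable[GwasVariant], path: str | Path) -> None:
    pd.DataFrame(
        [(v.rsid, v.chrom, v.pos, v.pvalue, v.trait) for v in variants],
        columns=["rsid", "chrom", "pos", "pvalue", "trait"],
    ).to_csv(path, sep="\t", index=False)


def read_tad_bed(path: str | Path) -> list[TadInterval]:
    """BED3 file of TAD intervals."""
    tads: list[TadInterval] = []
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
        try:
            tads.append(TadInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return tads


def write_tad_bed(tads: Iterable[TadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")


# ---------------------------------------------------------------------------
# linkage outputs
# ---------------------------------------------------------------------------

LINKAGE_TABLE_COLUMNS = [
    "source_name",
    "target_name",
    "chrom",
    "source_start",
    "source_end",
    "source_strand",
    "source_biotype",
    "source_ar",
    "source_score",
    "target_start",
    "target_end",
    "target_strand",
    "target_biotype",
    "target_ar",
    "target_score",
    "mechanism",
    "delta_ar",
    "linkage_score",
    "distance_bp",
    "tss_distance_bp",
]


def rank_linkages(linkages: Iterable[Linkage]) -> list[Linkage]:
    """Order by linkage score descending; ties by source then target name."""
    return sorted(
        linkages,
        key=lambda l: (-l.linkage_score, l.source_name, l.target_name),
    )


def linkages_to_frame(linkages: Sequence[Linkage]) -> pd.DataFrame:
    rows = [
        {col: getattr(l, col) for col in LINKAGE_TABLE_COLUMNS} for l in linkages
    ]
    return pd.DataFrame(rows, columns=LINKAGE_TABLE_COLUMNS)


def write_linkage_outputs(
    linkages: Iterable[Linkage],
    out_prefix: str | Path,
    log: "RunLog | None" = None,
) -> dict[str, Path]:
    """Write the ranked linkage table, BEDPE and BED tracks, and the run log.

    An empty linkage set is valid: header-only table, empty tracks, and a
    "0 linkages written" log line. Returns the paths written.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ranked = rank_linkages(linkages)
    own_log = log is None
    if log is None:
        log = RunLog()

    table_path = prefix.with_name(prefix.name + ".linkage_table.tsv")
    linkages_to_frame(ranked).to_csv(
        table_path, sep="\t", index=False, float_format="%.10g"
    )

    bedpe_path = prefix.with_name(prefix.name + ".bedpe")
    with open(bedpe_path, "w") as fh:
        for l in ranked:
            rgb = RGB_ENHANCING if l.mechanism == ENHANCING else RGB_REPRESSIVE
            fh.write(
                "\t".join(
                    [
                        l.chrom,
                        str(l.source_start),
                        str(l.source_end),
                        l.chrom,
                        str(l.target_start),
                        str(l.target_end),
                        f"{l.source_name}|{l.target_name}",
                        f"{l.linkage_score:.6g}",
                        l.source_strand,
                        l.target_strand,
                        l.mechanism,
                        f"{l.delta_ar:.6g}",
                        rgb,
                    ]
                )
                + "\n"
            )

    bed_path = prefix.with_name(prefix.name + ".bed")
    with open(bed_path, "w") as fh:
        fh.write('track name="linkages" itemRgb="On"\n')
        for l in ranked:
            rgb = RGB_ENHANCING if l.mechanism == ENHANCING else RGB_REPRESSIVE
            start = min(l.source_start, l.target_start)
            end = max(l.source_end, l.target_end)
            score = int(min(1000, round(l.linkage_score * 100)))
            fh.write(
                f"{l.chrom}\t{start}\t{end}\t{l.source_name}|{l.target_name}\t"
                f"{score}\t.\t{start}\t{end}\t{rgb}\n"
            )

    log.add(f"{len(ranked)} linkages written")
    paths = {"table": table_path, "bedpe": bedpe_path, "bed": bed_path}
    if own_log:
        log_path = prefix.with_name(prefix.name + ".log")
        log.write(log_path)
        paths["log"] = log_path
    return paths


def read_linkage_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, LINKAGE_TABLE_COLUMNS, path)
    return df


# ---------------------------------------------------------------------------
# run log
# ---------------------------------------------------------------------------

@dataclass
class RunLog:
    """Accumulates one line per event: parameters, per-stage counts, warnings."""

    lines: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.lines.append(message)

    def add_params(self, params: Mapping[str, object]) -> None:
        for key, value in params.items():
            self.lines.append(f"param {key} = {value}")

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("".join(line + "\n" for line in self.lines))
        return path

    def __str__(self) -> str:
        return "\n".join(self.lines)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _iter_tsv(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
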