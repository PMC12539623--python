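"""Synthetic data with planted ground truth.

The generator emulates the statistical structure the linkage method
assumes: a mostly biallelic transcriptome (allelic ratio 0.5), a minority
of loci with strong planted allelic imbalance, and cis-proximal pairs of
such loci whose imbalance is correlated (enhancing) or anti-correlated
(repressive). Allele counts are drawn beta-binomially so the overdispersion
of real allele-specific counts is represented; reads are perfect-match,
single-end, fixed-length records carrying the correct haplotype base at
every covered SNP.

Planted link pairs are placed within the linkage window and isolated from
members of *other* planted pairs by more than the window, so the planted
truth set is exactly the set of discoverable in-window allelic pairs and
precision/recall against it is well defined. Background loci are placed
uniformly with only a small non-overlap margin.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import (
    SnpIndex,
    write_annotation,
    write_biotype_map,
    write_snps,
)
from .link import NCRNA_TO_PCGENE, LinkParams, run_link
from .quant import QuantParams, allelic_score, merge_replicates, quantify_sample
from .records import (
    BIOTYPE_NCRNA,
    BIOTYPE_PCGENE,
    ENHANCING,
    REPRESSIVE,
    AnnotationRecord,
    LinkageKey,
    PhasedSNP,
)

READ_LENGTH = 50  # single-end, perfect match
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedLink:
    """One ground-truth cis-regulatory pair, by locus index."""

    source_index: int
    target_index: int
    mechanism: str
    source_ar: float
    target_ar: float

    def __post_init__(self) -> None:
        if self.mechanism not in (ENHANCING, REPRESSIVE):
            raise ValueError(f"invalid mechanism {self.mechanism!r}")
        for ar in (self.source_ar, self.target_ar):
            if not (0.0 <= ar <= 1.0):
                raise ValueError("planted allelic ratios must be in [0, 1]")


def make_planted_links(
    n_links: int = 20,
    strong_ar: float = 0.85,
    weak_ar: float = 0.15,
) -> list[PlantedLink]:
    """Deterministic planted-link layout: pair (2i, 2i+1), mechanisms
    alternating enhancing / repressive, AR magnitudes ``strong_ar`` away
    from balance."""
    links = []
    for i in range(n_links):
        enhancing = i % 2 == 0
        links.append(
            PlantedLink(
                source_index=2 * i,
                target_index=2 * i + 1,
                mechanism=ENHANCING if enhancing else REPRESSIVE,
                source_ar=strong_ar,
                target_ar=strong_ar if enhancing else weak_ar,
            )
        )
    return links


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the benchmark conditions used throughout the test
    suite: 200 loci on two chromosomes, 20 planted links with allelic
    ratios 0.85 / 0.15, mean coverage 50 SNP-overlapping reads per locus,
    and moderate beta-binomial overdispersion (concentration 200).
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 30_000_000
    n_loci: int = 200
    ncrna_fraction: float = 0.3
    locus_length_bp: int = 2_000
    snps_per_locus: float = 3.0
    coverage_per_locus: float = 50.0
    concentration: float = 200.0  # beta-binomial; math.inf = pure binomial
    planted_links: tuple[PlantedLink, ...] = tuple(make_planted_links())
    baseline_ar: float = 0.5
    min_link_gap_bp: int = 5_000
    max_link_gap_bp: int = 50_000
    pair_isolation_bp: int = 150_000
    min_locus_separation_bp: int = 200
    link_active_prob: float = 0.6
    tissue: str = "synthetic_tissue"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 2 * len(self.planted_links):
            raise ValueError("not enough loci for the planted links")
        if not (0.0 <= self.ncrna_fraction <= 1.0):
            raise ValueError("ncrna_fraction must be in [0, 1]")
        if self.max_link_gap_bp < self.min_link_gap_bp:
            raise ValueError("max_link_gap_bp < min_link_gap_bp")


@dataclass
class Genome:
    """A simulated annotation + phased-SNP set with per-locus true AR."""

    annotation: list[AnnotationRecord]
    snps: SnpIndex
    chrom_lengths: dict[str, int]
    true_ar: dict[str, float]
    planted_pairs: list[tuple[str, str, str]]  # (source, target, mechanism)

    @property
    def truth_keys(self) -> set[LinkageKey]:
        return {LinkageKey(s, t) for s, t, _ in self.planted_pairs}

    def locus(self, name: str) -> AnnotationRecord:
        return next(a for a in self.annotation if a.name == name)

    def write(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": prefix.with_name(prefix.name + ".annotation.bed"),
            "biotypes": prefix.with_name(prefix.name + ".biotypes.tsv"),
            "snps": prefix.with_name(prefix.name + ".snps.bed"),
            "truth": prefix.with_name(prefix.name + ".truth.tsv"),
        }
        write_annotation(self.annotation, paths["annotation"])
        write_biotype_map(self.annotation, paths["biotypes"])
        write_snps(self.snps, paths["snps"])
        with open(paths["truth"], "w") as fh:
            fh.write("locus_name\ttrue_ar\n")
            for a in self.annotation:
                fh.write(f"{a.name}\t{self.true_ar[a.name]:g}\n")
        return paths


def simulate_genome(config: TruthConfig) -> Genome:
    """Place non-overlapping loci, planted pairs first, then SNPs.

    Deterministic for a fixed config (including its seed). Raises when the
    loci cannot be placed without violating the separation constraints.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length_bp for c in chroms}
    L = config.locus_length_bp

    n_ncrna = math.floor(config.ncrna_fraction * config.n_loci)
    planted_sources = {pl.source_index for pl in config.planted_links}
    planted_targets = {pl.target_index for pl in config.planted_links}
    if planted_sources & planted_targets:
        raise ValueError("a locus index appears as both source and target")
    if len(planted_sources) > n_ncrna:
        raise ValueError("ncrna_fraction too small for the planted sources")
    biotypes: dict[int, str] = {}
    for idx in planted_sources:
        biotypes[idx] = BIOTYPE_NCRNA
    for idx in planted_targets:
        biotypes[idx] = BIOTYPE_PCGENE
    quota = n_ncrna - len(planted_sources)
    for idx in range(config.n_loci):
        if idx in biotypes:
            continue
        biotypes[idx] = BIOTYPE_NCRNA if quota > 0 else BIOTYPE_PCGENE
        quota -= 1 if biotypes[idx] == BIOTYPE_NCRNA else 0

    # placement bookkeeping: per chrom sorted (start, end, is_pair_member)
    placed: dict[str, list[tuple[int, int, bool]]] = {c: [] for c in chroms}

    def conflicts(chrom: str, start: int, end: int, is_pair: bool) -> bool:
        for s, e, pair_member in placed[chrom]:
            margin = (
                config.pair_isolation_bp
                if (is_pair and pair_member)
                else config.min_locus_separation_bp
            )
            if start < e + margin and s < end + margin:
                return True
        return False

    intervals: dict[int, tuple[str, int, int]] = {}

    def place(idx: int, chrom: str, start: int, end: int, is_pair: bool) -> None:
        placed[chrom].append((start, end, is_pair))
        intervals[idx] = (chrom, start, end)

    for pl in config.planted_links:
        gap = int(rng.integers(config.min_link_gap_bp, config.max_link_gap_bp + 1))
        block = 2 * L + gap
        for attempt in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_lengths[chrom] - block))
            if not conflicts(chrom, start, start + block, True):
                break
        else:
            raise ValueError("cannot place planted pair without overlap")
        place(pl.source_index, chrom, start, start + L, True)
        place(pl.target_index, chrom, start + L + gap, start + block, True)

    for idx in range(config.n_loci):
        if idx in intervals:
            continue
        for attempt in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_lengths[chrom] - L))
            if not conflicts(chrom, start, start + L, False):
                break
        else:
            raise ValueError("cannot place locus without overlap")
        place(idx, chrom, start, start + L, False)

    annotation: list[AnnotationRecord] = []
    snps: list[PhasedSNP] = []
    true_ar: dict[str, float] = {}
    ar_by_index: dict[int, float] = {}
    for pl in config.planted_links:
        ar_by_index[pl.source_index] = pl.source_ar
        ar_by_index[pl.target_index] = pl.target_ar
    for idx in range(config.n_loci):
        chrom, start, end = intervals[idx]
        name = f"L{idx:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        annotation.append(
            AnnotationRecord(
                chrom=chrom,
                start=start,
                end=end,
                name=name,
                score=0.0,
                strand=strand,
                biotype=biotypes[idx],
            )
        )
        true_ar[name] = ar_by_index.get(idx, config.baseline_ar)
        n_snps = max(1, int(rng.poisson(config.snps_per_locus)))
        lo, hi = start + 5, end - 5
        n_snps = min(n_snps, hi - lo)
        positions = rng.choice(np.arange(lo, hi), size=n_snps, replace=False)
        for pos in sorted(int(p) for p in positions):
            a1, a2 = rng.choice(4, size=2, replace=False)
            snps.append(PhasedSNP(chrom, pos, str(_BASES[a1]), str(_BASES[a2])))

    planted_pairs = [
        (f"L{pl.source_index:04d}", f"L{pl.target_index:04d}", pl.mechanism)
        for pl in config.planted_links
    ]
    return Genome(annotation, SnpIndex(snps), chrom_lengths, true_ar, planted_pairs)


# ---------------------------------------------------------------------------
# allele-count sampling
# ---------------------------------------------------------------------------

def _sample_allele1(rng: np.random.Generator, n: int, ar: float, concentration: float) -> int:
    """Beta-binomial allele-1 count around the true AR."""
    if n == 0:
        return 0
    if ar <= 0.0:
        return 0
    if ar >= 1.0:
        return n
    if math.isinf(concentration):
        p = ar
    else:
        p = float(rng.beta(ar * concentration, (1.0 - ar) * concentration))
    return int(rng.binomial(n, p))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Genome,
    config: TruthConfig,
    out_sam: str | Path,
    seed: int | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Write a SAM file of perfect-match reads and return the truth counts.

    Per locus the allele-1 read count is beta-binomial around the locus's
    true allelic ratio at the configured mean coverage; each read spans one
    of the locus's SNPs and carries the correct haplotype base at every SNP
    it covers. Reads are emitted on the locus strand. Zero coverage yields
    a valid header-only SAM.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = sorted(genome.chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": genome.chrom_lengths[c]} for c in chroms],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    truth_rows = []
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(chroms)}
        for locus in genome.annotation:
            locus_snps = genome.snps.in_interval(locus.chrom, locus.start, locus.end)
            ar = genome.true_ar[locus.name]
            n_reads = int(rng.poisson(config.coverage_per_locus))
            a1 = _sample_allele1(rng, n_reads, ar, config.concentration)
            truth_rows.append(
                {"locus_name": locus.name, "a1_reads": a1, "a2_reads": n_reads - a1}
            )
            for i in range(n_reads):
                allele = 1 if i < a1 else 2
                snp = locus_snps[int(rng.integers(len(locus_snps)))]
                lo = max(0, snp.pos - (READ_LENGTH - 1))
                hi = min(snp.pos, genome.chrom_lengths[locus.chrom] - READ_LENGTH)
                start = int(rng.integers(lo, hi + 1))
                seq = ["A"] * READ_LENGTH
                for covered in genome.snps.in_interval(
                    locus.chrom, start, start + READ_LENGTH
                ):
                    base = (
                        covered.allele1_base if allele == 1 else covered.allele2_base
                    )
                    seq[covered.pos - start] = base
                read = pysam.AlignedSegment()
                read.query_name = f"{sample_id}:{locus.name}:r{i:05d}"
                read.query_sequence = "".join(seq)
                read.flag = 16 if locus.strand == "-" else 0
                read.reference_id = tid[locus.chrom]
                read.reference_start = start
                read.mapping_quality = 60
                read.cigarstring = f"{READ_LENGTH}M"
                read.set_tag("RG", sample_id)
                out.write(read)
    return pd.DataFrame(truth_rows, columns=["locus_name", "a1_reads", "a2_reads"])


# ---------------------------------------------------------------------------
# cohort simulation (locus tables + toy integration tables)
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    genome: Genome
    locus_tables: list[pd.DataFrame]  # one per individual
    active: pd.DataFrame  # planted link x individual activity (bool)
    eqtls: list
    gwas: list
    tads: list

    @property
    def truth_keys(self) -> set[LinkageKey]:
        return self.genome.truth_keys


def simulate_cohort(
    config: TruthConfig,
    n_individuals: int,
    seed: int | None = None,
    tad_size_bp: int = 2_000_000,
) -> CohortSim:
    """Per-individual locus tables with genotype-driven imbalance.

    Each planted link is active in a random subset of individuals
    (``link_active_prob``); where inactive, both loci revert to the
    biallelic baseline — the situation where a regulatory relationship
    exists but the individual's genotype cannot reveal it. Toy eQTL records
    sit inside every planted source locus and point at the true target;
    toy GWAS variants straddle the genome-wide significance threshold; TADs
    tile each chromosome.
    """
    from .records import EqtlRecord, GwasVariant, TadInterval

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genome = simulate_genome(config)
    links = list(config.planted_links)
    active = rng.random((len(links), n_individuals)) < config.link_active_prob

    name_of = {i: f"L{i:04d}" for i in range(config.n_loci)}
    ar_active: dict[str, float] = {}
    link_of_locus: dict[str, int] = {}
    for li, pl in enumerate(links):
        for idx, ar in ((pl.source_index, pl.source_ar), (pl.target_index, pl.target_ar)):
            ar_active[name_of[idx]] = ar
            link_of_locus[name_of[idx]] = li

    tables = []
    for ind in range(n_individuals):
        rows = []
        for locus in genome.annotation:
            li = link_of_locus.get(locus.name)
            if li is not None and active[li, ind]:
                ar_true = ar_active[locus.name]
            else:
                ar_true = config.baseline_ar
            n = int(rng.poisson(config.coverage_per_locus))
            a1 = _sample_allele1(rng, n, ar_true, config.concentration)
            a2 = n - a1
            rows.append(
                {
                    "locus_name": locus.name,
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "strand": locus.strand,
                    "biotype": locus.biotype,
                    "total_reads": float(n),
                    "a1_reads": a1,
                    "a2_reads": a2,
                    "n_snps": len(genome.snps.in_interval(locus.chrom, locus.start, locus.end)),
                    "allelic_ratio": a1 / n if n else math.nan,
                    "allelic_score": allelic_score(a1, a2) if n else math.nan,
                }
            )
        tables.append(pd.DataFrame(rows))

    eqtls = []
    gwas = []
    for li, pl in enumerate(links):
        src = genome.locus(name_of[pl.source_index])
        tgt = genome.locus(name_of[pl.target_index])
        mid = (src.start + src.end) // 2
        eqtls.append(EqtlRecord(src.chrom, mid, tgt.name, config.tissue))
        gwas.append(
            GwasVariant(f"rs_sig_{li}", src.chrom, mid + 1, 1e-9, "synthetic_trait")
        )
        gwas.append(
            GwasVariant(
                f"rs_weak_{li}",
                tgt.chrom,
                (tgt.start + tgt.end) // 2,
                1e-6 if li % 2 == 0 else 5e-8,
                "synthetic_trait",
            )
        )
    tads = []
    for chrom, length in sorted(genome.chrom_lengths.items()):
        for start in range(0, length, tad_size_bp):
            tads.append(TadInterval(chrom, start, min(start + tad_size_bp, length)))

    return CohortSim(
        genome=genome,
        locus_tables=tables,
        active=pd.DataFrame(
            active,
            index=[f"{s}->{t}" for s, t, _ in genome.planted_pairs],
            columns=[f"ind{i:03d}" for i in range(n_individuals)],
        ),
        eqtls=eqtls,
        gwas=gwas,
        tads=tads,
    )


# ---------------------------------------------------------------------------
# constructed-truth fixtures (domain-scale silencing analogues)
# ---------------------------------------------------------------------------

def _fixture_row(
    name: str,
    chrom: str,
    start: int,
    length: int,
    biotype: str,
    ar: float,
    coverage: int,
) -> dict:
    a1 = int(round(coverage * ar))
    a2 = coverage - a1
    return {
        "locus_name": name,
        "chrom": chrom,
        "start": start,
        "end": start + length,
        "strand": "+",
        "biotype": biotype,
        "total_reads": float(coverage),
        "a1_reads": a1,
        "a2_reads": a2,
        "n_snps": 3,
        "allelic_ratio": a1 / coverage,
        "allelic_score": allelic_score(a1, a2),
    }


def simulate_silenced_domain(
    n_targets: int = 40,
    n_escape: int = 2,
    regulator_ar: float = 0.9,
    target_ar: float = 0.1,
    coverage: int = 50,
    spacing_bp: int = 500_000,
    chrom: str = "chrX",
    knockout: bool = False,
) -> tuple[pd.DataFrame, list[str], str]:
    """Chromosome-wide repressor fixture with deterministic counts.

    One allelic ncRNA regulator followed by ``n_targets`` opposite-allele
    genes and ``n_escape`` biallelic escape genes spaced along one
    chromosome. With ``knockout=True`` the regulator is biallelic (the
    deletion analogue) and must attract no linkages. Returns (locus table,
    true target names, regulator name).
    """
    rows = [
        _fixture_row(
            "regulator",
            chrom,
            100_000,
            10_000,
            BIOTYPE_NCRNA,
            0.5 if knockout else regulator_ar,
            coverage,
        )
    ]
    targets = []
    pos = 100_000 + spacing_bp
    escape_slots = set(
        np.linspace(1, n_targets + n_escape, n_escape, dtype=int)
    ) if n_escape else set()
    gi = ei = 0
    for slot in range(1, n_targets + n_escape + 1):
        if slot in escape_slots and ei < n_escape:
            rows.append(
                _fixture_row(
                    f"escape{ei:02d}", chrom, pos, 5_000, BIOTYPE_PCGENE, 0.5, coverage
                )
            )
            ei += 1
        else:
            name = f"gene{gi:02d}"
            rows.append(
                _fixture_row(name, chrom, pos, 5_000, BIOTYPE_PCGENE, target_ar, coverage)
            )
            targets.append(name)
            gi += 1
        pos += spacing_bp
    return pd.DataFrame(rows), targets, "regulator"


def simulate_imprinted_cluster(
    n_targets: int = 3,
    regulator_ar: float = 0.15,
    target_ar: float = 0.85,
    coverage: int = 50,
    span_bp: int = 4_000_000,
    chrom: str = "chr17",
    knockout: bool = False,
) -> tuple[pd.DataFrame, list[str], str]:
    """Imprinted-cluster fixture: one paternal ncRNA repressing a handful of
    maternal genes within a multi-megabase span (link with a widened
    window, e.g. 4 Mb). ``knockout=True`` sets the ncRNA biallelic."""
    rows = [
        _fixture_row(
            "cluster_ncRNA",
            chrom,
            1_000_000,
            80_000,
            BIOTYPE_NCRNA,
            0.5 if knockout else regulator_ar,
            coverage,
        )
    ]
    targets = []
    step = span_bp // (n_targets + 1)
    for i in range(n_targets):
        name = f"cluster_gene{i}"
        rows.append(
            _fixture_row(
                name, chrom, 1_000_000 + (i + 1) * step, 20_000, BIOTYPE_PCGENE,
                target_ar, coverage,
            )
        )
        targets.append(name)
    return pd.DataFrame(rows), targets, "cluster_ncRNA"


# ---------------------------------------------------------------------------
# end-to-end parameter recovery
# ---------------------------------------------------------------------------

def recover_planted_links(
    config: TruthConfig | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    workdir: str | Path | None = None,
) -> dict:
    """Run the full quant -> merge -> link pipeline on simulated reads and
    score the recovered linkage keys against the planted truth.

    Returns a dict with precision, recall, the linkages and the truth keys.
    Intermediate SAM files go to ``workdir`` (a temporary directory by
    default).
    """
    if config is None:
        config = replace(TruthConfig(), seed=seed)
    genome = simulate_genome(config)
    params = QuantParams(min_reads_per_snp=1, library_orientation="forward")

    def run(workdir: Path) -> dict:
        tables = []
        for rep in range(n_replicates):
            sam = workdir / f"rep{rep}.sam"
            simulate_reads(
                genome, config, sam, seed=seed * 1000 + rep, sample_id=f"rep{rep}"
            )
            tables.append(quantify_sample(sam, genome.annotation, genome.snps, params))
        merged = merge_replicates(tables, "all_samples", min_total_reads=20)
        link_params = LinkParams(window_bp=100_000, biotype_filter=NCRNA_TO_PCGENE)
        linkages, _ = run_link(merged, link_params)
        predicted = {l.key for l in linkages}
        from .integrate import evaluate_against_truth

        precision, recall = evaluate_against_truth(predicted, genome.truth_keys)
        return {
            "precision": precision,
            "recall": recall,
            "linkages": linkages,
            "predicted": predicted,
            "truth": genome.truth_keys,
            "merged_table": merged,
        }

    if workdir is not None:
        return run(Path(workdir))
    with tempfile.TemporaryDirectory() as tmp:
        return run(Path(tmp))
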