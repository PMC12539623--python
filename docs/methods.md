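# Methods

## Model and procedure

`aselink` treats allele-specific expression (ASE) as a per-locus binomial
problem and *cis*-regulation as co-occurrence of allelic imbalance within a
genomic window.

**Quantification.** Each aligned read that covers at least one phased
heterozygous SNP casts one vote per covered SNP (match/mismatch-aligned
bases only; inserted and soft-clipped bases have no reference coordinate
and cannot vote). The read is assigned to the haplotype with the majority
of votes; an exact tie is a *conflict* and a read matching neither allele
at every covered SNP is *unassigned* — both are excluded from the counts
but tallied in the run log, so the per-locus ledger
`a1 + a2 + conflict + unassigned + snp-less + snp-filtered = overlapping reads`
always balances. Reads are the counting unit (not read×SNP pairs): the
quantity of interest is SNP-overlapping *reads*, and double-counting a
fragment once per SNP would overstate the evidence. A per-SNP minimum
(default 1 assigned read) drops SNPs with insufficient support together
with reads supported only by them.

The allelic ratio is `AR = a1/(a1+a2)`, undefined at zero reads (written
as a blank cell, never coerced to a number). The allelic score is
`AS = sign(AR - 0.5) * (-log10 p)` with `p` the two-sided exact binomial
p-value against 0.5 under the minimum-likelihood tail definition. Because
the null is symmetric, this tail equals `min(1, 2·P(X ≤ min(a1,a2)))`,
which is evaluated through the log-CDF; when even the log-CDF underflows
(counts beyond ~10⁶ on one allele) the tail is summed directly from
log-probability masses, so `|AS|` stays finite and accurate at any
realistic depth.

**Strand and replicate merging.** Stranded libraries are quantified per
strand (`forward`, `reverse`, `unstranded`; read-2 of a pair flips) and
the per-strand tables concatenated — they must partition the annotation.
Replicates merge by median total reads and median AR; the merged score
magnitude is the *minimum* |AS| across replicates (the most conservative
replicate), signed by the side of the median AR. Replicates whose score
sign disagrees with that side are counted in the log. A locus is
informative when total reads reach the cut-off (default 20) in *all*
replicates (inbred-cross rule) or in *at least one* sample
(outbred-cohort rule).

**Linking.** Loci passing `total ≥ 20` and `AR ≥ 0.7` or `≤ 0.3`
(boundaries inclusive, both thresholds configurable) are paired whenever
the minimum gap between their BED intervals is within the window
(default ±100 kb; `inf` gives a chromosome-wide window; multi-megabase
windows suit imprinted clusters). The gap — not the TSS distance — is the
gate because it is strand-neutral and matches interval intersection
semantics; TSS distance is reported as a column. Mechanism is *enhancing*
iff `(AR1-0.5)(AR2-0.5) > 0`. Each unordered pair yields one linkage:
under a biotype filter the source is the ncRNA (or peak); otherwise the
lexicographically smaller name is the source — the score and mechanism
are symmetric, so orientation is purely presentational. Ranked output
ties break lexicographically by source then target name for determinism.

**Downstream analyses.** Enrichment percentages are ncRNA-centric
(fraction of allelic ncRNAs with ≥1 allelic / biallelic pcGene within the
window); a pcGene-centric mode is available because "co-occurrence" can be
normalized either way. Group comparisons default to the paired Wilcoxon
signed-rank test since allelic and biallelic percentages arise in pairs
per tissue. Distance categories are mutually exclusive with priority
shared-promoter (TSSs within ±2 kb) > overlapping bodies > distant.
eQTL confirmation requires an eQTL *inside the source locus interval*
whose target equals the predicted target (gene-body overlap, not a
promoter window); same-tissue beats other-tissue, and because the
same-tissue denominator is ambiguous both "of all linkages" and "of
confirmed linkages" rates are emitted. GWAS intersection uses a strict
`p < 5e-8` threshold and full gene-body containment on both sides. TAD
co-localization demands both loci *fully inside* one TAD (partial-overlap
definitions are order-dependent and were rejected); TADs must be
non-overlapping per chromosome. Linkage identity across samples is the
(source, target) gene-id pair only — mechanism is deliberately excluded
so that mechanism *consistency* (enhancing fraction ≥ 75% or ≤ 25% by
default) can be measured on recurrent keys. Saturation curves subsample
individuals without replacement (default 1000 iterations, seeded); the
full-cohort point uses the exact union with sd 0.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `min_total_reads` | reads | 20 | below ~20 reads the binomial test cannot distinguish 0.7 from 0.5 reliably |
| `ar_high` / `ar_low` | ratio | 0.7 / 0.3 | symmetric cut separating allelic from biallelic loci |
| `min_reads_per_snp` | reads | 1 | drops unsupported SNPs without discarding low-coverage loci |
| `window_bp` | bp | 100 000 | the range where allelic ncRNAs are enriched near allelic genes; `inf` and 4 Mb variants serve domain-scale regulators |
| consistency cutoff | fraction | 0.75 | a 3-of-4 majority; an even split stays unclassified |
| GWAS threshold | p-value | 5e-8 | genome-wide significance, strict inequality |

## The synthetic generator

`TruthConfig` defaults define the benchmark conditions used throughout:
200 loci of 2 kb on two 30 Mb chromosomes, 30% ncRNA, ~3 SNPs per locus,
mean coverage 50 SNP-overlapping reads, 20 planted links with allelic
ratios 0.85 / 0.15 and alternating mechanisms, and beta-binomial allele
sampling with concentration 200 — enough overdispersion that counts are
visibly noisier than binomial, while planted loci still clear the 0.7/0.3
cut-offs at coverage 50 most of the time. Planted pairs are placed within
5–50 kb of each other and isolated from members of *other* pairs by more
than the linkage window, so the planted list is exactly the set of
discoverable in-window allelic pairs and precision/recall against it is
well defined; background (biallelic) loci are placed uniformly with a
small non-overlap margin, and a false linkage requires two of them to
drift past the AR cut-offs within one window — rare at these depths.
Reads are single-end, perfect-match, fixed 50 bp, each spanning one of
its locus's SNPs and carrying the correct haplotype base at every SNP it
covers; placement margins guarantee a read never reaches another locus,
which is what makes the quantifier-vs-truth round trip exact.

What the generator does *not* emulate: sequencing error, mapping bias
toward the reference allele, splicing structure, paired-end fragments,
phasing errors, and overlapping gene models. Passing tests therefore
demonstrate the correctness of the counting, scoring, linking, and
integration logic under the stated statistical structure — not robustness
to alignment artifacts, which upstream tools (duplicate marking,
bias-aware mapping) are expected to handle.

The chromosome-wide silenced-domain and imprinted-cluster fixtures are
constructed-truth tables with deterministic rounded counts
(`a1 = round(coverage · AR)`): they exercise the linker's window,
mechanism, and escape-gene logic, while sampling noise is covered by the
beta-binomial cohort path.

## Numerical choices and degenerate inputs

- Exact binomial tail in log space (see above); `a1 = a2` returns p = 1
  and score 0 exactly.
- Locus tables are written without float rounding (shortest-exact reprs),
  so write∘read is an identity on finite values; blank cells round-trip
  as NaN.
- All coordinates are 0-based half-open; the 1-based display conversion
  is an exact round trip.
- Zero linkages is a valid result everywhere: writers emit header-only
  tables plus a "0 linkages written" log line; empty truth sets are an
  error (precision/recall undefined), while an empty prediction set has
  precision 1.0 by convention.
- Mechanism classification at AR exactly 0.5 is an error by contract; the
  allele-specific filter makes it unreachable in the pipeline.
- Degenerate Wilcoxon input (identical paired vectors) reports p = 1 with
  a degeneracy flag instead of raising.

## Problem sizes

The test suite and acceptance script run on desk-scale problems: cohorts
of ≤ 8 individuals, ≤ 200 loci, coverage ≤ 50, three replicates (~30 000
reads per SAM), 100 random locus sets for the interval-logic oracles, and
500–1000 subsampling iterations for saturation. These sizes keep every
check exhaustive or brute-force-verifiable.

## Known limitations

- Trans (inter-chromosomal) linking is out of scope by design; the method
  is a *cis* method.
- Linkages are ranked by score, not assigned p-values; correlated ASE can
  arise from shared enhancers or co-regulation, so calls are candidates,
  not causal claims.
- The per-read majority vote is one of two defensible counting units; a
  per-(read,SNP) mode could be added behind a flag if parity with other
  counters is needed.
- BAM input works through pysam where the runtime supports it, but the
  bundled generator and fixtures use SAM text for portability.
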