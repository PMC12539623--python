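"""Proximity enrichment: are allelic ncRNAs clustered near allelic genes?

Simulates locus tables for several tissues (each a cohort individual of
the generator), computes per-tissue percentages of allele-specific ncRNAs
with an allele-specific vs biallelic protein-coding neighbour within
100 kb, and compares the paired percentages with a Wilcoxon signed-rank
test. Because planted pairs place allelic ncRNAs next to allelic genes,
the allelic percentage should dominate.
"""

from aselink import (
    LinkParams,
    TruthConfig,
    compare_enrichment,
    proximity_enrichment,
    simulate_cohort,
)

config = TruthConfig(seed=5, link_active_prob=0.8)
sim = simulate_cohort(config, n_individuals=6)

results = []
for i, table in enumerate(sim.locus_tables):
    r = proximity_enrichment(table, LinkParams(), 100_000, group_label=f"tissue{i}")
    results.append(r)
    print(
        f"{r.group_label}: {r.pct_near_allelic:5.1f}% of allelic ncRNAs near an "
        f"allelic pcGene, {r.pct_near_biallelic:5.1f}% near a biallelic pcGene "
        f"(n={r.n_allelic_ncrna})"
    )

cmp = compare_enrichment(
    [r.pct_near_allelic for r in results],
    [r.pct_near_biallelic for r in results],
    paired=True,
)
print(f"\npaired Wilcoxon signed-rank p = {cmp.pvalue:.4g}")
print("A small p indicates allelic ncRNAs cluster near allelic genes, the")
print("signal that makes windowed cis-linkage informative.")
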