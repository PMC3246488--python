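"""Build significant regions from a scan and count recovered known loci.

Regions grow from seed SNPs (p < 5e-4) by absorbing neighbors with
p < 5e-3 within 25 kb of the region edge; a known locus is recovered when
a catalog SNP falls inside a top region or within 250 kb of its index SNP.
"""

import pgskit
from pgskit import assoc

cfg = pgskit.SimConfig(n_snps=4000, rng_seed=5)
samples = pgskit.simulate_pedigrees(cfg)
genotypes = pgskit.drop_genotypes(samples, cfg)
truth = pgskit.make_true_panel(genotypes, n_causal=40,
                               score_variance_share=0.25, rng_seed=5)
samples = pgskit.simulate_phenotype(genotypes, samples, truth, rng_seed=5)
model = pgskit.adjust_phenotype(samples)

scan = assoc.ols_scan(model.residuals, genotypes)
gc = assoc.gc_correct(scan, assoc.gc_lambda(scan["chi2"]))
regions = pgskit.top_regions(pgskit.build_regions(gc.assoc), k=100)

# the catalog of "previously reported" loci is the causal truth here
catalog = genotypes.snps.iloc[truth.snp_indices][["snp_id", "chrom", "pos"]]
report = pgskit.recover_known_loci(regions, catalog, window=250_000)

print(f"{len(regions)} significant regions; "
      f"{report.n_recovered}/{len(catalog)} known loci recovered "
      f"({report.n_in_region} inside regions, "
      f"{report.n_near_index} within 250 kb of an index SNP)")
for _, row in report.table.head(5).iterrows():
    print(f"  chr{row.chrom}:{row.start}-{row.end}  "
          f"index {row.index_snp_id} (p={row.index_p:.2e})  "
          f"hits: {row.catalog_near_index or '-'}")
# With 40 causal SNPs explaining 25% of variance at n=1304, only the
# larger effects clear the seed threshold, so recovery is partial —
# the expected behavior for an underpowered single cohort.
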