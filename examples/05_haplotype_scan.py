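"""Haplotype inference and the exhaustive AIC model scan.

All 1-4 SNP subsets of the typed region SNPs are fitted as haplotype-effect
logistic models; models within 2 rescaled-AIC units are equivalent and the
most parsimonious equivalent model wins.  On ghost cohorts the winner
isolates the rare risk haplotype that actually carries the causal allele.
"""

from hapghost.haplotypes import aic_scan, em_haplotypes, haplotype_conditional
from hapghost.synthetic_data import default_ghost_spec, simulate_cohort

spec = default_ghost_spec()
bundle = simulate_cohort(spec, 1500, 1200, or_causal=3.0, seed=1)
gm = bundle.observed.genotypes
pheno = bundle.observed.phenotype

scan = aic_scan(gm, pheno, region=spec.region, max_size=3,
                covariates=["PC1", "PC2", "PC3", "PC4"])
print(f"scanned {scan.n_models} haplotype models; "
      f"{len(scan.equivalence)} within 2 AIC units of the best")
print(f"winner: {','.join(scan.best_snps)}")

model = scan.best_model
print(f"global haplotypic association: chi2 = {model.global_chi2:.1f} "
      f"({model.global_df} df), p = {model.global_p:.2g}")
for e in model.effects:
    lo, hi = e.ci()
    print(f"  haplotype {e.haplotype}: controls {e.control_freq:.3f} / "
          f"cases {e.case_freq:.3f}, OR {e.odds_ratio:.2f} [{lo:.2f}-{hi:.2f}]")

# adjusting on a block-SNP dose collapses the risk-haplotype OR
sub = gm.subset(scan.best_snps)
phase = em_haplotypes(sub)
adj = haplotype_conditional(phase, pheno,
                            bundle.observed.dosages.column(spec.ids("block")[0]),
                            covariates=["PC1", "PC2", "PC3", "PC4"], snps=sub.snps)
risk = max(model.effects, key=lambda e: e.log_or)
risk_adj = next(e for e in adj.effects if e.haplotype == risk.haplotype)
print(f"\nrisk haplotype {risk.haplotype}: OR {risk.odds_ratio:.2f} crude -> "
      f"{risk_adj.odds_ratio:.2f} adjusted on a block-SNP dose")
print("the haplotype only tagged the block; the block only tagged the culprit")
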