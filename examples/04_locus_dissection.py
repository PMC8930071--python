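"""Dissecting a flagged locus: genotypic ORs, model ladder, haplotypes, AIC.

On the merged tagging cohort: (1) genotypic odds ratios of the rare variant
without any genetic-model assumption; (2) the forward-selection ladder of
nested logistic models with LRTs; (3) per-haplotype odds ratios from the
EM + GLM; (4) the AIC comparison of SNP / interaction / haplotype
parameterisations; (5) a skewed Lp(a)-like trait analysed on the
inverse-normal scale with and without adjustment for a KIV-repeat-like
covariate.
"""

import numpy as np
import pandas as pd

import episcan as ep
from episcan.prioritize import merge_studies

config = ep.scenario_tagging(seed=3, n_studies=6, n_cases=1500, n_controls=1500)
studies = ep.simulate_cohorts(config)
merged = merge_studies(studies, mds_k=10, exact_cutoff=2000)
cohort = merged.cohort
cov = merged.study_covariates.join(cohort.mds)
snps = ["rare", "tagA", "tagB"]

print("1) genotypic ORs of the rare variant (reference: hom-major):")
for e in ep.genotypic_or("rare", cohort, cov):
    if e.estimable:
        print(f"   {e.genotype_class:10s} OR={np.exp(e.log_or):.2f} "
              f"p={e.p:.3g}  ({e.n_cases} cases / {e.n_controls} controls)")
    else:
        print(f"   {e.genotype_class:10s} unestimable "
              f"({e.n_cases} cases / {e.n_controls} controls)")

print("\n2) forward model selection (nested LRTs):")
table = ep.forward_model_selection(snps, cohort, cov)
with pd.option_context("display.width", 120):
    print(table.to_dataframe().round(4).to_string(index=False))

print("\n3) 3-SNP haplotype ORs (reference: most frequent haplotype):")
em = ep.haplotype_em(cohort, snps)
for h in ep.haplotype_glm(em, cohort, cov):
    label = "".join(map(str, h.alleles))
    if h.is_reference:
        print(f"   {label}  freq={h.frequency:.4f}  OR=1.00 (reference)")
    elif h.estimable:
        print(f"   {label}  freq={h.frequency:.4f}  OR={np.exp(h.log_or):.2f} "
              f"p={h.p:.3g}")
    else:
        print(f"   {label}  freq={h.frequency:.4f}  unestimable")

print("\n4) AIC comparison of model families:")
comp = ep.aic_model_comparison(cohort, snps, em, cov)
print(comp.to_dataframe().round(4).to_string(index=False))
print(f"   best model: {comp.best()}")

print("\n5) Lp(a)-like trait association (inverse-normal transformed):")
pheno = ep.simulate_traits(studies[0], ep.TraitModel(), seed=3)
idx = studies[0].genotypes.samples
pred = pd.DataFrame({"rare": studies[0].genotypes.column("rare")}, index=idx)
kiv = pd.DataFrame({"kiv": pheno.trait("kiv")}, index=idx)
raw = ep.trait_association(pred, pheno.trait("lpa"))
adj = ep.trait_association(pred, pheno.trait("lpa"), covariates=kiv)
print(f"   unadjusted:   beta={raw.loc['rare', 'beta']:.2f} "
      f"p={raw.loc['rare', 'p']:.3g}")
print(f"   KIV-adjusted: beta={adj.loc['rare', 'beta']:.2f} "
      f"p={adj.loc['rare', 'p']:.3g}")
print("   (the rare variant raises the trait partly via fewer KIV repeats; "
      "a direct effect remains after adjustment)")
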