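# Methods

This note records the statistical model behind `episcan`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions a maintainer needs to know.

## Disease model and the two scan stages

The scan targets pairwise statistical epistasis on a binary phenotype: a
non-zero coefficient on the product of two encoded genotypes beyond their
additive effects. Stage 1 fits the linear probability model
`y ~ 1 + e1 + e2 + e1*e2` by OLS per study and tests the interaction
coefficient with a two-sided *t* statistic on *n* − 4 degrees of freedom.
A linear fit on a 0/1 outcome is mis-specified as a probability model but is
an adequate and very fast screen for a *non-zero* interaction; the exact
test form at this stage is a package convention. Each SNP enters in one of
four encodings — dosage (identity), dominant, recessive, heterozygous, all
with respect to the minor allele — giving 16 combinations per pair.
Indicator encodings are computed on hard calls: imputed dosages are rounded
to the nearest integer, ties at .5 rounding up. Degenerate designs (a
constant encoded column, or a product column collinear with a main effect,
e.g. dominant×dominant of the same SNP) are detected through the rank of the
scaled 4×4 normal-equations matrix and skipped with a reason code rather
than fitted.

Per-study interaction estimates are pooled by inverse-variance fixed-effects
meta-analysis (weights 1/se²; two-sided normal p). Pooling effect sizes
rather than p-values subsumes the p-value version and preserves direction
information for the replication criterion.

Stage 2 refits each surviving pair — in the encoding combination with the
smallest Stage-1 meta p; ties prefer (dosage, dosage), then lexicographic
order — by per-study logistic regression with the first *k* MDS components
as covariates, Wald-tests the interaction, meta-analyses as above, and
applies a Bonferroni bar α/(*n*(*n* − 1)/2) on the number *n* of
LD-independent SNPs. The 16-fold encoding multiplicity within a pair is
handled by best-combination selection, not by further correction; the bar
is defined on pair counts only. Studies that fail to converge or show
(quasi-)separation — detected by non-finite estimates or absurd standard
errors — are dropped from that pair's meta-analysis with a reason.

## LD, pruning, MDS

Pairwise LD from unphased genotypes uses the standard two-locus EM under
Hardy–Weinberg equilibrium: the double heterozygote is the only
phase-ambiguous class, and its coupling/repulsion split is iterated to the
MLE; r² and D′ come from the estimated haplotype frequencies. Monomorphic
input yields a flagged undefined result, never a crash. LD pruning is a
greedy positional sweep — keep a variant unless its r² with an already-kept
variant on the same chromosome reaches the threshold (default 0.5) — chosen
for determinism; the retained set provably satisfies the pairwise bound.

Ancestry covariates are classical (Torgerson) MDS coordinates of the
distance 1 − IBS, where IBS(i, j) = 1 − mean|dᵢ − dⱼ|/2 over mean-imputed
dosages. Axes are ordered by eigenvalue, centred, and sign-fixed so the
largest-magnitude loading of each axis is positive. For cohorts above a
configurable cutoff (pipeline default 2000 samples) the embedding switches
to landmark (Nyström) MDS: exact classical MDS on a deterministic,
evenly-spaced landmark subset (default 1000), with the remaining samples
triangulated from their distances to the landmarks. A dense double-centred
Gram matrix at merged-cohort sizes (tens of thousands of samples) is
otherwise the dominant memory and time cost, and with no simulated
population structure the approximation is inconsequential; the exact path
is used automatically for small cohorts and is what the unit tests check
the landmark path against.

## Conditional analysis and the dependency verdict

The conditional LRT compares logistic models with and without the
interaction term, both containing the two target SNPs, the conditioning SNP
as minor-allele dosage, MDS covariates recomputed on the merged multi-study
dataset, and study indicator covariates (df = 1, χ² reference). Conditioning
SNPs nearly collinear with a target (r² > 0.99) are skipped. Every SNP
within ±200 kb of either pair member is tested, plus any supplied external
list.

Two rules decide "the interaction is dependent on SNP₃": the generic
Bonferroni rule α/#conditioning-SNPs (library default), and a fixed absolute
bar, default 7.8×10⁻⁶ in the pipeline. The absolute bar exists because at
small conditioning-set sizes the Bonferroni bar lands inside the
selection-noise floor: the flagged pair was chosen as the most significant
of many pairs × 16 encodings, so even after conditioning removes all real
signal, the retained noise component of the interaction estimate can reach
|z| ≈ 3. A genuine interaction keeps conditional p around 10⁻¹³ while a
fully explained tagging signal rises to 10⁻³–10⁻¹, so any bar between
10⁻¹⁰ and 10⁻⁴ separates them; the default sits in that range.

## Prioritization criteria

1. **Replication** — meta p below the scan bar *and* per-study effect signs
   agreeing with the meta estimate in ≥ `min_consistent` studies (default
   8, or 80% of studies in the pipeline). A strict variant requiring
   per-study significance is available behind `strict=True`; at realistic
   single-study power it is essentially unattainable and is not the
   default.
2. **Pair LD** — r² < 0.2 for same-chromosome pairs; different chromosomes
   pass outright.
3. **Proxy support** — variants with r² > 0.5 to either member are
   substituted in and re-tested by the Stage-2 machinery; the criterion
   passes when at least one proxy pair shows a same-direction interaction
   with p < 0.05 ("weak signal" operationalised as nominal significance;
   configurable). No proxies ⇒ vacuous pass, flagged.
4. **Conditional independence** — no dependency verdict in the window scan.

Classification: significant pair + dependency ⇒ `tagging-consistent`
(naming the variant); all four criteria pass ⇒ `epistasis-consistent`; no
significant pair ⇒ `no-signal`; otherwise `inconclusive`.

## Locus dissection

Genotypic ORs use two indicator columns (het, hom-minor) against the
hom-major reference; classes empty of cases or controls are reported
unestimable. The forward ladder is: covariates-only → +SNP₁ → +SNP₂+SNP₃ →
+SNP₂×SNP₃ → all two- and three-way interactions (→ +SNP₄ → full four-way
crossing), each row LRT-tested against the previous row and against the
SNP₁-only baseline; deviance is non-increasing by nesting. Type-III term
tests drop one term from the full model while retaining all others
(deviance-based LRT, equivalent to type-III sums of squares for GLMs);
dropping a main effect under its interaction is permitted and logged.

The inverse normal transform is rank-based with the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties.

Haplotype frequencies over m ≤ 4 SNPs come from an EM over all diplotypes
compatible with each multilocus genotype under an HWE diplotype prior,
initialised at the product of single-SNP allele frequencies (deterministic),
converged when the largest frequency change is below 10⁻⁸; the
log-likelihood is asserted non-decreasing at every iteration. The haplotype
GLM regresses status on *expected* haplotype dosages (posterior-weighted
counts) with the most frequent haplotype as the omitted reference —
expected-dosage substitution rather than a full EM-weighted likelihood,
matching standard practice; haplotypes below a frequency floor (10⁻⁴) are
dropped and reported unestimable.

The AIC comparison fits five models — covariates only, +haplotype dosages,
+SNP dosages, +SNP full crossing, and the combination — with
AIC = deviance + 2·(number of regression coefficients, intercept included).
EM haplotype frequencies are estimated in a separate step and are **not**
penalised; this convention is a declared choice. The combined design is
rank-deficient by construction (SNP dosages are linear in the haplotype
dosages), so dependent columns are dropped via pivoted QR and the parameter
count adjusted. Note that expected haplotype dosages can partially mimic a
genotype-product term (double heterozygotes all receive the same expected
cis-dosage), which is why the interaction-vs-haplotype comparison is
genuinely close and needs sample sizes in the 10⁴ range to resolve.

## Synthetic cohorts: what they emulate, and what they don't

Genotypes are drawn as two haplotypes per individual from an explicit pool;
LD is specified directly through pool frequencies, with no recombination or
coalescent realism, no inbreeding, autosomes only. Disease status is
Bernoulli(logistic(η)) with η assembled from additive dosage effects,
encoded-product interaction effects and per-copy haplotype effects;
case–control ascertainment is by batched rejection sampling to exact counts
(which preserves logistic slopes, shifting only the intercept). One master
seed; study *i* uses stream seed + *i*.

The canonical tagging pool places a rare allele (MAF 0.0155) exclusively on
haplotypes carrying the minor alleles of both tag SNPs (MAFs 0.159 and
0.225). The background-haplotype frequency (default 0.02) controls how
concentrated carriage is; it was set so that a rare-variant effect of
OR 1.98 induces an apparent pair interaction of OR_int ≈ 1.4 with z ≈ 7 at
the canonical cohort size of 10 studies × (1500 cases + 1500 controls) ≈
30 000 — the regime in which such signals are realistically discovered. The
single-SNP rare–tag r² values (≈0.08 and ≈0.05) depend only on the marginal
MAFs and stay in the realistic low range regardless. Each cohort also
carries 32 unlinked background SNPs (MAF 0.05–0.5) on a separate chromosome:
they carry no signal and exist so the relationship matrix behind MDS is not
built from the scan region itself — with covariates computed from a handful
of region SNPs, the MDS axes become near-linear in the scan genotypes and
absorb the signal, a small-panel artefact rather than a property of the
method. The `haplotype` scenario uses a commoner background (0.10) so its
phase-carrying risk haplotype (frequency ≈ 0.085) is estimable.

Quantitative traits: a latent normal trait with a direct genotype effect
(default 1.1 per rare allele) plus a contribution from a KIV-repeat-like
covariate (mean 27, SD 5, slope −5.74 repeats per rare allele, loading
−0.085 per repeat — so the covariate explains ≈18% of latent variance and
the total genotype effect is ≈1.6), exponentiated to give the right-skewed
observed scale. Passing tests on these cohorts demonstrate the machinery's
correctness and calibration under the stated generative model; they do not
speak to imputation error, genotyping artefacts, real LD complexity,
population stratification or phenotype misclassification in real cohorts.

## Problem sizes and thresholds used by the test suite

Scan and conditional discrimination run at 10 studies × (1500+1500) with a
Stage-1 filter of 10⁻⁵ — chosen a priori so the null scenario's family-wise
false-flag rate is ≈0.5% (28 scan pairs × 16 correlated encodings) while a
z ≈ 6.5 signal is detected with ≈98% power. CI-coverage uses 200 replicates
of 10 studies × (400+400) (coverage is sample-size invariant); type-I
calibration uses 1000 null pairs at n = 2000; the AIC comparison uses 8
studies × (1500+1500) with a planted pure-interaction OR of 1.6 (no
empirical anchor exists for a genuine pure interaction; the tagging-induced
1.42 stays the scan default) and a risk-haplotype OR of 2.0. Library
defaults keep the published thresholds (Stage-1 10⁻⁸, the Bonferroni rule,
r² < 0.2, r² > 0.5, ±500 kb, ±200 kb, k = 10 MDS components).

## Known limitations

- The Stage-1 screen's linear-probability p-values are approximations;
  borderline pairs should be judged on the Stage-2 logistic results.
- Haplotype machinery is limited to m ≤ 4 SNPs (diplotype enumeration grows
  as 4^m); no phasing against reference panels.
- The haplotype GLM's expected-dosage substitution slightly understates
  uncertainty when phase is very ambiguous.
- Landmark MDS is an approximation; exact MDS is used below the cutoff and
  the approximation is only relied on where structure is absent or weak.
- The generator's LD is block-wise by construction; conclusions about LD
  decay with distance cannot be drawn from it.
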