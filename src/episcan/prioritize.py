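"""Candidate-pair prioritization and conditional likelihood-ratio analysis.

Four criteria separate promising epistasis candidates from artefacts:

1. replication — the meta-analysed interaction is significant and the
   per-study effects point the same way in at least ``min_consistent``
   studies;
2. pair LD — the two SNPs are in low LD (r² < 0.2) or on different
   chromosomes, ruling out trivially correlated pairs;
3. proxy support — SNPs in strong LD (r² > 0.5) with either member show a
   same-direction (weaker) interaction signal, as a true signal's LD
   neighbourhood should;
4. conditional independence — the interaction term survives conditioning on
   every third variant nearby: an LRT between the model with the two target
   SNPs plus the conditioning SNP (all additive) and the same model plus the
   interaction term.  An interaction whose LRT collapses when a third SNP
   enters the model is flagged *dependent* — the signature of a SNP pair
   tagging a rarer causal variant on a shared haplotype rather than genuine
   epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeTable, StudyCohort, encode_genotype
from .ld import compute_ld
from .mds import compute_mds
from .regress import fit_logistic, likelihood_ratio_test
from .scan import PairTest, StudyFit, _impute_mean, _meta_fill, logistic_interaction_fit


# ---------------------------------------------------------------------------
# Merged multi-study dataset
# ---------------------------------------------------------------------------

@dataclass
class MergedCohort:
    """All studies concatenated, with study indicators and merged-data MDS."""

    cohort: StudyCohort
    study_covariates: pd.DataFrame  # indicator columns, first study as reference


def merge_studies(
    studies: list[StudyCohort],
    mds_k: int = 10,
    exact_cutoff: int = 4000,
) -> MergedCohort:
    """Concatenate studies and recompute MDS coordinates on the merged data."""
    samples: list[str] = []
    dosages = []
    status = []
    study_col = []
    for s in studies:
        samples.extend(s.genotypes.samples)
        dosages.append(s.genotypes.dosages)
        status.append(s.phenotypes.status)
        study_col.extend([s.name] * s.n_samples)
    gm = GenotypeMatrix(samples, studies[0].genotypes.variants, np.vstack(dosages))
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"status": np.concatenate(status).astype(int)}, index=pd.Index(samples)
        )
    )
    mds = compute_mds(gm, k=mds_k, exact_cutoff=exact_cutoff)
    cohort = StudyCohort("merged", gm, pheno, mds=mds)
    dummies = pd.get_dummies(
        pd.Series(study_col, index=pd.Index(samples)), prefix="study", dtype=float
    ).iloc[:, 1:]
    return MergedCohort(cohort, dummies)


# ---------------------------------------------------------------------------
# Criteria 1–3
# ---------------------------------------------------------------------------

@dataclass
class CriterionVerdict:
    passed: bool
    detail: str = ""
    value: float = np.nan
    flag: str = ""


def check_replication(
    pair: PairTest,
    threshold: float = 4.6178e-9,
    min_consistent: int = 8,
    strict: bool = False,
) -> CriterionVerdict:
    """Criterion 1: significance plus direction consistency across studies.

    Default reading: meta p below ``threshold`` and per-study betas agreeing
    in sign with the meta estimate in at least ``min_consistent`` studies.
    ``strict=True`` instead demands per-study p < threshold (same sign) in
    at least ``min_consistent`` studies individually.
    """
    fits = pair.valid_fits()
    if len(fits) < min_consistent:
        return CriterionVerdict(
            False, f"only {len(fits)} usable studies (< {min_consistent})"
        )
    if strict:
        n_ok = sum(
            f.p < threshold and np.sign(f.beta) == np.sign(pair.meta_beta)
            for f in fits
        )
        return CriterionVerdict(
            n_ok >= min_consistent,
            f"{n_ok} studies individually significant and consistent",
            value=float(n_ok),
        )
    consistent = pair.direction_consistency
    sig = np.isfinite(pair.meta_p) and pair.meta_p < threshold
    return CriterionVerdict(
        bool(sig and consistent >= min_consistent),
        f"meta p={pair.meta_p:.3g}, {consistent}/{len(fits)} same-direction",
        value=float(consistent),
    )


def check_pair_ld(
    pair: PairTest, matrix: GenotypeMatrix, r2_max: float = 0.2
) -> CriterionVerdict:
    """Criterion 2: same-chromosome pairs must have r² below ``r2_max``."""
    v1, v2 = matrix.variant(pair.snp1), matrix.variant(pair.snp2)
    if v1.chromosome != v2.chromosome:
        return CriterionVerdict(True, "different chromosomes", flag="trans")
    ld = compute_ld(matrix.column(pair.snp1), matrix.column(pair.snp2))
    if not ld.defined:
        return CriterionVerdict(False, "LD undefined (monomorphic SNP)")
    return CriterionVerdict(
        ld.r_squared < r2_max, f"r2={ld.r_squared:.3g}", value=ld.r_squared
    )


def find_proxies(
    matrix: GenotypeMatrix,
    target: str,
    candidates: list[str],
    r2_min: float = 0.5,
) -> list[str]:
    """Variant ids with r² above ``r2_min`` to ``target`` (target excluded)."""
    out = []
    tcol = matrix.column(target)
    for vid in candidates:
        if vid == target:
            continue
        ld = compute_ld(tcol, matrix.column(vid))
        if ld.defined and ld.r_squared > r2_min:
            out.append(vid)
    return out


def check_proxy_support(
    pair: PairTest,
    studies: list[StudyCohort],
    proxy_r2: float = 0.5,
    proxy_p: float = 0.05,
    mds_k: int = 10,
) -> CriterionVerdict:
    """Criterion 3: a same-direction interaction among proxy-substituted pairs.

    Proxies (r² > ``proxy_r2`` with either target, measured in the first
    study) replace the member they proxy; each substituted pair is re-tested
    by the Stage-2 logistic meta-analysis.  When no proxy exists the
    criterion passes vacuously with a flag.
    """
    matrix = studies[0].genotypes
    candidates = [v.id for v in matrix.variants if v.id not in pair.pair]
    sub_pairs = [
        (proxy, pair.snp2)
        for proxy in find_proxies(matrix, pair.snp1, candidates, proxy_r2)
    ] + [
        (pair.snp1, proxy)
        for proxy in find_proxies(matrix, pair.snp2, candidates, proxy_r2)
    ]
    if not sub_pairs:
        return CriterionVerdict(True, "no proxies exist", flag="no proxies")
    details = []
    passed = False
    for s1, s2 in sub_pairs:
        fits = []
        for cohort in studies:
            fit = logistic_interaction_fit(
                cohort, s1, s2, pair.encoding1, pair.encoding2, mds_k
            )
            if fit.converged:
                beta, se, p = fit.wald("e1xe2")
                fits.append(StudyFit(cohort.name, beta, se, p, cohort.n_samples))
        if not fits:
            continue
        pt = _meta_fill(PairTest(s1, s2, pair.encoding1, pair.encoding2, fits))
        same_dir = np.sign(pt.meta_beta) == np.sign(pair.meta_beta)
        details.append(f"{s1}x{s2}: p={pt.meta_p:.3g}")
        if same_dir and pt.meta_p < proxy_p:
            passed = True
    return CriterionVerdict(passed, "; ".join(details))


# ---------------------------------------------------------------------------
# Criterion 4: conditional LRT
# ---------------------------------------------------------------------------

@dataclass
class ConditionalResult:
    """LRT for the interaction term after conditioning on a third SNP."""

    conditioning_snp: str
    lrt_statistic: float
    df: int
    p: float
    dependent: bool = False
    skipped: bool = False
    reason: str = ""


def conditional_lrt(
    pair: PairTest,
    conditioning_snp: str,
    merged: MergedCohort,
    mds_k: int = 10,
) -> ConditionalResult:
    """LRT of the pair's interaction term conditional on a third SNP.

    Reduced model: status ~ e1 + e2 + snp3 + MDS + study; full model adds
    e1·e2.  The conditioning SNP enters as minor-allele dosage.  A
    conditioning SNP essentially collinear with either target (r² > 0.99)
    is skipped.
    """
    cohort = merged.cohort
    gm = cohort.genotypes
    for target in pair.pair:
        ld = compute_ld(gm.column(target), gm.column(conditioning_snp))
        if ld.defined and ld.r_squared > 0.99:
            return ConditionalResult(
                conditioning_snp, np.nan, 0, np.nan, skipped=True,
                reason=f"collinear with {target} (r2={ld.r_squared:.3g})",
            )
    e1 = _impute_mean(encode_genotype(gm.column(pair.snp1), pair.encoding1))
    e2 = _impute_mean(encode_genotype(gm.column(pair.snp2), pair.encoding2))
    d3 = _impute_mean(gm.column(conditioning_snp).copy())
    base = pd.DataFrame({"e1": e1, "e2": e2, "snp3": d3}, index=gm.samples)
    if cohort.mds is not None and mds_k > 0:
        base = base.join(cohort.mds.iloc[:, :mds_k])
    base = base.join(merged.study_covariates)
    full = base.copy()
    full.insert(2, "e1xe2", e1 * e2)
    y = cohort.phenotypes.status
    fit_red = fit_logistic(y, base)
    fit_full = fit_logistic(y, full)
    if not (fit_red.converged and fit_full.converged):
        return ConditionalResult(
            conditioning_snp, np.nan, 0, np.nan, skipped=True,
            reason=fit_red.reason or fit_full.reason,
        )
    stat, df, p = likelihood_ratio_test(fit_full, fit_red)
    return ConditionalResult(conditioning_snp, stat, df, p)


def conditioning_window_scan(
    pair: PairTest,
    merged: MergedCohort,
    window: int = 200_000,
    extra_snps: list[str] | None = None,
    alpha: float = 0.05,
    bar: float | None = None,
    mds_k: int = 10,
) -> list[ConditionalResult]:
    """Conditional LRT against every SNP near the pair plus supplied extras.

    Eligible conditioning SNPs are those within ±``window`` bp of either
    pair member (same chromosome) and any id in ``extra_snps``.  The
    *dependent* verdict compares each LRT p-value with a significance bar:
    by default the Bonferroni rule alpha / n_tested; a fixed absolute
    ``bar`` may be supplied instead (useful when only a handful of
    conditioning SNPs exist, where the Bonferroni bar sits inside the
    selection-noise floor left by best-encoding selection).  A conditioning
    SNP whose LRT fails the bar explains away the interaction.
    """
    gm = merged.cohort.genotypes
    targets = [gm.variant(pair.snp1), gm.variant(pair.snp2)]
    eligible: list[str] = []
    for v in gm.variants:
        if v.id in pair.pair:
            continue
        near = any(
            v.chromosome == t.chromosome and abs(v.position - t.position) <= window
            for t in targets
        )
        if near:
            eligible.append(v.id)
    for vid in extra_snps or []:
        if vid in gm and vid not in eligible and vid not in pair.pair:
            eligible.append(vid)
    results = [conditional_lrt(pair, vid, merged, mds_k) for vid in eligible]
    tested = [r for r in results if not r.skipped]
    if tested:
        level = bar if bar is not None else alpha / len(tested)
        for r in tested:
            r.dependent = bool(r.p >= level)
    return results


@dataclass
class CriteriaReport:
    """Verdicts of the four prioritization criteria for one pair."""

    pair: tuple[str, str]
    replication: CriterionVerdict
    pair_ld: CriterionVerdict
    proxy_support: CriterionVerdict
    conditional: list[ConditionalResult] = field(default_factory=list)

    @property
    def conditional_pass(self) -> bool:
        tested = [r for r in self.conditional if not r.skipped]
        return all(not r.dependent for r in tested)

    @property
    def worst_conditional(self) -> ConditionalResult | None:
        tested = [r for r in self.conditional if not r.skipped]
        return max(tested, key=lambda r: r.p) if tested else None

    @property
    def dependencies(self) -> list[ConditionalResult]:
        return [r for r in self.conditional if not r.skipped and r.dependent]

    @property
    def overall_pass(self) -> bool:
        return (
            self.replication.passed
            and self.pair_ld.passed
            and self.proxy_support.passed
            and self.conditional_pass
        )


def evaluate_criteria(
    pair: PairTest,
    studies: list[StudyCohort],
    merged: MergedCohort,
    replication_threshold: float = 4.6178e-9,
    min_consistent: int = 8,
    window: int = 200_000,
    extra_snps: list[str] | None = None,
    conditional_bar: float | None = None,
    mds_k: int = 10,
) -> CriteriaReport:
    """Run all four criteria for one stage-2 pair."""
    return CriteriaReport(
        pair=pair.pair,
        replication=check_replication(pair, replication_threshold, min_consistent),
        pair_ld=check_pair_ld(pair, merged.cohort.genotypes),
        proxy_support=check_proxy_support(pair, studies, mds_k=mds_k),
        conditional=conditioning_window_scan(
            pair, merged, window=window, extra_snps=extra_snps,
            bar=conditional_bar, mds_k=mds_k,
        ),
    )
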