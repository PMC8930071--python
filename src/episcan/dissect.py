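"""Post-hoc dissection of a flagged locus.

Once the scan and the conditional analysis have pointed at a small set of
SNPs, this module asks what the locus actually looks like: genotypic odds
ratios free of any genetic-model assumption, a forward ladder of nested
logistic models with likelihood-ratio tests, type-III term tests,
quantitative-trait association on inverse-normal-transformed values,
multi-SNP haplotype frequencies by EM, per-haplotype odds ratios from a GLM
on expected haplotype dosages, and an AIC comparison of SNP-only,
interaction and haplotype parameterisations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genotypes import StudyCohort, hard_calls
from .regress import GLMFit, fit_logistic, fit_ols, likelihood_ratio_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genotypic odds ratios
# ---------------------------------------------------------------------------

@dataclass
class GenotypicEffect:
    """Log-OR of one genotype class relative to the major-allele homozygote."""

    genotype_class: str  # "hom_major" (reference), "het", "hom_minor"
    log_or: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    estimable: bool = True


def genotypic_or(
    snp: str,
    cohort: StudyCohort,
    covariates: pd.DataFrame | None = None,
) -> list[GenotypicEffect]:
    """Genotypic (2-df) logistic model: indicator columns for het and
    hom-minor against the hom-major reference, plus covariates.

    A genotype class with no cases or no controls is reported as
    unestimable rather than given a meaningless estimate.
    """
    g = hard_calls(cohort.genotypes.column(snp))
    y = cohort.phenotypes.status
    keep = np.isfinite(g)
    g, y = g[keep], y[keep]
    idx = np.array(cohort.genotypes.samples)[keep]
    counts = {
        k: (int(((g == v) & (y == 1)).sum()), int(((g == v) & (y == 0)).sum()))
        for k, v in (("hom_major", 0), ("het", 1), ("hom_minor", 2))
    }
    cols, usable = {}, {}
    for name, v in (("het", 1), ("hom_minor", 2)):
        ca, co = counts[name]
        usable[name] = ca > 0 and co > 0
        if usable[name]:
            cols[name] = (g == v).astype(float)
    x = pd.DataFrame(cols, index=idx)
    if covariates is not None:
        x = x.join(covariates.loc[idx])
    fit = fit_logistic(y, x)
    out = [
        GenotypicEffect("hom_major", 0.0, 0.0, 1.0, *counts["hom_major"])
    ]
    for name in ("het", "hom_minor"):
        ca, co = counts[name]
        if usable[name] and fit.converged:
            b, se, p = fit.wald(name)
            out.append(GenotypicEffect(name, b, se, p, ca, co))
        else:
            out.append(
                GenotypicEffect(name, np.nan, np.nan, np.nan, ca, co, estimable=False)
            )
    return out


# ---------------------------------------------------------------------------
# Model ladders: forward selection, type-III terms
# ---------------------------------------------------------------------------

Term = tuple[str, ...]


def crossing(*snps: str) -> list[Term]:
    """All main effects and interactions of the given SNPs (a*b*... expansion)."""
    out: list[Term] = []
    for r in range(1, len(snps) + 1):
        out.extend(itertools.combinations(snps, r))
    return out


def term_name(term: Term) -> str:
    return ":".join(term)


def build_design(
    cohort: StudyCohort,
    terms: list[Term],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Design matrix with one product column per term plus covariates."""
    names = [term_name(t) for t in terms]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate predictor terms: {names}")
    cols = {}
    for term, name in zip(terms, names):
        col = np.ones(cohort.n_samples)
        for snp in term:
            d = cohort.genotypes.column(snp)
            if np.isnan(d).any():
                d = np.where(np.isnan(d), np.nanmean(d), d)
            col = col * d
        cols[name] = col
    x = pd.DataFrame(cols, index=cohort.genotypes.samples)
    if covariates is not None:
        x = x.join(covariates)
    return x


@dataclass
class ModelRow:
    """One row of a nested-model ANOVA ladder."""

    description: str
    resid_df: float
    resid_deviance: float
    delta_df: float = np.nan
    delta_deviance: float = np.nan
    p_vs_previous: float = np.nan
    p_vs_baseline: float = np.nan
    converged: bool = True
    reason: str = ""


@dataclass
class ModelComparisonTable:
    rows: list[ModelRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r.description for r in self.rows],
                "resid_df": [r.resid_df for r in self.rows],
                "resid_deviance": [r.resid_deviance for r in self.rows],
                "delta_df": [r.delta_df for r in self.rows],
                "delta_deviance": [r.delta_deviance for r in self.rows],
                "p_vs_previous": [r.p_vs_previous for r in self.rows],
                "p_vs_baseline": [r.p_vs_baseline for r in self.rows],
            }
        )


def default_ladder(snps: list[str]) -> list[tuple[str, list[Term]]]:
    """The forward-selection ladder used for the locus dissection.

    With SNPs (s1, s2, s3[, s4]): covariates-only → +s1 → +s2 +s3 →
    +s2×s3 → all two- and three-way interactions of (s1, s2, s3)
    [→ +s4 → full crossing of all four].
    """
    if len(snps) not in (3, 4):
        raise ValueError("the dissection ladder expects 3 or 4 SNPs")
    s1, s2, s3 = snps[:3]
    ladder: list[tuple[str, list[Term]]] = [
        ("covariates only", []),
        (f"+ {s1}", [(s1,)]),
        (f"+ {s2} + {s3}", [(s1,), (s2,), (s3,)]),
        (f"+ {s2}x{s3}", [(s1,), (s2,), (s3,), (s2, s3)]),
        (f"{s1}*{s2}*{s3}", crossing(s1, s2, s3)),
    ]
    if len(snps) == 4:
        s4 = snps[3]
        ladder.append((f"+ {s4}", crossing(s1, s2, s3) + [(s4,)]))
        ladder.append((f"{s1}*{s2}*{s3}*{s4}", crossing(s1, s2, s3, s4)))
    return ladder


def forward_model_selection(
    snps: list[str],
    cohort: StudyCohort,
    covariates: pd.DataFrame | None = None,
    baseline_row: int = 1,
) -> ModelComparisonTable:
    """Fit the nested forward-selection ladder and report LRTs.

    Every row is compared with the previous row and with a fixed baseline
    row (default: the first-SNP-only model), mirroring a sequential ANOVA
    table for nested logistic models.
    """
    ladder = default_ladder(snps)
    # nesting sanity: each row's terms must contain the previous row's
    for (_, prev), (_, cur) in zip(ladder, ladder[1:]):
        if not set(prev) <= set(cur):
            raise ValueError("model ladder is not nested")
    y = cohort.phenotypes.status
    fits: list[GLMFit] = []
    table = ModelComparisonTable()
    for desc, terms in ladder:
        fit = fit_logistic(y, build_design(cohort, terms, covariates))
        fits.append(fit)
        row = ModelRow(desc, fit.df_resid, fit.deviance, converged=fit.converged,
                       reason=fit.reason)
        if len(fits) > 1 and fit.converged and fits[-2].converged:
            stat, df, p = likelihood_ratio_test(fit, fits[-2])
            row.delta_df = df
            row.delta_deviance = fits[-2].deviance - fit.deviance
            row.p_vs_previous = p
        if len(fits) - 1 > baseline_row and fit.converged:
            base = fits[baseline_row]
            if base.converged:
                _, _, row.p_vs_baseline = likelihood_ratio_test(fit, base)
        table.rows.append(row)
    return table


def type3_terms(
    cohort: StudyCohort,
    terms: list[Term],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Type-III (marginal) chi-square tests: each term is dropped from the
    full model while every other term is retained, and tested by LRT.

    Dropping a main effect while its interactions remain is permitted —
    that is what type-III semantics mean — but is logged.
    """
    y = cohort.phenotypes.status
    full = fit_logistic(y, build_design(cohort, terms, covariates))
    rows = []
    for term in terms:
        remaining = [t for t in terms if t != term]
        if len(term) == 1 and any(term[0] in t for t in remaining if len(t) > 1):
            logger.info(
                "type-III: dropping main effect %s while interactions remain",
                term_name(term),
            )
        reduced = fit_logistic(y, build_design(cohort, remaining, covariates))
        stat, df, p = likelihood_ratio_test(full, reduced)
        rows.append({"term": term_name(term), "lrt": stat, "df": df, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quantitative traits
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform, Φ⁻¹((rank − c)/(n + 1 − 2c)).

    Default offset c = 3/8 (Blom).  Ties receive average ranks, so tied
    inputs map to the same value; output is monotone in the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    ranks = scipy.stats.rankdata(v, method="average")
    return scipy.stats.norm.ppf((ranks - offset) / (v.size + 1 - 2 * offset))


def trait_association(
    predictors: pd.DataFrame,
    trait: np.ndarray,
    covariates: pd.DataFrame | None = None,
    transform: bool = True,
) -> pd.DataFrame:
    """Linear association of a quantitative trait with SNP/interaction
    predictors, adjusting for covariates; the trait is inverse-normal
    transformed first unless ``transform=False``."""
    y = inverse_normal_transform(trait) if transform else np.asarray(trait, float)
    x = predictors if covariates is None else predictors.join(covariates)
    res = fit_ols(y, x)
    return pd.DataFrame(
        {
            "beta": res.params[predictors.columns],
            "se": res.bse[predictors.columns],
            "p": res.pvalues[predictors.columns],
        }
    )


# ---------------------------------------------------------------------------
# Haplotype EM and haplotype GLM
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEMResult:
    """EM-estimated haplotype frequencies over m SNPs (m ≤ 4)."""

    snps: list[str]
    haplotypes: list[tuple[int, ...]]  # minor-allele indicator patterns
    frequencies: np.ndarray
    expected_dosages: np.ndarray  # samples (with complete calls) × haplotypes
    sample_index: np.ndarray  # row positions of the retained samples
    loglik_trace: list[float]
    n_iter: int

    @property
    def reference(self) -> int:
        """Index of the most frequent haplotype."""
        return int(np.argmax(self.frequencies))


def haplotype_em(
    cohort: StudyCohort,
    snps: list[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeEMResult:
    """EM over all diplotypes consistent with each multilocus genotype.

    Hard calls; samples with any missing call at the m SNPs are excluded.
    The HWE diplotype prior is iterated from linkage-equilibrium starting
    frequencies; the log-likelihood is asserted non-decreasing every
    iteration and convergence is declared when the largest frequency change
    falls below ``tol``.
    """
    m = len(snps)
    if m > 4:
        raise ValueError("haplotype EM supports at most 4 SNPs")
    g = np.column_stack([hard_calls(cohort.genotypes.column(s)) for s in snps])
    keep = np.isfinite(g).all(axis=1)
    g = g[keep].astype(int)
    n = g.shape[0]
    if n == 0:
        raise ValueError("no samples with complete calls at the requested SNPs")
    haps = [tuple(h) for h in itertools.product((0, 1), repeat=m)]
    hap_arr = np.array(haps)
    n_hap = len(haps)
    # compatible haplotype pairs per distinct genotype pattern
    pairs = [
        (i, j) for i in range(n_hap) for j in range(i, n_hap)
    ]
    pair_sum = {pr: tuple(hap_arr[pr[0]] + hap_arr[pr[1]]) for pr in pairs}
    patterns, inverse = np.unique(g, axis=0, return_inverse=True)
    compat = [
        [pr for pr in pairs if pair_sum[pr] == tuple(pat)] for pat in patterns
    ]
    if any(len(c) == 0 for c in compat):
        raise ValueError("genotype incompatible with biallelic haplotypes")
    pattern_counts = np.bincount(inverse, minlength=len(patterns)).astype(float)

    # init: product of single-SNP allele frequencies (deterministic)
    af = g.mean(axis=0) / 2.0
    p = np.array(
        [np.prod([af[k] if h[k] else 1 - af[k] for k in range(m)]) for h in haps]
    )
    p = np.clip(p, 1e-300, None)
    p /= p.sum()

    def pair_prior(freqs, i, j):
        return (2.0 if i != j else 1.0) * freqs[i] * freqs[j]

    loglik_trace: list[float] = []
    last_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: posterior expected haplotype counts per pattern
        counts = np.zeros(n_hap)
        ll = 0.0
        post_by_pattern = []
        for pat_i, cp in enumerate(compat):
            w = np.array([pair_prior(p, i, j) for i, j in cp])
            tot = w.sum()
            ll += pattern_counts[pat_i] * np.log(tot)
            w = w / tot
            post_by_pattern.append(w)
            for (i, j), wk in zip(cp, w):
                counts[i] += pattern_counts[pat_i] * wk
                counts[j] += pattern_counts[pat_i] * wk
        assert ll >= last_ll - 1e-9, "EM log-likelihood decreased"
        last_ll = ll
        loglik_trace.append(ll)
        p_new = counts / (2.0 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new

    # expected per-individual haplotype dosages from the final posteriors
    exp_pattern = np.zeros((len(patterns), n_hap))
    for pat_i, cp in enumerate(compat):
        w = np.array([pair_prior(p, i, j) for i, j in cp])
        w = w / w.sum()
        for (i, j), wk in zip(cp, w):
            exp_pattern[pat_i, i] += wk
            exp_pattern[pat_i, j] += wk
    expected = exp_pattern[inverse]
    return HaplotypeEMResult(
        snps=list(snps),
        haplotypes=haps,
        frequencies=p,
        expected_dosages=expected,
        sample_index=np.flatnonzero(keep),
        loglik_trace=loglik_trace,
        n_iter=n_iter,
    )


@dataclass
class HaplotypeModel:
    """Odds ratio of one haplotype relative to the most frequent one."""

    alleles: tuple[int, ...]
    frequency: float
    log_or: float
    se: float
    p: float
    is_reference: bool = False
    estimable: bool = True


def haplotype_glm(
    em: HaplotypeEMResult,
    cohort: StudyCohort,
    covariates: pd.DataFrame | None = None,
    freq_floor: float = 1e-4,
) -> list[HaplotypeModel]:
    """Logistic regression of status on expected haplotype dosages.

    The most frequent haplotype is the (omitted) reference, so every log-OR
    is relative to it; haplotypes below ``freq_floor`` are dropped from the
    design and reported unestimable.
    """
    ref = em.reference
    y = cohort.phenotypes.status[em.sample_index]
    idx = pd.Index(np.array(cohort.genotypes.samples)[em.sample_index])
    cols, modelled = {}, []
    for h, hap in enumerate(em.haplotypes):
        if h == ref or em.frequencies[h] < freq_floor:
            continue
        cols["h" + "".join(map(str, hap))] = em.expected_dosages[:, h]
        modelled.append(h)
    x = pd.DataFrame(cols, index=idx)
    if covariates is not None:
        x = x.join(covariates.loc[idx])
    fit = fit_logistic(y, x)
    out = []
    for h, hap in enumerate(em.haplotypes):
        freq = float(em.frequencies[h])
        if h == ref:
            out.append(HaplotypeModel(hap, freq, 0.0, 0.0, 1.0, is_reference=True))
        elif h in modelled and fit.converged:
            b, se, p = fit.wald("h" + "".join(map(str, hap)))
            out.append(HaplotypeModel(hap, freq, b, se, p))
        else:
            out.append(
                HaplotypeModel(hap, freq, np.nan, np.nan, np.nan, estimable=False)
            )
    return out


# ---------------------------------------------------------------------------
# AIC comparison of SNP / interaction / haplotype models
# ---------------------------------------------------------------------------

@dataclass
class AICRow:
    name: str
    aic: float
    n_params: int
    p_vs_snps: float = np.nan
    p_vs_interact: float = np.nan


@dataclass
class AICComparison:
    rows: list[AICRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def best(self) -> str:
        finite = [r for r in self.rows if np.isfinite(r.aic)]
        return min(finite, key=lambda r: r.aic).name


def aic_model_comparison(
    cohort: StudyCohort,
    snps: list[str],
    em: HaplotypeEMResult,
    covariates: pd.DataFrame | None = None,
) -> AICComparison:
    """Five nested-and-parallel logistic models compared by AIC and LRT.

    Models: no-genetics, haplotypes, SNPs (additive), SNPs + all
    interactions, haplotypes + SNPs + interactions.  AIC counts every
    estimated regression coefficient (including the intercept); EM
    haplotype frequencies are estimated in a separate step and are not
    penalised.  The rank-deficient full design (haplotype dosages are
    linearly related to SNP dosages) has dependent columns dropped, with
    the parameter count adjusted accordingly.
    """
    y_full = cohort.phenotypes.status
    idx = em.sample_index
    y = y_full[idx]
    sample_ids = pd.Index(np.array(cohort.genotypes.samples)[idx])
    cov = covariates.loc[sample_ids] if covariates is not None else None

    def sub(x: pd.DataFrame) -> pd.DataFrame:
        return x.loc[sample_ids]

    ref = em.reference
    hap_cols = pd.DataFrame(
        {
            "h" + "".join(map(str, hap)): em.expected_dosages[:, h]
            for h, hap in enumerate(em.haplotypes)
            if h != ref and em.frequencies[h] >= 1e-4
        },
        index=sample_ids,
    )
    snp_design = sub(build_design(cohort, [(s,) for s in snps]))
    inter_design = sub(build_design(cohort, crossing(*snps)))

    def with_cov(x: pd.DataFrame) -> pd.DataFrame:
        return x if cov is None else x.join(cov)

    empty = pd.DataFrame(index=sample_ids)
    fit_null = fit_logistic(y, with_cov(empty))
    fit_haplo = fit_logistic(y, with_cov(hap_cols), drop_collinear=True)
    fit_snps = fit_logistic(y, with_cov(snp_design))
    fit_inter = fit_logistic(y, with_cov(inter_design), drop_collinear=True)
    fit_full = fit_logistic(
        y, with_cov(hap_cols.join(inter_design)), drop_collinear=True
    )

    def lrt_p(full: GLMFit, reduced: GLMFit) -> float:
        if not (full.converged and reduced.converged):
            return np.nan
        if full.df_resid >= reduced.df_resid:
            return np.nan  # degenerate nesting after column drops
        return likelihood_ratio_test(full, reduced)[2]

    rows = [
        AICRow("no_genetics", fit_null.aic, fit_null.n_params),
        AICRow("haplotypes", fit_haplo.aic, fit_haplo.n_params),
        AICRow("snps", fit_snps.aic, fit_snps.n_params),
        AICRow(
            "snps_interactions",
            fit_inter.aic,
            fit_inter.n_params,
            p_vs_snps=lrt_p(fit_inter, fit_snps),
        ),
        AICRow(
            "full",
            fit_full.aic,
            fit_full.n_params,
            p_vs_snps=lrt_p(fit_full, fit_snps),
            p_vs_interact=lrt_p(fit_full, fit_inter),
        ),
    ]
    return AICComparison(rows)
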