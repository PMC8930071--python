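"""The two-stage SNP×SNP interaction scan.

Stage 1 is a fast screen: for every unordered SNP pair and each of the
4 × 4 = 16 genetic-model encoding combinations, an ordinary least-squares
fit of the (0/1) disease status on ``[1, e1, e2, e1·e2]`` — a linear
probability model whose interaction t-test is a cheap stand-in for the
logistic fit.  Per-study interaction estimates are pooled by inverse-variance
fixed-effects meta-analysis and a loose p-value filter is applied.

Stage 2 refits the surviving pairs — each in its best-performing encoding
combination — with per-study logistic regression including MDS ancestry
covariates, meta-analyses the Wald estimates, and applies a Bonferroni
threshold defined on the number of LD-independent SNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genotypes import ENCODINGS, StudyCohort, encode_genotype
from .regress import fit_logistic

ENCODING_COMBINATIONS: tuple[tuple[str, str], ...] = tuple(
    itertools.product(ENCODINGS, ENCODINGS)
)  # 16 combinations per pair


@dataclass
class StudyFit:
    """One study's interaction estimate for one pair/encoding combination."""

    study: str
    beta: float
    se: float
    p: float
    n: int
    skipped: bool = False
    reason: str = ""


@dataclass
class PairTest:
    """Per-pair, per-encoding interaction result across studies."""

    snp1: str
    snp2: str
    encoding1: str
    encoding2: str
    per_study: list[StudyFit] = field(default_factory=list)
    meta_beta: float = np.nan
    meta_se: float = np.nan
    meta_p: float = np.nan
    n_studies: int = 0
    direction_consistency: int = 0
    significant: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp1, self.snp2)

    def valid_fits(self) -> list[StudyFit]:
        return [f for f in self.per_study if not f.skipped]


@dataclass
class ScanConfig:
    """Thresholds and settings of the two-stage scan."""

    stage1_threshold: float = 1e-8
    stage2_threshold: float | None = None  # None: Bonferroni on n_indep SNPs
    mds_k: int = 10
    encodings: tuple[str, ...] = ENCODINGS

    def __post_init__(self) -> None:
        if not (0.0 < self.stage1_threshold < 1.0):
            raise ValueError("stage1_threshold must lie in (0, 1)")
        if self.stage2_threshold is not None and not (0.0 < self.stage2_threshold < 1.0):
            raise ValueError("stage2_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Stage 1: linear interaction screen
# ---------------------------------------------------------------------------

def _impute_mean(col: np.ndarray) -> np.ndarray:
    if np.isnan(col).any():
        m = np.nanmean(col)
        col = np.where(np.isnan(col), m if np.isfinite(m) else 0.0, col)
    return col


def ols_interaction(
    y: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> tuple[float, float, float] | str:
    """Interaction (beta, se, p) from OLS of y on [1, e1, e2, e1·e2].

    The p-value is the two-sided t test of the interaction coefficient with
    n − 4 degrees of freedom.  Returns a reason string instead when the
    design is degenerate (constant or collinear columns).
    """
    n = y.size
    if n < 10:
        return "fewer than 10 samples"
    x = np.column_stack([np.ones(n), e1, e2, e1 * e2])
    if np.ptp(e1) == 0 or np.ptp(e2) == 0 or np.ptp(x[:, 3]) == 0:
        return "constant encoded column"
    xtx = x.T @ x
    # scaled condition check catches e1*e2 == e1 etc.
    d = np.sqrt(np.diag(xtx))
    corr = xtx / np.outer(d, d)
    if np.linalg.matrix_rank(corr, tol=1e-10) < 4:
        return "collinear design"
    xty = x.T @ y
    try:
        beta = np.linalg.solve(xtx, xty)
        cov_unscaled = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return "singular design"
    resid = y - x @ beta
    dof = n - 4
    s2 = float(resid @ resid) / dof
    se = float(np.sqrt(s2 * cov_unscaled[3, 3]))
    if se == 0 or not np.isfinite(se):
        return "zero residual variance"
    t = beta[3] / se
    p = 2.0 * scipy.stats.t.sf(abs(t), dof)
    return float(beta[3]), se, float(p)


def stage1_screen(
    study: StudyCohort,
    variant_ids: list[str],
    config: ScanConfig | None = None,
) -> dict[tuple[str, str, str, str], StudyFit]:
    """All pairs × 16 encoding combinations for one study.

    Returns a mapping keyed by (snp1, snp2, encoding1, encoding2); degenerate
    combinations are present but flagged ``skipped`` with a reason.
    """
    config = config or ScanConfig()
    y = study.phenotypes.status
    n = y.size
    encoded = {
        (vid, enc): _impute_mean(encode_genotype(study.genotypes.column(vid), enc))
        for vid in variant_ids
        for enc in config.encodings
    }
    out: dict[tuple[str, str, str, str], StudyFit] = {}
    for v1, v2 in itertools.combinations(variant_ids, 2):
        for enc1 in config.encodings:
            for enc2 in config.encodings:
                res = ols_interaction(y, encoded[(v1, enc1)], encoded[(v2, enc2)])
                key = (v1, v2, enc1, enc2)
                if isinstance(res, str):
                    out[key] = StudyFit(
                        study.name, np.nan, np.nan, np.nan, n, skipped=True, reason=res
                    )
                else:
                    beta, se, p = res
                    out[key] = StudyFit(study.name, beta, se, p, n)
    return out


# ---------------------------------------------------------------------------
# Fixed-effects meta-analysis
# ---------------------------------------------------------------------------

def fixed_effects_meta(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effects pooling; (beta, se, two-sided normal p)."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    if not ok.any():
        return np.nan, np.nan, np.nan
    w = 1.0 / ses[ok] ** 2
    beta = float((w * betas[ok]).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    # floor against underflow so p stays in (0, 1] and sortable
    return beta, se, max(2.0 * float(scipy.stats.norm.sf(abs(z))), 1e-300)


def _meta_fill(pt: PairTest) -> PairTest:
    fits = pt.valid_fits()
    if fits:
        pt.meta_beta, pt.meta_se, pt.meta_p = fixed_effects_meta(
            np.array([f.beta for f in fits]), np.array([f.se for f in fits])
        )
        pt.n_studies = len(fits)
        if np.isfinite(pt.meta_beta):
            pt.direction_consistency = int(
                sum(np.sign(f.beta) == np.sign(pt.meta_beta) for f in fits)
            )
    return pt


def run_stage1(
    studies: list[StudyCohort],
    variant_ids: list[str],
    config: ScanConfig | None = None,
) -> list[PairTest]:
    """Stage-1 screen in every study, meta-analysed per pair × combination."""
    config = config or ScanConfig()
    per_study = [stage1_screen(s, variant_ids, config) for s in studies]
    out = []
    for key in per_study[0]:
        v1, v2, enc1, enc2 = key
        pt = PairTest(v1, v2, enc1, enc2, per_study=[d[key] for d in per_study])
        out.append(_meta_fill(pt))
    return out


# ---------------------------------------------------------------------------
# Best-encoding selection and Stage 2
# ---------------------------------------------------------------------------

def _encoding_rank(pt: PairTest) -> tuple:
    # ties: (dosage, dosage) first, then lexicographic encoding order
    return (
        0 if (pt.encoding1, pt.encoding2) == ("dosage", "dosage") else 1,
        pt.encoding1,
        pt.encoding2,
    )


def select_best_encoding(combinations: list[PairTest]) -> PairTest | None:
    """The encoding combination with the smallest meta p for one pair.

    Deterministic ties: (dosage, dosage) preferred, then lexicographic.
    Returns None (pair dropped) when every combination was skipped.
    """
    valid = [pt for pt in combinations if np.isfinite(pt.meta_p)]
    if not valid:
        return None
    return min(valid, key=lambda pt: (pt.meta_p, _encoding_rank(pt)))


def stage1_pass(
    results: list[PairTest], config: ScanConfig | None = None
) -> list[PairTest]:
    """Best encoding per pair, filtered at the loose Stage-1 threshold."""
    config = config or ScanConfig()
    by_pair: dict[tuple[str, str], list[PairTest]] = {}
    for pt in results:
        by_pair.setdefault(pt.pair, []).append(pt)
    out = []
    for combos in by_pair.values():
        best = select_best_encoding(combos)
        if best is not None and best.meta_p < config.stage1_threshold:
            out.append(best)
    return out


def logistic_interaction_fit(
    cohort: StudyCohort,
    snp1: str,
    snp2: str,
    encoding1: str,
    encoding2: str,
    mds_k: int = 10,
    extra_covariates: pd.DataFrame | None = None,
):
    """Per-study logistic fit of status on [e1, e2, e1·e2, MDS_1..k (+extras)]."""
    e1 = _impute_mean(encode_genotype(cohort.genotypes.column(snp1), encoding1))
    e2 = _impute_mean(encode_genotype(cohort.genotypes.column(snp2), encoding2))
    x = pd.DataFrame(
        {"e1": e1, "e2": e2, "e1xe2": e1 * e2}, index=cohort.genotypes.samples
    )
    if cohort.mds is not None and mds_k > 0:
        x = x.join(cohort.mds.iloc[:, :mds_k])
    if extra_covariates is not None:
        x = x.join(extra_covariates)
    return fit_logistic(cohort.phenotypes.status, x)


def stage2_refine(
    pairs: list[PairTest],
    studies: list[StudyCohort],
    threshold: float,
    mds_k: int = 10,
) -> list[PairTest]:
    """Logistic refinement with MDS covariates of Stage-1 survivors.

    Non-converging or separated studies are excluded from a pair's
    meta-analysis with a logged reason; a pair left with fewer than two
    studies is flagged via its ``reason`` entries and never significant.
    """
    out = []
    for pt in pairs:
        fits: list[StudyFit] = []
        for cohort in studies:
            fit = logistic_interaction_fit(
                cohort, pt.snp1, pt.snp2, pt.encoding1, pt.encoding2, mds_k
            )
            n = cohort.n_samples
            if not fit.converged:
                fits.append(
                    StudyFit(cohort.name, np.nan, np.nan, np.nan, n, True, fit.reason)
                )
                continue
            beta, se, p = fit.wald("e1xe2")
            fits.append(StudyFit(cohort.name, beta, se, p, n))
        refined = PairTest(pt.snp1, pt.snp2, pt.encoding1, pt.encoding2, fits)
        _meta_fill(refined)
        refined.significant = (
            refined.n_studies >= min(2, len(studies))
            and np.isfinite(refined.meta_p)
            and refined.meta_p < threshold
        )
        out.append(refined)
    return out


def bonferroni_threshold(n_indep: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance level over all pairs of
    ``n_indep`` LD-independent SNPs: alpha / (n_indep choose 2)."""
    if n_indep < 2:
        raise ValueError("need at least 2 LD-independent SNPs")
    return alpha / (n_indep * (n_indep - 1) / 2.0)


def run_scan(
    studies: list[StudyCohort],
    variant_ids: list[str],
    config: ScanConfig | None = None,
) -> tuple[list[PairTest], list[PairTest], float]:
    """Full two-stage scan; returns (stage1 survivors, stage2 results, threshold)."""
    config = config or ScanConfig()
    stage1 = run_stage1(studies, variant_ids, config)
    survivors = stage1_pass(stage1, config)
    threshold = (
        config.stage2_threshold
        if config.stage2_threshold is not None
        else bonferroni_threshold(len(variant_ids))
    )
    stage2 = stage2_refine(survivors, studies, threshold, config.mds_k)
    return survivors, stage2, threshold
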