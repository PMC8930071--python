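"""Stage-1 OLS screen, fixed-effects meta-analysis, encoding selection and
Stage-2 logistic refinement, each against an independent reference."""

import numpy as np
import pandas as pd
import pytest

from episcan import (
    ENCODING_COMBINATIONS,
    PairTest,
    ScanConfig,
    bonferroni_threshold,
    fixed_effects_meta,
    select_best_encoding,
    stage1_screen,
    stage2_refine,
)
from episcan.scan import StudyFit, ols_interaction, run_stage1
from .conftest import make_cohort


# ---------------------------------------------------------------------------
# Independent reference solvers
# ---------------------------------------------------------------------------

def reference_ols(y, e1, e2):
    """Generic full least-squares solve via SVD pseudo-inverse + t test."""
    import scipy.stats

    n = y.size
    x = np.column_stack([np.ones(n), e1, e2, e1 * e2])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    s2 = resid @ resid / (n - 4)
    cov = s2 * np.linalg.pinv(x.T @ x)
    se = np.sqrt(cov[3, 3])
    t = beta[3] / se
    return beta[3], se, 2 * scipy.stats.t.sf(abs(t), n - 4)


def reference_irls(y, x, max_iter=50):
    """Hand-rolled Newton/IRLS logistic solver, independent of statsmodels."""
    x = np.column_stack([np.ones(len(y)), x])
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        h = x.T @ (x * w[:, None])
        grad = x.T @ (y - mu)
        step = np.linalg.solve(h, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    cov = np.linalg.inv(h)
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

def test_sixteen_combinations_enumerated_per_pair(toy_cohort):
    assert len(ENCODING_COMBINATIONS) == 16
    results = stage1_screen(toy_cohort, ["snp1", "snp2"])
    assert len(results) == 16
    assert {k[:2] for k in results} == {("snp1", "snp2")}


def test_stage1_matches_reference_ols_on_fixed_toy():
    rng = np.random.default_rng(20)
    e1 = rng.integers(0, 3, 20).astype(float)
    e2 = rng.integers(0, 3, 20).astype(float)
    y = rng.integers(0, 2, 20).astype(float)
    got = ols_interaction(y, e1, e2)
    assert not isinstance(got, str)
    expected = reference_ols(y, e1, e2)
    np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)


def test_stage1_symmetric_under_snp_swap(toy_cohort):
    res = stage1_screen(toy_cohort, ["snp1", "snp2"])
    fwd = res[("snp1", "snp2", "dosage", "dominant")]
    y = toy_cohort.phenotypes.status
    rev = ols_interaction(
        y,
        toy_cohort.genotypes.column("snp2"),
        toy_cohort.genotypes.column("snp1"),
    )
    # swapping SNPs (and their encodings) leaves the interaction untouched
    res_dom = ols_interaction(
        y,
        np.minimum(toy_cohort.genotypes.column("snp2"), 1),
        toy_cohort.genotypes.column("snp1"),
    )
    assert res_dom[0] == pytest.approx(fwd.beta, abs=1e-12)


def test_collinear_combination_skipped_with_reason():
    # identical SNPs under dominant encoding: e1 == e2, product == e1
    rng = np.random.default_rng(21)
    a = rng.integers(0, 3, 50).astype(float)
    cohort = make_cohort(np.column_stack([a, a]), rng.integers(0, 2, 50))
    res = stage1_screen(cohort, ["snp1", "snp2"])
    fit = res[("snp1", "snp2", "dominant", "dominant")]
    assert fit.skipped
    assert fit.reason


def test_constant_recessive_column_skipped():
    rng = np.random.default_rng(22)
    a = rng.integers(0, 2, 60).astype(float)  # no hom-minor genotype
    b = rng.integers(0, 3, 60).astype(float)
    cohort = make_cohort(np.column_stack([a, b]), rng.integers(0, 2, 60))
    res = stage1_screen(cohort, ["snp1", "snp2"])
    fit = res[("snp1", "snp2", "recessive", "dosage")]
    assert fit.skipped and "constant" in fit.reason


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

class TestMeta:
    def test_single_study_identity(self):
        beta, se, p = fixed_effects_meta([0.31], [0.07])
        assert (beta, se) == (pytest.approx(0.31), pytest.approx(0.07))

    def test_identical_studies_shrink_se_by_sqrt_k(self):
        k = 4
        beta, se, _ = fixed_effects_meta([0.3] * k, [0.1] * k)
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / np.sqrt(k))

    def test_inverse_variance_closed_form(self):
        # w = (100, 25): beta = (0.2*100 + 0.4*25)/125 = 0.24; se = 1/sqrt(125)
        beta, se, _ = fixed_effects_meta([0.2, 0.4], [0.1, 0.2])
        assert beta == pytest.approx(0.24, abs=1e-12)
        assert se == pytest.approx(0.08944271909999159, abs=1e-10)

    def test_meta_se_never_exceeds_best_study(self):
        rng = np.random.default_rng(30)
        ses = rng.uniform(0.05, 0.5, 10)
        betas = rng.normal(0, 0.2, 10)
        _, se_all, _ = fixed_effects_meta(betas, ses)
        assert se_all <= ses.min()
        _, se_fewer, _ = fixed_effects_meta(betas[:5], ses[:5])
        assert se_all <= se_fewer

    def test_all_missing_flagged(self):
        beta, se, p = fixed_effects_meta([np.nan], [np.nan])
        assert np.isnan(beta) and np.isnan(se) and np.isnan(p)


# ---------------------------------------------------------------------------
# Encoding selection
# ---------------------------------------------------------------------------

def _pt(enc1, enc2, p):
    pt = PairTest("a", "b", enc1, enc2)
    pt.meta_p = p
    return pt


class TestBestEncoding:
    def test_single_valid_combination_returned(self):
        pt = _pt("recessive", "dosage", 0.01)
        assert select_best_encoding([pt]) is pt

    def test_exact_tie_prefers_dosage_dosage(self):
        a = _pt("dominant", "dominant", 1e-5)
        b = _pt("dosage", "dosage", 1e-5)
        assert select_best_encoding([a, b]) is b

    def test_all_skipped_drops_pair(self):
        pt = _pt("dosage", "dosage", np.nan)
        assert select_best_encoding([pt]) is None

    def test_planted_dosage_interaction_selects_dosage_encoding(self):
        import episcan as ep

        hits = 0
        for rep in range(8):
            cfg = ep.scenario_interaction(
                seed=600 + rep, or_int=1.8, n_studies=2, n_cases=1500,
                n_controls=1500,
            )
            studies = ep.simulate_cohorts(cfg)
            results = run_stage1(studies, ["tagA", "tagB"])
            best = select_best_encoding(results)
            hits += (best.encoding1, best.encoding2) == ("dosage", "dosage")
        assert hits >= 6


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------

def test_stage2_matches_independent_irls(toy_cohort):
    pair = PairTest("snp1", "snp2", "dosage", "dosage")
    refined = stage2_refine([pair], [toy_cohort], threshold=0.05, mds_k=0)
    fit = refined[0].per_study[0]
    e1 = toy_cohort.genotypes.column("snp1")
    e2 = toy_cohort.genotypes.column("snp2")
    x = np.column_stack([e1, e2, e1 * e2])
    beta, se = reference_irls(toy_cohort.phenotypes.status, x)
    assert fit.beta == pytest.approx(beta[3], abs=1e-6)
    assert fit.se == pytest.approx(se[3], abs=1e-6)


def test_stage2_separation_excluded_with_reason():
    # y perfectly determined by snp1 -> separation in the logistic fit
    n = 40
    a = np.array([0, 2] * (n // 2), float)
    b = np.tile([0, 1, 2, 1], n // 4).astype(float)
    cohort = make_cohort(np.column_stack([a, b]), (a > 0).astype(int))
    pair = PairTest("snp1", "snp2", "dosage", "dosage")
    refined = stage2_refine([pair], [cohort], threshold=0.05, mds_k=0)
    fit = refined[0].per_study[0]
    assert fit.skipped
    assert not refined[0].significant


def test_bonferroni_threshold_values():
    assert abs(bonferroni_threshold(4654) - 4.6178e-9) < 1e-13
    assert bonferroni_threshold(2) == pytest.approx(0.05)
    assert bonferroni_threshold(10) == pytest.approx(0.05 / 45)
    with pytest.raises(ValueError):
        bonferroni_threshold(1)


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(stage1_threshold=1.5)
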