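"""Locus dissection: genotypic ORs, nested ladders, type-III tests, INT,
haplotype EM/GLM and the AIC model comparison."""

import numpy as np
import pandas as pd
import pytest

from episcan import (
    TraitModel,
    aic_model_comparison,
    forward_model_selection,
    genotypic_or,
    haplotype_em,
    haplotype_glm,
    inverse_normal_transform,
    scenario_haplotype,
    simulate_study,
    simulate_traits,
    trait_association,
    type3_terms,
)
from episcan.dissect import build_design, crossing
from .conftest import make_cohort
from .test_ld import grid_mle_2locus


# ---------------------------------------------------------------------------
# Genotypic odds ratios
# ---------------------------------------------------------------------------

class TestGenotypicOR:
    def test_matches_contingency_table_odds_ratios(self, rng):
        g = rng.integers(0, 3, 600).astype(float)
        logits = -0.5 + 0.45 * g
        y = (rng.random(600) < 1 / (1 + np.exp(-logits))).astype(int)
        cohort = make_cohort(g[:, None], y, ids=["snp"])
        effects = {e.genotype_class: e for e in genotypic_or("snp", cohort)}
        counts = {
            k: (((g == v) & (y == 1)).sum(), ((g == v) & (y == 0)).sum())
            for k, v in (("hom_major", 0), ("het", 1), ("hom_minor", 2))
        }
        for cls in ("het", "hom_minor"):
            ca, co = counts[cls]
            ca0, co0 = counts["hom_major"]
            hand = np.log((ca / co) / (ca0 / co0))
            assert effects[cls].log_or == pytest.approx(hand, abs=1e-8)

    def test_reference_class_or_exactly_one(self, toy_cohort):
        effects = genotypic_or("snp1", toy_cohort)
        ref = effects[0]
        assert ref.genotype_class == "hom_major"
        assert ref.log_or == 0.0

    def test_empty_class_flagged_unestimable(self, rng):
        g = rng.integers(0, 2, 300).astype(float)  # no hom-minor at all
        y = rng.integers(0, 2, 300)
        cohort = make_cohort(g[:, None], y, ids=["snp"])
        effects = {e.genotype_class: e for e in genotypic_or("snp", cohort)}
        assert not effects["hom_minor"].estimable
        assert effects["het"].estimable


# ---------------------------------------------------------------------------
# Inverse normal transform
# ---------------------------------------------------------------------------

class TestINT:
    def test_middle_of_three_maps_to_zero(self):
        out = inverse_normal_transform(np.array([5.0, 1.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardised_output(self, rng):
        out = inverse_normal_transform(rng.exponential(size=500))
        assert abs(out.mean()) < 0.05
        assert abs(out.var() - 1.0) < 0.05

    def test_monotone_and_tie_consistent(self):
        x = np.array([3.0, 1.0, 1.0, 7.0, 5.0])
        out = inverse_normal_transform(x)
        assert out[1] == out[2]
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.array([1.0]))


# ---------------------------------------------------------------------------
# Forward model selection and type-III terms
# ---------------------------------------------------------------------------

class TestModelLadder:
    def test_deviance_non_increasing_down_the_ladder(self, rng):
        g = rng.integers(0, 3, size=(800, 4)).astype(float)
        eta = -0.3 + 0.4 * g[:, 0] + 0.3 * g[:, 1] * g[:, 2]
        y = (rng.random(800) < 1 / (1 + np.exp(-eta))).astype(int)
        cohort = make_cohort(g, y, ids=["s1", "s2", "s3", "s4"])
        table = forward_model_selection(["s1", "s2", "s3", "s4"], cohort)
        dev = [r.resid_deviance for r in table.rows]
        assert all(d2 <= d1 + 1e-8 for d1, d2 in zip(dev, dev[1:]))
        assert len(table.rows) == 7

    def test_noise_snp_lrt_calibrated(self, rng):
        # appending a pure-noise SNP: LRT p vs previous row ~ uniform
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            g = rng.integers(0, 3, size=(400, 3)).astype(float)
            y = rng.integers(0, 2, 400)
            cohort = make_cohort(g, y, ids=["s1", "s2", "s3"])
            table = forward_model_selection(["s1", "s2", "s3"], cohort)
            hits += table.rows[1].p_vs_previous < 0.05
        # 99.9% binomial envelope around 0.05 of 40 replicates
        assert hits <= 8

    def test_ladder_requires_three_or_four_snps(self, toy_cohort):
        with pytest.raises(ValueError):
            forward_model_selection(["snp1", "snp2"], toy_cohort)


class TestType3:
    def test_orthogonal_design_type3_equals_sequential(self, rng):
        # balanced 2x2 factorial in dosages {0,2}: terms exactly orthogonal
        cells = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], float)
        g = np.repeat(cells, 100, axis=0)
        y = rng.integers(0, 2, 400)
        cohort = make_cohort(g, y, ids=["a", "b"])
        terms = [("a",), ("b",)]
        t3 = type3_terms(cohort, terms).set_index("term")["p"]
        # sequential: add terms one at a time, LRT each addition in reverse
        from episcan.regress import fit_logistic, likelihood_ratio_test

        full = fit_logistic(cohort.phenotypes.status, build_design(cohort, terms))
        for term in terms:
            reduced = fit_logistic(
                cohort.phenotypes.status,
                build_design(cohort, [t for t in terms if t != term]),
            )
            seq_p = likelihood_ratio_test(full, reduced)[2]
            assert t3[":".join(term)] == pytest.approx(seq_p, abs=1e-10)

    def test_null_term_p_roughly_uniform(self, rng):
        hits = 0
        for rep in range(30):
            g = rng.integers(0, 3, size=(300, 2)).astype(float)
            eta = -0.2 + 0.5 * g[:, 0]
            y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
            cohort = make_cohort(g, y, ids=["real", "noise"])
            t3 = type3_terms(cohort, [("real",), ("noise",)]).set_index("term")
            hits += t3.loc["noise", "p"] < 0.05
        assert hits <= 7

    def test_duplicate_predictor_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="duplicate"):
            type3_terms(toy_cohort, [("snp1",), ("snp1",)])


# ---------------------------------------------------------------------------
# Trait association
# ---------------------------------------------------------------------------

class TestTraitAssociation:
    def _cohort_with_traits(self, seed, beta_direct):
        cfg = scenario_haplotype(seed=seed, n_cases=2000, n_controls=2000)
        cohort = simulate_study(cfg, 0)
        tm = TraitModel(beta_direct=beta_direct)
        pheno = simulate_traits(cohort, tm, seed=seed + 1)
        return cohort, pheno

    def test_fully_mediated_effect_vanishes_after_adjustment(self):
        cohort, pheno = self._cohort_with_traits(31, beta_direct=0.0)
        pred = pd.DataFrame(
            {"rare": cohort.genotypes.column("rare")},
            index=cohort.genotypes.samples,
        )
        kiv = pd.DataFrame(
            {"kiv": pheno.trait("kiv")}, index=cohort.genotypes.samples
        )
        res = trait_association(
            pred, np.log(pheno.trait("lpa")), covariates=kiv, transform=False
        )
        assert abs(res.loc["rare", "beta"]) < 3 * res.loc["rare", "se"]

    def test_direct_effect_recovered_after_adjustment(self):
        cohort, pheno = self._cohort_with_traits(32, beta_direct=1.1)
        pred = pd.DataFrame(
            {"rare": cohort.genotypes.column("rare")},
            index=cohort.genotypes.samples,
        )
        kiv = pd.DataFrame(
            {"kiv": pheno.trait("kiv")}, index=cohort.genotypes.samples
        )
        res = trait_association(
            pred, np.log(pheno.trait("lpa")), covariates=kiv, transform=False
        )
        beta, se = res.loc["rare", "beta"], res.loc["rare", "se"]
        assert beta - 2.6 * se < 1.1 < beta + 2.6 * se


# ---------------------------------------------------------------------------
# Haplotype EM and GLM
# ---------------------------------------------------------------------------

class TestHaplotypeEM:
    def test_unambiguous_genotypes_equal_direct_counting(self):
        # all individuals homozygous at every SNP: no phase ambiguity
        # minor-oriented already (column frequencies 1/3 and 1/6)
        g = np.array([[0, 0], [2, 2], [0, 0], [0, 0], [2, 0], [0, 0]], float)
        cohort = make_cohort(g, [0, 1, 0, 1, 0, 1], ids=["a", "b"])
        em = haplotype_em(cohort, ["a", "b"])
        freqs = dict(zip(em.haplotypes, em.frequencies))
        assert freqs[(0, 0)] == pytest.approx(8 / 12, abs=1e-9)
        assert freqs[(1, 1)] == pytest.approx(2 / 12, abs=1e-9)
        assert freqs[(1, 0)] == pytest.approx(2 / 12, abs=1e-9)

    def test_matches_grid_oracle_with_double_heterozygote(self):
        g_a = np.array([0, 0, 1, 2, 1, 1])
        g_b = np.array([0, 1, 1, 2, 0, 2])
        cohort = make_cohort(
            np.column_stack([g_a, g_b]).astype(float), [0, 1] * 3, ids=["a", "b"]
        )
        em = haplotype_em(cohort, ["a", "b"])
        oracle = grid_mle_2locus(g_a, g_b)  # order (11, 10, 01, 00)
        freqs = dict(zip(em.haplotypes, em.frequencies))
        got = [freqs[(1, 1)], freqs[(1, 0)], freqs[(0, 1)], freqs[(0, 0)]]
        np.testing.assert_allclose(got, oracle, atol=1e-4)

    def test_loglik_monotone_and_frequencies_normalised(self, rng):
        g = rng.integers(0, 3, size=(200, 3)).astype(float)
        cohort = make_cohort(g, rng.integers(0, 2, 200), ids=["a", "b", "c"])
        em = haplotype_em(cohort, ["a", "b", "c"])
        trace = np.array(em.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert em.frequencies.sum() == pytest.approx(1.0, abs=1e-8)

    def test_monomorphic_degenerates_to_single_haplotype(self):
        g = np.zeros((10, 2))
        cohort = make_cohort(g, [0, 1] * 5, ids=["a", "b"])
        em = haplotype_em(cohort, ["a", "b"])
        assert em.frequencies.max() == pytest.approx(1.0)

    def test_rejects_more_than_four_snps(self, rng):
        g = rng.integers(0, 3, size=(50, 5)).astype(float)
        cohort = make_cohort(g, rng.integers(0, 2, 50))
        with pytest.raises(ValueError, match="at most 4"):
            haplotype_em(cohort, cohort.genotypes.variant_ids)


class TestHaplotypeGLM:
    def test_reference_haplotype_or_exactly_one(self, rng):
        g = rng.integers(0, 3, size=(400, 2)).astype(float)
        cohort = make_cohort(g, rng.integers(0, 2, 400), ids=["a", "b"])
        em = haplotype_em(cohort, ["a", "b"])
        models = haplotype_glm(em, cohort)
        ref = [m for m in models if m.is_reference]
        assert len(ref) == 1
        assert ref[0].log_or == 0.0
        assert ref[0].frequency == max(m.frequency for m in models)

    def test_recovers_planted_risk_haplotype_effect(self):
        cfg = scenario_haplotype(seed=33, or_hap=2.0, n_cases=4000, n_controls=4000)
        cohort = simulate_study(cfg, 0)
        em = haplotype_em(cohort, ["tagA", "rare", "tagB"])
        models = {m.alleles: m for m in haplotype_glm(em, cohort)}
        risk = models[(1, 0, 1)]
        assert risk.estimable
        # ascertainment compresses the marginal haplotype OR a little;
        # the estimate must sit on the right side and near ln(2)
        assert risk.log_or - 2.6 * risk.se < np.log(2.0)
        assert risk.log_or > 2 * risk.se

    def test_rare_haplotype_dropped_below_floor(self, rng):
        g = np.vstack(
            [np.zeros((100, 2)), np.full((99, 2), 2.0), [[2.0, 0.0]]]
        )  # haplotype (1,0) appears on a single gamete pair: freq 0.005
        cohort = make_cohort(g, rng.integers(0, 2, 200), ids=["a", "b"])
        em = haplotype_em(cohort, ["a", "b"])
        models = {m.alleles: m for m in haplotype_glm(em, cohort, freq_floor=0.05)}
        assert not models[(1, 0)].estimable


def test_aic_is_deviance_plus_two_parameters(toy_cohort):
    from episcan.regress import fit_logistic

    x = build_design(toy_cohort, [("snp1",), ("snp2",)])
    fit = fit_logistic(toy_cohort.phenotypes.status, x)
    assert fit.aic == pytest.approx(fit.deviance + 2 * 3)  # 2 SNPs + intercept


def test_aic_comparison_reports_five_models(toy_cohort):
    em = haplotype_em(toy_cohort, ["snp1", "snp2"])
    comp = aic_model_comparison(toy_cohort, ["snp1", "snp2"], em)
    names = [r.name for r in comp.rows]
    assert names == ["no_genetics", "haplotypes", "snps", "snps_interactions", "full"]
    assert all(np.isfinite(r.aic) for r in comp.rows)
    # the full model drops collinear columns rather than crashing
    assert np.isfinite(comp.rows[-1].aic)
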