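"""Synthetic multi-study case–control cohorts with block-wise LD.

The generator draws diploid genotypes from an explicit haplotype pool (LD is
specified directly through the pool, not through a recombination model),
assigns disease status from a logistic model that may contain additive,
product-interaction and haplotype effects, and ascertains exact case/control
counts by rejection sampling.  A skewed lipoprotein(a)-like quantitative
trait with a negatively correlated kringle-repeat-like covariate can be
layered on top.

Three canonical scenarios mirror the situations the scan must tell apart:

``scenario_interaction``
    a genuine multiplicative SNP×SNP interaction with no marginal effects;
``scenario_tagging``
    a low-frequency causal variant carried exclusively on a two-SNP
    haplotype background, so the pair *tags* the rare allele and produces a
    spurious interaction signal;
``scenario_null``
    no genetic effect at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    PhenotypeTable,
    StudyCohort,
    Variant,
    encode_genotype,
)


# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """A finite pool of phased haplotypes with population frequencies."""

    variants: list[Variant]
    haplotypes: np.ndarray  # (n_haplotypes, n_variants) of 0/1
    frequencies: np.ndarray  # simplex weights

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype array shape must be (H, n_variants)")
        if self.frequencies.shape != (self.haplotypes.shape[0],):
            raise ValueError("one frequency per haplotype required")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        if (self.frequencies < 0).any():
            raise ValueError("haplotype frequencies must be non-negative")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def allele_frequency(self, variant_id: str) -> float:
        j = self.variant_ids.index(variant_id)
        return float(self.frequencies @ self.haplotypes[:, j])

    def add_independent_snp(self, variant: Variant, maf: float) -> "HaplotypePool":
        """Append a SNP in linkage equilibrium with everything in the pool."""
        h0 = np.hstack([self.haplotypes, np.zeros((len(self.frequencies), 1), np.int8)])
        h1 = np.hstack([self.haplotypes, np.ones((len(self.frequencies), 1), np.int8)])
        return HaplotypePool(
            self.variants + [variant],
            np.vstack([h0, h1]),
            np.concatenate([self.frequencies * (1 - maf), self.frequencies * maf]),
        )

    def add_proxy_snp(
        self, variant: Variant, target_id: str, agreement: float = 0.975
    ) -> "HaplotypePool":
        """Append a SNP matching ``target_id``'s allele on a fraction of haplotypes.

        ``agreement`` ≈ 0.975 with a MAF-0.2 target yields r² ≈ 0.9, the
        proxy regime used for criterion-3 style checks.
        """
        j = self.variant_ids.index(target_id)
        same = np.hstack(
            [self.haplotypes, self.haplotypes[:, j : j + 1].astype(np.int8)]
        )
        diff = np.hstack(
            [self.haplotypes, (1 - self.haplotypes[:, j : j + 1]).astype(np.int8)]
        )
        return HaplotypePool(
            self.variants + [variant],
            np.vstack([same, diff]),
            np.concatenate(
                [self.frequencies * agreement, self.frequencies * (1 - agreement)]
            ),
        )


def build_tagging_pool(
    maf_rare: float = 0.0155,
    maf_tag1: float = 0.159,
    maf_tag2: float = 0.225,
    background_freq: float = 0.02,
    chromosome: str = "6",
    positions: tuple[int, int, int] = (1_000_000, 1_020_000, 1_040_000),
    ids: tuple[str, str, str] = ("tagA", "rare", "tagB"),
) -> HaplotypePool:
    """Three-SNP pool in which a rare allele rides a two-SNP haplotype background.

    The rare allele (MAF ``maf_rare`` ≤ 0.05) is placed exclusively on
    haplotypes carrying the minor allele at *both* common tag SNPs (the
    "background", at haplotype frequency ``background_freq``), so carriage
    of the rare allele is informative for the tag-SNP genotype *product*
    while each single tag SNP stays in low LD with it.
    """
    if not 0.0 <= maf_rare <= 0.05:
        raise ValueError("maf_rare must lie in [0, 0.05]")
    if background_freq < maf_rare:
        raise ValueError(
            "background haplotype frequency must be >= maf_rare "
            "(the rare allele lives only on background haplotypes)"
        )
    q11 = background_freq
    q10 = maf_tag1 - q11
    q01 = maf_tag2 - q11
    q00 = 1.0 - maf_tag1 - maf_tag2 + q11
    if min(q10, q01, q00) < 0:
        raise ValueError("infeasible tag-SNP frequencies for this background")
    id1, id_r, id2 = ids
    p1, pr, p2 = positions
    variants = [
        Variant(id1, chromosome, p1, minor_allele_frequency=maf_tag1),
        Variant(id_r, chromosome, pr, minor_allele_frequency=maf_rare),
        Variant(id2, chromosome, p2, minor_allele_frequency=maf_tag2),
    ]
    haps = np.array(
        [
            [1, 1, 1],  # background carrying the rare allele
            [1, 0, 1],  # background without it
            [1, 0, 0],
            [0, 0, 1],
            [0, 0, 0],
        ],
        dtype=np.int8,
    )
    freqs = np.array([maf_rare, q11 - maf_rare, q10, q01, q00])
    freqs = freqs / freqs.sum()  # guard rounding; sum is 1 analytically
    return HaplotypePool(variants, haps, freqs)


def default_pool(
    maf_rare: float = 0.0155,
    background_freq: float = 0.02,
    n_neutral: int = 6,
) -> HaplotypePool:
    """The canonical scan substrate: tagging triplet + proxy + neutral SNPs.

    Adds a high-r² proxy of ``tagA`` (for proxy-support checks), neutral
    SNPs inside the ±200 kb conditioning window, and two far-away SNPs
    (one on another chromosome) so region machinery has something to clip.
    """
    pool = build_tagging_pool(maf_rare=maf_rare, background_freq=background_freq)
    pool = pool.add_proxy_snp(
        Variant("proxyA", "6", 1_005_000, minor_allele_frequency=0.16), "tagA"
    )
    rng = np.random.default_rng(20210420)  # fixed pool layout, not a sim seed
    mafs = rng.uniform(0.1, 0.45, size=n_neutral)
    pos = np.linspace(1_060_000, 1_180_000, n_neutral).astype(int)
    for i in range(n_neutral):
        pool = pool.add_independent_snp(
            Variant(f"neutral{i+1}", "6", int(pos[i]), minor_allele_frequency=mafs[i]),
            float(mafs[i]),
        )
    pool = pool.add_independent_snp(
        Variant("far1", "6", 5_000_000, minor_allele_frequency=0.3), 0.3
    )
    pool = pool.add_independent_snp(
        Variant("other1", "9", 2_000_000, minor_allele_frequency=0.3), 0.3
    )
    return pool


# ---------------------------------------------------------------------------
# Disease and trait models
# ---------------------------------------------------------------------------

@dataclass
class DiseaseModel:
    """Logistic disease model on the generative side.

    ``interactions`` maps a variant-id pair to the log-OR multiplying the
    product of the two encoded genotypes (default encoding: dosage).
    ``haplotype_effects`` lists (variant_ids, alleles, log_or): each copy of
    a haplotype matching ``alleles`` at ``variant_ids`` adds ``log_or``.
    """

    intercept: float = 0.0
    additive: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    interaction_encoding: str = "dosage"
    haplotype_effects: list[tuple[tuple[str, ...], tuple[int, ...], float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        vals = (
            [self.intercept]
            + list(self.additive.values())
            + list(self.interactions.values())
            + [b for *_, b in self.haplotype_effects]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("all disease-model effects must be finite")


@dataclass
class TraitModel:
    """Lp(a)-like skewed trait driven by one variant, partially via a
    KIV-repeat-like covariate.

    The latent (log-scale) trait is
    ``beta_direct * dosage + kiv_coef * (KIV - kiv_mean) + noise`` and the
    observed trait is its exponential (hence right-skewed); KIV itself is
    ``kiv_mean + kiv_slope * dosage + noise`` with a negative slope, so the
    trait and the covariate are negatively correlated.
    """

    trait_variant: str = "rare"
    beta_direct: float = 1.1
    kiv_mean: float = 27.0
    kiv_sd: float = 5.0
    kiv_slope: float = -5.74
    kiv_coef: float = -0.085
    noise_sd: float = 0.9


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a multi-study simulation."""

    pool: HaplotypePool
    model: DiseaseModel
    n_studies: int = 10
    n_cases: int = 1500
    n_controls: int = 1500
    seed: int = 0
    trait_model: TraitModel | None = None
    # unlinked genome-background SNPs appended to every cohort; they carry no
    # disease signal and exist so the genetic relationship matrix (MDS) is
    # not built from the scan region itself
    n_background: int = 32

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("study and sample counts must be positive")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _linear_predictor(
    model: DiseaseModel,
    pool: HaplotypePool,
    dosages: np.ndarray,
    hap_idx: np.ndarray,
) -> np.ndarray:
    ids = pool.variant_ids
    eta = np.full(dosages.shape[0], model.intercept)
    for vid, beta in model.additive.items():
        eta += beta * dosages[:, ids.index(vid)]
    for (v1, v2), beta in model.interactions.items():
        e1 = encode_genotype(dosages[:, ids.index(v1)], model.interaction_encoding)
        e2 = encode_genotype(dosages[:, ids.index(v2)], model.interaction_encoding)
        eta += beta * e1 * e2
    for vids, alleles, beta in model.haplotype_effects:
        cols = [ids.index(v) for v in vids]
        pattern = np.asarray(alleles, dtype=np.int8)
        match = (pool.haplotypes[:, cols] == pattern).all(axis=1)
        eta += beta * (match[hap_idx[:, 0]].astype(float) + match[hap_idx[:, 1]])
    return eta


def simulate_study(
    config: SimulationConfig,
    study_index: int,
    max_batches: int = 2000,
) -> StudyCohort:
    """One ascertained case–control study, deterministic under (seed, study_index).

    Individuals are formed by drawing two haplotypes from the pool, status by
    Bernoulli(logistic(η)); batches are rejection-sampled until the requested
    case and control counts are reached.
    """
    rng = np.random.default_rng(config.seed + study_index)
    pool, model = config.pool, config.model
    need_cases, need_controls = config.n_cases, config.n_controls
    kept_dos, kept_hap, kept_status = [], [], []
    batch = 4 * (need_cases + need_controls)
    for _ in range(max_batches):
        hap_idx = rng.choice(len(pool.frequencies), size=(batch, 2), p=pool.frequencies)
        dosages = (
            pool.haplotypes[hap_idx[:, 0]].astype(float)
            + pool.haplotypes[hap_idx[:, 1]]
        )
        eta = _linear_predictor(model, pool, dosages, hap_idx)
        prob = 1.0 / (1.0 + np.exp(-eta))
        status = (rng.random(batch) < prob).astype(int)
        take_case = np.flatnonzero(status == 1)[:need_cases]
        take_ctrl = np.flatnonzero(status == 0)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        kept_dos.append(dosages[take])
        kept_hap.append(hap_idx[take])
        kept_status.append(status[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
        if need_cases == 0 and need_controls == 0:
            break
    else:
        raise RuntimeError(
            "case/control ascertainment did not complete: the disease model "
            "makes one of the outcome classes practically unattainable"
        )
    dosages = np.vstack(kept_dos)
    status = np.concatenate(kept_status)
    hap_idx = np.vstack(kept_hap)
    # stable order: all cases first, then controls, in draw order
    order = np.argsort(1 - status, kind="stable")
    dosages, status, hap_idx = dosages[order], status[order], hap_idx[order]
    samples = [f"st{study_index}_s{i}" for i in range(status.size)]
    variants = list(pool.variants)
    if config.n_background:
        layout = np.random.default_rng(777)  # fixed background layout
        bg_mafs = layout.uniform(0.05, 0.5, config.n_background)
        bg = rng.binomial(2, bg_mafs, size=(status.size, config.n_background))
        dosages = np.hstack([dosages, bg.astype(float)])
        variants += [
            Variant(f"bg{i+1}", "20", 100_000 + 10_000 * i,
                    minor_allele_frequency=float(bg_mafs[i]))
            for i in range(config.n_background)
        ]
    gm = GenotypeMatrix(samples, variants, dosages)
    pheno = PhenotypeTable(
        pd.DataFrame({"status": status.astype(int)}, index=pd.Index(samples))
    )
    cohort = StudyCohort(f"study{study_index}", gm, pheno)
    cohort._hap_idx = hap_idx  # retained for trait simulation / debugging
    return cohort


def population_sample(
    config: SimulationConfig, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unascertained population draw: (dosages, status) for ``n`` individuals.

    Useful for checking prevalence, allele frequencies and Hardy–Weinberg
    proportions free of case–control ascertainment.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool, model = config.pool, config.model
    hap_idx = rng.choice(len(pool.frequencies), size=(n, 2), p=pool.frequencies)
    dosages = (
        pool.haplotypes[hap_idx[:, 0]].astype(float) + pool.haplotypes[hap_idx[:, 1]]
    )
    eta = _linear_predictor(model, pool, dosages, hap_idx)
    status = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return dosages, status


def simulate_cohorts(config: SimulationConfig) -> list[StudyCohort]:
    """All studies of a configuration (per-study streams seed + index)."""
    return [simulate_study(config, i) for i in range(config.n_studies)]


def simulate_traits(
    cohort: StudyCohort,
    trait_model: TraitModel,
    seed: int,
) -> PhenotypeTable:
    """Attach a skewed Lp(a)-like trait and KIV-like covariate to a cohort."""
    rng = np.random.default_rng(seed)
    d = cohort.genotypes.column(trait_model.trait_variant)
    n = d.size
    kiv = (
        trait_model.kiv_mean
        + trait_model.kiv_slope * d
        + rng.normal(0.0, trait_model.kiv_sd, n)
    )
    latent = (
        trait_model.beta_direct * d
        + trait_model.kiv_coef * (kiv - trait_model.kiv_mean)
        + rng.normal(0.0, trait_model.noise_sd, n)
    )
    data = cohort.phenotypes.data.copy()
    data["lpa"] = np.exp(latent)
    data["kiv"] = kiv
    return PhenotypeTable(data)


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------

def _base_config(pool: HaplotypePool, model: DiseaseModel, seed: int, **kw):
    return SimulationConfig(pool=pool, model=model, seed=seed, **kw)


def scenario_null(seed: int = 0, **kw) -> SimulationConfig:
    """No genetic effect; baseline prevalence 25%."""
    model = DiseaseModel(intercept=np.log(0.25 / 0.75))
    return _base_config(default_pool(), model, seed, **kw)


def scenario_interaction(
    seed: int = 0, or_int: float = 1.42, **kw
) -> SimulationConfig:
    """Genuine dosage×dosage interaction between the two tag SNPs,
    with zero marginal effects (the scan's qualitative signature)."""
    model = DiseaseModel(
        intercept=np.log(0.25 / 0.75),
        interactions={("tagA", "tagB"): float(np.log(or_int))},
    )
    return _base_config(default_pool(), model, seed, **kw)


def scenario_tagging(seed: int = 0, or_rare: float = 1.98, **kw) -> SimulationConfig:
    """Additive effect of the rare variant only; the tag pair picks up a
    spurious interaction because the rare allele rides their joint background."""
    model = DiseaseModel(
        intercept=np.log(0.25 / 0.75),
        additive={"rare": float(np.log(or_rare))},
    )
    return _base_config(default_pool(), model, seed, **kw)


def scenario_haplotype(seed: int = 0, or_hap: float = 2.0, **kw) -> SimulationConfig:
    """Risk attached to one specific 3-SNP haplotype (phase matters), which
    SNP-dosage models — even with interactions — cannot fully express.

    Uses a commoner two-SNP background (haplotype frequency 0.10) so the
    risk haplotype tagA–tagB-without-rare is frequent enough to carry a
    phase signal; cis and trans carriers of the two tag alleles get the
    same genotype product but different haplotype counts.
    """
    model = DiseaseModel(
        intercept=np.log(0.25 / 0.75),
        haplotype_effects=[(("tagA", "rare", "tagB"), (1, 0, 1), float(np.log(or_hap)))],
    )
    return _base_config(default_pool(background_freq=0.10), model, seed, **kw)


SCENARIOS = {
    "null": scenario_null,
    "interaction": scenario_interaction,
    "tagging": scenario_tagging,
    "haplotype": scenario_haplotype,
}
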