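"""Shared fixtures: tiny deterministic genotype sets and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from episcan import (
    GenotypeMatrix,
    PhenotypeTable,
    StudyCohort,
    Variant,
)


def make_matrix(dosages, chromosome="1", positions=None, ids=None):
    """GenotypeMatrix from a raw (n_samples, n_variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    ids = ids or [f"snp{j+1}" for j in range(m)]
    variants = [Variant(ids[j], chromosome, positions[j]) for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)


def make_cohort(dosages, status, name="toy", **matrix_kw):
    gm = make_matrix(dosages, **matrix_kw)
    pheno = PhenotypeTable(
        pd.DataFrame({"status": np.asarray(status, int)}, index=pd.Index(gm.samples))
    )
    return StudyCohort(name, gm, pheno)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210420)


@pytest.fixture(scope="session")
def toy_cohort():
    """200 samples, 3 variants, random binary outcome; for oracle checks."""
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(200, 3)).astype(float)
    status = rng.integers(0, 2, size=200)
    return make_cohort(dosages, status)


@pytest.fixture(scope="session")
def tagging_run():
    """One powered tagging-scenario run shared by the conditional tests."""
    import episcan as ep
    from episcan.mds import compute_mds
    from episcan.pipeline import PipelineConfig, select_scan_variants
    from episcan.prioritize import merge_studies

    config = ep.scenario_tagging(seed=11, n_studies=10, n_cases=1500, n_controls=1500)
    studies = ep.simulate_cohorts(config)
    for s in studies:
        s.mds = compute_mds(s.genotypes, k=10, exact_cutoff=2000)
    scan_ids = select_scan_variants(studies[0].genotypes, PipelineConfig())
    stage1, stage2, threshold = ep.run_scan(
        studies, scan_ids, ep.ScanConfig(stage1_threshold=1e-5)
    )
    merged = merge_studies(studies, mds_k=10, exact_cutoff=2000)
    return {
        "studies": studies,
        "stage1": stage1,
        "stage2": stage2,
        "threshold": threshold,
        "merged": merged,
    }
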