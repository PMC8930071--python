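"""End-to-end orchestration: simulate → scan → prioritize → condition → dissect.

A :class:`PipelineConfig` fully determines a run (scenario, sample sizes,
thresholds, seed); identical configs give byte-identical report bundles.
The final classification follows the evidence trail:

``epistasis-consistent``
    a pair passes the Stage-2 Bonferroni bar, all four prioritization
    criteria pass and no conditioning SNP explains the interaction away;
``tagging-consistent``
    a pair is significant but conditioning on some third variant collapses
    the interaction LRT — the signature of a haplotype tagging a rarer
    causal variant (the named variant is reported);
``no-signal``
    nothing passes the scan;
``inconclusive``
    a significant pair fails a criterion without a conditional dependency.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .dissect import aic_model_comparison, forward_model_selection, genotypic_or, haplotype_em, haplotype_glm
from .mds import compute_mds
from .prioritize import CriteriaReport, MergedCohort, evaluate_criteria, merge_studies
from .scan import PairTest, ScanConfig, run_scan
from .simulate import SCENARIOS, simulate_cohorts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single-file configuration of a full run; round-trips through JSON."""

    scenario: str = "tagging"
    n_studies: int = 10
    n_cases: int = 1500
    n_controls: int = 1500
    seed: int = 0
    # scan substrate: ±window regions around lead SNPs, QC'd by MAF and
    # greedily LD-pruned, mirroring how susceptibility regions are built
    lead_snps: list[str] = field(default_factory=lambda: ["tagA"])
    region_window: int = 500_000
    scan_maf_min: float = 0.05
    prune_r2: float | None = 0.5
    stage1_threshold: float = 1e-8
    stage2_threshold: float | None = None  # None → Bonferroni on scanned SNPs
    mds_k: int = 10
    mds_exact_cutoff: int = 2000  # larger cohorts use landmark MDS
    replication_threshold: float | None = None  # None → the stage-2 threshold
    min_consistent: int | None = None  # None → 80% of studies (8 of 10)
    conditioning_window: int = 200_000
    conditional_bar: float | None = 7.8e-6  # absolute bar for the
    # conditional-independence criterion; None falls back to the Bonferroni
    # rule over conditioning SNPs (see docs/methods.md)
    extra_condition_snps: list[str] = field(default_factory=list)
    dissect_snps: list[str] | None = None
    output_dir: str = "episcan_out"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for thr in (self.stage1_threshold, self.stage2_threshold,
                    self.replication_threshold):
            if thr is not None and not (0.0 < thr < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    config: PipelineConfig
    stage1_pairs: list[PairTest]
    stage2_pairs: list[PairTest]
    threshold: float
    criteria: CriteriaReport | None
    classification: str
    dependency_snp: str | None
    summary: str


def select_scan_variants(gm, config: PipelineConfig) -> list[str]:
    """Region SNPs around the lead loci, MAF-filtered and LD-pruned.

    Falls back to every variant when no lead SNP matches (e.g. externally
    supplied data without the canonical ids).
    """
    import warnings

    from .genotypes import define_regions, select_region_snps
    from .ld import ld_prune

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        regions = define_regions(config.lead_snps, gm, config.region_window)
    ids = select_region_snps(gm, regions) if regions else gm.variant_ids
    ids = [i for i in ids if gm.maf(i) >= config.scan_maf_min]
    if config.prune_r2 is not None and len(ids) > 1:
        ids = ld_prune(gm.subset_variants(ids), config.prune_r2)
    return ids


def _min_consistent(config: PipelineConfig) -> int:
    if config.min_consistent is not None:
        return config.min_consistent
    return max(2, int(np.ceil(0.8 * config.n_studies)))


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the whole procedure on a simulated multi-study dataset."""
    chash = eio.config_hash(dataclasses.asdict(config))
    logger.info("pipeline start scenario=%s seed=%d", config.scenario, config.seed)
    sim_config = SCENARIOS[config.scenario](
        seed=config.seed,
        n_studies=config.n_studies,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    studies = simulate_cohorts(sim_config)
    for s in studies:
        s.mds = compute_mds(
            s.genotypes, k=config.mds_k, exact_cutoff=config.mds_exact_cutoff
        )
    variant_ids = select_scan_variants(studies[0].genotypes, config)
    logger.info("scanning %d region SNPs after QC and pruning", len(variant_ids))
    scan_config = ScanConfig(
        stage1_threshold=config.stage1_threshold,
        stage2_threshold=config.stage2_threshold,
        mds_k=config.mds_k,
    )
    stage1, stage2, threshold = run_scan(studies, variant_ids, scan_config)
    logger.info(
        "scan: %d pairs passed stage 1, %d significant at stage 2 (bar %.3g)",
        len(stage1), sum(p.significant for p in stage2), threshold,
    )

    significant = [p for p in stage2 if p.significant]
    criteria: CriteriaReport | None = None
    dependency: str | None = None
    classification = "no-signal"
    merged: MergedCohort | None = None
    if significant:
        top = min(significant, key=lambda p: p.meta_p)
        merged = merge_studies(
            studies, mds_k=config.mds_k, exact_cutoff=config.mds_exact_cutoff
        )
        criteria = evaluate_criteria(
            top,
            studies,
            merged,
            replication_threshold=config.replication_threshold or threshold,
            min_consistent=_min_consistent(config),
            window=config.conditioning_window,
            extra_snps=config.extra_condition_snps,
            conditional_bar=config.conditional_bar,
            mds_k=config.mds_k,
        )
        if criteria.dependencies:
            dependency = min(criteria.dependencies, key=lambda r: -r.p).conditioning_snp
            classification = "tagging-consistent"
        elif criteria.overall_pass:
            classification = "epistasis-consistent"
        else:
            classification = "inconclusive"

    summary = write_report(
        config, chash, stage1, stage2, threshold, criteria, classification,
        dependency, write=write,
    )

    # Locus dissection on the flagged SNPs (skipped when nothing was flagged).
    if write and significant and merged is not None:
        top = min(significant, key=lambda p: p.meta_p)
        snps = config.dissect_snps or (
            [dependency, top.snp1, top.snp2] if dependency else None
        )
        if snps:
            outdir = Path(config.output_dir)
            cohort = merged.cohort
            cov = merged.study_covariates.join(cohort.mds)
            geno = genotypic_or(snps[0], cohort, cov)
            eio.write_results_tsv(
                pd.DataFrame([g.__dict__ for g in geno]),
                outdir / "genotypic_or.tsv", chash,
            )
            ladder = forward_model_selection(snps, cohort, cov)
            eio.write_results_tsv(
                ladder.to_dataframe(), outdir / "model_ladder.tsv", chash
            )
            em = haplotype_em(cohort, snps)
            haps = haplotype_glm(em, cohort, cov)
            eio.write_results_tsv(
                pd.DataFrame(
                    [
                        {
                            "haplotype": "".join(map(str, h.alleles)),
                            "frequency": h.frequency,
                            "log_or": h.log_or, "se": h.se, "p": h.p,
                            "reference": h.is_reference, "estimable": h.estimable,
                        }
                        for h in haps
                    ]
                ),
                outdir / "haplotypes.tsv", chash,
            )
            aic = aic_model_comparison(cohort, snps, em, cov)
            eio.write_results_tsv(aic.to_dataframe(), outdir / "aic.tsv", chash)

    return PipelineResult(
        config, stage1, stage2, threshold, criteria, classification, dependency,
        summary,
    )


def write_report(
    config: PipelineConfig,
    chash: str,
    stage1: list[PairTest],
    stage2: list[PairTest],
    threshold: float,
    criteria: CriteriaReport | None,
    classification: str,
    dependency: str | None,
    write: bool = True,
) -> str:
    """Human-readable run summary plus the per-stage TSVs."""
    lines = [
        f"episcan run summary (config {chash})",
        f"scenario={config.scenario} seed={config.seed} "
        f"studies={config.n_studies} x ({config.n_cases}+{config.n_controls})",
        f"stage 1: {len(stage1)} pair(s) passed the loose filter "
        f"(p < {config.stage1_threshold:g})",
        f"stage 2: {sum(p.significant for p in stage2)} pair(s) significant "
        f"at the Bonferroni bar {threshold:.3g}",
    ]
    if not stage1:
        lines.append("no pair passed Stage 1; nothing to refine")
    if criteria is not None:
        c = criteria
        lines += [
            f"top pair {c.pair[0]} x {c.pair[1]}:",
            f"  criterion 1 (replication): "
            f"{'pass' if c.replication.passed else 'FAIL'} — {c.replication.detail}",
            f"  criterion 2 (pair LD):     "
            f"{'pass' if c.pair_ld.passed else 'FAIL'} — {c.pair_ld.detail}",
            f"  criterion 3 (proxies):     "
            f"{'pass' if c.proxy_support.passed else 'FAIL'} — "
            f"{c.proxy_support.flag or 'proxy signal checked'}",
            f"  criterion 4 (conditional): "
            f"{'pass' if c.conditional_pass else 'FAIL'} — "
            f"{len(c.dependencies)} dependent verdict(s)",
        ]
        for r in criteria.conditional:
            if r.skipped:
                lines.append(
                    f"    SKIP condition {r.conditioning_snp}: {r.reason}"
                )
    if dependency:
        lines.append(
            f"classification: {classification} (interaction dependent on "
            f"conditioning variant {dependency})"
        )
    else:
        lines.append(f"classification: {classification}")
    summary = "\n".join(lines) + "\n"
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.txt").write_text(summary)
        (outdir / "config.json").write_text(config.to_json())
        eio.write_results_tsv(
            eio.pair_tests_to_frame(stage1), outdir / "stage1_pairs.tsv", chash
        )
        eio.write_results_tsv(
            eio.pair_tests_to_frame(stage2), outdir / "stage2_pairs.tsv", chash
        )
    return summary
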