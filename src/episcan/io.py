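"""Readers and writers for the plain-text formats the pipeline speaks.

Genotypes come either from a VCF (GT hard calls, or the DS dosage field
when present) or from a dosage TSV (one row per sample, one column per
variant, values in [0, 2] or NA).  Phenotypes, regions and variant metadata
are simple TSVs.  Everything written is TSV with ``#`` header comments so a
run is inspectable with standard shell tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeTable, Region, StudyCohort, Variant


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, dosage_field: str = "DS") -> GenotypeMatrix:
    """Genotype matrix from a VCF; multi-allelic sites are rejected.

    Hard GT calls are used unless the per-sample ``dosage_field`` (imputed
    dosage) is present, in which case dosages are preferred.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {rec.CHROM}:{rec.POS}; split it first"
            )
        try:
            col = np.asarray(rec.format(dosage_field), dtype=float).ravel()
        except Exception:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            col = gt.sum(axis=1)
        variants.append(
            Variant(
                rec.ID or f"{rec.CHROM}:{rec.POS}",
                str(rec.CHROM),
                int(rec.POS),
                rec.REF,
                rec.ALT[0],
            )
        )
        columns.append(col)
    return GenotypeMatrix(samples, variants, np.column_stack(columns))


def read_dosage_tsv(
    path: str | Path, variants_tsv: str | Path | None = None
) -> GenotypeMatrix:
    """Genotypes from a sample × variant dosage table.

    First column: sample id; remaining columns: variant ids; values in
    [0, 2] or NA.  Variant metadata (chromosome/position/alleles) comes from
    an optional companion TSV with columns ``id chromosome position ref alt``;
    without it, placeholder coordinates in column order are used.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta = {}
    if variants_tsv is not None:
        vdf = pd.read_csv(variants_tsv, sep="\t", comment="#")
        meta = {
            row["id"]: Variant(
                row["id"], str(row["chromosome"]), int(row["position"]),
                str(row.get("ref", "A")), str(row.get("alt", "B")),
            )
            for _, row in vdf.iterrows()
        }
    variants = [
        meta.get(vid, Variant(vid, "0", j + 1)) for j, vid in enumerate(df.columns)
    ]
    return GenotypeMatrix(list(df.index.astype(str)), variants, df.to_numpy(float))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Phenotype TSV with ``sample_id``, binary ``status`` and free trait columns."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
    return PhenotypeTable(df)


def read_regions(path: str | Path) -> list[Region]:
    """BED-like TSV: chrom, start, end, lead_snp (1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chromosome", "start", "end", "lead_snp"], header=0,
    )
    return [
        Region(str(r.chromosome), int(r.start), int(r.end), str(r.lead_snp))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, header_comments: list[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_cohort(cohort: StudyCohort, outdir: str | Path) -> None:
    """Write one study's genotypes, variant metadata and phenotypes as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = cohort.genotypes
    gdf = pd.DataFrame(gm.dosages, index=gm.samples, columns=gm.variant_ids)
    gdf.index.name = "sample_id"
    gdf.reset_index().pipe(
        _write_tsv, outdir / f"{cohort.name}.dosages.tsv", [f"study={cohort.name}"]
    )
    vdf = pd.DataFrame(
        {
            "id": gm.variant_ids,
            "chromosome": [v.chromosome for v in gm.variants],
            "position": [v.position for v in gm.variants],
            "ref": [v.ref_allele for v in gm.variants],
            "alt": [v.alt_allele for v in gm.variants],
            "maf": [v.minor_allele_frequency for v in gm.variants],
        }
    )
    _write_tsv(vdf, outdir / f"{cohort.name}.variants.tsv", [f"study={cohort.name}"])
    pdf = cohort.phenotypes.data.copy()
    pdf.index.name = "sample_id"
    _write_tsv(
        pdf.reset_index(), outdir / f"{cohort.name}.phenotypes.tsv",
        [f"study={cohort.name}"],
    )


def read_cohort(outdir: str | Path, name: str) -> StudyCohort:
    """Read back a study written by :func:`write_cohort`."""
    outdir = Path(outdir)
    gm = read_dosage_tsv(
        outdir / f"{name}.dosages.tsv", outdir / f"{name}.variants.tsv"
    )
    pheno = read_phenotypes(outdir / f"{name}.phenotypes.tsv")
    return StudyCohort(name, gm, pheno)


def pair_tests_to_frame(pairs) -> pd.DataFrame:
    """Flatten PairTest objects into one row per pair for TSV output."""
    rows = []
    for pt in pairs:
        row = {
            "snp1": pt.snp1, "snp2": pt.snp2,
            "encoding1": pt.encoding1, "encoding2": pt.encoding2,
            "meta_beta": pt.meta_beta, "meta_se": pt.meta_se, "meta_p": pt.meta_p,
            "n_studies": pt.n_studies,
            "direction_consistency": pt.direction_consistency,
            "significant": pt.significant,
        }
        for f in pt.per_study:
            row[f"{f.study}_beta"] = f.beta
            row[f"{f.study}_se"] = f.se
            row[f"{f.study}_p"] = f.p
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tsv(
    df: pd.DataFrame, path: str | Path, config_hash: str = ""
) -> None:
    _write_tsv(df, Path(path), [f"config_hash={config_hash}"] if config_hash else [])


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serialisable config."""
    import hashlib

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
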