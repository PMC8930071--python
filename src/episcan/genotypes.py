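"""Core genotype/phenotype data model, genetic-model encodings and regions.

Genotypes are stored as minor-allele dosages in ``[0, 2]`` (possibly
fractional after imputation) with ``NaN`` marking missing calls.  Every
variant is oriented so that its minor-allele frequency (MAF) is at most 0.5;
downstream encodings ("dominant", "recessive", "heterozygous") are always
taken with respect to the minor allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ENCODINGS = ("dosage", "dominant", "recessive", "heterozygous")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with sample-derived minor-allele frequency."""

    id: str
    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str = "A"
    alt_allele: str = "B"
    minor_allele_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")
        maf = self.minor_allele_frequency
        if np.isfinite(maf) and not (0.0 <= maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: MAF {maf} outside [0, 0.5]")


@dataclass
class Region:
    """A susceptibility region around a lead SNP (1-based, inclusive)."""

    chromosome: str
    start: int
    end: int
    lead_snp: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


class GenotypeMatrix:
    """Sample x variant minor-allele dosage matrix.

    Parameters
    ----------
    samples : sequence of str
        Unique sample identifiers (rows).
    variants : sequence of Variant
        Variant metadata (columns).
    dosages : ndarray of shape (n_samples, n_variants)
        Values in ``[0, 2]``; ``NaN`` marks missing calls.  Orientation to
        the minor allele is enforced at construction: any column whose
        allele frequency exceeds 0.5 is flipped (``d -> 2 - d``) and its
        ref/alt labels swapped, so that per-variant MAF <= 0.5 always holds.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[Variant],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        finite = dosages[np.isfinite(dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2] or be NaN")

        self.samples = list(samples)
        dosages = dosages.copy()
        variants = list(variants)
        # Orient each variant to its minor allele.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            freq = np.nanmean(dosages, axis=0) / 2.0
        flip = freq > 0.5
        dosages[:, flip] = 2.0 - dosages[:, flip]
        freq = np.where(flip, 1.0 - freq, freq)
        self.dosages = dosages
        self.variants = [
            replace(
                v,
                ref_allele=v.alt_allele if f else v.ref_allele,
                alt_allele=v.ref_allele if f else v.alt_allele,
                minor_allele_frequency=float(q) if np.isfinite(q) else float("nan"),
            )
            for v, f, q in zip(variants, flip, freq)
        ]
        self._index = {v.id: j for j, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("variant ids must be unique")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector (with NaN for missing) of one variant."""
        return self.dosages[:, self._index[variant_id]]

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self._index[variant_id]]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def maf(self, variant_id: str) -> float:
        return self.variants[self._index[variant_id]].minor_allele_frequency

    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(variant_ids)
        cols = [self._index[i] for i in ids]
        return GenotypeMatrix(
            self.samples,
            [self.variants[c] for c in cols],
            self.dosages[:, cols],
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            [self.samples[i] for i in np.flatnonzero(rows)]
            if rows.dtype == bool
            else [self.samples[i] for i in rows],
            self.variants,
            self.dosages[rows],
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing values replaced by the per-variant mean."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(d, axis=0)
            mean = np.where(np.isfinite(mean), mean, 0.0)
            idx = np.where(np.isnan(d))
            d[idx] = mean[idx[1]]
        return d


@dataclass
class PhenotypeTable:
    """Per-sample disease status plus optional quantitative traits/covariates.

    ``data`` is indexed by sample id and must carry a binary ``status``
    column (case = 1, control = 0); every other column is a free trait or
    covariate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "status" not in self.data.columns:
            raise ValueError("phenotype table must have a 'status' column")
        if self.data.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        status = self.data["status"].to_numpy()
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must be binary 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def status(self) -> np.ndarray:
        return self.data["status"].to_numpy(dtype=float)

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class StudyCohort:
    """One study's genotypes, phenotypes and (optionally) MDS coordinates."""

    name: str
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    mds: pd.DataFrame | None = None  # sample x component, centered

    def __post_init__(self) -> None:
        if self.genotypes.samples != self.phenotypes.samples:
            raise ValueError("genotype and phenotype sample ids must align")

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


# ---------------------------------------------------------------------------
# Genetic-model encodings
# ---------------------------------------------------------------------------

def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to the nearest integer genotype; ties at .5 round up."""
    d = np.asarray(dosages, dtype=float)
    return np.where(np.isfinite(d), np.floor(d + 0.5), np.nan)


def encode_genotype(dosages: np.ndarray, model: str) -> np.ndarray:
    """Encode a minor-allele dosage vector under one of the four genetic models.

    ``dosage`` is the identity; ``dominant``/``recessive``/``heterozygous``
    are 0/1 indicators computed on hard calls.  Missing values propagate.
    """
    d = np.asarray(dosages, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
        raise ValueError("dosages must lie in [0, 2]")
    if model == "dosage":
        return d.copy()
    g = hard_calls(d)
    if model == "dominant":
        out = (g >= 1).astype(float)
    elif model == "recessive":
        out = (g == 2).astype(float)
    elif model == "heterozygous":
        out = (g == 1).astype(float)
    else:
        raise ValueError(f"unknown encoding {model!r}; expected one of {ENCODINGS}")
    out[~np.isfinite(d)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Susceptibility regions
# ---------------------------------------------------------------------------

def define_regions(
    lead_snps: Sequence[str],
    matrix: GenotypeMatrix,
    window: int = 500_000,
) -> list[Region]:
    """±``window`` bp regions around each lead SNP present in the matrix.

    Lead SNPs absent from the matrix are skipped with a warning, mirroring
    how a scan simply drops loci that did not survive genotyping QC.
    """
    regions = []
    for lead in lead_snps:
        if lead not in matrix:
            warnings.warn(f"lead SNP {lead} not in genotype matrix; region skipped")
            continue
        v = matrix.variant(lead)
        regions.append(
            Region(
                chromosome=v.chromosome,
                start=max(1, v.position - window),
                end=v.position + window,
                lead_snp=lead,
            )
        )
    return regions


def select_region_snps(matrix: GenotypeMatrix, regions: Sequence[Region]) -> list[str]:
    """Deduplicated union of variant ids falling in any region, in matrix order."""
    out = []
    for v in matrix.variants:
        if any(r.contains(v.chromosome, v.position) for r in regions):
            out.append(v.id)
    return out
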