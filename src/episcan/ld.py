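"""Linkage-disequilibrium statistics and LD pruning.

Pairwise LD between unphased biallelic genotypes is computed from two-locus
haplotype frequencies estimated by an EM algorithm under Hardy–Weinberg
equilibrium: the only phase-ambiguous class is the double heterozygote,
whose coupling/repulsion split is iterated to the maximum-likelihood value.
r² and D' are then taken from the estimated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, hard_calls


@dataclass(frozen=True)
class LDStats:
    """r² and D' between two SNPs; ``defined`` is False for monomorphic input."""

    r_squared: float
    d_prime: float
    defined: bool = True


def two_locus_em(
    g_a: np.ndarray,
    g_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Haplotype frequencies (pAB, pAb, paB, pab) from unphased genotypes.

    ``A``/``B`` denote the minor alleles at the two loci.  Genotypes are
    rounded to hard calls; samples missing at either locus are excluded.
    Returns frequencies ordered as (11, 10, 01, 00) in minor-allele
    indicator coordinates.
    """
    a = hard_calls(g_a)
    b = hard_calls(g_b)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep].astype(int), b[keep].astype(int)
    n = a.size
    if n == 0:
        raise ValueError("no samples with calls at both loci")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)

    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    # Initialise at linkage equilibrium.
    p = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    n_dh = counts[1, 1]  # double heterozygotes: the only ambiguous class
    # Unambiguous haplotype counts contributed by the other 8 genotype cells.
    base = np.zeros(4)
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]

    for _ in range(max_iter):
        # E-step: split double heterozygotes between coupling (AB/ab)
        # and repulsion (Ab/aB) phase under HWE.
        coup = p[0] * p[3]
        rep = p[1] * p[2]
        tot = coup + rep
        w = 0.5 if tot <= 0 else coup / tot
        counts_h = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        p_new = counts_h / (2.0 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p


def compute_ld(g_a: np.ndarray, g_b: np.ndarray) -> LDStats:
    """EM-based r² and D' between two unphased genotype vectors.

    Monomorphic input at either locus makes LD undefined; a flagged
    result (``defined=False``) is returned rather than raising.
    """
    a = hard_calls(np.asarray(g_a, dtype=float))
    b = hard_calls(np.asarray(g_b, dtype=float))
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return LDStats(float("nan"), float("nan"), defined=False)
    p = two_locus_em(a, b)
    p_a = p[0] + p[1]
    p_b = p[0] + p[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return LDStats(float("nan"), float("nan"), defined=False)
    d = p[0] - p_a * p_b
    r2 = d * d / denom
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    return LDStats(float(min(r2, 1.0)), float(min(d_prime, 1.0)))


def ld_prune(
    matrix: GenotypeMatrix,
    r2_threshold: float = 0.5,
) -> list[str]:
    """Greedy positional LD pruning: retained set has all pairwise r² < threshold.

    Variants are swept left to right (position order within chromosome); a
    variant is kept unless its r² with any already-kept variant on the same
    chromosome reaches the threshold.  Deterministic given input order.
    """
    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (matrix.variants[j].chromosome, matrix.variants[j].position),
    )
    kept: list[int] = []
    for j in order:
        vj = matrix.variants[j]
        ok = True
        for i in kept:
            vi = matrix.variants[i]
            if vi.chromosome != vj.chromosome:
                continue
            ld = compute_ld(matrix.dosages[:, i], matrix.dosages[:, j])
            if ld.defined and ld.r_squared >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    kept_ids = {matrix.variants[i].id for i in kept}
    return [v.id for v in matrix.variants if v.id in kept_ids]
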