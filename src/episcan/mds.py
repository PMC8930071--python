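"""Population-structure coordinates: classical MDS of 1 − IBS distances.

The genetic relationship between two samples is summarised by identity by
state, IBS(i, j) = 1 − mean_v |d_iv − d_jv| / 2 over variants (missing
dosages mean-imputed per variant).  Classical (metric, Torgerson) MDS of the
distance 1 − IBS yields the ancestry covariates used by the logistic stages.

For cohorts too large to hold the dense n×n Gram matrix, the embedding
switches to landmark (Nyström) MDS: exact classical MDS on a deterministic
subset of landmark samples, remaining samples triangulated from their
distances to the landmarks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg
import scipy.spatial.distance

from .genotypes import GenotypeMatrix


def _ibs_distance(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise 1 − IBS distances between rows of x (and y if given)."""
    d = scipy.spatial.distance.cdist(x, x if y is None else y, metric="cityblock")
    return d / (2.0 * x.shape[1])


def _top_eig(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric matrix, descending eigenvalue order."""
    n = b.shape[0]
    if k >= n - 1 or n <= 200:
        w, v = scipy.linalg.eigh(b)
        idx = np.argsort(w)[::-1][:k]
        return w[idx], v[:, idx]
    w, v = scipy.sparse.linalg.eigsh(b, k=k, which="LA")
    idx = np.argsort(w)[::-1]
    return w[idx], v[:, idx]


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each axis positive (determinism)."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                coords[:, j] = -col
    return coords


def compute_mds(
    matrix: GenotypeMatrix,
    k: int = 10,
    exact_cutoff: int = 4000,
    n_landmarks: int = 1000,
) -> pd.DataFrame:
    """First ``k`` classical-MDS components of the 1 − IBS distance matrix.

    Returns a DataFrame (index = sample ids, columns ``MDS1..MDSk``) with
    per-axis mean zero, axes ordered by decreasing eigenvalue, and sign fixed
    so each axis' largest-magnitude loading is positive.  Axes whose
    eigenvalue is not positive (degenerate data) are returned as zeros.
    Cohorts larger than ``exact_cutoff`` use the landmark approximation.
    """
    n = matrix.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    x = matrix.imputed()
    if n <= exact_cutoff:
        d2 = _ibs_distance(x) ** 2
        b = -0.5 * (
            d2
            - d2.mean(axis=0, keepdims=True)
            - d2.mean(axis=1, keepdims=True)
            + d2.mean()
        )
        w, v = _top_eig(b, k)
        coords = v * np.sqrt(np.clip(w, 0.0, None))
        coords[:, w <= 0] = 0.0
    else:
        m = min(n_landmarks, n)
        land = np.linspace(0, n - 1, m).astype(int)  # deterministic landmark set
        xl = x[land]
        d2_ll = _ibs_distance(xl) ** 2
        b = -0.5 * (
            d2_ll
            - d2_ll.mean(axis=0, keepdims=True)
            - d2_ll.mean(axis=1, keepdims=True)
            + d2_ll.mean()
        )
        w, v = _top_eig(b, k)
        pos = w > 0
        # pseudo-inverse transpose of the landmark embedding
        lk_inv = np.zeros((m, k))
        lk_inv[:, pos] = v[:, pos] / np.sqrt(w[pos])
        d2_all = _ibs_distance(x, xl) ** 2
        coords = -0.5 * (d2_all - d2_ll.mean(axis=0, keepdims=True)) @ lk_inv
    coords = coords - coords.mean(axis=0, keepdims=True)
    coords = _fix_signs(coords)
    return pd.DataFrame(
        coords, index=matrix.samples, columns=[f"MDS{i+1}" for i in range(k)]
    )
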