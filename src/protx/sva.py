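"""Surrogate-variable estimation for latent structure (batch, unmodeled noise).

The number of surrogate variables is chosen by permutation parallel
analysis on the design-residual matrix: each observed singular value is
compared against the 95th percentile of the matching singular value across
B row-permuted (and re-residualized) copies; k is the count of leading
components that exceed their null percentile.

Scores are estimated in two steps: right singular vectors of the residual
matrix, then, for each component, a refit of the vector from the residual
sub-matrix of features associated with it at raw p < 0.1 in a per-feature
simple regression. The refined scores are re-orthonormalized.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, SurrogateVariables
from .errors import DesignError


def _as_array(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.data.to_numpy(dtype=float), list(matrix.data.columns)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    return arr, list(range(arr.shape[1]))


def _residual_projector(design: np.ndarray) -> np.ndarray:
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise DesignError("design matrix is rank deficient")
    hat = design @ np.linalg.pinv(design)
    return np.eye(n) - hat


def estimate_num_sv(
    matrix, design, n_perm: int = 100, quantile: float = 0.95, seed: int = 0
) -> int:
    """Permutation parallel analysis for the number of latent components.

    ``matrix`` is feature x sample (log scale); ``design`` is sample x p.
    """
    y, _ = _as_array(matrix)
    x = np.asarray(design, dtype=float)
    if y.shape[1] < x.shape[1] + 2:
        raise DesignError("need at least p + 2 samples to estimate latent factors")
    q = _residual_projector(x)
    resid = y @ q
    s = np.linalg.svd(resid, compute_uv=False)
    # variance fractions: insensitive to the overall shrink that the second
    # residualization applies to permuted copies
    obs = s**2 / np.sum(s**2)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for b in range(n_perm):
        # permute each feature's residuals independently, then re-residualize
        idx = np.argsort(rng.random(resid.shape), axis=1)
        shuffled = np.take_along_axis(resid, idx, axis=1)
        s0 = np.linalg.svd(shuffled @ q, compute_uv=False)
        null[b] = s0**2 / np.sum(s0**2)
    thresh = np.quantile(null, quantile, axis=0)

    k = 0
    for i in range(obs.size):
        if obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k


def estimate_svs(matrix, design, k: int, screen_alpha: float = 0.1) -> SurrogateVariables:
    """Estimate k orthonormal surrogate-variable score vectors."""
    y, sample_ids = _as_array(matrix)
    x = np.asarray(design, dtype=float)
    if k == 0:
        return SurrogateVariables(
            scores=pd.DataFrame(index=pd.Index(sample_ids, name="sample_id")),
            eigen_share=np.zeros(0),
        )
    q = _residual_projector(x)
    resid = y @ q
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if k > rank:
        raise DesignError(f"k={k} exceeds residual rank {rank}")
    eigen_share = (s**2 / np.sum(s**2))[:k]

    n = resid.shape[1]
    refined = []
    for j in range(k):
        v = vt[j]
        # per-feature simple regression of residuals on the candidate vector
        vv = v - v.mean()
        denom = float(vv @ vv)
        slope = resid @ vv / denom
        fitted = np.outer(slope, vv)
        rss = np.sum((resid - resid.mean(axis=1, keepdims=True) - fitted) ** 2, axis=1)
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2 / denom, 1e-300))
        tstat = slope / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        sel = pvals < screen_alpha
        # refit from the raw (row-centered) sub-matrix of screened features,
        # keeping the eigengene most correlated with the candidate: surrogates
        # may retain design-correlated components of a real factor
        sub = y[sel] if sel.sum() >= 2 else y
        sub = sub - sub.mean(axis=1, keepdims=True)
        _, _, vt_sub = np.linalg.svd(sub, full_matrices=False)
        cors = np.abs(vt_sub @ vv) / (np.linalg.norm(vv) + 1e-300)
        w = vt_sub[int(np.argmax(cors))]
        if np.dot(w, v) < 0:
            w = -w
        refined.append(w)

    basis, _ = np.linalg.qr(np.column_stack(refined))
    # QR may flip signs; align each column with its refined vector
    for j in range(k):
        if np.dot(basis[:, j], refined[j]) < 0:
            basis[:, j] = -basis[:, j]
    scores = pd.DataFrame(
        basis,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"SV{j + 1}" for j in range(k)],
    )
    return SurrogateVariables(scores=scores, eigen_share=eigen_share)
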