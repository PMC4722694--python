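"""Differential-abundance engines and multiple-testing procedures.

Two engines share the :func:`protx.datatypes.make_de_table` result layout:

* :func:`fit_moderated_lm` — per-feature ordinary least squares on log2
  abundance with empirical-Bayes variance moderation: the per-feature
  residual variances are shrunk toward a pooled prior (d0, s0^2) fitted by
  matching moments of log s^2 to a scaled-F model, and the group
  coefficient is tested with a moderated t on d0 + d residual df.

* :func:`fit_nb_glm` — negative-binomial log-link GLM on counts with
  median-of-ratios size factors, per-gene dispersion estimated by maximum
  likelihood, shrunk toward a 1/mu trend through a lognormal prior, and a
  Wald test on the group coefficient. A deliberately compact re-derivation
  of the standard count-based DE recipe: no fold-change shrinkage, no
  Cox-Reid adjustment, no outlier replacement. IRLS is vectorized across
  genes. Non-converged genes keep p = 1 (flagged), so the BH denominator
  always equals the filtered gene count.

Multiple testing: Benjamini-Hochberg step-up (``bh_adjust``) and Storey
q-values with a cubic-smoother pi0 estimate (``qvalue``).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, special, stats

from .datatypes import AbundanceMatrix, make_de_table
from .errors import DesignError
from .simulate import RIN_BIN_THRESHOLD


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix(
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    svs: pd.DataFrame | None = None,
    group_col: str = "group",
    case_label: str = "PD",
) -> pd.DataFrame:
    """Intercept + group indicator (control = 0, case = 1) + covariates + SVs.

    ``rin_bin`` may be requested as a covariate even if only ``rin`` is
    present; it is then derived with the standard threshold (RIN <= 7 low).
    """
    cols = {"intercept": np.ones(len(samples))}
    cols[group_col] = (samples[group_col] == case_label).astype(float).to_numpy()
    for cov in covariates:
        if cov == "rin_bin" and cov not in samples.columns:
            cols[cov] = (samples["rin"] > RIN_BIN_THRESHOLD).astype(float).to_numpy()
        else:
            cols[cov] = samples[cov].astype(float).to_numpy()
    x = pd.DataFrame(cols, index=samples.index)
    if svs is not None and svs.shape[1]:
        x = pd.concat([x, svs.loc[x.index]], axis=1)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return x


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def low_count_filter(counts: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Drop genes with zero counts in more than half of either group (strict >)."""
    groups = groups.loc[counts.columns]
    labels = groups.unique()
    if len(labels) != 2:
        raise DesignError(f"expected two groups, found {list(labels)}")
    keep = np.ones(len(counts), dtype=bool)
    for lab in labels:
        cols = groups.index[groups == lab]
        zeros = (counts[cols] == 0).sum(axis=1).to_numpy()
        keep &= zeros <= 0.5 * len(cols)
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = _check_pvals(pvals)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def estimate_pi0(pvals, lambdas=None) -> float:
    """Storey pi0: cubic smoother through pi0(lambda), evaluated at 0.95.

    Falls back to the lambda = 0.5 plug-in when the smoother is
    ill-conditioned or returns a non-positive value.
    """
    p = _check_pvals(pvals)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    pi0 = np.nan
    try:
        spl = interpolate.UnivariateSpline(lambdas, pi0_lam, k=3)
        pi0 = float(spl(lambdas[-1]))
    except Exception:
        pi0 = np.nan
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = float(np.mean(p > 0.5) / 0.5)
    if pi0 <= 0:
        positive = pi0_lam[pi0_lam > 0]
        pi0 = float(positive.min()) if positive.size else 1.0
    return min(pi0, 1.0)


def qvalue(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0 = 1 these equal BH adjusted p-values."""
    p = _check_pvals(pvals)
    if p.size < 1:
        return p
    if pi0 is None:
        pi0 = estimate_pi0(p) if p.size >= 10 else 1.0
    order = np.argsort(p, kind="mergesort")
    m = p.size
    ranked = p[order] * pi0 * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# moderated linear model
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iteration on a monotone function)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled-F prior (d0, s0^2) for residual variances.

    Matches mean/variance of log s^2 under s^2 ~ s0^2 * F(df, d0); returns
    d0 = inf when the observed spread of log s^2 is no larger than the
    sampling component trigamma(df/2).
    """
    z = np.log(s2)
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(np.mean(e)))
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(np.mean(e) + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0 = np.inf, np.exp(np.mean(e))
    return float(d0), float(s0)


def fit_moderated_lm(
    matrix,
    design: pd.DataFrame,
    coef: str = "group",
    adjust: str = "qvalue",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-tests for one design coefficient.

    ``matrix`` is feature x sample log2 abundance. ``prior_df`` overrides the
    fitted d0 (0 recovers ordinary t-tests; ``numpy.inf`` fully pools
    variances).
    """
    if isinstance(matrix, AbundanceMatrix):
        data = matrix.data
    else:
        data = matrix
    y = data.to_numpy(dtype=float)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise DesignError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid < 2:
        raise DesignError("need at least 2 residual degrees of freedom")
    j = list(design.columns).index(coef)

    xtxi = np.linalg.inv(x.T @ x)
    pinv = xtxi @ x.T
    beta = y @ pinv.T
    resid = y - beta @ x.T
    s2 = np.sum(resid**2, axis=1) / df_resid
    v = xtxi[j, j]

    informative = s2 > 1e-12  # all-constant features carry no evidence
    if prior_df is None:
        if informative.sum() >= 2:
            d0, s0 = fit_f_prior(s2[informative], df_resid)
        else:
            d0, s0 = np.inf, float(np.mean(s2[informative])) if informative.any() else 1.0
    else:
        d0 = prior_df
        s0 = fit_f_prior(s2[informative], df_resid)[1] if informative.sum() >= 2 else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = 1e12
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    b = beta[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = b / np.sqrt(s2_post * v)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.where(informative, pvals, 1.0)
    b = np.where(informative, b, 0.0)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    adj = qvalue(pvals) if adjust == "qvalue" else bh_adjust(pvals)
    return make_de_table(
        features=data.index,
        log2fc=b,
        raw_p=pvals,
        adj_p=adj,
        adj_method=adjust,
        mean_abundance=y.mean(axis=1),
        engine="moderated_lm",
        converged=informative,
    )


# ---------------------------------------------------------------------------
# negative-binomial GLM
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1."""
    vals = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(vals)
    loggeo = logc.mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise DesignError("no gene has positive counts in every sample")
    ratios = logc[usable] - loggeo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf /= np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; y, mu are (m, n), alpha is (m,) or scalar."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    r = 1.0 / alpha[:, None]
    return np.sum(
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu) + 1e-300),
        axis=1,
    )


def _grid_argmax(objective, m: int, grid: np.ndarray) -> np.ndarray:
    """Maximize a per-gene objective over a shared log-alpha grid.

    Returns per-gene log-alpha after 3-point parabolic refinement around the
    grid argmax.
    """
    vals = np.empty((grid.size, m))
    for gi, la in enumerate(grid):
        vals[gi] = objective(np.full(m, np.exp(la)), la)
    best = np.argmax(vals, axis=0)
    la = grid[best]
    inner = (best > 0) & (best < grid.size - 1)
    idx = np.flatnonzero(inner)
    if idx.size:
        h = grid[1] - grid[0]
        f0 = vals[best[idx] - 1, idx]
        f1 = vals[best[idx], idx]
        f2 = vals[best[idx] + 1, idx]
        denom = f0 - 2 * f1 + f2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / denom, 0.0)
        la[idx] = la[idx] + np.clip(shift, -1.0, 1.0) * h
    return la


def _irls_nb(
    y: np.ndarray,
    x: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    beta0: np.ndarray | None = None,
    maxit: int = 30,
    tol: float = 1e-6,
):
    """Vectorized IRLS for NB log-link GLMs across genes.

    Returns (beta, mu, cov, converged): beta is (m, p); cov is the (m, p, p)
    inverse weighted information used for Wald SEs.
    """
    m, n = y.shape
    p = x.shape[1]
    if beta0 is None:
        z0 = np.log((y + 0.5)) - log_sf[None, :]
        beta = np.linalg.lstsq(x, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()
    ridge = 1e-8 * np.eye(p)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    for _ in range(maxit):
        if not active.any():
            break
        eta = beta[active] @ x.T + log_sf[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[active, None] * mu)
        z = (eta - log_sf[None, :]) + (y[active] - mu) / mu
        xtwx = np.einsum("np,mn,nq->mpq", x, w, x, optimize=True)
        xtwz = np.einsum("np,mn,mn->mp", x, w, z, optimize=True)
        new = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new - beta[active]), axis=1)
        beta[active] = new
        done = delta < tol
        conv_idx = np.flatnonzero(active)[done]
        converged[conv_idx] = True
        still = np.flatnonzero(active)[~done]
        active = np.zeros(m, dtype=bool)
        active[still] = True
    eta = beta @ x.T + log_sf[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("np,mn,nq->mpq", x, w, x, optimize=True)
    cov = np.linalg.inv(xtwx + ridge)
    return beta, mu, cov, converged


def _fit_dispersion_trend(alpha_gw: np.ndarray, base_mean: np.ndarray):
    """Robust fit of alpha(mu) = a1/mu + a0 by iterated trimmed NNLS."""
    good = (alpha_gw > 1e-7) & (base_mean > 0)
    a0, a1 = 1e-3, 1.0
    for _ in range(10):
        if good.sum() < 10:
            break
        a_mat = np.column_stack([np.ones(good.sum()), 1.0 / base_mean[good]])
        coefs, _ = optimize.nnls(a_mat, alpha_gw[good])
        a0 = max(coefs[0], 1e-6)
        a1 = max(coefs[1], 0.0)
        pred = a0 + a1 / base_mean
        ratio = alpha_gw / pred
        new_good = good & (ratio > 1e-4) & (ratio < 15.0)
        if new_good.sum() == good.sum():
            break
        good = new_good
    return a0, a1


def fit_nb_glm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    coef: str = "group",
    adjust: str = "bh",
    min_disp: float = 1e-8,
    max_disp: float = 30.0,
) -> pd.DataFrame:
    """Negative-binomial Wald tests for one design coefficient.

    Expects low-count-filtered integer counts (genes x samples). The reported
    effect is the group coefficient re-expressed in log2 units.
    """
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise DesignError("design matrix is rank deficient")
    j = list(design.columns).index(coef)
    y = counts.to_numpy(dtype=float)
    m = y.shape[0]

    sf = size_factors(counts)
    log_sf = np.log(sf.to_numpy())
    norm = y / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    # method-of-moments start for the dispersion
    var = norm.var(axis=1, ddof=1)
    alpha0 = np.clip((var - base_mean) / np.maximum(base_mean, 1e-8) ** 2,
                     min_disp, max_disp)

    beta, mu, _, _ = _irls_nb(y, x, log_sf, alpha0)

    grid = np.linspace(np.log(min_disp), np.log(max_disp), 60)

    def gw_objective(alpha_vec, _la):
        return _nb_loglik(y, mu, alpha_vec)

    log_alpha_gw = _grid_argmax(gw_objective, m, grid)
    alpha_gw = np.exp(log_alpha_gw)

    a0, a1 = _fit_dispersion_trend(alpha_gw, base_mean)
    alpha_trend = np.clip(a0 + a1 / np.maximum(base_mean, 1e-8), min_disp, max_disp)

    # lognormal prior width: spread of log residuals beyond sampling noise
    lr = np.log(alpha_gw) - np.log(alpha_trend)
    informative = alpha_gw > min_disp * 1.01
    if informative.sum() >= 10:
        mad = np.median(np.abs(lr[informative] - np.median(lr[informative])))
        s2_lr = (1.4826 * mad) ** 2
    else:
        s2_lr = 1.0
    sampling_var = special.polygamma(1, max((n - p) / 2.0, 0.5))
    prior_var = max(s2_lr - sampling_var, 0.25)

    log_trend = np.log(alpha_trend)

    def map_objective(alpha_vec, _la):
        ll = _nb_loglik(y, mu, alpha_vec)
        return ll - (np.log(alpha_vec) - log_trend) ** 2 / (2.0 * prior_var)

    log_alpha_map = _grid_argmax(map_objective, m, grid)
    alpha_map = np.exp(log_alpha_map)
    # dispersion outliers far above the trend keep their gene-wise estimate
    outlier = lr > 2.0 * np.sqrt(s2_lr + sampling_var)
    alpha_map[outlier] = alpha_gw[outlier]
    alpha_map = np.clip(alpha_map, min_disp, max_disp)

    beta, mu, cov, converged = _irls_nb(y, x, log_sf, alpha_map, beta0=beta)
    se = np.sqrt(np.maximum(cov[:, j, j], 1e-300))
    wald = beta[:, j] / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(converged, pvals, 1.0)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    adj = bh_adjust(pvals) if adjust == "bh" else qvalue(pvals)
    return make_de_table(
        features=counts.index,
        log2fc=beta[:, j] / np.log(2.0),
        raw_p=pvals,
        adj_p=adj,
        adj_method=adjust,
        mean_abundance=base_mean,
        engine="nb_glm",
        converged=converged,
    )
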