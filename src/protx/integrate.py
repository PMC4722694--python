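"""Cross-platform concordance, evidence classification and detection bias.

Terminology for two differential tables A and B over overlapping feature
universes (typically A = RNA-Seq, B = proteomics):

* corrected significance — adjusted p below ``alpha`` in that platform;
* nominal significance — raw p below ``alpha_nominal``;
* AND evidence — corrected in at least one platform and nominal in the
  other (the strict "common signal" class);
* OR evidence — corrected in at least one platform.

Detection bias asks whether direction of effect among A's corrected-
significant features depends on presence in B's universe, via a Pearson
chi-squared test (no continuity correction) on the 2x2 table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats


def percent(numerator: float, denominator: float) -> float:
    """Share of a printed count pair expressed in percent."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return 100.0 * numerator / denominator


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (df = 1, no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-squared test undefined: zero margin")
    n = t.sum()
    chi2 = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / np.prod(rows) / np.prod(cols)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def detection_bias_test(sig_directions: pd.Series, universe_b) -> tuple[np.ndarray, float, float]:
    """Direction-of-effect vs detected-in-B contingency test.

    ``sig_directions`` maps significant features of platform A to "up"/"down";
    features with direction "zero" are excluded (no direction class is
    defined for a zero effect). Returns (2x2 table, chi2, p) with rows
    (detected, undetected) and columns (up, down).
    """
    universe_b = set(universe_b)
    keep = sig_directions[sig_directions.isin(["up", "down"])]
    dropped = len(sig_directions) - len(keep)
    if dropped:
        warnings.warn(f"excluded {dropped} zero-direction features", stacklevel=2)
    detected = keep.index.isin(universe_b)
    up = (keep == "up").to_numpy()
    table = np.array(
        [
            [np.sum(detected & up), np.sum(detected & ~up)],
            [np.sum(~detected & up), np.sum(~detected & ~up)],
        ],
        dtype=float,
    )
    chi2, p = chi2_2x2(table)
    return table, chi2, p


def foldchange_correlation(
    de_a: pd.DataFrame, de_b: pd.DataFrame, subset=None, method: str = "spearman"
) -> tuple[float, float, int]:
    """Correlation of log2 fold changes over the shared (or given) feature set."""
    common = de_a.index.intersection(de_b.index)
    if subset is not None:
        common = common.intersection(pd.Index(subset))
    if len(common) < 3:
        raise ValueError("need at least 3 shared features")
    a = de_a.loc[common, "log2fc"].to_numpy()
    b = de_b.loc[common, "log2fc"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant fold-change vector; correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(a, b)
    elif method == "pearson":
        r, p = stats.pearsonr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), int(len(common))


def classify_evidence(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float = 0.05,
    alpha_nominal: float = 0.05,
) -> pd.DataFrame:
    """Per-feature AND/OR evidence classes over the common universe."""
    common = de_a.index.intersection(de_b.index)
    a = de_a.loc[common]
    b = de_b.loc[common]
    sig_a = a["adj_p"] < alpha
    sig_b = b["adj_p"] < alpha
    nom_a = a["raw_p"] < alpha_nominal
    nom_b = b["raw_p"] < alpha_nominal
    and_ev = (sig_a & nom_b) | (sig_b & nom_a)
    or_ev = sig_a | sig_b
    cls = np.where(and_ev, "AND", np.where(or_ev, "OR", "neither"))
    return pd.DataFrame(
        {
            "feature": common,
            "sig_a_corrected": sig_a.to_numpy(),
            "sig_b_corrected": sig_b.to_numpy(),
            "nominal_a": nom_a.to_numpy(),
            "nominal_b": nom_b.to_numpy(),
            "direction_a": a["direction"].to_numpy(),
            "direction_b": b["direction"].to_numpy(),
            "class": cls,
        }
    ).set_index("feature")


@dataclass
class ConcordanceReport:
    """Set-algebra summary of two differential tables."""

    n_universe_a: int
    n_universe_b: int
    n_common_features: int
    n_sig_a: int
    n_sig_b: int
    n_sig_a_in_b_universe: int
    n_sig_b_in_a_universe: int
    n_sig_both: int
    n_sig_both_same_direction: int
    n_and_evidence: int
    n_or_evidence: int
    pct_up_sig_a_detected_in_b: float | None
    pct_up_sig_a_undetected_in_b: float | None
    foldchange_corr: dict = field(default_factory=dict)
    contingency: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        """Internal additivity/consistency checks."""
        assert self.n_sig_both <= min(self.n_sig_a, self.n_sig_b)
        assert self.n_sig_both_same_direction <= self.n_sig_both
        assert self.n_sig_a_in_b_universe <= self.n_sig_a
        assert self.n_sig_b_in_a_universe <= self.n_sig_b
        assert self.n_or_evidence >= self.n_sig_both
        assert self.n_common_features <= min(self.n_universe_a, self.n_universe_b)
        if self.contingency:
            t = np.asarray(self.contingency["table"])
            assert t.sum(axis=1)[0] <= self.n_sig_a_in_b_universe
            assert int(t.sum()) <= self.n_sig_a


def overlap_summary(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float = 0.05,
    alpha_nominal: float = 0.05,
    fc_method: str = "spearman",
) -> ConcordanceReport:
    """Full cross-platform overlap report (set algebra + bias + correlation)."""
    univ_a, univ_b = set(de_a.index), set(de_b.index)
    common = de_a.index.intersection(de_b.index)
    if len(common) == 0:
        warnings.warn("platforms share no features; report is all zeros", stacklevel=2)
        return ConcordanceReport(len(univ_a), len(univ_b), 0, 0, 0, 0, 0, 0, 0, 0, 0,
                                 None, None)

    sig_a = de_a.index[de_a["adj_p"] < alpha]
    sig_b = de_b.index[de_b["adj_p"] < alpha]
    sig_a_in_b = sig_a.intersection(univ_b)
    sig_b_in_a = sig_b.intersection(univ_a)
    both = sig_a.intersection(sig_b)
    same_dir = [
        f for f in both
        if de_a.loc[f, "direction"] == de_b.loc[f, "direction"]
        and de_a.loc[f, "direction"] != "zero"
    ]
    ev = classify_evidence(de_a, de_b, alpha, alpha_nominal)
    n_and = int((ev["class"] == "AND").sum())
    n_or = int((ev["sig_a_corrected"] | ev["sig_b_corrected"]).sum())

    def pct_up(features) -> float | None:
        dirs = de_a.loc[list(features), "direction"]
        dirs = dirs[dirs.isin(["up", "down"])]
        return percent((dirs == "up").sum(), len(dirs)) if len(dirs) else None

    det = sig_a_in_b
    undet = sig_a.difference(univ_b)

    fc = {}
    try:
        r, p, n = foldchange_correlation(de_a, de_b, method=fc_method)
        fc = {"method": fc_method, "r": r, "p": p, "n": n}
    except ValueError:
        fc = {}
    cont = {}
    try:
        table, chi2, p = detection_bias_test(de_a.loc[sig_a, "direction"], univ_b)
        cont = {"table": table.astype(int).tolist(), "chi2": chi2, "p": p}
    except ValueError:
        cont = {}

    report = ConcordanceReport(
        n_universe_a=len(univ_a),
        n_universe_b=len(univ_b),
        n_common_features=len(common),
        n_sig_a=len(sig_a),
        n_sig_b=len(sig_b),
        n_sig_a_in_b_universe=len(sig_a_in_b),
        n_sig_b_in_a_universe=len(sig_b_in_a),
        n_sig_both=len(both),
        n_sig_both_same_direction=len(same_dir),
        n_and_evidence=n_and,
        n_or_evidence=n_or,
        pct_up_sig_a_detected_in_b=pct_up(det),
        pct_up_sig_a_undetected_in_b=pct_up(undet),
        foldchange_corr=fc,
        contingency=cont,
    )
    report.check()
    return report


def per_gene_abundance_correlation(
    prot_log2: pd.DataFrame, rna_log2: pd.DataFrame, common_samples=None
) -> pd.Series:
    """Per-feature Pearson correlation of protein vs mRNA abundance.

    Inputs are log2 matrices (feature x sample); features and samples are
    intersected. Zero-variance features get NaN (excluded downstream).
    """
    features = prot_log2.index.intersection(rna_log2.index)
    samples = prot_log2.columns.intersection(rna_log2.columns)
    if common_samples is not None:
        samples = samples.intersection(pd.Index(common_samples))
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    a = prot_log2.loc[features, samples].to_numpy(dtype=float)
    b = rna_log2.loc[features, samples].to_numpy(dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=1))
    nb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    n_dropped = int(np.isnan(r).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} zero-variance features set to NaN", stacklevel=2)
    return pd.Series(r, index=features, name="r")


def compare_abs_correlations(r_all, r_subset) -> tuple[float, float]:
    """Welch two-sample t-test on absolute correlation values."""
    a = np.abs(np.asarray(r_all, dtype=float))
    b = np.abs(np.asarray(r_subset, dtype=float))
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def detected_vs_undetected_abundance(
    rna_norm: pd.DataFrame, detected
) -> dict:
    """Mean log2 mRNA abundance contrast for proteomics-detected vs missed genes.

    ``rna_norm`` holds size-factor-normalized counts over the proteomics-
    profiled samples; per gene the statistic is log2(mean + 1).
    """
    detected = set(detected)
    log2_mean = np.log2(rna_norm.mean(axis=1) + 1.0)
    in_det = log2_mean.index.isin(detected)
    det_vals = log2_mean[in_det]
    undet_vals = log2_mean[~in_det]
    if det_vals.empty or undet_vals.empty:
        raise ValueError("both strata must be non-empty")
    t, p = stats.ttest_ind(det_vals, undet_vals, equal_var=False)
    return {
        "mean_detected": float(det_vals.mean()),
        "mean_undetected": float(undet_vals.mean()),
        "n_detected": int(det_vals.size),
        "n_undetected": int(undet_vals.size),
        "t": float(t),
        "p": float(p),
    }
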