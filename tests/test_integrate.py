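"""Cross-platform set algebra, contingency tests and correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protx import (
    chi2_2x2,
    compare_abs_correlations,
    detected_vs_undetected_abundance,
    detection_bias_test,
    foldchange_correlation,
    overlap_summary,
    per_gene_abundance_correlation,
    percent,
)
from protx.datatypes import make_de_table
from protx.integrate import classify_evidence


def _de_table(features, log2fc, raw_p, adj_p, engine="nb_glm"):
    return make_de_table(features, log2fc, raw_p, adj_p, "bh",
                         np.ones(len(features)), engine)


# ------------------------------------------------------------- chi2 and bias

def test_chi2_independence_is_zero():
    chi2, p = chi2_2x2([[25, 25], [25, 25]])
    assert chi2 == 0.0 and np.isclose(p, 1.0)


def test_chi2_matches_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        t = rng.integers(1, 200, size=(2, 2))
        mine, p_mine = chi2_2x2(t)
        ref, p_ref, _, _ = stats.chi2_contingency(t, correction=False)
        assert np.isclose(mine, ref, atol=1e-10)
        assert np.isclose(p_mine, p_ref, rtol=1e-10)


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi2_2x2([[0, 0], [5, 5]])


def test_detection_bias_test_counts_and_zero_direction_excluded():
    dirs = pd.Series(
        ["up", "up", "down", "zero", "down", "up"],
        index=["a", "b", "c", "d", "e", "f"],
    )
    with pytest.warns(UserWarning, match="zero-direction"):
        table, chi2, p = detection_bias_test(dirs, universe_b={"a", "c", "d"})
    np.testing.assert_array_equal(table, [[1, 1], [2, 1]])


# ------------------------------------------------------------- correlations

def test_foldchange_correlation_identity_and_antisymmetry():
    rng = np.random.default_rng(1)
    lfc = rng.normal(size=30)
    a = _de_table([f"g{i}" for i in range(30)], lfc, np.full(30, 0.5), np.full(30, 0.5))
    r, _, n = foldchange_correlation(a, a)
    assert np.isclose(r, 1.0) and n == 30
    b = _de_table([f"g{i}" for i in range(30)], -lfc, np.full(30, 0.5), np.full(30, 0.5))
    assert np.isclose(foldchange_correlation(a, b)[0], -1.0)


def test_foldchange_spearman_matches_midrank_oracle():
    rng = np.random.default_rng(2)
    x = np.round(rng.normal(size=30), 1)  # rounding induces ties -> midranks
    y = np.round(rng.normal(size=30), 1)
    feats = [f"g{i}" for i in range(30)]
    a = _de_table(feats, x, np.full(30, 0.5), np.full(30, 0.5))
    b = _de_table(feats, y, np.full(30, 0.5), np.full(30, 0.5))
    r, _, _ = foldchange_correlation(a, b)
    rx = stats.rankdata(x)  # midranks
    ry = stats.rankdata(y)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert np.isclose(r, oracle, atol=1e-12)


def test_per_gene_correlation_affine_invariance_and_nan():
    rng = np.random.default_rng(3)
    prot = pd.DataFrame(rng.normal(size=(10, 8)),
                        index=[f"g{i}" for i in range(10)],
                        columns=[f"s{i}" for i in range(8)])
    rna = prot * 3.0 - 7.0  # per-feature affine transform
    r = per_gene_abundance_correlation(prot, rna)
    np.testing.assert_allclose(r, 1.0, atol=1e-12)
    rna2 = rna.copy()
    rna2.iloc[0] = 5.0  # constant -> undefined correlation
    with pytest.warns(UserWarning, match="zero-variance"):
        r2 = per_gene_abundance_correlation(prot, rna2)
    assert np.isnan(r2.iloc[0]) and np.isfinite(r2.iloc[1:]).all()


def test_per_gene_correlation_null_mean_near_zero():
    rng = np.random.default_rng(4)
    n_feat = 400
    prot = pd.DataFrame(rng.normal(size=(n_feat, 24)), columns=[f"s{i}" for i in range(24)])
    rna = pd.DataFrame(rng.normal(size=(n_feat, 24)), index=prot.index,
                       columns=prot.columns)
    r = per_gene_abundance_correlation(prot, rna)
    assert abs(r.mean()) < 3.0 / np.sqrt(n_feat)


def test_compare_abs_correlations_identity_and_closed_form():
    vals = np.array([0.1, -0.4, 0.3, 0.8, -0.2])
    t, p = compare_abs_correlations(vals, vals)
    assert t == 0.0 and np.isclose(p, 1.0)
    a, b = np.abs([0.10, 0.20, 0.40]), np.abs([0.50, 0.70, 0.60])
    t, p = compare_abs_correlations(a, b)
    # Welch statistic by hand
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert np.isclose(t, t_ref, rtol=1e-12)


def test_detected_vs_undetected_direction_and_null():
    rng = np.random.default_rng(5)
    n = 500
    means = rng.lognormal(3, 1, size=n)
    rna = pd.DataFrame(rng.poisson(means[:, None], size=(n, 24)).astype(float),
                       index=[f"g{i}" for i in range(n)])
    # planted bias: detect the most abundant half
    detected = rna.index[np.argsort(means)[n // 2:]]
    res = detected_vs_undetected_abundance(rna, detected)
    assert res["mean_detected"] > res["mean_undetected"]
    assert res["p"] < 1e-10
    # random detection: no signal expected
    ps = []
    for seed in range(10):
        rnd = np.random.default_rng(seed).choice(rna.index, size=n // 2, replace=False)
        ps.append(detected_vs_undetected_abundance(rna, rnd)["p"])
    assert np.mean(np.asarray(ps) > 0.01) >= 0.9


# ---------------------------------------------------------------- set algebra

def test_percent_matches_hand_arithmetic():
    assert np.isclose(percent(106, 283), 37.455830388692576)
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)


def test_overlap_identity_report():
    rng = np.random.default_rng(6)
    feats = [f"g{i}" for i in range(200)]
    raw_p = rng.uniform(0.2, 1.0, size=200)
    raw_p[:20] = 1e-6
    adj_p = np.minimum(raw_p * 4, 1.0)
    a = _de_table(feats, rng.normal(size=200), raw_p, adj_p)
    rep = overlap_summary(a, a)
    assert rep.n_sig_a == rep.n_sig_b == rep.n_sig_both == 20
    assert rep.n_sig_both_same_direction == rep.n_sig_both
    assert np.isclose(rep.foldchange_corr["r"], 1.0)
    rep.check()


def test_overlap_counts_match_set_oracle():
    rng = np.random.default_rng(7)
    feats_a = [f"g{i}" for i in range(300)]
    feats_b = [f"g{i}" for i in range(100, 360)]
    pa, pb = rng.uniform(size=300), rng.uniform(size=260)
    a = _de_table(feats_a, rng.normal(size=300), pa, np.minimum(pa * 3, 1))
    b = _de_table(feats_b, rng.normal(size=260), pb, np.minimum(pb * 3, 1),
                  engine="moderated_lm")
    rep = overlap_summary(a, b)
    sig_a = {f for f in feats_a if a.loc[f, "adj_p"] < 0.05}
    sig_b = {f for f in feats_b if b.loc[f, "adj_p"] < 0.05}
    common = set(feats_a) & set(feats_b)
    assert rep.n_common_features == len(common)
    assert rep.n_sig_a == len(sig_a) and rep.n_sig_b == len(sig_b)
    assert rep.n_sig_both == len(sig_a & sig_b)
    and_oracle = {
        f for f in common
        if (a.loc[f, "adj_p"] < 0.05 and b.loc[f, "raw_p"] < 0.05)
        or (b.loc[f, "adj_p"] < 0.05 and a.loc[f, "raw_p"] < 0.05)
    }
    or_oracle = {f for f in common if a.loc[f, "adj_p"] < 0.05 or b.loc[f, "adj_p"] < 0.05}
    assert rep.n_and_evidence == len(and_oracle)
    assert rep.n_or_evidence == len(or_oracle)
    rep.check()


def test_evidence_classes():
    feats = ["corr_both", "and_gene", "or_gene", "nothing"]
    a = _de_table(feats, [1, 1, 1, 0.1], [0.001, 0.001, 0.001, 0.9],
                  [0.01, 0.01, 0.01, 0.95])
    b = _de_table(feats, [1, -1, 1, 0.1], [0.001, 0.02, 0.5, 0.8],
                  [0.01, 0.2, 0.9, 0.9])
    ev = classify_evidence(a, b)
    assert ev.loc["corr_both", "class"] == "AND"  # corrected both implies AND
    assert ev.loc["and_gene", "class"] == "AND"
    assert ev.loc["or_gene", "class"] == "OR"
    assert ev.loc["nothing", "class"] == "neither"


def test_disjoint_universes_warns_zero_report():
    a = _de_table(["a"], [1.0], [0.5], [0.5])
    b = _de_table(["b"], [1.0], [0.5], [0.5])
    with pytest.warns(UserWarning, match="no features"):
        rep = overlap_summary(a, b)
    assert rep.n_common_features == 0 and rep.n_sig_both == 0
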