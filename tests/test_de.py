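"""Differential engines, filters and multiple-testing procedures."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protx import (
    SimConfig,
    bh_adjust,
    design_matrix,
    fit_moderated_lm,
    fit_nb_glm,
    generate_cohort,
    low_count_filter,
    qvalue,
    size_factors,
)
from protx import simulate as sim
from protx.de import estimate_pi0
from protx.errors import DesignError


# ------------------------------------------------------------------ filtering

def test_low_count_filter_strict_boundary():
    n_case, n_ctrl = 29, 44
    cols = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
    groups = pd.Series(["PD"] * n_case + ["control"] * n_ctrl, index=cols)
    removed = ([0] * 15 + [5] * 14) + [5] * n_ctrl  # 15/29 = 51.7% zeros in cases
    kept = [5] * n_case + ([0] * 22 + [5] * 22)  # exactly 50% zeros in controls
    counts = pd.DataFrame([removed, kept], index=["removed", "kept"], columns=cols)
    out = low_count_filter(counts, groups)
    assert list(out.index) == ["kept"]


def test_low_count_filter_matches_brute_force(small_cohort):
    counts = small_cohort["counts"]
    groups = small_cohort["samples"]["group"]
    out = low_count_filter(counts, groups)
    expected = []
    for g, row in counts.iterrows():
        ok = True
        for lab in ("PD", "control"):
            sub = row[groups[counts.columns] == lab]
            if (sub == 0).sum() > 0.5 * len(sub):
                ok = False
        if ok:
            expected.append(g)
    assert list(out.index) == expected


def test_design_matrix_coding_and_rin_bin():
    samples = pd.DataFrame(
        {"group": ["control", "PD", "control", "PD", "control", "PD"],
         "age": [70.0, 80.0, 65.0, 75.0, 60.0, 85.0],
         "pmi": [5.0, 6.0, 10.0, 3.0, 8.0, 4.0],
         "rin": [7.0, 7.1, 8.0, 6.5, 9.0, 6.0]},
        index=list("abcdef"),
    )
    x = design_matrix(samples, covariates=("age", "pmi", "rin_bin"))
    assert x.loc["a", "group"] == 0.0 and x.loc["b", "group"] == 1.0
    assert x.loc["a", "rin_bin"] == 0.0  # ties at 7 go to the low bin
    assert x.loc["b", "rin_bin"] == 1.0


# ------------------------------------------------------------- moderated model

def _random_logmatrix(m, samples24, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=(m, len(samples24)))
    if effect is not None:
        y[:, :12] += effect  # first 12 columns are cases
    return pd.DataFrame(y, columns=samples24.index)


def test_moderated_prior_df_zero_equals_ordinary_t(samples24):
    y = _random_logmatrix(50, samples24, seed=1)
    x = design_matrix(samples24)
    tab = fit_moderated_lm(y, x, prior_df=0)
    xv = x.to_numpy()
    xtxi = np.linalg.inv(xv.T @ xv)
    for i in range(0, 50, 7):
        beta = np.linalg.lstsq(xv, y.to_numpy()[i], rcond=None)[0]
        resid = y.to_numpy()[i] - xv @ beta
        s2 = resid @ resid / (24 - 2)
        t = beta[1] / np.sqrt(s2 * xtxi[1, 1])
        p = 2 * stats.t.sf(abs(t), 22)
        assert np.isclose(tab.raw_p.iloc[i], p, atol=1e-10)
        assert np.isclose(tab.log2fc.iloc[i], beta[1], atol=1e-10)


def test_moderated_prior_df_inf_pools_variances(samples24):
    y = _random_logmatrix(200, samples24, seed=2)
    x = design_matrix(samples24)
    tab = fit_moderated_lm(y, x, prior_df=np.inf)
    # with infinite prior df, every feature is tested against the same variance:
    # |t| must be a fixed multiple of |log2fc|
    ratio = np.abs(stats.norm.isf(tab.raw_p / 2)) / np.abs(tab.log2fc)
    assert np.nanstd(ratio) / np.nanmean(ratio) < 1e-3


def test_moderated_null_calibration(samples24):
    y = _random_logmatrix(2000, samples24, seed=3)
    x = design_matrix(samples24)
    tab = fit_moderated_lm(y, x)
    frac = (tab.raw_p < 0.05).mean()
    assert abs(frac - 0.05) < 0.015


def test_moderated_constant_feature_flagged(samples24):
    y = _random_logmatrix(20, samples24, seed=4)
    y.iloc[0] = 3.14
    tab = fit_moderated_lm(y, design_matrix(samples24))
    assert tab.raw_p.iloc[0] == 1.0
    assert tab.log2fc.iloc[0] == 0.0
    assert not tab.converged.iloc[0]


def test_moderated_power_on_planted_effect(samples24):
    y = _random_logmatrix(300, samples24, seed=5)
    y.iloc[:30, :12] += 2.0
    tab = fit_moderated_lm(y, design_matrix(samples24))
    assert (tab.adj_p.iloc[:30] < 0.05).mean() > 0.9
    assert (tab.log2fc.iloc[:30] > 0).all()


# --------------------------------------------------------------------- NB GLM

def test_size_factors_identical_samples():
    counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
    np.testing.assert_allclose(size_factors(counts), 1.0)


def test_size_factors_doubled_library():
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=200)
    counts = pd.DataFrame({"s1": base, "s2": 2 * base})
    sf = size_factors(counts)
    np.testing.assert_allclose(sf["s2"] / sf["s1"], 2.0, rtol=1e-12)
    np.testing.assert_allclose(np.exp(np.mean(np.log(sf))), 1.0, rtol=1e-12)


def test_nb_log2fc_invariant_to_sample_scaling():
    cfg = SimConfig(n_genes=300, n_rna_case=10, n_rna_control=10, plex_count=2,
                    channels_per_plex=6, frac_low=0.0, seed=21,
                    age_effect_sd=0, pmi_effect_sd=0, rin_effect_sd=0)
    samples, truth = generate_cohort(cfg)
    counts = sim.simulate_counts(truth, samples, cfg)
    counts = low_count_filter(counts, samples["group"])
    x = design_matrix(samples)
    scaled = counts.copy()
    scaled.iloc[:, 0] = 3 * scaled.iloc[:, 0]
    # size factors absorb the scaling: the scaled sample's factor triples
    sf1, sf2 = size_factors(counts), size_factors(scaled)
    np.testing.assert_allclose((sf2 / sf1).iloc[0] / (sf2 / sf1).iloc[1], 3.0,
                               rtol=1e-9)
    # per-gene estimates shift only through the scaled sample's likelihood
    # weight; in aggregate the effects are stable
    tab1 = fit_nb_glm(counts, x)
    tab2 = fit_nb_glm(scaled, x)
    assert (tab1.log2fc - tab2.log2fc).abs().mean() < 0.05
    assert np.corrcoef(tab1.log2fc, tab2.log2fc)[0, 1] > 0.99


def test_nb_null_calibration_and_planted_recovery():
    cfg = SimConfig(n_genes=1000, n_rna_case=20, n_rna_control=20, plex_count=2,
                    frac_de_rna=0.0, frac_low=0.0, seed=22,
                    age_effect_sd=0, pmi_effect_sd=0, rin_effect_sd=0)
    samples, truth = generate_cohort(cfg)
    counts = sim.simulate_counts(truth, samples, cfg)
    counts = low_count_filter(counts, samples["group"])
    tab = fit_nb_glm(counts, design_matrix(samples))
    assert abs((tab.raw_p < 0.05).mean() - 0.05) < 0.02

    cfg2 = SimConfig(n_genes=1000, n_rna_case=20, n_rna_control=20, plex_count=2,
                     frac_low=0.0, seed=23,
                     age_effect_sd=0, pmi_effect_sd=0, rin_effect_sd=0)
    samples2, truth2 = generate_cohort(cfg2)
    planted = truth2.genes.true_log2fc_rna != 0
    truth2.genes.loc[planted, "true_log2fc_rna"] = 1.0
    counts2 = sim.simulate_counts(truth2, samples2, cfg2)
    counts2 = low_count_filter(counts2, samples2["group"])
    tab2 = fit_nb_glm(counts2, design_matrix(samples2))
    idx = truth2.genes.index[planted].intersection(tab2.index)
    assert abs(tab2.loc[idx, "log2fc"].mean() - 1.0) < 0.1


# ----------------------------------------------------------- multiple testing

def test_bh_closed_form_and_single():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.4]), [0.4])


def _bh_brute(p):
    p = np.asarray(p)
    m = len(p)
    adj = np.empty(m)
    order = np.argsort(p)
    for i_rank, i in enumerate(order):
        candidates = [
            min(m * p[j] / (list(order).index(j) + 1), 1.0)
            for j in order[i_rank:]
        ]
        adj[i] = min(candidates)
    return adj


def test_bh_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    p = rng.uniform(1e-6, 1, size=300)
    np.testing.assert_allclose(bh_adjust(p), _bh_brute(p), rtol=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
def test_bh_monotone_and_bounded(p):
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_qvalue_reduces_to_bh_when_pi0_one():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=500)
    np.testing.assert_allclose(qvalue(p, pi0=1.0), bh_adjust(p), rtol=1e-12)


def test_qvalue_pi0_null_and_mixture():
    rng = np.random.default_rng(3)
    p_null = rng.uniform(size=10_000)
    assert abs(estimate_pi0(p_null) - 1.0) < 0.05
    p_mix = np.concatenate([rng.uniform(size=8_000), rng.beta(0.05, 10, size=2_000)])
    p_mix = np.clip(p_mix, 1e-300, 1.0)
    assert abs(estimate_pi0(p_mix) - 0.8) < 0.05


def test_qvalue_never_exceeds_bh():
    rng = np.random.default_rng(4)
    p = np.concatenate([rng.uniform(size=500), rng.beta(0.1, 10, size=100)])
    p = np.clip(p, 1e-300, 1.0)
    q = qvalue(p)
    assert np.all(q <= bh_adjust(p) + 1e-12)


@pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]])
def test_invalid_pvalues_rejected(bad):
    with pytest.raises(ValueError):
        bh_adjust(bad)


def test_rank_deficient_design_raises(samples24):
    y = _random_logmatrix(10, samples24)
    x = design_matrix(samples24)
    x["dup"] = x["group"]
    with pytest.raises(DesignError):
        fit_moderated_lm(y, x)
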