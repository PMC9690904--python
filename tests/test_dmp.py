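"""The per-probe linear model, eBayes moderation and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import episig as es
from episig.dmp import LinearFit, ebayes_moderate, fit_linear_model


def _sheet(groups):
    return pd.DataFrame({"group": groups}, index=[f"s{i}" for i in range(len(groups))])


def test_two_group_fit_matches_pooled_t():
    m = pd.DataFrame(
        [[1.0, 2.0, 3.0, 0.0, 0.0, 0.0], [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]],
        index=["a", "b"],
        columns=[f"s{i}" for i in range(6)],
    )
    sheet = _sheet(["case"] * 3 + ["control"] * 3)
    fit = fit_linear_model(m, sheet)
    assert fit.effect["a"] == pytest.approx(2.0)
    t_ref = stats.ttest_ind([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], equal_var=True).statistic
    assert fit.t_ordinary["a"] == pytest.approx(t_ref)
    assert fit.df_residual == 4


def test_fit_invariant_to_sample_and_probe_order():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(
        rng.normal(size=(30, 12)),
        index=[f"p{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(12)],
    )
    sheet = _sheet(["case"] * 6 + ["control"] * 6)
    sheet["age"] = rng.integers(5, 50, 12)
    base = fit_linear_model(m, sheet, ("age",))
    perm = rng.permutation(12)
    shuffled = fit_linear_model(m.iloc[::-1, perm], sheet, ("age",))
    pd.testing.assert_series_equal(
        base.effect.sort_index(), shuffled.effect.sort_index()
    )
    pd.testing.assert_series_equal(base.s2.sort_index(), shuffled.s2.sort_index())


def test_rank_deficient_design_names_collinear_columns():
    m = pd.DataFrame(np.zeros((3, 8)), columns=[f"s{i}" for i in range(8)])
    sheet = _sheet(["case"] * 4 + ["control"] * 4)
    sheet["constant"] = 1.0  # collinear with the intercept
    with pytest.raises(ValueError, match="constant"):
        fit_linear_model(m, sheet, ("constant",))


def test_moderation_degenerate_prior_keeps_variances():
    idx = pd.Index([f"p{i}" for i in range(10)])
    fit = LinearFit(
        effect=pd.Series(1.0, index=idx),
        s2=pd.Series(0.25, index=idx),
        df_residual=8,
        t_ordinary=pd.Series(2.0, index=idx),
        stdev_unscaled=1.0,
    )
    mod = ebayes_moderate(fit)
    assert np.allclose(mod["s2_post"], 0.25)


def test_moderation_off_reproduces_ordinary_t():
    rng = np.random.default_rng(2)
    idx = pd.Index([f"p{i}" for i in range(200)])
    s2 = pd.Series(rng.chisquare(8, 200) / 8, index=idx)
    eff = pd.Series(rng.normal(size=200), index=idx)
    fit = LinearFit(
        effect=eff, s2=s2, df_residual=8,
        t_ordinary=eff / np.sqrt(s2), stdev_unscaled=1.0,
    )
    mod = ebayes_moderate(fit, df_prior=0)
    assert np.allclose(mod["t_moderated"], fit.t_ordinary)


def test_moderation_shrinks_toward_the_prior():
    rng = np.random.default_rng(3)
    idx = pd.Index([f"p{i}" for i in range(2000)])
    s2 = pd.Series(0.5 * rng.chisquare(6, 2000) / 6, index=idx)
    eff = pd.Series(rng.normal(size=2000), index=idx)
    fit = LinearFit(
        effect=eff, s2=s2, df_residual=6,
        t_ordinary=eff / np.sqrt(s2), stdev_unscaled=1.0,
    )
    mod = ebayes_moderate(fit)
    s2_prior = mod["s2_prior"].iloc[0]
    smaller = (s2 < s2_prior).to_numpy()
    shrunk = (np.abs(mod["t_moderated"]) < np.abs(fit.t_ordinary)).to_numpy()
    assert np.array_equal(shrunk, smaller)


def test_moderated_p_values_are_uniform_under_the_null():
    rng = np.random.default_rng(4)
    n_probes, n = 5000, 16
    m = pd.DataFrame(
        rng.normal(size=(n_probes, n)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{i}" for i in range(n)],
    )
    sheet = _sheet(["case"] * 8 + ["control"] * 8)
    fit = fit_linear_model(m, sheet)
    mod = ebayes_moderate(fit)
    assert stats.kstest(mod["p_value"], "uniform").pvalue > 0.01


def test_moderation_rejects_nonpositive_variances():
    idx = pd.Index(["a", "b"])
    fit = LinearFit(
        effect=pd.Series(1.0, index=idx),
        s2=pd.Series([0.1, 0.0], index=idx),
        df_residual=5,
        t_ordinary=pd.Series(1.0, index=idx),
        stdev_unscaled=1.0,
    )
    with pytest.raises(ValueError):
        ebayes_moderate(fit)


def _bh_bruteforce(p):
    """O(n^2) reference: adj_i = min over p_j >= p_i of n*p_j/rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    ranks = np.array([(p <= v).sum() for v in p])
    out = np.empty(n)
    for i in range(n):
        cands = [n * p[j] / ranks[j] for j in range(n) if p[j] >= p[i]]
        out[i] = min(1.0, min(cands))
    return out


def test_bh_hand_example_and_edge_cases():
    assert np.allclose(es.adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
    assert es.adjust_bh(np.array([0.4]))[0] == pytest.approx(0.4)
    with pytest.raises(ValueError):
        es.adjust_bh(np.array([1.5]))


@pytest.mark.parametrize("n,seed", [(10, 0), (100, 1), (1000, 2)])
def test_bh_equals_bruteforce_and_statsmodels(n, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    p[: n // 5] = rng.uniform(0, 1e-3, size=n // 5)  # some strong signals
    ours = es.adjust_bh(p)
    assert np.allclose(ours, _bh_bruteforce(p))
    from statsmodels.stats.multitest import multipletests
    assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])


def test_delta_beta_basics():
    beta = pd.DataFrame(
        {"c1": [0.4, 0.7], "c2": [0.4, 0.7], "k1": [0.5, 0.7], "k2": [0.5, 0.7]},
        index=["a", "b"],
    )
    d = es.delta_beta(beta, ["c1", "c2"], ["k1", "k2"])
    assert d["a"] == pytest.approx(-0.10)
    assert d["b"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        es.delta_beta(beta, [], ["k1"])


def test_delta_beta_recovers_planted_effects(small_dataset):
    ds = small_dataset
    ctrl = list(ds.samples.index[ds.samples["role"] == "control"])
    d = es.delta_beta(ds.beta, ds.truth.case_ids, ctrl).loc[ds.truth.signature_probe_ids]
    resid = d - ds.truth.delta
    se = resid.std() / np.sqrt(len(resid))
    assert abs(resid.mean()) < 3 * se + 0.005
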