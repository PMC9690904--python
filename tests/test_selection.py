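"""Three-step probe selection, clustering diagnostics and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

import episig as es
from episig.selection import _auc_folded, mds_diagnostic, hierarchical_diagnostic


def _dmp_frame(delta, p):
    ids = [f"p{i}" for i in range(len(delta))]
    return pd.DataFrame({"delta_beta": delta, "p_value": p}, index=ids)


def test_step1_score_is_product_of_delta_and_log_p():
    # |0.10| * 4 = 0.4 beats |0.20| * 1 = 0.2
    dmp = _dmp_frame([0.10, 0.20], [1e-4, 1e-1])
    assert es.select_step1_product(dmp, k1=1)[0] == "p0"


def test_step1_identity_when_k1_covers_everything():
    rng = np.random.default_rng(0)
    dmp = _dmp_frame(rng.uniform(-0.2, 0.2, 50), rng.uniform(size=50))
    assert set(es.select_step1_product(dmp, k1=50)) == set(dmp.index)
    assert set(es.select_step1_product(dmp, k1=999)) == set(dmp.index)


def test_step1_reduces_to_delta_ranking_for_equal_p():
    dmp = _dmp_frame([0.05, 0.30, 0.10, 0.20], [0.01] * 4)
    assert es.select_step1_product(dmp, k1=2) == ["p1", "p3"]


def test_step1_handles_zero_p():
    dmp = _dmp_frame([0.1, 0.2], [0.0, 0.5])
    ids = es.select_step1_product(dmp, k1=2)
    assert ids[0] == "p0"  # floored, not crashed


def _labelled_beta(n_probes, n_case, n_ctrl, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
    beta = pd.DataFrame(
        rng.uniform(size=(n_probes, n_case + n_ctrl)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=cols,
    )
    labels = pd.Series([c.startswith("c") for c in cols], index=cols)
    return beta, labels


def test_step2_perfect_separation_gives_auc_one():
    beta, labels = _labelled_beta(3, 4, 6, seed=1)
    beta.loc["p1", labels] = [0.1, 0.12, 0.15, 0.11]
    beta.loc["p1", ~labels] = [0.5, 0.6, 0.7, 0.8, 0.9, 0.55]
    kept, auc = es.select_step2_auc(beta, labels, ["p0", "p1", "p2"], k2=1)
    assert kept == ["p1"]
    assert auc["p1"] == pytest.approx(1.0)


def test_step2_rejects_single_class():
    beta, labels = _labelled_beta(3, 4, 6)
    with pytest.raises(ValueError):
        es.select_step2_auc(beta, labels & False, list(beta.index), k2=2)


def _auc_pair_count(x, case_mask):
    """O(n^2) all-pairs oracle: wins + half ties over case/control pairs."""
    cases, ctrls = x[case_mask], x[~case_mask]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in ctrls)
    return wins / (len(cases) * len(ctrls))


@pytest.mark.parametrize("seed", range(5))
def test_step2_auc_equals_bruteforce_pair_count(seed):
    rng = np.random.default_rng(seed)
    n_case, n_ctrl = rng.integers(3, 10), rng.integers(3, 11)
    beta, labels = _labelled_beta(20, n_case, n_ctrl, seed=seed)
    # inject ties to exercise the rank correction
    beta.iloc[0] = np.round(beta.iloc[0] * 4) / 4
    lab = labels.to_numpy()
    auc = _auc_folded(beta, lab)
    for p in beta.index:
        raw = _auc_pair_count(beta.loc[p].to_numpy(), lab)
        assert auc[p] == pytest.approx(max(raw, 1 - raw))


def test_step2_null_folded_auc_matches_monte_carlo_oracle():
    rng = np.random.default_rng(7)
    n_case, n_ctrl = 12, 36
    beta, labels = _labelled_beta(2000, n_case, n_ctrl, seed=7)
    mean_auc = _auc_folded(beta, labels.to_numpy()).mean()
    # independent oracle: folded AUC of pure-noise probes by pair counting
    sims = []
    for _ in range(2000):
        x = rng.normal(size=n_case + n_ctrl)
        raw = _auc_pair_count(x, labels.to_numpy())
        sims.append(max(raw, 1 - raw))
    assert mean_auc == pytest.approx(np.mean(sims), abs=0.01)
    assert mean_auc > 0.5


def test_step3_keeps_one_of_two_duplicates():
    beta, _ = _labelled_beta(4, 3, 5, seed=3)
    beta.loc["p2"] = beta.loc["p0"]
    kept = es.select_step3_decorrelate(beta, ["p0", "p2", "p1", "p3"], r_cut=0.6)
    assert "p0" in kept and "p2" not in kept


def test_step3_keeps_orthogonal_probes():
    beta = pd.DataFrame(np.eye(4) * 0.5 + 0.25, index=list("abcd"))
    kept = es.select_step3_decorrelate(beta, list("abcd"), r_cut=0.6)
    assert kept == list("abcd")


def test_step3_warns_and_drops_zero_variance():
    beta, _ = _labelled_beta(3, 3, 5, seed=5)
    beta.loc["p1"] = 0.5
    with pytest.warns(UserWarning, match="zero variance"):
        kept = es.select_step3_decorrelate(beta, ["p0", "p1", "p2"], r_cut=0.9)
    assert "p1" not in kept


def _greedy_oracle(beta, order, r_cut):
    corr = np.corrcoef(beta.loc[order].to_numpy())
    kept = []
    for i in range(len(order)):
        if all(abs(corr[i, j]) <= r_cut for j in kept):
            kept.append(i)
    return [order[i] for i in kept]


@pytest.mark.parametrize("seed", range(5))
def test_step3_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(3, 40))
    mix = rng.uniform(-1, 1, size=(10, 3)) @ base + 0.3 * rng.normal(size=(10, 40))
    beta = pd.DataFrame(mix, index=[f"p{i}" for i in range(10)])
    order = list(beta.index)
    assert es.select_step3_decorrelate(beta, order, 0.6) == _greedy_oracle(beta, order, 0.6)


def test_final_set_shrinks_with_r_cut(small_dataset, small_discovery):
    _, disc = small_discovery
    beta = disc.beta_filtered
    train = disc.model.train_case_ids + disc.matched_control_ids
    labels = pd.Series([s in disc.model.train_case_ids for s in train], index=train)
    sizes = []
    for r_cut in (0.9, 0.6, 0.3, 0.1):
        sig = es.select_episignature(beta[train], disc.dmp, labels, r_cut=r_cut)
        sizes.append(len(sig))
    assert sizes == sorted(sizes, reverse=True)


def test_selection_invariant_to_input_order(small_dataset, small_discovery):
    _, disc = small_discovery
    beta = disc.beta_filtered
    train = disc.model.train_case_ids + disc.matched_control_ids
    labels = pd.Series([s in disc.model.train_case_ids for s in train], index=train)
    a = es.select_episignature(beta[train], disc.dmp, labels)
    rng = np.random.default_rng(0)
    perm_rows = rng.permutation(len(beta))
    perm_cols = rng.permutation(train)
    b = es.select_episignature(
        beta.iloc[perm_rows][perm_cols], disc.dmp.iloc[perm_rows], labels
    )
    assert a.probes == b.probes


def test_k2_must_not_exceed_k1(small_discovery):
    _, disc = small_discovery
    labels = pd.Series(True, index=disc.beta_filtered.columns[:4])
    with pytest.raises(ValueError, match="k2"):
        es.select_episignature(disc.beta_filtered.iloc[:, :4], disc.dmp, labels, k1=10, k2=20)


def test_hierarchical_separates_planted_classes(small_dataset, small_discovery):
    _, disc = small_discovery
    cases = disc.model.train_case_ids
    train = cases + disc.matched_control_ids
    labels = pd.Series([s in cases for s in train], index=train)
    diag = hierarchical_diagnostic(disc.beta_filtered[train], disc.probe_set.probes, labels)
    assert diag.purity == 1.0


def test_hierarchical_purity_near_chance_without_signal():
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(
        rng.uniform(size=(40, 30)),
        index=[f"p{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(30)],
    )
    labels = pd.Series([i < 10 for i in range(30)], index=beta.columns)
    diag = hierarchical_diagnostic(beta, list(beta.index), labels)
    # majority class is 2/3 of samples; purity cannot go below that and
    # should not approach perfect separation
    assert 2 / 3 <= diag.purity < 0.95


def test_mds_equilateral_triangle():
    beta = pd.DataFrame(
        np.array([[0.0, 1.0, 0.5], [0.0, 0.0, np.sqrt(3) / 2]]),
        index=["p0", "p1"],
        columns=["a", "b", "c"],
    )
    out = mds_diagnostic(beta, ["p0", "p1"])
    d = pdist(out.coords.to_numpy())
    assert np.allclose(d, d[0], atol=1e-9)
    assert out.stress == pytest.approx(0.0, abs=1e-9)


def test_mds_exactly_embeds_rank_two_configurations():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(8, 2))
    beta = pd.DataFrame(coords.T, index=["p0", "p1"], columns=[f"s{i}" for i in range(8)])
    out = mds_diagnostic(beta, ["p0", "p1"])
    assert np.allclose(pdist(out.coords.to_numpy()), pdist(coords), atol=1e-9)


def test_mds_separates_planted_classes(small_dataset, small_discovery):
    _, disc = small_discovery
    cases = disc.model.train_case_ids
    train = cases + disc.matched_control_ids
    out = mds_diagnostic(disc.beta_filtered[train], disc.probe_set.probes)
    labels = [s in cases for s in train]
    assert silhouette_score(out.coords.to_numpy(), labels) > 0.5


def test_cross_validation_is_deterministic(small_dataset, small_discovery):
    cfg, disc = small_discovery
    ds = small_dataset
    cases = disc.model.train_case_ids
    kwargs = dict(
        rounds=2, seed=5, k1=cfg.k1, k2=cfg.k2, r_cut=cfg.r_cut,
        min_delta=cfg.min_delta, max_adj_p=cfg.max_adj_p,
    )
    a = es.cross_validate(
        disc.beta_filtered, disc.m_filtered, ds.samples, cases,
        disc.matched_control_ids, cfg.covariates, **kwargs,
    )
    b = es.cross_validate(
        disc.beta_filtered, disc.m_filtered, ds.samples, cases,
        disc.matched_control_ids, cfg.covariates, **kwargs,
    )
    pd.testing.assert_frame_equal(a.records, b.records)


def test_cross_validation_requires_enough_cases(small_dataset, small_discovery):
    cfg, disc = small_discovery
    with pytest.raises(ValueError, match="rounds"):
        es.cross_validate(
            disc.beta_filtered, disc.m_filtered, small_dataset.samples,
            disc.model.train_case_ids, disc.matched_control_ids, rounds=0,
        )
    with pytest.raises(ValueError, match="case"):
        es.cross_validate(
            disc.beta_filtered, disc.m_filtered, small_dataset.samples,
            disc.model.train_case_ids[:3], disc.matched_control_ids,
        )
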