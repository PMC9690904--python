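"""Probe/sample QC, the beta<->M transform and control matching."""

import numpy as np
import pandas as pd
import pytest

import episig as es


def _toy_tables():
    """10 probes: 2 on chrX, 1 SNP-flagged, 1 failing detection in one
    sample (all distinct probes)."""
    probes = [f"p{i}" for i in range(10)]
    samples = ["s1", "s2", "s3"]
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (10, 3)), index=probes, columns=samples)
    detp = pd.DataFrame(np.zeros((10, 3)), index=probes, columns=samples)
    detp.loc["p5", "s2"] = 0.2
    manifest = pd.DataFrame(
        {
            "chrom": ["1", "1", "X", "X", "2", "2", "3", "3", "4", "4"],
            "pos": range(100, 1100, 100),
            "snp_flag": [False] * 10,
            "crossreactive_flag": [False] * 10,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    manifest.loc["p6", "snp_flag"] = True
    return beta, detp, manifest


def test_filter_probes_toy_counts():
    beta, detp, manifest = _toy_tables()
    out, report = es.filter_probes(beta, detp, manifest)
    assert report.per_rule["chrX"] == 2
    assert report.per_rule["snp"] == 1
    assert report.per_rule["detection_p"] == 1
    assert report.per_rule["chrY"] == 0
    assert report.removed_union == 4
    assert report.n_remaining == 6 == len(out)
    assert report.n_input == 10


def test_filter_probes_union_counts_double_flagged_probe_once():
    beta, detp, manifest = _toy_tables()
    manifest.loc["p2", "snp_flag"] = True  # chrX AND snp
    out, report = es.filter_probes(beta, detp, manifest)
    assert report.per_rule["chrX"] == 2
    assert report.per_rule["snp"] == 2  # tallied in both rules
    assert report.removed_union == 4  # but removed once
    assert len(out) == 6


def test_filter_probes_identity_when_clean():
    beta, detp, manifest = _toy_tables()
    manifest["snp_flag"] = False
    manifest["chrom"] = "1"
    detp[:] = 0.0
    out, report = es.filter_probes(beta, detp, manifest)
    assert len(out) == 10
    assert all(v == 0 for v in report.per_rule.values())


def test_filter_probes_is_idempotent():
    beta, detp, manifest = _toy_tables()
    once, _ = es.filter_probes(beta, detp, manifest)
    twice, report2 = es.filter_probes(once, detp.loc[once.index], manifest)
    assert report2.removed_union == 0
    pd.testing.assert_frame_equal(once, twice)


def test_filter_probes_rejects_misaligned_inputs():
    beta, detp, manifest = _toy_tables()
    with pytest.raises(ValueError, match="not aligned"):
        es.filter_probes(beta, detp.iloc[:-1], manifest)
    with pytest.raises(ValueError, match="manifest"):
        es.filter_probes(beta, detp, manifest.iloc[:-1])


def test_qc_samples_uses_strictly_more_than_rule():
    probes = [f"p{i}" for i in range(1000)]
    detp = pd.DataFrame(0.0, index=probes, columns=["exact5", "over5", "clean"])
    detp.loc[probes[:50], "exact5"] = 0.2  # exactly 5.0% failed
    detp.loc[probes[:60], "over5"] = 0.2  # 6% failed
    assert es.qc_samples(detp) == ["over5"]
    detp[:] = 0.0
    assert es.qc_samples(detp) == []
    with pytest.raises(ValueError):
        es.qc_samples(detp.iloc[:0])


def test_beta_to_m_closed_forms_and_roundtrip():
    beta = pd.DataFrame({"s": [0.5, 0.8, 0.2]}, index=["a", "b", "c"])
    m = es.beta_to_m(beta)
    assert m.loc["a", "s"] == pytest.approx(0.0)
    assert m.loc["b", "s"] == pytest.approx(2.0)
    assert m.loc["c", "s"] == pytest.approx(-2.0)
    rng = np.random.default_rng(1)
    b = pd.DataFrame(rng.uniform(1e-5, 1 - 1e-5, (50, 4)))
    assert np.allclose(es.m_to_beta(es.beta_to_m(b)), b, atol=1e-9)
    with pytest.raises(ValueError):
        es.beta_to_m(pd.DataFrame({"s": [1.2]}))


def _sheets(n_cases=4, n_pool=40, seed=0):
    rng = np.random.default_rng(seed)
    cases = pd.DataFrame(
        {
            "sex": ["F", "F", "M", "M"][:n_cases],
            "array": "EPIC",
            "age": rng.integers(5, 40, n_cases),
        },
        index=[f"case{i}" for i in range(n_cases)],
    )
    pool = pd.DataFrame(
        {
            "sex": ["F", "M"] * (n_pool // 2),
            "array": "EPIC",
            "age": rng.integers(5, 40, n_pool),
        },
        index=[f"ctrl{i}" for i in range(n_pool)],
    )
    return cases, pool


def test_matching_respects_ratio_and_exact_strata():
    cases, pool = _sheets()
    picked = es.match_controls(cases, pool, ratio=5, seed=3)
    assert len(picked) == 20
    assert len(set(picked)) == 20  # without replacement
    sexes = pool.loc[picked, "sex"].value_counts()
    assert sexes["F"] == 10 and sexes["M"] == 10  # cases' sex distribution x5


def test_matching_finds_exact_age_duplicates():
    cases, pool = _sheets()
    pool.loc["ctrl0", ["sex", "age"]] = ["F", cases.loc["case0", "age"]]
    pool.loc["ctrl2", ["sex", "age"]] = ["F", cases.loc["case1", "age"]]
    pool.loc["ctrl1", ["sex", "age"]] = ["M", cases.loc["case2", "age"]]
    pool.loc["ctrl3", ["sex", "age"]] = ["M", cases.loc["case3", "age"]]
    picked = es.match_controls(cases, pool, ratio=1, seed=0)
    ages = pool.loc[picked, "age"].sort_values().to_numpy()
    assert np.array_equal(ages, np.sort(cases["age"].to_numpy()))


def test_matching_errors_on_insufficient_stratum():
    cases, pool = _sheets()
    pool = pool[pool["sex"] == "M"]  # no female controls left
    with pytest.raises(ValueError, match="insufficient"):
        es.match_controls(cases, pool, ratio=2, seed=0)


def test_matching_is_deterministic_and_age_optimal():
    rng = np.random.default_rng(9)
    cases = pd.DataFrame(
        {"sex": "F", "array": "EPIC", "age": rng.integers(5, 60, 10)},
        index=[f"c{i}" for i in range(10)],
    )
    pool = pd.DataFrame(
        {"sex": "F", "array": "EPIC", "age": rng.integers(5, 60, 80)},
        index=[f"k{i}" for i in range(80)],
    )
    a = es.match_controls(cases, pool, ratio=3, seed=4)
    b = es.match_controls(cases, pool, ratio=3, seed=4)
    assert a == b
    # matched controls are closer in age than random subsets of equal size
    matched_err = np.abs(
        np.sort(pool.loc[a, "age"].to_numpy()) .mean() - cases["age"].mean()
    )
    matched_mean_gap = _mean_min_gap(pool.loc[a, "age"].to_numpy(), cases["age"].to_numpy())
    rand_gaps = []
    for s in range(30):
        sub = rng.choice(pool.index, size=len(a), replace=False)
        rand_gaps.append(_mean_min_gap(pool.loc[sub, "age"].to_numpy(), cases["age"].to_numpy()))
    assert matched_mean_gap <= min(rand_gaps) + 1e-9


def _mean_min_gap(ctrl_ages, case_ages):
    return float(np.mean([np.abs(ctrl_ages - a).min() for a in case_ages]))
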