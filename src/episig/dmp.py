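"""Per-probe differential methylation on M-values.

Each probe is fit by ordinary least squares, ``M ~ group + covariates``,
with estimated blood-cell proportions entering as confounder columns.
Probe-wise residual variances are then shrunk toward a common prior by the
empirical-Bayes scheme of moderated t-statistics: a scaled
inverse-chi-square prior is fitted to the observed variances by the
closed-form moments-of-log-variance method, giving

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod   = effect / (se_unscaled * s_post),   df = d + d0

Moderation borrows strength across probes so that probes with accidentally
tiny residual variance do not dominate the ranking. Effect sizes are also
reported on the beta scale (mean case-control beta difference), which is the
scale on which episignature effect-size floors are stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "LinearFit",
    "fit_linear_model",
    "ebayes_moderate",
    "adjust_bh",
    "delta_beta",
    "run_dmp",
]

_DF_PRIOR_CAP = 1e6


@dataclass
class LinearFit:
    """Per-probe OLS results for the group contrast."""

    effect: pd.Series  # group (case - control) coefficient on the M scale
    s2: pd.Series  # residual variance
    df_residual: int
    t_ordinary: pd.Series
    stdev_unscaled: float  # sqrt of the group-coefficient entry of (X'X)^-1


def _design_matrix(
    sample_sheet: pd.DataFrame,
    covariate_names: tuple[str, ...],
    group_col: str,
    case_label: str,
) -> tuple[np.ndarray, list[str]]:
    n = len(sample_sheet)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append((sample_sheet[group_col] == case_label).to_numpy(float))
    names.append(group_col)
    for name in covariate_names:
        col = sample_sheet[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            for lev in levels[1:]:  # drop first level
                cols.append((col == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    return np.column_stack(cols), names


def fit_linear_model(
    m: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    covariate_names: tuple[str, ...] = (),
    group_col: str = "group",
    case_label: str = "case",
) -> LinearFit:
    """OLS of M ~ group + covariates, probe by probe (vectorized).

    ``sample_sheet`` must be indexed by sample id and cover every column of
    ``m``. Categorical covariates (e.g. sex) are dummy-encoded dropping the
    first level. Results are invariant to probe-row and sample-column order.
    """
    sheet = sample_sheet.loc[m.columns]
    x, names = _design_matrix(sheet, tuple(covariate_names), group_col, case_label)
    n, p = x.shape
    if n - p < 1:
        raise ValueError(f"not enough samples ({n}) for {p} design columns")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        bad = []
        kept: list[int] = []
        for j in range(p):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    groups = sheet[group_col].value_counts()
    if groups.get(case_label, 0) < 2 or (n - groups.get(case_label, 0)) < 2:
        raise ValueError("need at least 2 samples in each group")

    y = np.asarray(m, dtype=float).T  # samples x probes
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)  # p x probes
    resid = y - x @ coef
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    c_gg = xtx_inv[1, 1]
    se = np.sqrt(np.maximum(s2, 0.0) * c_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[1] / se, 0.0)
    idx = m.index
    return LinearFit(
        effect=pd.Series(coef[1], index=idx, name="effect"),
        s2=pd.Series(s2, index=idx, name="s2"),
        df_residual=df,
        t_ordinary=pd.Series(t, index=idx, name="t_ordinary"),
        stdev_unscaled=float(np.sqrt(c_gg)),
    )


def _trigamma_inverse(y: np.ndarray | float, iters: int = 50) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(iters):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def ebayes_moderate(
    fit: LinearFit,
    df_prior: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes variance moderation of a per-probe linear fit.

    The prior (df_prior, s2_prior) is estimated from the marginal
    distribution of log residual variances; pass ``df_prior=0`` to disable
    moderation (t_moderated then equals t_ordinary). When the observed
    variances are (nearly) identical the prior degrees of freedom diverge;
    they are capped at 1e6 and the posterior variances collapse onto the
    common value.
    """
    s2 = fit.s2.to_numpy(float)
    if np.any(s2 <= 0):
        raise ValueError("all residual variances must be positive")
    df = fit.df_residual

    if df_prior is None:
        z = np.log(s2)
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        ebar = e.mean()
        n = len(e)
        evar = np.sum((e - ebar) ** 2) / (n - 1) if n > 1 else 0.0
        target = evar - special.polygamma(1, df / 2.0)
        if n > 1 and target > 0:
            d0 = 2.0 * float(_trigamma_inverse(target))
            d0 = min(d0, _DF_PRIOR_CAP)
            s2_prior = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            # (near-)identical variances: the prior collapses onto their
            # geometric mean so posteriors equal the observed values
            d0 = _DF_PRIOR_CAP
            s2_prior = float(np.exp(np.mean(z)))
    else:
        d0 = float(df_prior)
        s2_prior = float(np.exp(np.mean(np.log(s2))))

    if d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s2_prior + df * s2) / (d0 + df)
    se = fit.stdev_unscaled * np.sqrt(s2_post)
    t_mod = fit.effect.to_numpy(float) / se
    df_total = min(df + d0, _DF_PRIOR_CAP)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    return pd.DataFrame(
        {
            "t_moderated": t_mod,
            "p_value": p,
            "s2_post": s2_post,
        },
        index=fit.s2.index,
    ).assign(df_prior=d0, s2_prior=s2_prior)


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="p_adjusted")
    return out


def delta_beta(
    beta: pd.DataFrame, case_ids: list[str], control_ids: list[str]
) -> pd.Series:
    """Mean(case) - mean(control) per probe, on the beta scale."""
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("both groups must be non-empty")
    d = beta[list(case_ids)].mean(axis=1) - beta[list(control_ids)].mean(axis=1)
    d.name = "delta_beta"
    return d


def run_dmp(
    m: pd.DataFrame,
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    covariate_names: tuple[str, ...] = (),
    moderation: bool = True,
) -> pd.DataFrame:
    """Full per-probe differential-methylation table.

    Fits the linear model on the case + control columns of ``m``, moderates
    the statistics, BH-adjusts the p-values and attaches the beta-scale mean
    difference. Returns one row per probe with columns
    effect / delta_beta / t_ordinary / s2 / df_residual / t_moderated /
    p_value / p_adjusted.
    """
    samples = list(case_ids) + list(control_ids)
    sheet = sample_sheet.loc[samples].copy()
    sheet["group"] = ["case"] * len(case_ids) + ["control"] * len(control_ids)
    fit = fit_linear_model(m[samples], sheet, tuple(covariate_names))
    mod = ebayes_moderate(fit, df_prior=None if moderation else 0)
    out = pd.DataFrame(
        {
            "effect": fit.effect,
            "delta_beta": delta_beta(beta.loc[m.index], list(case_ids), list(control_ids)),
            "t_ordinary": fit.t_ordinary,
            "s2": fit.s2,
            "df_residual": fit.df_residual,
            "t_moderated": mod["t_moderated"],
            "p_value": mod["p_value"],
        }
    )
    out["p_adjusted"] = adjust_bh(out["p_value"])
    return out
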