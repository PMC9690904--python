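"""Differentially methylated region (DMR) calling.

Significant probes are chained along each chromosome whenever consecutive
probes lie within ``max_gap`` base pairs; a chain is reported as a DMR if it
contains at least ``min_cpgs`` probes, its mean beta-difference magnitude is
at least ``min_delta``, and the Fisher combination of its member p-values is
below ``max_p``. This is a self-contained region caller implementing those
criteria directly; no kernel smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DmrCall", "fisher_combine", "call_dmrs", "dmrs_to_frame", "dmrs_to_bed"]


@dataclass
class DmrCall:
    """One called region (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_delta_beta: float
    fisher_p: float
    direction: str  # "hypo" or "hyper"
    probe_ids: list[str]
    gene_context: str = ""


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def default_sig_rule(dmp: pd.DataFrame, max_adj_p: float = 0.05, min_delta: float = 0.05) -> pd.Series:
    """Default member-significance rule: BH-adjusted p < 0.05 and
    |delta beta| >= 0.05."""
    return (dmp["p_adjusted"] < max_adj_p) & (dmp["delta_beta"].abs() >= min_delta)


def call_dmrs(
    dmp: pd.DataFrame,
    manifest: pd.DataFrame,
    max_gap: int = 1000,
    min_cpgs: int = 5,
    min_delta: float = 0.05,
    max_p: float = 0.01,
    sig_rule: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> list[DmrCall]:
    """Chain significant probes into regions and filter by the DMR criteria.

    ``dmp`` must carry delta_beta / p_value / p_adjusted; chromosome and
    position come from the manifest. Input probe order is irrelevant
    (positions are sorted internally); duplicate positions are allowed.
    """
    rule = sig_rule or default_sig_rule
    sig = dmp[rule(dmp).to_numpy(bool)]
    if sig.empty:
        return []
    man = manifest.loc[sig.index]
    df = sig.assign(chrom=man["chrom"].to_numpy(), pos=man["pos"].to_numpy(np.int64))

    calls: list[DmrCall] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "p_value"], kind="stable")
        pos = grp["pos"].to_numpy(np.int64)
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            if len(chunk) < min_cpgs:
                continue
            sub = grp.iloc[chunk]
            mean_delta = float(sub["delta_beta"].mean())
            if abs(mean_delta) < min_delta:
                continue
            p_comb = fisher_combine(np.maximum(sub["p_value"].to_numpy(float), np.finfo(float).tiny))
            if p_comb >= max_p:
                continue
            calls.append(
                DmrCall(
                    chrom=str(chrom),
                    start=int(sub["pos"].min()),
                    end=int(sub["pos"].max()),
                    n_cpgs=len(sub),
                    mean_delta_beta=mean_delta,
                    fisher_p=float(p_comb),
                    direction="hypo" if mean_delta < 0 else "hyper",
                    probe_ids=[str(i) for i in sub.index],
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def dmrs_to_frame(calls: list[DmrCall]) -> pd.DataFrame:
    """Tabular view of the calls (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_cpgs": c.n_cpgs,
                "mean_delta_beta": c.mean_delta_beta,
                "fisher_p": c.fisher_p,
                "direction": c.direction,
            }
            for c in calls
        ]
    )


def dmrs_to_bed(calls: list[DmrCall]) -> str:
    """BED text (0-based half-open) for the calls."""
    lines = [
        f"{c.chrom}\t{c.start - 1}\t{c.end}\tdmr_{i + 1}\t{c.n_cpgs}\t{'-' if c.direction == 'hypo' else '+'}"
        for i, c in enumerate(calls)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
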