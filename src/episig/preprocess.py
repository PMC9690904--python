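"""Probe and sample QC, beta/M transformation, and matched-control selection.

The filtering rules mirror standard EPIC-array episignature practice: drop
probes that fail detection in any retained sample, probes on the sex
chromosomes, probes overlapping SNPs and cross-reactive probes; drop samples
with more than 5% failed probes. Beta values are mapped to M-values
(log2 logit) before linear modelling. Controls are matched to cases exactly
on sex and array type and by nearest-neighbour on age, at a configurable
case:control ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "filter_probes",
    "qc_samples",
    "beta_to_m",
    "m_to_beta",
    "match_controls",
    "pca_coordinates",
]


@dataclass
class FilterReport:
    """Per-rule and unique-union probe removal counts.

    A probe hit by several rules is tallied once per rule but removed once;
    ``removed_union + n_remaining == n_input``.
    """

    n_input: int
    per_rule: dict[str, int] = field(default_factory=dict)
    removed_union: int = 0
    n_remaining: int = 0
    removed_samples: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "per_rule": self.per_rule,
                "removed_union": self.removed_union,
                "n_remaining": self.n_remaining,
                "removed_samples": self.removed_samples,
            },
            indent=1,
        )


def _check_alignment(beta: pd.DataFrame, detp: pd.DataFrame, manifest: pd.DataFrame) -> None:
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        mism = beta.index.symmetric_difference(detp.index)
        first = mism[0] if len(mism) else "(column mismatch)"
        raise ValueError(f"beta and detection-p matrices are not aligned; first mismatch: {first}")
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise ValueError(f"manifest does not cover all probes; first missing: {missing[0]}")


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: pd.DataFrame,
    detp_threshold: float = 0.1,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove failed, sex-chromosome, SNP-overlapping and cross-reactive probes.

    A probe fails detection if its detection p-value exceeds the threshold in
    *any* sample of ``detp`` (run :func:`qc_samples` first and drop failed
    samples so a bad sample does not decimate the probe set).
    """
    _check_alignment(beta, detp, manifest)
    man = manifest.loc[beta.index]

    rules = {
        "detection_p": (detp > detp_threshold).any(axis=1).to_numpy(),
        "chrX": (man["chrom"] == "X").to_numpy(),
        "chrY": (man["chrom"] == "Y").to_numpy(),
        "snp": man["snp_flag"].to_numpy(bool),
        "crossreactive": man["crossreactive_flag"].to_numpy(bool),
    }
    union = np.zeros(len(beta), dtype=bool)
    per_rule = {}
    for name, mask in rules.items():
        per_rule[name] = int(mask.sum())
        union |= mask

    report = FilterReport(
        n_input=len(beta),
        per_rule=per_rule,
        removed_union=int(union.sum()),
        n_remaining=int((~union).sum()),
    )
    return beta.loc[~union], report


def qc_samples(
    detp: pd.DataFrame,
    max_failed_fraction: float = 0.05,
    detp_threshold: float = 0.1,
) -> list[str]:
    """Samples whose fraction of failed probes is strictly greater than
    ``max_failed_fraction`` (more-than-5% rule)."""
    if detp.size == 0:
        raise ValueError("detection-p matrix is empty")
    frac = (detp > detp_threshold).mean(axis=0)
    return list(frac.index[frac > max_failed_fraction])


def beta_to_m(beta: pd.DataFrame, clip: float = 1e-6) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)) after clipping betas to [clip, 1-clip]."""
    vals = np.asarray(beta, dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(vals, clip, 1.0 - clip)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (for betas inside the clip window)."""
    p = np.power(2.0, np.asarray(m, dtype=float))
    b = p / (1.0 + p)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def match_controls(
    case_sheet: pd.DataFrame,
    control_pool_sheet: pd.DataFrame,
    ratio: int = 5,
    exact_cols: tuple[str, ...] = ("sex", "array"),
    age_col: str = "age",
    seed: int = 0,
) -> list[str]:
    """Select ``ratio`` controls per case: exact on sex/array, nearest on age.

    Within each exact-match stratum, cases are processed in descending age
    order and greedily take their ``ratio`` nearest-age controls without
    replacement; ties (equal ages, equal distances) are broken by a seeded
    shuffle so the result is deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for key, cases in case_sheet.groupby(list(exact_cols), sort=True):
        pool = control_pool_sheet
        for col, val in zip(exact_cols, key if isinstance(key, tuple) else (key,)):
            pool = pool[pool[col] == val]
        if len(pool) < ratio * len(cases):
            raise ValueError(
                f"insufficient control pool in stratum {dict(zip(exact_cols, key if isinstance(key, tuple) else (key,)))}: "
                f"need {ratio * len(cases)}, have {len(pool)}"
            )
        pool_ids = pool.index.to_numpy()
        pool_ages = pool[age_col].to_numpy(float)
        tie = rng.permutation(len(pool_ids))
        available = np.ones(len(pool_ids), dtype=bool)

        case_order = cases.sort_values(age_col, ascending=False, kind="stable")
        case_tie = rng.permutation(len(case_order))
        case_order = case_order.iloc[np.lexsort((case_tie, -case_order[age_col].to_numpy(float)))]
        for _, case in case_order.iterrows():
            dist = np.abs(pool_ages - float(case[age_col]))
            order = np.lexsort((tie, dist))
            picked = [i for i in order if available[i]][:ratio]
            for i in picked:
                available[i] = False
                selected.append(str(pool_ids[i]))
    return selected


def pca_coordinates(m: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample PCA coordinates for batch/outlier inspection (diagnostic only;
    no decision rule is attached)."""
    x = np.asarray(m, dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    u, s_, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_components] * s_[:n_components]
    return pd.DataFrame(
        coords, index=m.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
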