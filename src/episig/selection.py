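"""Episignature probe selection and unsupervised diagnostics.

Probes are selected in three steps, applied to a candidate set of
differentially methylated probes:

1. keep the top ``k1`` probes by the product of the absolute beta-scale
   mean difference and -log10 of the (moderated) p-value;
2. keep the top ``k2`` by per-probe ROC AUC, computed as the Mann-Whitney U
   statistic over case/control pairs and folded so direction does not
   matter;
3. greedily drop probes whose Pearson correlation (absolute value) with any
   already-kept probe exceeds ``r_cut``, scanning in descending step-2 AUC
   order.

By default the candidate set entering step 1 is restricted to probes
passing a DMP evidence floor (BH-adjusted p and |delta beta| thresholds);
the three steps are otherwise pure top-k filters. The selected set is
assessed by Ward hierarchical clustering, classical multidimensional
scaling, and leave-25%-out cross-validation in which the whole selection is
re-run on each training split and held-out samples are assigned to the
nearer of the training case/control centroids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .dmp import run_dmp

__all__ = [
    "EpisignatureProbeSet",
    "select_step1_product",
    "select_step2_auc",
    "select_step3_decorrelate",
    "select_episignature",
    "hierarchical_diagnostic",
    "mds_diagnostic",
    "cross_validate",
]


@dataclass
class EpisignatureProbeSet:
    """Selected probes with per-stage provenance.

    ``table`` has one row per candidate probe (columns delta_beta, p_value,
    auc, step1, step2, step3); ``probes`` is the ordered final list
    (descending step-2 AUC).
    """

    probes: list[str]
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)


def select_step1_product(dmp: pd.DataFrame, k1: int = 1000) -> list[str]:
    """Top-``k1`` probes by |delta beta| * (-log10 p).

    Zero p-values are floored at the smallest positive normal float. Ties
    are broken by smaller p-value, then lexicographic probe id.
    """
    if k1 > len(dmp):
        k1 = len(dmp)
    p = np.maximum(dmp["p_value"].to_numpy(float), np.finfo(float).tiny)
    score = np.abs(dmp["delta_beta"].to_numpy(float)) * (-np.log10(p))
    order = np.lexsort((dmp.index.to_numpy(), p, -score))
    return [str(x) for x in dmp.index.to_numpy()[order][:k1]]


def _auc_folded(beta: pd.DataFrame, case_mask: np.ndarray) -> pd.Series:
    """Per-probe two-class AUC via the rank-sum identity, folded to >= 0.5."""
    x = np.asarray(beta, dtype=float)
    n1 = int(case_mask.sum())
    n2 = int((~case_mask).sum())
    ranks = rankdata(x, axis=1)
    u = ranks[:, case_mask].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    return pd.Series(np.maximum(auc, 1.0 - auc), index=beta.index, name="auc")


def select_step2_auc(
    beta: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str],
    k2: int = 500,
) -> tuple[list[str], pd.Series]:
    """Top-``k2`` candidate probes by folded per-probe ROC AUC.

    ``labels`` is a boolean Series (True = case) over the columns of
    ``beta``. Returns the retained ids (descending AUC, ties by probe id)
    and the AUC of every candidate.
    """
    lab = labels.loc[beta.columns].to_numpy(bool)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    sub = beta.loc[candidates]
    auc = _auc_folded(sub, lab)
    k2 = min(k2, len(candidates))
    order = np.lexsort((auc.index.to_numpy(), -auc.to_numpy()))
    kept = [str(x) for x in auc.index.to_numpy()[order][:k2]]
    return kept, auc


def select_step3_decorrelate(
    beta: pd.DataFrame,
    ranked_candidates: list[str],
    r_cut: float = 0.60,
) -> list[str]:
    """Greedy Pearson-correlation pruning in rank order.

    A probe is kept iff |r| with every already-kept probe is <= ``r_cut``,
    computed across the training samples. Zero-variance probes are excluded
    with a warning (their correlation is undefined).
    """
    x = beta.loc[ranked_candidates].to_numpy(float)
    n = x.shape[1]
    sd = x.std(axis=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    kept_idx: list[int] = []
    for i, probe in enumerate(ranked_candidates):
        if not ok[i]:
            warnings.warn(f"probe {probe} has zero variance; excluded from step 3")
            continue
        if kept_idx:
            r = z[kept_idx] @ z[i] / n
            if np.any(np.abs(r) > r_cut):
                continue
        kept_idx.append(i)
    return [ranked_candidates[i] for i in kept_idx]


def select_episignature(
    beta: pd.DataFrame,
    dmp: pd.DataFrame,
    labels: pd.Series,
    k1: int = 1000,
    k2: int = 500,
    r_cut: float = 0.60,
    min_delta: float | None = 0.05,
    max_adj_p: float | None = 0.01,
) -> EpisignatureProbeSet:
    """Run the three selection steps on the DMP table.

    ``min_delta`` / ``max_adj_p`` define the DMP evidence floor applied
    before step 1 (pass ``None`` for either to disable it). ``beta`` must
    contain exactly the training samples (cases + controls) indexed by
    ``labels``.
    """
    if k2 > k1:
        raise ValueError(f"k2 ({k2}) must not exceed k1 ({k1})")
    cand = dmp
    if max_adj_p is not None:
        cand = cand[cand["p_adjusted"] < max_adj_p]
    if min_delta is not None:
        cand = cand[cand["delta_beta"].abs() >= min_delta]

    step1 = select_step1_product(cand, k1)
    if len(step1) == 0:
        table = dmp.loc[[], ["delta_beta", "p_value"]].assign(
            auc=[], step1=[], step2=[], step3=[]
        )
        return EpisignatureProbeSet(probes=[], table=table, params=_params(k1, k2, r_cut, min_delta, max_adj_p))
    step2, auc = select_step2_auc(beta, labels, step1, k2)
    step3 = select_step3_decorrelate(beta, step2, r_cut)

    table = dmp.loc[step1, ["delta_beta", "p_value"]].copy()
    table["auc"] = auc
    table["step1"] = True
    table["step2"] = table.index.isin(step2)
    table["step3"] = table.index.isin(step3)
    return EpisignatureProbeSet(
        probes=step3, table=table, params=_params(k1, k2, r_cut, min_delta, max_adj_p)
    )


def _params(k1, k2, r_cut, min_delta, max_adj_p) -> dict:
    return {
        "k1": k1,
        "k2": k2,
        "r_cut": r_cut,
        "min_delta": min_delta,
        "max_adj_p": max_adj_p,
    }


@dataclass
class ClusterDiagnostic:
    linkage: np.ndarray
    clusters: pd.Series  # sample -> {1, 2}
    purity: float


def hierarchical_diagnostic(
    beta: pd.DataFrame, probes: list[str], labels: pd.Series
) -> ClusterDiagnostic:
    """Ward/Euclidean clustering of samples on the selected probes.

    The dendrogram is cut at two clusters; purity is the fraction of samples
    whose cluster's majority label matches their own. Ties in a cluster's
    majority vote are resolved toward the case label (documented
    tie-break; purity is symmetric in the two-cluster case regardless).
    """
    x = beta.loc[probes].to_numpy(float).T
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    assign = hierarchy.fcluster(link, t=2, criterion="maxclust")
    lab = labels.loc[beta.columns].to_numpy(bool)
    correct = 0
    for c in np.unique(assign):
        m = assign == c
        n_case = int(lab[m].sum())
        correct += max(n_case, int(m.sum()) - n_case) if n_case * 2 != m.sum() else n_case
    purity = correct / len(lab)
    return ClusterDiagnostic(
        linkage=link,
        clusters=pd.Series(assign, index=beta.columns, name="cluster"),
        purity=float(purity),
    )


@dataclass
class MdsDiagnostic:
    coords: pd.DataFrame
    stress: float


def mds_diagnostic(beta: pd.DataFrame, probes: list[str], n_components: int = 2) -> MdsDiagnostic:
    """Classical (Torgerson) multidimensional scaling of pairwise Euclidean
    distances between samples on the selected probes.

    Coordinates are unique up to sign/rotation; the reported stress is
    sqrt(sum (d - d_hat)^2 / sum d^2) over sample pairs.
    """
    x = beta.loc[probes].to_numpy(float).T
    d = squareform(pdist(x))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)
    d_hat = squareform(pdist(coords))
    denom = (d**2).sum()
    stress = math.sqrt(((d - d_hat) ** 2).sum() / denom) if denom > 0 else 0.0
    return MdsDiagnostic(
        coords=pd.DataFrame(
            coords, index=beta.columns, columns=[f"dim{i + 1}" for i in range(n_components)]
        ),
        stress=float(stress),
    )


@dataclass
class CrossValidationResult:
    """Leave-25%-out assignments of held-out samples."""

    records: pd.DataFrame  # round, sample_id, is_case, assigned ("case"/"control")
    case_coclustering_rate: float
    per_sample_case_rate: pd.Series  # fraction of a sample's held-out rounds
    # in which it was assigned to the case cluster

    def failed_cases(self, min_rate: float = 0.5) -> list[str]:
        """Case samples assigned to the control cluster in >= ``1 - min_rate``
        of their held-out rounds."""
        cases = self.records[self.records["is_case"]]["sample_id"].unique()
        r = self.per_sample_case_rate
        return [s for s in cases if r.get(s, 0.0) < min_rate]


def _centroid_assign(
    beta: pd.DataFrame, probes: list[str], case_ids: list[str], control_ids: list[str], sample_ids: list[str]
) -> list[str]:
    sub = beta.loc[probes]
    c_case = sub[case_ids].mean(axis=1).to_numpy()
    c_ctrl = sub[control_ids].mean(axis=1).to_numpy()
    out = []
    for s in sample_ids:
        v = sub[s].to_numpy()
        d_case = np.linalg.norm(v - c_case)
        d_ctrl = np.linalg.norm(v - c_ctrl)
        out.append("case" if d_case < d_ctrl else "control")
    return out


def cross_validate(
    beta: pd.DataFrame,
    m: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    covariate_names: tuple[str, ...] = (),
    rounds: int = 4,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    **selection_kwargs,
) -> CrossValidationResult:
    """Leave-``holdout_fraction``-out cross-validation of the selection.

    Cases are partitioned into ``ceil(1/holdout_fraction)`` folds per cycle
    (so with the default 25% and 4 rounds every case is held out exactly
    once); an equal fraction of controls is held out alongside. Each round
    re-runs differential methylation and the full three-step selection on
    the training samples only, then assigns every held-out sample to the
    nearer training-centroid (case vs control) on the selected probes.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if len(case_ids) < 4:
        raise ValueError("need at least 4 case samples")
    rng = np.random.default_rng(seed)
    n_folds = max(2, math.ceil(1.0 / holdout_fraction))

    recs: list[dict] = []
    case_arr = np.array(case_ids)
    ctrl_arr = np.array(control_ids)
    r = 0
    while r < rounds:
        case_perm = rng.permutation(len(case_arr))
        ctrl_perm = rng.permutation(len(ctrl_arr))
        case_folds = np.array_split(case_perm, n_folds)
        ctrl_folds = np.array_split(ctrl_perm, n_folds)
        for f in range(n_folds):
            if r >= rounds:
                break
            held_cases = list(case_arr[case_folds[f]])
            held_ctrls = list(ctrl_arr[ctrl_folds[f]])
            tr_cases = [c for c in case_ids if c not in held_cases]
            tr_ctrls = [c for c in control_ids if c not in held_ctrls]
            tr = tr_cases + tr_ctrls
            dmp = run_dmp(m[tr], beta[tr], sample_sheet, tr_cases, tr_ctrls, covariate_names)
            labels = pd.Series([s in tr_cases for s in tr], index=tr)
            sig = select_episignature(beta[tr], dmp, labels, **selection_kwargs)
            held = held_cases + held_ctrls
            if len(sig.probes) == 0:
                assigned = ["control"] * len(held)  # no signature: nothing to co-cluster with
            else:
                assigned = _centroid_assign(beta, sig.probes, tr_cases, tr_ctrls, held)
            for s, a in zip(held, assigned):
                recs.append(
                    {"round": r, "sample_id": s, "is_case": s in held_cases, "assigned": a}
                )
            r += 1

    records = pd.DataFrame(recs)
    case_rec = records[records["is_case"]]
    rate = float((case_rec["assigned"] == "case").mean()) if len(case_rec) else float("nan")
    per_sample = (
        records.assign(hit=records["assigned"] == "case")
        .groupby("sample_id")["hit"]
        .mean()
    )
    return CrossValidationResult(
        records=records,
        case_coclustering_rate=rate,
        per_sample_case_rate=per_sample,
    )
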