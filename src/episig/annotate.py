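"""Genomic-context annotation of DMPs and cross-cohort comparison.

CpG-island context is assigned from the distance to the nearest island
boundary (shore 0-2 kb, shelf 2-4 kb, inter-CGI beyond); gene context from
the TSS-upstream distance and gene-body membership with precedence
promoter > promoter+ > gene body > intergenic. Cohorts are compared by the
(asymmetric) percentage of one cohort's DMPs found in another's, and by
average-linkage clustering of median methylation profiles over the union of
per-cohort top DMPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

CGI_CATEGORIES = ("island", "shore", "shelf", "inter_CGI")
GENE_CATEGORIES = ("promoter", "promoter+", "gene_body", "intergenic")

__all__ = [
    "CohortDmpSet",
    "annotate_cgi",
    "annotate_genes",
    "dmp_overlap_matrix",
    "cohort_tree",
    "CGI_CATEGORIES",
    "GENE_CATEGORIES",
]


@dataclass
class CohortDmpSet:
    """A cohort's differentially methylated probes over a shared universe."""

    name: str
    probe_ids: list[str]
    delta_beta: pd.Series | None = None
    p_value: pd.Series | None = None

    @classmethod
    def from_dmp(
        cls,
        name: str,
        dmp: pd.DataFrame,
        min_delta: float = 0.05,
        max_adj_p: float = 0.01,
    ) -> "CohortDmpSet":
        """DMP definition: |delta beta| >= ``min_delta`` and BH-adjusted
        p < ``max_adj_p`` (consistent with the episignature effect-size
        floor)."""
        hit = dmp[(dmp["delta_beta"].abs() >= min_delta) & (dmp["p_adjusted"] < max_adj_p)]
        return cls(
            name=name,
            probe_ids=[str(i) for i in hit.index],
            delta_beta=hit["delta_beta"].copy(),
            p_value=hit["p_value"].copy(),
        )


def annotate_cgi(probe_ids: list[str], manifest: pd.DataFrame) -> pd.Series:
    """Counts over {island, shore, shelf, inter_CGI}; a partition of the
    input (island: distance 0; shore: up to 2 kb; shelf: 2-4 kb)."""
    counts = pd.Series(0, index=list(CGI_CATEGORIES), dtype=int)
    if len(probe_ids) == 0:
        return counts
    d = manifest.loc[list(probe_ids), "cgi_dist"].to_numpy(np.int64)
    counts["island"] = int((d == 0).sum())
    counts["shore"] = int(((d > 0) & (d <= 2000)).sum())
    counts["shelf"] = int(((d > 2000) & (d <= 4000)).sum())
    counts["inter_CGI"] = int((d > 4000).sum())
    return counts


def annotate_genes(probe_ids: list[str], manifest: pd.DataFrame) -> pd.Series:
    """Counts over {promoter, promoter+, gene_body, intergenic}.

    Precedence promoter (0-1 kb upstream of a TSS) > promoter+ (1-5 kb)
    > gene body > intergenic, so the assignment is exhaustive and mutually
    exclusive."""
    counts = pd.Series(0, index=list(GENE_CATEGORIES), dtype=int)
    if len(probe_ids) == 0:
        return counts
    man = manifest.loc[list(probe_ids)]
    tss = man["tss_dist"].to_numpy(np.int64)
    in_gene = man["in_gene"].to_numpy(bool)
    promoter = (tss > 0) & (tss <= 1000)
    promoter_plus = ~promoter & (tss > 1000) & (tss <= 5000)
    gene_body = ~promoter & ~promoter_plus & in_gene
    intergenic = ~promoter & ~promoter_plus & ~gene_body
    counts["promoter"] = int(promoter.sum())
    counts["promoter+"] = int(promoter_plus.sum())
    counts["gene_body"] = int(gene_body.sum())
    counts["intergenic"] = int(intergenic.sum())
    return counts


def dmp_overlap_matrix(cohorts: list[CohortDmpSet]) -> pd.DataFrame:
    """Row-wise percent overlap: entry (y, x) is the percentage of cohort
    y's DMPs that also appear among cohort x's DMPs. The diagonal is 100;
    the matrix is generally asymmetric."""
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    sets = {c.name: set(c.probe_ids) for c in cohorts}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for y in names:
        ny = len(sets[y])
        for x in names:
            out.loc[y, x] = 100.0 * len(sets[y] & sets[x]) / ny if ny else 0.0
    return out


@dataclass
class CohortTree:
    newick: str
    linkage: np.ndarray | None
    profiles: pd.DataFrame  # probes x cohorts, median beta
    mean_delta: pd.Series  # per-cohort mean delta beta over its own DMPs
    trend: pd.Series  # "hypo" / "hyper"


def cohort_tree(
    cohorts: list[CohortDmpSet],
    case_betas: dict[str, pd.DataFrame],
    top_n: int = 500,
) -> CohortTree:
    """Cluster cohorts on median methylation over the union of top DMPs.

    For each cohort the ``top_n`` DMPs by p-value (all of them if fewer)
    enter a shared probe universe; each cohort is profiled as the per-probe
    median beta across its case samples; profiles are clustered by
    Euclidean distance with average linkage and the tree emitted as Newick.
    The per-cohort mean delta beta over its own DMPs gives the methylation
    trend (hypo / hyper).
    """
    universe: set[str] = set()
    for c in cohorts:
        if c.p_value is not None and len(c.probe_ids) > top_n:
            top = c.p_value.sort_values(kind="stable").index[:top_n]
        else:
            top = c.probe_ids
        universe |= {str(p) for p in top}
    probes = sorted(universe)

    profiles = pd.DataFrame(
        {c.name: case_betas[c.name].loc[probes].median(axis=1) for c in cohorts},
        index=probes,
    )
    mean_delta = pd.Series(
        {c.name: float(c.delta_beta.mean()) if c.delta_beta is not None and len(c.delta_beta) else float("nan") for c in cohorts},
        name="mean_delta_beta",
    )
    trend = pd.Series(
        {k: ("hypo" if v < 0 else "hyper") for k, v in mean_delta.items()}, name="trend"
    )

    names = [c.name for c in cohorts]
    if len(cohorts) == 1:
        return CohortTree(
            newick=f"{names[0]};", linkage=None, profiles=profiles, mean_delta=mean_delta, trend=trend
        )
    link = hierarchy.linkage(pdist(profiles.to_numpy(float).T), method="average")
    tree = TreeNode.from_linkage_matrix(link, names)
    newick = str(tree).strip()
    return CohortTree(newick=newick, linkage=link, profiles=profiles, mean_delta=mean_delta, trend=trend)
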