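"""End-to-end drivers: discovery, validation/refinement and VUS scoring.

``run_discovery`` executes sample QC -> probe filtering -> control matching
-> differential methylation -> three-step probe selection -> leave-25%-out
cross-validation -> SVM/MVP training. Cases whose MVP score stays below 0.5
AND which co-cluster with controls in at least half of their held-out
cross-validation rounds are flagged as outliers, excluded from training,
and the whole selection is re-run without them.

``run_validation_and_refine`` scores a validation cohort against the
discovery signature, then merges it into the training set and repeats probe
selection to produce the refined signature, which is also used to score a
VUS carrier if present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .classify import MvpModel, classify_vus, score_samples, train_mvp
from .dmp import run_dmp
from .preprocess import FilterReport, beta_to_m, filter_probes, match_controls, qc_samples
from .selection import (
    CrossValidationResult,
    EpisignatureProbeSet,
    cross_validate,
    hierarchical_diagnostic,
    mds_diagnostic,
    select_episignature,
)
from .simulate import CELL_TYPES, SimulatedDataset

__all__ = ["PipelineConfig", "DiscoveryResult", "ValidationResult", "run_discovery", "run_validation_and_refine"]

# 5 of the 6 blood-cell composition columns enter the model (one dropped:
# they sum to one, so all six would be collinear with the intercept).
DEFAULT_COVARIATES: tuple[str, ...] = tuple(c for c in CELL_TYPES if c != "gran")


@dataclass
class PipelineConfig:
    """All stage parameters of the workflow, serializable to YAML/JSON.

    The control-match ratio defaults to 1:3 per case (the realized design
    of the reference study; 1:5 is also common and configurable).
    """

    detp_threshold: float = 0.1
    max_failed_fraction: float = 0.05
    match_ratio: int = 3
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    k1: int = 1000
    k2: int = 500
    r_cut: float = 0.60
    min_delta: float | None = 0.05
    max_adj_p: float | None = 0.01
    cv_rounds: int = 4
    holdout_fraction: float = 0.25
    svm_c: float = 1.0
    train_fraction: float = 0.75
    mvp_thresholds: tuple[float, float] = (0.25, 0.75)
    outlier_mvp_cutoff: float = 0.5
    dmr_max_gap: int = 1000
    dmr_min_cpgs: int = 5
    dmr_min_delta: float = 0.05
    dmr_max_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k2 > self.k1:
            raise ValueError(f"k2 ({self.k2}) must not exceed k1 ({self.k1})")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0,1)")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["covariates"] = list(d["covariates"])
        d["mvp_thresholds"] = list(d["mvp_thresholds"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["covariates"] = tuple(d.get("covariates", DEFAULT_COVARIATES))
        d["mvp_thresholds"] = tuple(d.get("mvp_thresholds", (0.25, 0.75)))
        return cls(**d)


@dataclass
class DiscoveryResult:
    probe_set: EpisignatureProbeSet
    model: MvpModel
    cv: CrossValidationResult
    outlier_ids: list[str]
    dmp: pd.DataFrame
    matched_control_ids: list[str]
    filter_report: FilterReport
    hierarchical_purity: float
    mds_stress: float
    config: PipelineConfig
    beta_filtered: pd.DataFrame
    m_filtered: pd.DataFrame

    def provenance(self) -> dict:
        return {
            "config": json.loads(json.dumps(asdict(self.config))),
            "seed": self.config.seed,
            "n_probes_after_filter": int(len(self.beta_filtered)),
            "n_selected": len(self.probe_set.probes),
            "outliers": self.outlier_ids,
        }


def _other_cohort_ids(samples: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for role in samples["role"].unique():
        if str(role).startswith("other_disorder:"):
            name = str(role).split(":", 1)[1]
            out[name] = list(samples.index[samples["role"] == role])
    return out


def run_discovery(config: PipelineConfig, dataset: SimulatedDataset) -> DiscoveryResult:
    """Discovery-stage workflow on a dataset with role-labelled samples.

    Discovery cases (including any samples later flagged as outliers) are
    the ``case_discovery`` + ``case_outlier`` roles; the control pool is
    the ``control`` role.
    """
    samples = dataset.samples
    failed = qc_samples(dataset.detp, config.max_failed_fraction, config.detp_threshold)
    keep_samples = [s for s in dataset.beta.columns if s not in failed]
    beta = dataset.beta[keep_samples]
    detp = dataset.detp[keep_samples]

    beta_f, report = filter_probes(beta, detp, dataset.manifest, config.detp_threshold)
    report.removed_samples = list(failed)
    m = beta_to_m(beta_f)

    disc_cases = [
        s for s in keep_samples
        if samples.loc[s, "role"] in ("case_discovery", "case_outlier")
    ]
    pool = samples.loc[[s for s in keep_samples if samples.loc[s, "role"] == "control"]]
    controls = match_controls(
        samples.loc[disc_cases], pool, ratio=config.match_ratio, seed=config.seed
    )

    def _select(cases: list[str]) -> tuple[pd.DataFrame, EpisignatureProbeSet, CrossValidationResult]:
        dmp = run_dmp(m, beta_f, samples, cases, controls, config.covariates)
        labels = pd.Series(
            [s in cases for s in cases + controls], index=cases + controls
        )
        sig = select_episignature(
            beta_f[cases + controls], dmp, labels,
            k1=config.k1, k2=config.k2, r_cut=config.r_cut,
            min_delta=config.min_delta, max_adj_p=config.max_adj_p,
        )
        cv = cross_validate(
            beta_f, m, samples, cases, controls, config.covariates,
            rounds=config.cv_rounds, holdout_fraction=config.holdout_fraction,
            seed=config.seed,
            k1=config.k1, k2=config.k2, r_cut=config.r_cut,
            min_delta=config.min_delta, max_adj_p=config.max_adj_p,
        )
        return dmp, sig, cv

    other = _other_cohort_ids(samples.loc[keep_samples])
    # iterate outlier flagging to a fixed point: excluding one outlier
    # sharpens the signature, which can expose another
    outliers: list[str] = []
    clean_cases = list(disc_cases)
    for _ in range(len(disc_cases)):
        dmp, sig, cv = _select(clean_cases)
        model = train_mvp(
            beta_f, sig.probes, clean_cases, controls, other,
            train_fraction=config.train_fraction, C=config.svm_c, seed=config.seed,
        )
        scores = score_samples(model, beta_f[clean_cases])
        cocluster_fail = set(cv.failed_cases(min_rate=0.5))
        new = [
            s for s in clean_cases
            if scores[s] < config.outlier_mvp_cutoff and s in cocluster_fail
        ]
        if not new:
            break
        outliers += new
        clean_cases = [s for s in clean_cases if s not in new]

    labels = pd.Series(
        [s in clean_cases for s in clean_cases + controls], index=clean_cases + controls
    )
    hier = hierarchical_diagnostic(beta_f[clean_cases + controls], sig.probes, labels)
    mds = mds_diagnostic(beta_f[clean_cases + controls], sig.probes)

    return DiscoveryResult(
        probe_set=sig,
        model=model,
        cv=cv,
        outlier_ids=outliers,
        dmp=dmp,
        matched_control_ids=controls,
        filter_report=report,
        hierarchical_purity=hier.purity,
        mds_stress=mds.stress,
        config=config,
        beta_filtered=beta_f,
        m_filtered=m,
    )


@dataclass
class ValidationResult:
    validation_scores: pd.Series
    validation_coclustering: pd.Series  # sample -> "case"/"control" assignment
    refined_probe_set: EpisignatureProbeSet
    refined_model: MvpModel
    refined_dmp: pd.DataFrame
    vus_call: tuple[str, float] | None
    matched_control_ids: list[str]


def run_validation_and_refine(
    config: PipelineConfig,
    dataset: SimulatedDataset,
    discovery: DiscoveryResult,
) -> ValidationResult:
    """Score the validation cohort, then refine the signature on the merged
    training set and (if present) call the VUS carrier."""
    samples = dataset.samples
    beta_f = discovery.beta_filtered
    m = discovery.m_filtered
    valid_cases = [
        s for s in beta_f.columns if samples.loc[s, "role"] == "case_validation"
    ]
    train_cases = [
        s for s in beta_f.columns
        if samples.loc[s, "role"] in ("case_discovery", "case_outlier")
        and s not in discovery.outlier_ids
    ]

    # score + co-cluster validation samples against the discovery signature
    val_scores = score_samples(discovery.model, beta_f[valid_cases])
    probes = discovery.probe_set.probes
    sub = beta_f.loc[probes]
    c_case = sub[train_cases].mean(axis=1).to_numpy()
    c_ctrl = sub[discovery.matched_control_ids].mean(axis=1).to_numpy()
    assign = {}
    for s in valid_cases:
        v = sub[s].to_numpy()
        assign[s] = (
            "case"
            if np.linalg.norm(v - c_case) < np.linalg.norm(v - c_ctrl)
            else "control"
        )

    # merge and repeat probe selection
    merged = train_cases + valid_cases
    pool = samples.loc[[s for s in beta_f.columns if samples.loc[s, "role"] == "control"]]
    controls = match_controls(
        samples.loc[merged], pool, ratio=config.match_ratio, seed=config.seed
    )
    dmp = run_dmp(m, beta_f, samples, merged, controls, config.covariates)
    labels = pd.Series([s in merged for s in merged + controls], index=merged + controls)
    refined = select_episignature(
        beta_f[merged + controls], dmp, labels,
        k1=config.k1, k2=config.k2, r_cut=config.r_cut,
        min_delta=config.min_delta, max_adj_p=config.max_adj_p,
    )
    other = _other_cohort_ids(samples.loc[list(beta_f.columns)])
    model = train_mvp(
        beta_f, refined.probes, merged, controls, other,
        train_fraction=config.train_fraction, C=config.svm_c, seed=config.seed,
    )

    vus_ids = [s for s in beta_f.columns if samples.loc[s, "role"] == "case_vus"]
    vus_call = None
    if vus_ids:
        vus_call = classify_vus(model, beta_f[vus_ids[0]], config.mvp_thresholds)

    return ValidationResult(
        validation_scores=val_scores,
        validation_coclustering=pd.Series(assign, name="assigned"),
        refined_probe_set=refined,
        refined_model=model,
        refined_dmp=dmp,
        vus_call=vus_call,
        matched_control_ids=controls,
    )
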