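"""SVM scoring of samples against an episignature (MVP score).

A linear support vector machine is trained to separate episignature
carriers from everything else (controls plus samples from other disorders)
on the beta values of the selected probes; 75% of the non-case samples are
used for training, the remainder reserved as a held-out specificity check.
The SVM decision value is mapped to a methylation-variant-pathogenicity
(MVP) score in [0, 1] by Platt sigmoid calibration fitted on the training
decision values. The sigmoid slope is parametrised as -exp(a) so the MVP
score is strictly increasing in the decision value by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.svm import SVC

__all__ = ["MvpModel", "train_mvp", "score_sample", "score_samples", "classify_vus"]


@dataclass
class MvpModel:
    """A trained linear-SVM episignature classifier.

    ``weights``/``intercept`` define the decision value d(x) = w.x + b over
    beta values in the frozen ``probe_ids`` order; ``platt_a`` (< 0) and
    ``platt_b`` define MVP = 1 / (1 + exp(platt_a * d + platt_b)).
    """

    probe_ids: list[str]
    weights: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    C: float
    train_case_ids: list[str] = field(default_factory=list)
    train_other_ids: list[str] = field(default_factory=list)
    test_other_ids: list[str] = field(default_factory=list)
    training_scores: dict[str, float] = field(default_factory=dict)

    def decision(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.weights + self.intercept

    def mvp(self, decision: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + np.exp(self.platt_a * np.asarray(decision, float) + self.platt_b))

    def to_json(self) -> str:
        return json.dumps(
            {
                "probe_ids": self.probe_ids,
                "weights": [float(w) for w in self.weights],
                "intercept": self.intercept,
                "platt_a": self.platt_a,
                "platt_b": self.platt_b,
                "C": self.C,
                "train_case_ids": self.train_case_ids,
                "train_other_ids": self.train_other_ids,
                "test_other_ids": self.test_other_ids,
                "training_scores": self.training_scores,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MvpModel":
        d = json.loads(text)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)


def _platt_fit(decision: np.ndarray, is_case: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid calibration with the usual regularized targets.

    Returns (A, B) with A < 0 guaranteed (slope parametrised as -exp(a)),
    so the calibrated probability is strictly increasing in the decision
    value."""
    n_pos = int(is_case.sum())
    n_neg = int(len(is_case) - n_pos)
    t = np.where(is_case, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        a, b = params
        z = -np.exp(a) * decision + b
        # stable log(1+exp(z)) and companions
        log1pez = np.logaddexp(0.0, z)
        # p = 1/(1+e^z); log p = -log1pez ; log(1-p) = z - log1pez
        return float(-(t * (-log1pez) + (1.0 - t) * (z - log1pez)).sum())

    best = None
    for a0 in (-1.0, 0.0, 1.0):
        res = minimize(nll, x0=np.array([a0, 0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    a, b = best.x
    return float(-np.exp(a)), float(b)


def train_mvp(
    beta: pd.DataFrame,
    probes: list[str],
    case_ids: list[str],
    control_ids: list[str],
    other_cohorts: dict[str, list[str]] | None = None,
    train_fraction: float = 0.75,
    C: float = 1.0,
    seed: int = 0,
) -> MvpModel:
    """Train the binary (case vs rest) MVP classifier.

    ``other_cohorts`` maps cohort names to sample ids; each cohort and the
    control set contribute ``train_fraction`` of their samples to training,
    the rest are held out (recorded on the model for specificity checks).
    """
    if not probes:
        raise ValueError("probe set is empty")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    other_cohorts = other_cohorts or {}
    rng = np.random.default_rng(seed)

    train_other: list[str] = []
    test_other: list[str] = []
    for ids in [list(control_ids)] + [list(v) for v in other_cohorts.values()]:
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        train_other += [ids[i] for i in perm[:n_train]]
        test_other += [ids[i] for i in perm[n_train:]]

    train_ids = list(case_ids) + train_other
    x = beta.loc[probes, train_ids].to_numpy(float).T
    y = np.array([1] * len(case_ids) + [0] * len(train_other))
    svm = SVC(kernel="linear", C=C)
    svm.fit(x, y)
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])

    decision = x @ w + b
    a_platt, b_platt = _platt_fit(decision, y.astype(bool))

    model = MvpModel(
        probe_ids=[str(p) for p in probes],
        weights=w,
        intercept=b,
        platt_a=a_platt,
        platt_b=b_platt,
        C=C,
        train_case_ids=list(case_ids),
        train_other_ids=train_other,
        test_other_ids=test_other,
    )
    model.training_scores = {
        s: float(model.mvp(d)) for s, d in zip(train_ids, decision)
    }
    return model


def score_sample(model: MvpModel, beta_column: pd.Series) -> float:
    """MVP score of one sample (a beta Series indexed by probe id)."""
    missing = [p for p in model.probe_ids if p not in beta_column.index]
    if missing:
        raise KeyError(f"sample is missing {len(missing)} model probes: {missing[:5]}")
    x = beta_column.loc[model.probe_ids].to_numpy(float)
    return float(model.mvp(model.decision(x)))


def score_samples(model: MvpModel, beta: pd.DataFrame) -> pd.Series:
    """MVP scores for every column of a beta matrix."""
    x = beta.loc[model.probe_ids].to_numpy(float).T
    return pd.Series(model.mvp(model.decision(x)), index=beta.columns, name="mvp")


def classify_vus(
    model: MvpModel,
    beta_column: pd.Series,
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> tuple[str, float]:
    """Three-way call for a variant of uncertain significance.

    MVP above the upper threshold -> "positive" (episignature present),
    below the lower -> "negative", otherwise "inconclusive". The default
    0.25/0.75 thresholds are reporting policy, not biology.
    """
    lo, hi = thresholds
    score = score_sample(model, beta_column)
    if score > hi:
        call = "positive"
    elif score < lo:
        call = "negative"
    else:
        call = "inconclusive"
    return call, score
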