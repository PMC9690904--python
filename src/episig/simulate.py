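"""Synthetic EPIC-like methylation datasets with known planted structure.

Every downstream stage of the episignature workflow (probe QC, differential
methylation, probe selection, classification, region calling, cohort
comparison) is exercised against data generated here, where the ground truth
— which probes carry a planted case/control difference, which samples carry
it — is known exactly.

The control methylome is modelled as a two-component logit-normal mixture
(low- and high-methylation modes near beta = 0.1 and 0.9) plus a minority of
intermediate probes, which reproduces the characteristic bimodality of array
methylomes. Cases are controls plus a planted mean beta-difference on a
chosen signature probe set; "outlier" cases carry no planted difference and a
single VUS carrier carries the full difference, mirroring the discovery /
validation / VUS study structure. Additional "other disorder" cohorts carry
their own signatures with a small configurable overlap to the primary one.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SimDesign",
    "PlantedTruth",
    "SimulatedDataset",
    "generate_manifest",
    "generate_dataset",
    "write_fixture_tables",
    "read_fixture_tables",
]

TABLE_VERSION = "episig-table-v1"

CELL_TYPES = ("cd4t", "cd8t", "nk", "bcell", "mono", "gran")
# Dirichlet concentration ~ typical adult whole-blood composition.
_CELL_ALPHA = np.array([15.0, 8.0, 6.0, 8.0, 8.0, 55.0])

CGI_CONTEXTS = ("island", "shore", "shelf", "inter_CGI")
GENE_CONTEXTS = ("promoter", "promoter+", "gene_body", "intergenic")


class InvalidDesignError(ValueError):
    """Raised for simulation designs that cannot be realized."""


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a simulated case/control methylation study.

    ``delta_range`` is the (low, high) absolute mean beta-difference planted
    on signature probes; the default 0.05-0.15 window matches the effect
    sizes typical of neurodevelopmental-disorder episignatures.
    ``noise_sd_logit`` is the per-sample biological + technical noise on the
    natural-logit scale.
    """

    n_probes: int = 20_000
    n_signature_probes: int = 200
    n_cases: int = 20
    n_control_pool: int = 100
    n_other_cohorts: int = 3
    samples_per_other_cohort: int = 10
    delta_range: tuple[float, float] = (0.05, 0.15)
    signature_direction: str = "hypo"  # {hypo, hyper, mixed}
    hypo_fraction: float = 1.0  # used when direction == "mixed"
    noise_sd_logit: float = 0.45
    n_outlier_cases: int = 2
    n_validation_cases: int = 9
    include_vus: bool = True
    other_signature_jaccard: float = 0.05
    signature_cluster_fraction: float = 0.3
    signature_cluster_size: int = 6
    detp_fail_rate: float = 1e-4
    confound_cell_fraction: float = 0.0  # case-associated shift of `gran`
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_probes >= self.n_probes:
            raise InvalidDesignError(
                "n_signature_probes must be smaller than n_probes "
                f"({self.n_signature_probes} >= {self.n_probes})"
            )
        lo, hi = self.delta_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidDesignError(f"delta_range {self.delta_range} not in (0,1)")
        if self.signature_direction not in ("hypo", "hyper", "mixed"):
            raise InvalidDesignError(
                f"unknown signature_direction {self.signature_direction!r}"
            )
        for name in ("n_cases", "n_probes"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be positive")
        if self.n_signature_probes < 0:
            raise InvalidDesignError("n_signature_probes must be >= 0 (0 = null design)")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset."""

    signature_probe_ids: list[str]
    delta: pd.Series  # signed planted beta-difference, indexed by probe id
    case_ids: list[str]
    outlier_ids: list[str]
    validation_ids: list[str]
    vus_id: str | None
    other_signatures: dict[str, list[str]]
    other_deltas: dict[str, dict[str, float]]

    def to_json(self) -> str:
        payload = {
            "version": TABLE_VERSION,
            "signature_probe_ids": list(self.signature_probe_ids),
            "delta": {k: float(v) for k, v in self.delta.items()},
            "case_ids": list(self.case_ids),
            "outlier_ids": list(self.outlier_ids),
            "validation_ids": list(self.validation_ids),
            "vus_id": self.vus_id,
            "other_signatures": {k: list(v) for k, v in self.other_signatures.items()},
            "other_deltas": self.other_deltas,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            signature_probe_ids=d["signature_probe_ids"],
            delta=pd.Series(d["delta"], dtype=float),
            case_ids=d["case_ids"],
            outlier_ids=d["outlier_ids"],
            validation_ids=d["validation_ids"],
            vus_id=d["vus_id"],
            other_signatures=d["other_signatures"],
            other_deltas=d["other_deltas"],
        )


@dataclass
class SimulatedDataset:
    beta: pd.DataFrame  # probes x samples, values in (0,1)
    detp: pd.DataFrame  # detection p-values, aligned to beta
    samples: pd.DataFrame  # one row per sample
    manifest: pd.DataFrame  # one row per probe
    truth: PlantedTruth
    design: SimDesign | None = None


def generate_manifest(
    n_probes: int,
    seed: int = 0,
    xy_fraction: float = 0.03,
    snp_rate: float = 0.03,
    crossreactive_rate: float = 0.08,
) -> pd.DataFrame:
    """Simulate a probe manifest: genomic position plus CGI / gene context.

    Probes are scattered over autosomes 1-22 plus X/Y (``xy_fraction`` of
    probes), with strictly increasing positions within each chromosome.
    ``cgi_dist`` is the distance (bp) to the nearest CpG-island boundary
    (0 inside an island); ``tss_dist`` the distance upstream of the nearest
    transcription start site (0 = no TSS upstream within range); ``in_gene``
    marks probes inside a gene body. SNP-overlap and cross-reactivity flags
    are drawn independently at the given rates.
    """
    if n_probes < 100:
        raise InvalidDesignError(f"n_probes must be >= 100, got {n_probes}")
    rng = np.random.default_rng(seed)

    autosomes = [str(i) for i in range(1, 23)]
    # chromosome weights roughly proportional to size
    w = np.linspace(2.0, 0.6, num=22)
    w = w / w.sum() * (1.0 - xy_fraction)
    chrom_labels = autosomes + ["X", "Y"]
    probs = np.concatenate([w, [0.8 * xy_fraction, 0.2 * xy_fraction]])
    chroms = rng.choice(chrom_labels, size=n_probes, p=probs)

    order = np.argsort(pd.Categorical(chroms, categories=chrom_labels).codes, kind="stable")
    chroms = chroms[order]

    pos = np.empty(n_probes, dtype=np.int64)
    for c in chrom_labels:
        mask = chroms == c
        k = int(mask.sum())
        if k == 0:
            continue
        # bimodal spacing: dense CpG clusters interleaved with open sea
        dense = rng.random(k) < 0.6
        gaps = np.where(dense, rng.integers(100, 800, size=k), rng.integers(1_500, 8_000, size=k))
        pos[mask] = 10_000 + np.cumsum(gaps)

    cgi_cat = rng.choice(4, size=n_probes, p=[0.30, 0.25, 0.10, 0.35])
    cgi_dist = np.zeros(n_probes, dtype=np.int64)
    cgi_dist[cgi_cat == 1] = rng.integers(1, 2_001, size=int((cgi_cat == 1).sum()))
    cgi_dist[cgi_cat == 2] = rng.integers(2_001, 4_001, size=int((cgi_cat == 2).sum()))
    cgi_dist[cgi_cat == 3] = rng.integers(4_001, 100_000, size=int((cgi_cat == 3).sum()))

    gene_cat = rng.choice(4, size=n_probes, p=[0.15, 0.10, 0.40, 0.35])
    tss_dist = np.zeros(n_probes, dtype=np.int64)
    tss_dist[gene_cat == 0] = rng.integers(1, 1_001, size=int((gene_cat == 0).sum()))
    tss_dist[gene_cat == 1] = rng.integers(1_001, 5_001, size=int((gene_cat == 1).sum()))
    tss_dist[gene_cat == 3] = rng.integers(5_001, 200_000, size=int((gene_cat == 3).sum()))
    in_gene = gene_cat == 2

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "cgi_dist": cgi_dist,
            "tss_dist": tss_dist,
            "in_gene": in_gene,
            "snp_flag": rng.random(n_probes) < snp_rate,
            "crossreactive_flag": rng.random(n_probes) < crossreactive_rate,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return manifest


def _expected_beta(mu: np.ndarray, sd: float, nodes: int = 41) -> np.ndarray:
    """E[sigmoid(mu + e)], e ~ N(0, sd), by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    z = mu[..., None] + sd * x
    vals = 1.0 / (1.0 + np.exp(-z))
    return vals @ (w / w.sum())


def _logit_mean_for_target(target: np.ndarray, sd: float) -> np.ndarray:
    """Invert ``_expected_beta``: the logit-mean whose realized mean beta is
    ``target`` under N(0, sd) logit noise. Vectorized bisection; without this
    calibration the planted beta-difference would be biased by the convexity
    of the logistic function."""
    lo = np.full_like(target, -15.0)
    hi = np.full_like(target, 15.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _expected_beta(mid, sd) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _signed_deltas(rng: np.random.Generator, design: SimDesign, n: int) -> np.ndarray:
    mag = rng.uniform(design.delta_range[0], design.delta_range[1], size=n)
    if design.signature_direction == "hypo":
        sign = -np.ones(n)
    elif design.signature_direction == "hyper":
        sign = np.ones(n)
    else:
        sign = np.where(rng.random(n) < design.hypo_fraction, -1.0, 1.0)
    return sign * mag


def _cluster_candidates(
    manifest: pd.DataFrame, eligible: np.ndarray, size: int, max_gap: int = 900
) -> np.ndarray:
    """Start indices of runs of ``size`` manifest-consecutive eligible probes
    on one chromosome with every inter-probe gap <= ``max_gap``."""
    pos = manifest["pos"].to_numpy(np.int64)
    chrom = manifest["chrom"].to_numpy()
    ok = (
        (np.diff(pos) <= max_gap)
        & (chrom[1:] == chrom[:-1])
        & eligible[1:]
        & eligible[:-1]
    )
    if size < 2:
        return np.flatnonzero(eligible)
    win = np.convolve(ok.astype(int), np.ones(size - 1, dtype=int), mode="valid")
    return np.flatnonzero(win == size - 1)


def _plant_signature(
    rng: np.random.Generator,
    design: SimDesign,
    manifest: pd.DataFrame,
    eligible: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick signature probes and their planted deltas.

    A fraction of the signature is planted as dense contiguous clusters
    (so region-level callers have true regions to find), sharing one delta
    per cluster; the remainder is scattered with i.i.d. deltas.
    """
    n_sig = design.n_signature_probes
    size = max(1, design.signature_cluster_size)
    n_clusters = int(round(design.signature_cluster_fraction * n_sig / size))

    chosen: list[int] = []
    deltas: list[float] = []
    if n_clusters > 0 and size > 1:
        cand = _cluster_candidates(manifest, eligible, size)
        taken = np.zeros(len(manifest), dtype=bool)
        starts = rng.permutation(cand)
        placed = 0
        for s in starts:
            if placed == n_clusters:
                break
            block = np.arange(s, s + size)
            if taken[max(0, s - size):s + 2 * size].any():
                continue
            taken[block] = True
            d = _signed_deltas(rng, design, 1)[0]
            chosen.extend(block.tolist())
            deltas.extend([d] * size)
            placed += 1

    n_rest = n_sig - len(chosen)
    pool = np.setdiff1d(np.flatnonzero(eligible), np.asarray(chosen, dtype=int))
    rest = rng.choice(pool, size=n_rest, replace=False)
    chosen.extend(rest.tolist())
    deltas.extend(_signed_deltas(rng, design, n_rest).tolist())

    clustered = [True] * (len(chosen) - n_rest) if n_rest < len(chosen) else []
    clustered = np.array(clustered + [False] * n_rest, dtype=bool)
    order = np.argsort(chosen)
    return (
        np.asarray(chosen, dtype=int)[order],
        np.asarray(deltas, dtype=float)[order],
        clustered[order],
    )


def _balanced_sexes(n: int) -> np.ndarray:
    out = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    return out


def generate_dataset(design: SimDesign, manifest: pd.DataFrame) -> SimulatedDataset:
    """Draw a full dataset (beta, detection p, sample sheet, truth).

    Control betas are logit-normal around probe-level baselines from the
    bimodal mixture; carrier samples (discovery cases, validation cases, the
    VUS) get signature-probe baselines shifted so the *beta-scale* mean
    difference equals the planted delta exactly in expectation. Outlier cases
    carry zero delta. Each "other disorder" cohort carries its own signature
    sharing a small Jaccard overlap with the primary one.
    """
    if len(manifest) != design.n_probes:
        raise InvalidDesignError(
            f"manifest has {len(manifest)} probes, design expects {design.n_probes}"
        )
    rng = np.random.default_rng(design.seed)
    n_probes = design.n_probes
    sd = design.noise_sd_logit

    # --- probe baselines: bimodal logit-normal mixture -------------------
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    mu = np.empty(n_probes)
    mu[comp == 0] = rng.normal(-2.2, 0.5, size=int((comp == 0).sum()))  # beta ~ 0.1
    mu[comp == 1] = rng.normal(2.2, 0.5, size=int((comp == 1).sum()))  # beta ~ 0.9
    mu[comp == 2] = rng.normal(0.0, 0.8, size=int((comp == 2).sum()))

    # --- signature probes: autosomal, unflagged, mid-range baselines -----
    eligible = (
        (~manifest["chrom"].isin(["X", "Y"]))
        & (~manifest["snp_flag"])
        & (~manifest["crossreactive_flag"])
    ).to_numpy()
    elig_idx = np.flatnonzero(eligible)
    if len(elig_idx) < design.n_signature_probes:
        raise InvalidDesignError("not enough eligible probes for the signature")
    sig_idx, deltas, clustered = _plant_signature(rng, design, manifest, eligible)

    # control baseline beta chosen so baseline + delta stays inside (0.05, 0.95).
    # Clustered (region-forming) probes start from near-saturated baselines —
    # the logit-scale effect of a given beta-difference is largest there, as
    # in real regions losing (or gaining) methylation coherently.
    lo = np.where(deltas < 0, 0.05 - deltas + 0.05, 0.10)
    hi = np.where(deltas < 0, 0.90, 0.90 - deltas)
    lo = np.where(clustered & (deltas < 0), np.maximum(lo, 0.62 - deltas), lo)
    hi = np.where(clustered & (deltas > 0), np.minimum(hi, 0.38 - deltas), hi)
    b_ctrl = rng.uniform(lo, hi)
    b_case = b_ctrl + deltas
    mu_ctrl_sig = _logit_mean_for_target(b_ctrl, sd)
    mu_case_sig = _logit_mean_for_target(b_case, sd)
    mu[sig_idx] = mu_ctrl_sig

    probe_ids = manifest.index.to_numpy()
    sig_ids = probe_ids[sig_idx]

    # --- other-disorder signatures with configurable overlap -------------
    other_signatures: dict[str, list[str]] = {}
    other_deltas: dict[str, dict[str, float]] = {}
    other_mu_case: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    s = design.n_signature_probes
    j = design.other_signature_jaccard
    n_shared = int(round(2.0 * s * j / (1.0 + j))) if j > 0 else 0
    non_sig_elig = np.setdiff1d(elig_idx, sig_idx)
    for c in range(design.n_other_cohorts):
        name = f"disorder_{chr(ord('A') + c)}"
        shared = rng.choice(sig_idx, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
        own = rng.choice(non_sig_elig, size=s - n_shared, replace=False)
        idx = np.sort(np.concatenate([shared, own]).astype(int))
        d = _signed_deltas(rng, design, len(idx))
        base = _expected_beta(mu[idx], sd)
        target = np.clip(base + d, 0.02, 0.98)
        d = target - base
        other_signatures[name] = [str(p) for p in probe_ids[idx]]
        other_deltas[name] = {str(p): float(v) for p, v in zip(probe_ids[idx], d)}
        other_mu_case[name] = (idx, _logit_mean_for_target(target, sd))

    # --- sample sheet -----------------------------------------------------
    roles: list[tuple[str, str]] = []  # (sample_id, role)
    roles += [(f"case_{i + 1:03d}", "case_discovery") for i in range(design.n_cases)]
    roles += [(f"outlier_{i + 1:02d}", "case_outlier") for i in range(design.n_outlier_cases)]
    roles += [(f"valid_{i + 1:03d}", "case_validation") for i in range(design.n_validation_cases)]
    if design.include_vus:
        roles += [("vus_001", "case_vus")]
    roles += [(f"ctrl_{i + 1:04d}", "control") for i in range(design.n_control_pool)]
    for name in other_signatures:
        roles += [
            (f"{name}_{i + 1:03d}", f"other_disorder:{name}")
            for i in range(design.samples_per_other_cohort)
        ]
    sample_ids = [r[0] for r in roles]
    role_arr = np.array([r[1] for r in roles])
    n_samples = len(sample_ids)

    sex = np.empty(n_samples, dtype=object)
    for role in np.unique(role_arr):
        m = role_arr == role
        sex[m] = _balanced_sexes(int(m.sum()))
    age = rng.integers(2, 60, size=n_samples)
    cell = rng.dirichlet(_CELL_ALPHA, size=n_samples)
    is_carrier = np.isin(role_arr, ["case_discovery", "case_validation", "case_vus"])
    if design.confound_cell_fraction > 0:
        shift = design.confound_cell_fraction * is_carrier
        cell[:, CELL_TYPES.index("gran")] += shift
        cell = cell / cell.sum(axis=1, keepdims=True)

    samples = pd.DataFrame(
        {
            "role": role_arr,
            "group": np.select(
                [
                    np.char.startswith(role_arr.astype(str), "case"),
                    role_arr == "control",
                ],
                ["case", "control"],
                default="other",
            ),
            "sex": sex,
            "age": age,
            "array": "EPIC",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for k, ct in enumerate(CELL_TYPES):
        samples[ct] = cell[:, k]

    # --- beta matrix ------------------------------------------------------
    mu_mat = np.tile(mu[:, None], (1, n_samples))
    mu_mat[np.ix_(sig_idx, np.flatnonzero(is_carrier))] = mu_case_sig[:, None]
    for name, (idx, mu_case_o) in other_mu_case.items():
        cols = np.flatnonzero(role_arr == f"other_disorder:{name}")
        mu_mat[np.ix_(idx, cols)] = mu_case_o[:, None]
    noise = rng.normal(0.0, sd, size=(n_probes, n_samples))
    beta_vals = 1.0 / (1.0 + np.exp(-(mu_mat + noise)))
    np.clip(beta_vals, 1e-6, 1.0 - 1e-6, out=beta_vals)

    beta = pd.DataFrame(beta_vals, index=manifest.index.copy(), columns=sample_ids)

    detp_vals = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < design.detp_fail_rate
    detp_vals[fail] = rng.uniform(0.1, 1.0, size=int(fail.sum()))
    detp = pd.DataFrame(detp_vals, index=beta.index.copy(), columns=sample_ids)

    truth = PlantedTruth(
        signature_probe_ids=[str(p) for p in sig_ids],
        delta=pd.Series(deltas, index=[str(p) for p in sig_ids], dtype=float),
        case_ids=[s_ for s_, r in roles if r == "case_discovery"],
        outlier_ids=[s_ for s_, r in roles if r == "case_outlier"],
        validation_ids=[s_ for s_, r in roles if r == "case_validation"],
        vus_id="vus_001" if design.include_vus else None,
        other_signatures=other_signatures,
        other_deltas=other_deltas,
    )
    return SimulatedDataset(beta=beta, detp=detp, samples=samples, manifest=manifest, truth=truth, design=design)


def _write_table(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TABLE_VERSION}\n")
        df.to_csv(fh, sep="\t")


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_fixture_tables(dataset: SimulatedDataset, directory: str) -> dict[str, str]:
    """Write beta.tsv, detp.tsv, samples.tsv, manifest.tsv and truth.json.

    Floats are written at full repr precision so a read-back reproduces the
    matrices exactly.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {
        "beta": os.path.join(directory, "beta.tsv"),
        "detp": os.path.join(directory, "detp.tsv"),
        "samples": os.path.join(directory, "samples.tsv"),
        "manifest": os.path.join(directory, "manifest.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    _write_table(dataset.beta, paths["beta"])
    _write_table(dataset.detp, paths["detp"])
    _write_table(dataset.samples, paths["samples"])
    _write_table(dataset.manifest, paths["manifest"])
    with open(paths["truth"], "w") as fh:
        fh.write(dataset.truth.to_json())
    return paths


def read_fixture_tables(directory: str) -> SimulatedDataset:
    """Read a dataset written by :func:`write_fixture_tables`."""
    beta = _read_table(os.path.join(directory, "beta.tsv"))
    detp = _read_table(os.path.join(directory, "detp.tsv"))
    samples = _read_table(os.path.join(directory, "samples.tsv"))
    manifest = _read_table(os.path.join(directory, "manifest.tsv"))
    with open(os.path.join(directory, "truth.json")) as fh:
        truth = PlantedTruth.from_json(fh.read())
    return SimulatedDataset(beta=beta, detp=detp, samples=samples, manifest=manifest, truth=truth)
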