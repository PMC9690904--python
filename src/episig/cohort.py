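"""The Clark-Baraitser (TRIP12) study cohort: parsing, variant
classification and summary counts.

The molecular table of the 32-case cohort and the clinical-feature lists
are shipped as plain-text fixtures under ``episig/data``. Variant strings
are classified by a minimal rule set sufficient for this cohort's HGVS-like
notation (this is deliberately not a general HGVS parser).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CaseRecord",
    "CohortSummary",
    "parse_cohort_table",
    "classify_variant",
    "summarize_cohort",
    "load_packaged_cohort",
    "load_packaged_phenotypes",
]

VARIANT_CLASSES = ("deletion", "splice site", "frameshift", "missense", "nonsense", "in-frame")
COHORT_ROLES = ("discovery", "discovery_outlier", "validation", "validation_VUS")


@dataclass(frozen=True)
class CaseRecord:
    id: int
    sex: str
    age: float
    variant: str
    origin: str
    test: str
    variant_class: str
    cohort_role: str


def classify_variant(variant: str) -> str:
    """Rule-based variant classification from the notation alone.

    Order matters: exon-level/cytoband deletions first, then frameshifts
    (``fs`` in the protein change, even when the cDNA change is an
    intron-spanning deletion), splice-site (intronic +/-n substitutions),
    nonsense (a stop without frameshift), in-frame codon deletions, and
    finally single amino-acid substitutions (missense).
    """
    v = variant.strip()
    if re.search(r"(?i)deletion\s*exons", v) or re.match(r"^\d+[pq]\d", v):
        return "deletion"
    if re.search(r"fs", v):
        return "frameshift"
    if re.search(r"c\.\d+[+-]\d+[ACGT]>[ACGT]", v):
        return "splice site"
    if "*" in v:
        return "nonsense"
    if re.search(r"p\.\(?[A-Z][a-z]{2}\d+_[A-Z][a-z]{2}\d+del", v):
        return "in-frame"
    if re.search(r"p\.\s*\(?[A-Z][a-z]{2}\d+[A-Z][a-z]{2}\)?", v):
        return "missense"
    raise ValueError(f"cannot classify variant string: {variant!r}")


def parse_cohort_table(path_or_buffer) -> list[CaseRecord]:
    """Read a cohort table (TSV with a ``#`` header comment line).

    Malformed rows (unknown sex or role, non-numeric age, unknown variant
    class) are rejected with their row number.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", dtype=str)
    required = ["id", "sex", "age", "variant", "origin", "test", "variant_class", "cohort_role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    records: list[CaseRecord] = []
    seen: set[int] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based plus header
        if row["sex"] not in ("F", "M"):
            raise ValueError(f"row {rownum}: invalid sex {row['sex']!r}")
        if row["cohort_role"] not in COHORT_ROLES:
            raise ValueError(f"row {rownum}: invalid cohort role {row['cohort_role']!r}")
        if row["variant_class"] not in VARIANT_CLASSES:
            raise ValueError(f"row {rownum}: invalid variant class {row['variant_class']!r}")
        try:
            cid = int(row["id"])
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {rownum}: non-numeric id or age") from exc
        if cid in seen:
            raise ValueError(f"row {rownum}: duplicate case id {cid}")
        seen.add(cid)
        records.append(
            CaseRecord(
                id=cid,
                sex=row["sex"],
                age=age,
                variant=row["variant"],
                origin=row["origin"],
                test=row["test"],
                variant_class=row["variant_class"],
                cohort_role=row["cohort_role"],
            )
        )
    return records


@dataclass
class CohortSummary:
    """Deterministic count tables over the cohort.

    ``sex_counts`` groups the outlier cases with discovery and the VUS with
    validation (they are members of those cohorts); ``variant_counts``
    keeps the VUS separate because the validation cohort's variant tally is
    conventionally reported over its pathogenic members only.
    """

    n_total: int
    sex_counts: pd.DataFrame  # rows discovery/validation, cols F/M
    variant_counts: pd.DataFrame  # rows discovery/validation/validation_VUS
    phenotype_counts: pd.Series


def _group(role: str) -> str:
    return "discovery" if role.startswith("discovery") else "validation"


def summarize_cohort(
    records: list[CaseRecord], phenotypes: dict | None = None
) -> CohortSummary:
    df = pd.DataFrame([r.__dict__ for r in records])
    df["cohort"] = df["cohort_role"].map(_group)

    sex_counts = (
        df.groupby(["cohort", "sex"]).size().unstack(fill_value=0).reindex(
            index=["discovery", "validation"], columns=["F", "M"], fill_value=0
        )
    )

    vgroup = df["cohort_role"].map(
        lambda r: "validation_VUS" if r == "validation_VUS" else _group(r)
    )
    variant_counts = (
        df.assign(vgroup=vgroup)
        .groupby(["vgroup", "variant_class"])
        .size()
        .unstack(fill_value=0)
        .reindex(
            index=["discovery", "validation", "validation_VUS"],
            columns=list(VARIANT_CLASSES),
            fill_value=0,
        )
    )

    if phenotypes is None:
        pheno = pd.Series(dtype=int)
    else:
        feats = phenotypes.get("features", phenotypes)
        pheno = pd.Series({k: len(v) for k, v in feats.items()}, dtype=int)
    return CohortSummary(
        n_total=len(records),
        sex_counts=sex_counts,
        variant_counts=variant_counts,
        phenotype_counts=pheno,
    )


def load_packaged_cohort() -> list[CaseRecord]:
    """The packaged 32-case molecular table."""
    ref = resources.files("episig.data").joinpath("clark_baraitser_cases.tsv")
    with ref.open("r") as fh:
        return parse_cohort_table(fh)


def load_packaged_phenotypes() -> dict:
    """The packaged clinical-feature lists."""
    ref = resources.files("episig.data").joinpath("phenotypes.json")
    with ref.open("r") as fh:
        return json.load(fh)
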