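"""Bronchodilator-response phenotype and covariate handling.

BDR is the percent change in FEV1 after albuterol:
``100 * (post - pre) / pre``.  It is analyzed both continuously and
dichotomized at clinical thresholds: >= 12% (the airway-reversibility
criterion commonly required for asthma trial inclusion) and >= 8% (a more
sensitive and specific reversibility indicator used as a sensitivity
analysis).  Both cuts are inclusive.

The adjustment covariates are age (years, continuous), sex (male
indicator), BMI category (indicators for underweight/overweight/obese with
normal as the reference class), asthma doctor visits in the past year
(count, untransformed) and the first six genotype principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("male", "female")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
PC_COLUMNS = [f"PC{i}" for i in range(1, 7)]

#: Fixed design-column order used by every model in the package.
COVARIATE_COLUMNS = [
    "age_years",
    "male",
    "bmi_underweight",
    "bmi_overweight",
    "bmi_obese",
    "doctor_visits",
    *PC_COLUMNS,
]


class PhenotypeError(ValueError):
    """Raised for invalid spirometry or covariate data."""


def compute_bdr(pre_fev1, post_fev1):
    """Percent change in FEV1: ``100 * (post - pre) / pre``.

    Accepts scalars or arrays; negative responses are legitimate (airway
    narrowing after the bronchodilator).  Requires ``pre_fev1 > 0``.
    """
    pre = np.asarray(pre_fev1, dtype=float)
    post = np.asarray(post_fev1, dtype=float)
    if np.any(pre <= 0):
        raise PhenotypeError("pre-bronchodilator FEV1 must be positive")
    out = 100.0 * (post - pre) / pre
    return float(out) if out.ndim == 0 else out


def dichotomize_bdr(bdr_percent, threshold: float = 12.0):
    """Responder flag: BDR at or above ``threshold`` percent (inclusive)."""
    if not np.isfinite(threshold):
        raise PhenotypeError("threshold must be finite")
    flag = np.asarray(bdr_percent, dtype=float) >= threshold
    return bool(flag) if flag.ndim == 0 else flag


@dataclass
class CohortTable:
    """Per-individual phenotype and covariates for one analysis cohort.

    Wraps a DataFrame with columns ``sample_id``, ``bdr_percent`` (or a
    binary ``responder`` for threshold-generated outcomes), optional
    ``pre_fev1``/``post_fev1``, ``age_years``, ``sex``, ``bmi_category``,
    ``doctor_visits`` and ``PC1..PC6``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise PhenotypeError("cohort table requires a sample_id column")
        if "bdr_percent" not in df.columns and "responder" not in df.columns:
            raise PhenotypeError("cohort table needs bdr_percent or responder")
        for col in ("age_years", "sex", "bmi_category", "doctor_visits", *PC_COLUMNS):
            if col not in df.columns:
                raise PhenotypeError(f"cohort table missing covariate column {col}")
        bad_bmi = sorted(set(df["bmi_category"]) - set(BMI_CATEGORIES))
        if bad_bmi:
            raise PhenotypeError(f"unknown BMI categories: {', '.join(map(str, bad_bmi))}")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise PhenotypeError(f"unknown sex values: {', '.join(map(str, bad_sex))}")
        if (df["doctor_visits"] < 0).any():
            raise PhenotypeError("doctor_visits must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def bdr_percent(self) -> np.ndarray:
        return self.data["bdr_percent"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def encode_covariates(cohort: CohortTable) -> pd.DataFrame:
    """Build the adjustment design columns in the package's fixed order.

    Age and doctor visits continuous; male indicator; BMI as three
    indicators with *normal* (the largest class) as reference; six PCs.
    Any missing value is an error listing the affected samples.
    """
    df = cohort.data
    raw = df[["age_years", "doctor_visits", *PC_COLUMNS]]
    if raw.isna().any().any() or df[["sex", "bmi_category"]].isna().any().any():
        bad = df.loc[
            raw.isna().any(axis=1) | df[["sex", "bmi_category"]].isna().any(axis=1),
            "sample_id",
        ]
        raise PhenotypeError(f"missing covariate values for samples: {', '.join(map(str, bad))}")
    out = pd.DataFrame(index=df.index)
    out["age_years"] = df["age_years"].astype(float)
    out["male"] = (df["sex"] == "male").astype(float)
    for cat in ("underweight", "overweight", "obese"):
        out[f"bmi_{cat}"] = (df["bmi_category"] == cat).astype(float)
    out["doctor_visits"] = df["doctor_visits"].astype(float)
    for pc in PC_COLUMNS:
        out[pc] = df[pc].astype(float)
    return out[COVARIATE_COLUMNS]


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read a phenotype/covariate CSV (missing values as empty fields).

    When both raw FEV1 columns and ``bdr_percent`` are present, BDR is
    recomputed from the raw spirometry (which wins) and the supplied column
    must agree within 0.01 BDR points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if {"pre_fev1", "post_fev1"}.issubset(df.columns):
        recomputed = compute_bdr(df["pre_fev1"], df["post_fev1"])
        if "bdr_percent" in df.columns:
            diff = np.abs(recomputed - df["bdr_percent"].to_numpy(dtype=float))
            if np.any(diff >= 0.01):
                bad = df.loc[diff >= 0.01, "sample_id"]
                raise PhenotypeError(
                    "bdr_percent inconsistent with pre/post FEV1 for samples: "
                    + ", ".join(map(str, bad))
                )
        df = df.assign(bdr_percent=recomputed)
    return CohortTable(df)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False)
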