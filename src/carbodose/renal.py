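"""Renal-function and body-size quantities entering the Calvert-type formulas.

Implements Cockcroft–Gault creatinine clearance, the CKD-EPI creatinine
equations (2009 and 2021 race-free versions), its exact inverse (serum
creatinine from a target eGFR, needed by the synthetic-cohort generator),
Du Bois and Mosteller body surface area, and the de-normalization of a
BSA-indexed eGFR to an absolute mL/min value.

Serum creatinine is mg/dL at this interface; cohort CSV input may carry
µmol/L with an explicit ``scr_unit`` column (divided by 88.4 on read).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Patient",
    "cockcroft_gault",
    "ckd_epi",
    "invert_ckd_epi",
    "bsa",
    "bsa_readjust_egfr",
    "read_cohort_csv",
    "write_cohort_csv",
]

Sex = Literal["female", "male"]

UMOL_PER_MGDL = 88.4

# CKD-EPI creatinine coefficients: intercept, kappa, alpha (scr<=kappa
# exponent), beta (scr>kappa exponent), per-year age decay, female factor.
_CKD_EPI = {
    2009: {
        "intercept": 141.0,
        "beta": -1.209,
        "age_decay": 0.993,
        "female_factor": 1.018,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.329, "male": -0.411},
    },
    2021: {
        "intercept": 142.0,
        "beta": -1.200,
        "age_decay": 0.9938,
        "female_factor": 1.012,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.241, "male": -0.302},
    },
}


def _check_sex(sex: str) -> str:
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    return sex


def cockcroft_gault(age: float, weight: float, scr: float, sex: Sex) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min).

    CrCL = (140 − age)·weight / (72·Scr), ×0.85 for women; age in years,
    weight in kg, serum creatinine in mg/dL.
    """
    _check_sex(sex)
    if not 0 < age <= 120:
        raise ValueError(f"age must be in (0, 120], got {age}")
    if not weight > 0:
        raise ValueError("weight must be positive")
    if not scr > 0:
        raise ValueError("serum creatinine must be positive")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return crcl


def ckd_epi(scr: float, age: float, sex: Sex, version: int = 2021) -> float:
    """CKD-EPI creatinine eGFR (mL/min/1.73 m²).

    Piecewise power law ``intercept · min(Scr/κ,1)^α · max(Scr/κ,1)^β ·
    age_decay^age``, times the female factor; 2021 is the race-free
    refit and the default.  The 2009 version is implemented without the
    race coefficient.
    """
    _check_sex(sex)
    if version not in _CKD_EPI:
        raise ValueError(f"unknown CKD-EPI version {version!r}; use 2009 or 2021")
    if not scr > 0:
        raise ValueError("serum creatinine must be positive")
    if not age > 0:
        raise ValueError("age must be positive")
    c = _CKD_EPI[version]
    kappa = c["kappa"][sex]
    alpha = c["alpha"][sex]
    r = scr / kappa
    egfr = (
        c["intercept"]
        * min(r, 1.0) ** alpha
        * max(r, 1.0) ** c["beta"]
        * c["age_decay"] ** age
    )
    if sex == "female":
        egfr *= c["female_factor"]
    return egfr


def invert_ckd_epi(egfr: float, age: float, sex: Sex, version: int = 2021) -> float:
    """Serum creatinine (mg/dL) giving a target CKD-EPI eGFR.

    The equation is strictly decreasing in creatinine, so the inverse is
    unique; it is evaluated in closed form on the appropriate branch of the
    piecewise power law.  eGFR must be positive and physiologically
    plausible (≤ 300 mL/min/1.73 m²).
    """
    _check_sex(sex)
    if version not in _CKD_EPI:
        raise ValueError(f"unknown CKD-EPI version {version!r}; use 2009 or 2021")
    if not 0 < egfr <= 300:
        raise ValueError(f"target eGFR outside attainable range: {egfr}")
    c = _CKD_EPI[version]
    kappa = c["kappa"][sex]
    alpha = c["alpha"][sex]
    knot = c["intercept"] * c["age_decay"] ** age  # eGFR at scr == kappa
    if sex == "female":
        knot *= c["female_factor"]
    if egfr >= knot:  # low-creatinine branch, exponent alpha < 0
        r = (egfr / knot) ** (1.0 / alpha)
    else:  # high-creatinine branch, exponent beta < 0
        r = (egfr / knot) ** (1.0 / c["beta"])
    return kappa * r


def bsa(height: float, weight: float, method: str = "mosteller") -> float:
    """Body surface area (m²) by Mosteller (default) or Du Bois."""
    if not height > 0 or not weight > 0:
        raise ValueError("height and weight must be positive")
    if method == "mosteller":
        return float(np.sqrt(weight * height / 3600.0))
    if method == "dubois":
        return 0.007184 * weight**0.425 * height**0.725
    raise ValueError(f"unknown BSA method {method!r}")


def bsa_readjust_egfr(egfr_normalized, bsa_m2):
    """De-normalize a BSA-indexed eGFR: eGFR_abs = eGFR · BSA / 1.73 (mL/min).

    Accepts scalars or numpy/pandas arrays (vectorized).
    """
    e = np.asarray(egfr_normalized, dtype=float)
    b = np.asarray(bsa_m2, dtype=float)
    if np.any(e <= 0) or np.any(b <= 0):
        raise ValueError("eGFR and BSA must be positive")
    out = e * b / 1.73
    if np.isscalar(egfr_normalized) and np.isscalar(bsa_m2):
        return float(out)
    return out


@dataclass
class Patient:
    """One dosing subject: renal function, body size and target exposure.

    ``crcl``/``egfr_normalized``/``bsa`` may be supplied directly (as in
    EHR extracts that already carry them) or derived from demographics via
    :meth:`from_demographics`.
    """

    id: str
    sex: Sex
    target_auc: float
    crcl: float
    egfr_normalized: float
    bsa: float
    age: float | None = None
    weight: float | None = None
    height: float | None = None
    serum_creatinine: float | None = None
    dataset_label: str = ""

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        for name in ("target_auc", "crcl", "egfr_normalized", "bsa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def egfr_absolute(self) -> float:
        """BSA-readjusted eGFR in mL/min."""
        return bsa_readjust_egfr(self.egfr_normalized, self.bsa)

    @classmethod
    def from_demographics(
        cls,
        id: str,
        sex: Sex,
        age: float,
        weight: float,
        height: float,
        serum_creatinine: float,
        target_auc: float,
        dataset_label: str = "",
        ckd_epi_version: int = 2021,
        bsa_method: str = "mosteller",
    ) -> "Patient":
        b = bsa(height, weight, bsa_method)
        return cls(
            id=id,
            sex=sex,
            target_auc=target_auc,
            crcl=cockcroft_gault(age, weight, serum_creatinine, sex),
            egfr_normalized=ckd_epi(serum_creatinine, age, sex, ckd_epi_version),
            bsa=b,
            age=age,
            weight=weight,
            height=height,
            serum_creatinine=serum_creatinine,
            dataset_label=dataset_label,
        )


COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "weight_kg",
    "height_cm",
    "scr",
    "bsa",
    "crcl",
    "egfr_normalized",
    "egfr_absolute",
    "target_auc",
    "dataset_label",
]


def read_cohort_csv(
    path: str | Path,
    ckd_epi_version: int = 2021,
    bsa_method: str = "mosteller",
) -> pd.DataFrame:
    """Read a patient cohort CSV into the canonical cohort frame.

    Precomputed ``crcl``, ``egfr_normalized`` and ``bsa`` columns are
    accepted verbatim; any of them that is missing is derived from the
    demographic columns (age, weight_kg, height_cm, scr[, scr_unit]).
    ``egfr_absolute`` is always (re)derived from eGFR and BSA.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or "target_auc" not in df.columns:
        raise ValueError("cohort CSV needs at least 'id' and 'target_auc' columns")
    if "sex" not in df.columns:
        df["sex"] = "female"
    if "dataset_label" not in df.columns:
        df["dataset_label"] = ""
    if "scr" in df.columns and "scr_unit" in df.columns:
        umol = df["scr_unit"].astype(str).str.lower().isin(["umol/l", "µmol/l", "umol"])
        df.loc[umol, "scr"] = df.loc[umol, "scr"] / UMOL_PER_MGDL
        df = df.drop(columns=["scr_unit"])
    if "bsa" not in df.columns:
        df["bsa"] = [
            bsa(h, w, bsa_method) for h, w in zip(df["height_cm"], df["weight_kg"])
        ]
    if "crcl" not in df.columns:
        df["crcl"] = [
            cockcroft_gault(a, w, s, x)
            for a, w, s, x in zip(df["age"], df["weight_kg"], df["scr"], df["sex"])
        ]
    if "egfr_normalized" not in df.columns:
        df["egfr_normalized"] = [
            ckd_epi(s, a, x, ckd_epi_version)
            for s, a, x in zip(df["scr"], df["age"], df["sex"])
        ]
    df["egfr_absolute"] = bsa_readjust_egfr(df["egfr_normalized"], df["bsa"])
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[COHORT_COLUMNS]


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format="%.10g")
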