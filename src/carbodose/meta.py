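"""Random-effects meta-analysis of published population-PK parameter estimates.

Published carboplatin population-PK models report typical (fixed-effect)
parameter values together with either a relative standard error (RSE, %CV)
or a standard error (SE).  This module harmonizes those uncertainties,
pools each parameter across studies with an inverse-variance random-effects
model (DerSimonian–Laird or REML between-study variance), and standardizes
the pooled set to the units used by the exposure simulation
(CL mL/min, V1 L, K12/K21 1/min).

Uncertainty harmonization supports two constructions:

``se_mode="reported"``
    the printed RSE/SE is taken at face value as the standard error of the
    typical value (RSE% -> SE = estimate * RSE/100).

``se_mode="sd_over_sqrt_n"``
    the printed value is treated as a subject-level standard deviation and
    converted to a standard error by dividing by sqrt(N).  This is the
    construction used when study summaries are pooled as mean +/- SD with N
    (the ``meta::metamean`` workflow in R).  Because the resulting
    within-study variances are tiny, between-study variance dominates the
    weights and the pooled mean is essentially the unweighted study mean,
    with I^2 in the high 90s; the result is insensitive to the exact N for
    N of a few dozen or more.  When a study table carries no subject
    counts, ``assumed_n`` is used.

``REFERENCE_POOLING_CONFIG`` is the documented configuration that reproduces the
published pooled carboplatin parameter set (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PARAMETERS",
    "StudyEstimate",
    "PooledParameter",
    "PooledParameterSet",
    "PoolingConfig",
    "REFERENCE_POOLING_CONFIG",
    "to_standard_error",
    "pool_random_effects",
    "heterogeneity",
    "standardize_units",
    "load_study_table",
    "packaged_study_table",
    "pool_study_table",
]

PARAMETERS = ("CL", "V1", "V2", "Q", "K12", "K21")

#: source-scale units of each PK parameter as published
PARAMETER_UNITS = {
    "CL": "L/h",
    "V1": "L",
    "V2": "L",
    "Q": "L/h",
    "K12": "1/h",
    "K21": "1/h",
}

Scale = Literal["linear", "log"]
Tau2Method = Literal["DL", "REML"]
SEMode = Literal["reported", "sd_over_sqrt_n"]


@dataclass(frozen=True)
class StudyEstimate:
    """One published fixed-effect PK parameter estimate with its uncertainty."""

    study_id: str
    parameter: str
    estimate: float
    uncertainty_value: float
    uncertainty_kind: Literal["RSE_percent", "SE"]
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not self.estimate > 0:
            raise ValueError(f"estimate must be positive, got {self.estimate}")
        if not self.uncertainty_value > 0:
            raise ValueError(
                f"uncertainty_value must be positive, got {self.uncertainty_value}"
            )
        if self.uncertainty_kind not in ("RSE_percent", "SE"):
            raise ValueError(f"unknown uncertainty_kind {self.uncertainty_kind!r}")
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive when given")


@dataclass(frozen=True)
class PooledParameter:
    """Meta-analytic summary for one PK parameter.

    ``I2_percent`` is ``None`` when not applicable (single study).
    ``tau2`` is reported on the pooling scale (log or linear).
    """

    parameter: str
    estimate: float
    ci95_low: float
    ci95_high: float
    tau2: float
    Q_stat: float
    df: int
    I2_percent: float | None
    k_studies: int
    pooling_scale: Scale
    tau2_method: str = "DL"
    se_mode: str = "reported"

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.estimate <= self.ci95_high):
            raise ValueError("estimate must lie inside its 95% CI")
        if self.tau2 < 0 or self.Q_stat < 0 or self.df < 0:
            raise ValueError("tau2, Q and df must be nonnegative")


@dataclass(frozen=True)
class PoolingConfig:
    """A documented meta-analysis configuration (the reproducibility lever)."""

    scale: Scale = "linear"
    tau2_method: Tau2Method = "REML"
    se_mode: SEMode = "reported"
    assumed_n: int = 100

    def describe(self) -> str:
        s = f"scale={self.scale}, tau2={self.tau2_method}, se_mode={self.se_mode}"
        if self.se_mode == "sd_over_sqrt_n":
            s += f" (assumed_n={self.assumed_n} when study N missing)"
        return s


#: configuration that reproduces the published pooled parameter set
REFERENCE_POOLING_CONFIG = PoolingConfig(
    scale="linear", tau2_method="REML", se_mode="sd_over_sqrt_n", assumed_n=100
)


def to_standard_error(
    e: StudyEstimate,
    scale: Scale = "linear",
    se_mode: SEMode = "reported",
    assumed_n: int = 100,
) -> float:
    """Harmonize a study's printed uncertainty to a standard error.

    On the linear scale an RSE% is ``estimate * RSE/100`` and an SE passes
    through; on the log scale the delta method gives ``SE_log =
    SE_linear/estimate``.  Under ``sd_over_sqrt_n`` the harmonized value is
    additionally divided by sqrt(N) (see module docstring).
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    if e.uncertainty_kind == "SE":
        se_lin = e.uncertainty_value
    else:
        se_lin = e.estimate * e.uncertainty_value / 100.0
    if se_mode == "sd_over_sqrt_n":
        n = e.n_subjects if e.n_subjects is not None else assumed_n
        se_lin = se_lin / np.sqrt(n)
    elif se_mode != "reported":
        raise ValueError(f"unknown se_mode {se_mode!r}")
    if scale == "log":
        return se_lin / e.estimate
    return se_lin


def heterogeneity(Q: float, df: int) -> float:
    """Higgins I^2 (%) from Cochran's Q and its degrees of freedom."""
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    if df < 0:
        raise ValueError("df must be nonnegative")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def _tau2_dl(y: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """DerSimonian–Laird tau^2 and Cochran's Q from fixed-effect weights."""
    w = 1.0 / s2
    mu = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu) ** 2))
    df = len(y) - 1
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return tau2, Q

def _tau2_reml(y: np.ndarray, s2: np.ndarray) -> float:
    """REML estimate of tau^2 by bounded scalar maximization."""

    def nll(t2: float) -> float:
        v = s2 + t2
        w = 1.0 / v
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    upper = max(10.0 * float(np.var(y, ddof=1)), 10.0 * float(np.max(s2)), 1e-8)
    res = optimize.minimize_scalar(
        nll, bounds=(0.0, upper), method="bounded", options={"xatol": 1e-14}
    )
    return float(res.x)


def pool_random_effects(
    estimates: Sequence[StudyEstimate],
    scale: Scale = "linear",
    tau2_method: Tau2Method = "REML",
    se_mode: SEMode = "reported",
    assumed_n: int = 100,
) -> PooledParameter:
    """Inverse-variance random-effects pooling of one parameter across studies.

    Q and I^2 are computed from fixed-effect weights; the pooled mean and
    its normal-theory 95% CI use random-effects weights ``1/(s_i^2 + tau^2)``
    and are back-transformed when pooling on the log scale.  With a single
    study the estimate is passed through with its own CI, ``tau2 = 0`` and
    ``I2_percent = None``.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("cannot pool an empty list of estimates")
    params = {e.parameter for e in estimates}
    if len(params) != 1:
        raise ValueError(f"mixed parameter names in pooling input: {sorted(params)}")
    parameter = estimates[0].parameter

    x = np.array([e.estimate for e in estimates], dtype=float)
    se = np.array(
        [to_standard_error(e, scale, se_mode, assumed_n) for e in estimates],
        dtype=float,
    )
    y = np.log(x) if scale == "log" else x
    s2 = se**2

    z = stats.norm.ppf(0.975)
    k = len(estimates)
    if k == 1:
        mu, sem = float(y[0]), float(se[0])
        tau2, Q, I2 = 0.0, 0.0, None
    else:
        tau2_dl, Q = _tau2_dl(y, s2)
        tau2 = tau2_dl if tau2_method == "DL" else _tau2_reml(y, s2)
        if tau2_method not in ("DL", "REML"):
            raise ValueError(f"unknown tau2_method {tau2_method!r}")
        w = 1.0 / (s2 + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        sem = float(1.0 / np.sqrt(np.sum(w)))
        I2 = heterogeneity(Q, k - 1)

    lo, hi = mu - z * sem, mu + z * sem
    if scale == "log":
        mu, lo, hi = float(np.exp(mu)), float(np.exp(lo)), float(np.exp(hi))
    return PooledParameter(
        parameter=parameter,
        estimate=mu,
        ci95_low=lo,
        ci95_high=hi,
        tau2=tau2 if k > 1 else 0.0,
        Q_stat=Q if k > 1 else 0.0,
        df=k - 1,
        I2_percent=I2,
        k_studies=k,
        pooling_scale=scale,
        tau2_method=tau2_method,
        se_mode=se_mode,
    )


@dataclass(frozen=True)
class PooledParameterSet:
    """Pooled typical PK values in simulation units (mL/min, L, 1/min).

    This is the "typical patient" two-compartment parameter set that drives
    every exposure prediction; no inter-individual variability is attached.
    """

    cl_ml_min: float
    v1_l: float
    k12_per_min: float
    k21_per_min: float
    provenance: tuple[PooledParameter, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("cl_ml_min", "v1_l", "k12_per_min", "k21_per_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        d = {
            "cl_ml_min": self.cl_ml_min,
            "v1_l": self.v1_l,
            "k12_per_min": self.k12_per_min,
            "k21_per_min": self.k21_per_min,
            "provenance": [asdict(p) for p in self.provenance],
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PooledParameterSet":
        prov = tuple(PooledParameter(**p) for p in d.get("provenance", []))
        return cls(
            cl_ml_min=d["cl_ml_min"],
            v1_l=d["v1_l"],
            k12_per_min=d["k12_per_min"],
            k21_per_min=d["k21_per_min"],
            provenance=prov,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PooledParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def standardize_units(
    cl_l_h: float,
    v1_l: float,
    k12_per_h: float,
    k21_per_h: float,
    provenance: Iterable[PooledParameter] = (),
) -> PooledParameterSet:
    """Convert pooled values from publication units (L/h, L, 1/h) to
    simulation units (mL/min, L, 1/min) by exact factors."""
    for name, v in (
        ("CL", cl_l_h),
        ("V1", v1_l),
        ("K12", k12_per_h),
        ("K21", k21_per_h),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return PooledParameterSet(
        cl_ml_min=cl_l_h * 1000.0 / 60.0,
        v1_l=v1_l,
        k12_per_min=k12_per_h / 60.0,
        k21_per_min=k21_per_h / 60.0,
        provenance=tuple(provenance),
    )


def load_study_table(path: str | Path) -> list[StudyEstimate]:
    """Read a study-parameter CSV (one row per published estimate)."""
    df = pd.read_csv(path)
    required = {"study_id", "parameter", "estimate", "uncertainty_value", "uncertainty_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        n = row.get("n_subjects")
        n = None if pd.isna(n) else int(n)
        out.append(
            StudyEstimate(
                study_id=str(row["study_id"]),
                parameter=str(row["parameter"]),
                estimate=float(row["estimate"]),
                uncertainty_value=float(row["uncertainty_value"]),
                uncertainty_kind=str(row["uncertainty_kind"]),
                n_subjects=n,
            )
        )
    return out


def packaged_study_table() -> list[StudyEstimate]:
    """The packaged table of published carboplatin PopPK estimates."""
    with resources.as_file(
        resources.files("carbodose.data").joinpath("study_estimates.csv")
    ) as p:
        return load_study_table(p)


def pool_study_table(
    estimates: Sequence[StudyEstimate],
    config: PoolingConfig = REFERENCE_POOLING_CONFIG,
) -> tuple[PooledParameterSet, dict[str, PooledParameter]]:
    """Pool every parameter in a study table and build the simulation set.

    Parameters reported by >= 2 studies are pooled; single-study parameters
    (peripheral volume and intercompartmental clearance in the packaged
    table) are passed through for provenance but are not part of the
    simulation set, which uses CL, V1 and the directly reported K12/K21.
    """
    by_param: dict[str, list[StudyEstimate]] = {}
    for e in estimates:
        by_param.setdefault(e.parameter, []).append(e)
    pooled = {
        p: pool_random_effects(
            es,
            scale=config.scale,
            tau2_method=config.tau2_method,
            se_mode=config.se_mode,
            assumed_n=config.assumed_n,
        )
        for p, es in by_param.items()
    }
    for need in ("CL", "V1", "K12", "K21"):
        if need not in pooled:
            raise ValueError(f"study table lacks parameter {need}")
    pset = standardize_units(
        cl_l_h=pooled["CL"].estimate,
        v1_l=pooled["V1"].estimate,
        k12_per_h=pooled["K12"].estimate,
        k21_per_h=pooled["K21"].estimate,
        provenance=[pooled[p] for p in sorted(pooled)],
    )
    return pset, pooled
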