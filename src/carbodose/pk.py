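"""Closed-form two-compartment model with constant-rate intravenous infusion.

The model: a central compartment (volume V1) eliminating with first-order
rate k10 = CL/V1, exchanging with a peripheral compartment by first-order
constants k12/k21.  Plasma concentration is a sum of two exponentials whose
rates (the hybrid constants λ1 > λ2 > 0) are the roots of

    λ² − (k10 + k12 + k21)·λ + k10·k21 = 0.

During an infusion at rate R0 the central concentration is

    C(t) = (R0 / V1) · Σᵢ Aᵢ (1 − e^{−λᵢ t}) / λᵢ ,      A₁ = (λ₁−k21)/(λ₁−λ₂),
                                                          A₂ = (k21−λ₂)/(λ₁−λ₂),

and after the infusion ends at T the two accumulated exponentials decay by
superposition.  AUC is integrated analytically piecewise; AUC(0→∞) reduces
to dose/CL exactly.

Internal canonical units are minutes, mg and mL, so AUC lands natively in
mg·min/mL as used by the Calvert formula.  Exposure predictions use the
pooled typical values only — no inter-individual variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meta import PooledParameterSet

__all__ = [
    "PKParameters",
    "InfusionRegimen",
    "ExposureResult",
    "hybrid_constants",
    "concentration",
    "auc",
    "auc_per_unit_dose",
]


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment parameters in simulation units (mL/min, L, 1/min)."""

    cl_ml_min: float
    v1_l: float
    k12_per_min: float
    k21_per_min: float

    def __post_init__(self) -> None:
        for name in ("cl_ml_min", "v1_l", "k21_per_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        # k12 = 0 is the decoupled limit (peripheral compartment never filled)
        if self.k12_per_min < 0:
            raise ValueError("k12_per_min must be nonnegative")

    @property
    def v1_ml(self) -> float:
        return self.v1_l * 1000.0

    @property
    def k10_per_min(self) -> float:
        """Elimination rate constant CL/V1 (1/min)."""
        return self.cl_ml_min / self.v1_ml

    @classmethod
    def from_pooled(cls, pset: PooledParameterSet) -> "PKParameters":
        return cls(
            cl_ml_min=pset.cl_ml_min,
            v1_l=pset.v1_l,
            k12_per_min=pset.k12_per_min,
            k21_per_min=pset.k21_per_min,
        )


@dataclass(frozen=True)
class InfusionRegimen:
    """A single constant-rate infusion; defaults are a 3 h infusion
    evaluated over a 24 h window."""

    dose_mg: float
    t_inf_min: float = 180.0
    horizon_min: float = 1440.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose must be nonnegative")
        if not self.t_inf_min > 0:
            raise ValueError("infusion duration must be positive")
        if self.horizon_min < self.t_inf_min:
            raise ValueError("horizon must not end before the infusion does")

    @property
    def rate_mg_min(self) -> float:
        return self.dose_mg / self.t_inf_min


@dataclass(frozen=True)
class ExposureResult:
    """Predicted exposure for one dose under the typical-value model."""

    dose_mg: float
    auc_0_horizon: float  # mg·min/mL
    auc_inf: float  # mg·min/mL == dose/CL
    profile: tuple = field(default_factory=tuple)  # optional (t_min, mg/mL) pairs


def hybrid_constants(p: PKParameters) -> tuple[float, float]:
    """Hybrid rate constants (λ1, λ2), λ1 > λ2 > 0, of the biexponential.

    Computed from the characteristic quadratic with a numerically stable
    product form (λ2 = k10·k21/λ1).  Near-repeated roots are rejected: the
    closed form below assumes distinct exponentials.
    """
    ksum = p.k10_per_min + p.k12_per_min + p.k21_per_min
    kprod = p.k10_per_min * p.k21_per_min
    disc = ksum * ksum - 4.0 * kprod
    if disc <= (1e-9 * ksum) ** 2:
        raise ValueError(
            "repeated hybrid rate constants (discriminant ~ 0); the "
            "biexponential closed form does not apply to this degenerate "
            "parameter set"
        )
    lam1 = 0.5 * (ksum + np.sqrt(disc))
    lam2 = kprod / lam1
    return float(lam1), float(lam2)


def _coefficients(p: PKParameters) -> tuple[float, float, float, float]:
    lam1, lam2 = hybrid_constants(p)
    a1 = (lam1 - p.k21_per_min) / (lam1 - lam2)
    a2 = (p.k21_per_min - lam2) / (lam1 - lam2)
    return lam1, lam2, a1, a2


def concentration(t, r: InfusionRegimen, p: PKParameters):
    """Central-compartment concentration (mg/mL) at time t (min, scalar or
    array) for a single constant-rate infusion starting at t = 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    lam1, lam2, a1, a2 = _coefficients(p)
    scale = r.rate_mg_min / p.v1_ml
    T = r.t_inf_min

    def during(tt):
        return scale * (
            a1 * (1.0 - np.exp(-lam1 * tt)) / lam1
            + a2 * (1.0 - np.exp(-lam2 * tt)) / lam2
        )

    def after(tt):
        return scale * (
            a1 * (1.0 - np.exp(-lam1 * T)) * np.exp(-lam1 * (tt - T)) / lam1
            + a2 * (1.0 - np.exp(-lam2 * T)) * np.exp(-lam2 * (tt - T)) / lam2
        )

    out = np.where(t_arr <= T, during(np.minimum(t_arr, T)), after(np.maximum(t_arr, T)))
    if np.isscalar(t):
        return float(out)
    return out


def auc(r: InfusionRegimen, p: PKParameters, t_end: float | None = None) -> float:
    """AUC (mg·min/mL) of the central concentration from 0 to ``t_end``.

    ``t_end=None`` (or ``inf``) gives the exact AUC(0→∞) = dose/CL.
    Integration is analytic on each piece of the profile.
    """
    if t_end is None or np.isinf(t_end):
        return r.dose_mg / p.cl_ml_min
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    lam1, lam2, a1, a2 = _coefficients(p)
    scale = r.rate_mg_min / p.v1_ml
    T = r.t_inf_min

    def int_during(tt):
        # ∫0^tt (1 − e^{−λu})/λ du = tt/λ − (1 − e^{−λ tt})/λ²
        return scale * (
            a1 * (tt / lam1 - (1.0 - np.exp(-lam1 * tt)) / lam1**2)
            + a2 * (tt / lam2 - (1.0 - np.exp(-lam2 * tt)) / lam2**2)
        )

    if t_end <= T:
        return float(int_during(t_end))
    tail = t_end - T
    post = scale * (
        a1 * (1.0 - np.exp(-lam1 * T)) * (1.0 - np.exp(-lam1 * tail)) / lam1**2
        + a2 * (1.0 - np.exp(-lam2 * T)) * (1.0 - np.exp(-lam2 * tail)) / lam2**2
    )
    return float(int_during(T) + post)


def auc_per_unit_dose(
    p: PKParameters, t_inf_min: float = 180.0, horizon_min: float = 1440.0
) -> float:
    """AUC(0→horizon) per mg of dose.

    The model is linear in dose, so cohort exposure predictions reduce to
    ``dose · auc_per_unit_dose``.  Equals f24/CL where f24 is the fraction
    of AUC(0→∞) captured inside the horizon.
    """
    reg = InfusionRegimen(dose_mg=1.0, t_inf_min=t_inf_min, horizon_min=horizon_min)
    return auc(reg, p, horizon_min)


def predict_exposure_for_dose(
    dose_mg: float,
    p: PKParameters,
    t_inf_min: float = 180.0,
    horizon_min: float = 1440.0,
    profile_times=None,
) -> ExposureResult:
    """Full exposure prediction (AUC over the window, AUC∞, optional profile)."""
    reg = InfusionRegimen(dose_mg=dose_mg, t_inf_min=t_inf_min, horizon_min=horizon_min)
    prof: tuple = ()
    if profile_times is not None and dose_mg > 0:
        c = concentration(np.asarray(profile_times, dtype=float), reg, p)
        prof = tuple(zip(np.asarray(profile_times, dtype=float).tolist(), c.tolist()))
    return ExposureResult(
        dose_mg=dose_mg,
        auc_0_horizon=auc(reg, p, horizon_min) if dose_mg > 0 else 0.0,
        auc_inf=dose_mg / p.cl_ml_min,
        profile=prof,
    )
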