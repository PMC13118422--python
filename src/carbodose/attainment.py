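"""Target-attainment classification and the α sweep.

Predicted 24 h exposures are classified against the carboplatin AUC bands
used for previously treated patients: target 4–6 mg·min/mL (inclusive),
under-exposure < 4 (reduced efficacy), over-exposure ≥ 7 (increased
myelotoxicity).  The open interval (6, 7) is a gap band that belongs to
none of the three named categories; it is reported explicitly so the four
proportions sum to 100%.

The α sweep evaluates the modified formula Dose = AUC·(eGFR_abs + 25 + α)
over an integer grid (default −25…+25 mL/min) and selects the α that
improves on the conventional eGFR formula: under-exposure ≤ baseline,
attainment ≥ baseline, over-exposure ≤ baseline, with at least one strict
improvement; ties resolve to the smallest |α|, then to the positive sign
(minimal perturbation of the established formula).  Selection uses
unrounded proportions; rounding to one decimal is for reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dosing import DoseFormula, cohort_exposures
from .meta import PooledParameterSet

__all__ = [
    "AttainmentBands",
    "BandProportions",
    "AlphaSweepResult",
    "classify",
    "cohort_proportions",
    "alpha_sweep",
    "select_alpha",
]

CATEGORIES = ("under", "target", "gap", "over")


@dataclass(frozen=True)
class AttainmentBands:
    """AUC band edges (mg·min/mL): under < target_low ≤ target ≤ target_high
    < gap < over_min ≤ over."""

    target_low: float = 4.0
    target_high: float = 6.0
    over_min: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.target_low <= self.target_high < self.over_min:
            raise ValueError("band edges must satisfy 0 < low <= high < over_min")


DEFAULT_BANDS = AttainmentBands()


def classify(auc, bands: AttainmentBands = DEFAULT_BANDS):
    """Band label(s) for AUC value(s): under | target | gap | over."""
    a = np.asarray(auc, dtype=float)
    if np.any(a < 0):
        raise ValueError("AUC must be nonnegative")
    out = np.select(
        [a < bands.target_low, a <= bands.target_high, a < bands.over_min],
        ["under", "target", "gap"],
        default="over",
    )
    if np.isscalar(auc):
        return str(out)
    return out


@dataclass(frozen=True)
class BandProportions:
    """Cohort percentages (unrounded) and raw counts per band."""

    n: int
    pct_under: float
    pct_target: float
    pct_gap: float
    pct_over: float
    counts: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 1) -> dict:
        return {
            "pct_under": round(self.pct_under, ndigits),
            "pct_target": round(self.pct_target, ndigits),
            "pct_gap": round(self.pct_gap, ndigits),
            "pct_over": round(self.pct_over, ndigits),
        }


def proportions_from_aucs(
    aucs: Sequence[float] | np.ndarray, bands: AttainmentBands = DEFAULT_BANDS
) -> BandProportions:
    a = np.asarray(aucs, dtype=float)
    if a.size == 0:
        raise ValueError("empty cohort: no AUCs to classify")
    labels = classify(a, bands)
    counts = {c: int(np.sum(labels == c)) for c in CATEGORIES}
    n = a.size
    return BandProportions(
        n=n,
        pct_under=100.0 * counts["under"] / n,
        pct_target=100.0 * counts["target"] / n,
        pct_gap=100.0 * counts["gap"] / n,
        pct_over=100.0 * counts["over"] / n,
        counts=counts,
    )


def cohort_proportions(
    cohort: pd.DataFrame,
    f: DoseFormula,
    params: PooledParameterSet,
    bands: AttainmentBands = DEFAULT_BANDS,
    t_inf_min: float = 180.0,
    horizon_min: float = 1440.0,
) -> BandProportions:
    """Dose the cohort with ``f``, predict 24 h AUCs, and tabulate bands."""
    exp = cohort_exposures(cohort, f, params, t_inf_min, horizon_min)
    return proportions_from_aucs(exp["auc_24h"].to_numpy(), bands)


@dataclass
class AlphaSweepResult:
    """Per-α attainment table with the conventional-eGFR baseline row and
    the selected optimum."""

    table: pd.DataFrame  # columns alpha, n, pct_under, pct_target, pct_gap, pct_over, qualifies
    baseline_alpha: float
    selected_alpha: int | None
    selection_rule: str

    @property
    def baseline(self) -> pd.Series:
        return self.table.loc[self.table["alpha"] == self.baseline_alpha].iloc[0]


SELECTION_RULE = (
    "qualify if pct_under <= baseline, pct_target >= baseline, "
    "pct_over <= baseline, with >= 1 strict improvement (unrounded); "
    "pick smallest |alpha|, ties to positive"
)


def _qualifies(row, base, tol: float = 0.0) -> bool:
    no_worse = (
        row["pct_under"] <= base["pct_under"] + tol
        and row["pct_target"] >= base["pct_target"] - tol
        and row["pct_over"] <= base["pct_over"] + tol
    )
    strictly_better = (
        row["pct_under"] < base["pct_under"] - tol
        or row["pct_target"] > base["pct_target"] + tol
        or row["pct_over"] < base["pct_over"] - tol
    )
    return bool(no_worse and strictly_better)


def alpha_sweep(
    cohort: pd.DataFrame,
    params: PooledParameterSet,
    alphas: Iterable[int] = range(-25, 26),
    bands: AttainmentBands = DEFAULT_BANDS,
    t_inf_min: float = 180.0,
    horizon_min: float = 1440.0,
) -> AlphaSweepResult:
    """Attainment proportions for the modified formula across an α grid.

    The α = 0 row is structurally identical to the conventional eGFR
    formula and serves as the selection baseline; if 0 is not on the grid
    the baseline is computed anyway (and not listed as a candidate).
    """
    alphas = sorted(set(int(a) for a in alphas))
    if not alphas:
        raise ValueError("empty alpha grid")
    rows = []
    for a in alphas:
        f = DoseFormula("egfr_modified", alpha=float(a))
        p = cohort_proportions(cohort, f, params, bands, t_inf_min, horizon_min)
        rows.append(
            {
                "alpha": a,
                "n": p.n,
                "pct_under": p.pct_under,
                "pct_target": p.pct_target,
                "pct_gap": p.pct_gap,
                "pct_over": p.pct_over,
            }
        )
    table = pd.DataFrame(rows)
    base = cohort_proportions(
        cohort, DoseFormula("egfr_conventional"), params, bands, t_inf_min, horizon_min
    )
    base_row = {
        "pct_under": base.pct_under,
        "pct_target": base.pct_target,
        "pct_over": base.pct_over,
    }
    table["qualifies"] = [
        _qualifies(r, base_row) and r["alpha"] != 0 for _, r in table.iterrows()
    ]
    selected = select_alpha(table)
    return AlphaSweepResult(
        table=table,
        baseline_alpha=0.0,
        selected_alpha=selected,
        selection_rule=SELECTION_RULE,
    )


def select_alpha(table: pd.DataFrame) -> int | None:
    """Pick the qualifying α with smallest |α| (ties resolve positive)."""
    q = table.loc[table["qualifies"], "alpha"].astype(int).tolist()
    if not q:
        return None
    return min(q, key=lambda a: (abs(a), -np.sign(a)))
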