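"""Fed-batch culture kinetics and titer unit conversion.

Implements the standard bioprocess quantities for a fed-batch run:

* specific growth rate µ (h⁻¹), the slope of ln(VCD) vs time during
  exponential growth (VCD = VCD₀·e^{µt});
* cumulative integral of viable cell density, IVCD (cells·h/mL), by the
  trapezium rule: IVCD_t = IVCD_{t−1} + ½(VCD_t + VCD_{t−1})·Δt;
* cell-specific productivity q_p, either the literal two-point quotient
  (P_t2 − P_t1)/(IVCD_t2 − IVCD_t1) or, by default, the least-squares
  slope of titer against IVCD over the whole run;
* unit conversions for products assayed in activity units: U/mL → mg/L
  via a specific activity (erythropoietin: 150 U/µg per the WHO 3rd
  International Standard), and µU/cell/day → pg/cell/day (pcd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CultureTimeSeries",
    "KineticsResult",
    "KineticsError",
    "fit_specific_growth_rate",
    "cumulative_ivcd",
    "fit_specific_productivity",
    "convert_titer",
    "convert_qp_units",
    "analyze_culture",
    "EPO_SPECIFIC_ACTIVITY",
]

#: U/µg, WHO 3rd International Standard for erythropoietin (NIBSC 11/170).
EPO_SPECIFIC_ACTIVITY = 150.0


class KineticsError(ValueError):
    """Invalid culture data for a kinetics fit."""


@dataclass(frozen=True)
class CultureTimeSeries:
    """A sampled culture trajectory.

    Times are hours and must be strictly increasing; titer may be in any
    consistent unit (U/mL or mg/L) — it is never assumed non-decreasing.
    """

    t: np.ndarray
    vcd: np.ndarray
    titer: np.ndarray | None = None
    viability: np.ndarray | None = None
    metabolites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "vcd", np.asarray(self.vcd, dtype=float))
        if self.titer is not None:
            object.__setattr__(self, "titer", np.asarray(self.titer, dtype=float))
        if self.t.ndim != 1 or self.t.size == 0:
            raise KineticsError("time vector must be 1-D and non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise KineticsError("sampling times must be strictly increasing")
        if self.vcd.shape != self.t.shape:
            raise KineticsError("vcd and t must be the same length")
        if np.any(self.vcd < 0):
            raise KineticsError("vcd must be non-negative")
        if self.titer is not None and self.titer.shape != self.t.shape:
            raise KineticsError("titer and t must be the same length")


@dataclass(frozen=True)
class KineticsResult:
    """Fitted kinetics of one culture."""

    mu: float  # h⁻¹
    ivcd: np.ndarray  # cells·h/mL, ivcd[0] == 0, non-decreasing
    qp: float | None  # titer units per (cells·h/mL)
    conversion_factor: float = EPO_SPECIFIC_ACTIVITY  # U/µg


def _resolve_window(series: CultureTimeSeries, window) -> np.ndarray:
    """Indices selected by ``window``: None → all vcd>0; (lo, hi) index
    range (inclusive); or an explicit index sequence."""
    if window is None:
        return np.flatnonzero(series.vcd > 0)
    if isinstance(window, tuple) and len(window) == 2:
        lo, hi = window
        return np.arange(lo, hi + 1)
    return np.asarray(window, dtype=int)


def fit_specific_growth_rate(series: CultureTimeSeries, window=None) -> float:
    """OLS slope of ln(VCD) vs t over the window, in h⁻¹.

    ``window`` selects the exponential phase: ``None`` uses every point
    with VCD > 0, a ``(lo, hi)`` tuple an inclusive index range, and any
    other sequence explicit indices.
    """
    idx = _resolve_window(series, window)
    if idx.size < 2:
        raise KineticsError("growth-rate fit needs at least 2 points")
    t = series.t[idx]
    vcd = series.vcd[idx]
    if np.any(vcd <= 0):
        raise KineticsError("all VCD values in the fit window must be > 0")
    return float(stats.linregress(t, np.log(vcd)).slope)


def cumulative_ivcd(series: CultureTimeSeries) -> np.ndarray:
    """Cumulative trapezium-rule integral of VCD over time.

    ``ivcd[0] == 0``; units cells·h/mL for VCD in cells/mL and t in hours.
    """
    increments = 0.5 * (series.vcd[1:] + series.vcd[:-1]) * np.diff(series.t)
    return np.concatenate(([0.0], np.cumsum(increments)))


def fit_specific_productivity(
    titer: np.ndarray,
    ivcd: np.ndarray,
    mode: str = "regression",
) -> float:
    """Cell-specific productivity q_p from aligned titer and IVCD series.

    ``regression`` (default) is the least-squares slope of titer vs IVCD
    over all points; ``two-point`` the literal quotient between the first
    and last samples.
    """
    titer = np.asarray(titer, dtype=float)
    ivcd = np.asarray(ivcd, dtype=float)
    if titer.shape != ivcd.shape or titer.ndim != 1:
        raise KineticsError("titer and IVCD series must be aligned 1-D arrays")
    if titer.size < 2:
        raise KineticsError("productivity fit needs at least 2 points")
    if mode == "two-point":
        d_ivcd = ivcd[-1] - ivcd[0]
        if d_ivcd == 0:
            raise KineticsError("zero IVCD increment in two-point mode")
        return float((titer[-1] - titer[0]) / d_ivcd)
    if mode == "regression":
        return float(stats.linregress(ivcd, titer).slope)
    raise ValueError(f"unknown mode {mode!r}")


def convert_titer(
    u_per_ml: float,
    specific_activity: float = EPO_SPECIFIC_ACTIVITY,
    rounding: str = "none",
) -> float:
    """Convert an activity titer (U/mL) to a mass titer (mg/L).

    U/mL ÷ U/µg = µg/mL = mg/L.  ``rounding="integer"`` applies the
    nearest-integer display convention of published titer tables.
    """
    if u_per_ml < 0:
        raise ValueError("titer must be non-negative")
    if specific_activity <= 0:
        raise ValueError("specific activity must be positive")
    mg_per_l = u_per_ml / specific_activity
    if rounding == "integer":
        return float(round(mg_per_l))
    if rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    return mg_per_l


def convert_qp_units(
    qp_uu_per_cell_day: float,
    specific_activity: float = EPO_SPECIFIC_ACTIVITY,
) -> float:
    """Convert q_p from µU/cell/day to pg/cell/day (pcd).

    µU ÷ (U/µg) = 10⁻⁶ µg = 1 pg, so the conversion is a direct quotient:
    150 µU/cell/day at 150 U/µg is exactly 1 pcd.
    """
    if specific_activity <= 0:
        raise ValueError("specific activity must be positive")
    return qp_uu_per_cell_day / specific_activity


def analyze_culture(
    series: CultureTimeSeries,
    growth_window=None,
    qp_mode: str = "regression",
    specific_activity: float = EPO_SPECIFIC_ACTIVITY,
) -> KineticsResult:
    """Fit µ, IVCD and (when a titer series is present) q_p in one call."""
    ivcd = cumulative_ivcd(series)
    qp = (
        fit_specific_productivity(series.titer, ivcd, mode=qp_mode)
        if series.titer is not None
        else None
    )
    return KineticsResult(
        mu=fit_specific_growth_rate(series, growth_window),
        ivcd=ivcd,
        qp=qp,
        conversion_factor=specific_activity,
    )
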