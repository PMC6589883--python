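"""Electrochemical performance metrics for soil microbial fuel cells.

Converts logged voltage traces (across a known external resistance) and
polarization sweeps into the standard MFC performance figures: current
density I' = U/(R*A), power density P' = U^2/(R*A) (both normalised to
the projected cathode area A), accumulated charge Q = integral of U/R dt,
start-up time, open-circuit voltage and internal resistance.

Units are V, ohm, m^2 and s internally; current density is reported in
mA m^-2, power density in mW m^-2 and charge in coulombs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VoltageTrace",
    "PolarizationSweep",
    "PolarizationFit",
    "MFCMetrics",
    "current_density",
    "power_density",
    "accumulate_charge",
    "startup_time",
    "fit_polarization",
    "percent_increase",
    "percent_increase_int",
    "trace_metrics",
    "read_traces",
    "read_sweeps",
]

#: default sampling/cycle interval of the data logger, seconds
DEFAULT_INTERVAL_S = 1800.0


@dataclass(frozen=True)
class VoltageTrace:
    """Timestamped voltage of one reactor under a fixed external resistance."""

    reactor_id: str
    treatment: str
    time_s: np.ndarray
    voltage_V: np.ndarray
    resistance_ohm: float = 100.0
    cathode_area_m2: float = 0.0036

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        u = np.asarray(self.voltage_V, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "voltage_V", u)
        if t.size != u.size:
            raise ValueError("time and voltage lengths differ")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if self.resistance_ohm <= 0 or self.cathode_area_m2 <= 0:
            raise ValueError("resistance and cathode area must be positive")


@dataclass(frozen=True)
class PolarizationSweep:
    """(external resistance, voltage) pairs from a polarization run."""

    resistance_ohm: np.ndarray
    voltage_V: np.ndarray
    treatment: str = ""
    cathode_area_m2: float = 0.0036

    def __post_init__(self):
        r = np.asarray(self.resistance_ohm, dtype=float)
        u = np.asarray(self.voltage_V, dtype=float)
        object.__setattr__(self, "resistance_ohm", r)
        object.__setattr__(self, "voltage_V", u)
        if r.size != u.size:
            raise ValueError("resistance and voltage lengths differ")
        if (r <= 0).any():
            raise ValueError("resistances must be positive")


@dataclass(frozen=True)
class PolarizationFit:
    """Result of the ohmic-region line fit U = OCV - Rint * I."""

    ocv_V: float
    internal_resistance_ohm: float
    power_curve: pd.DataFrame  # resistance, voltage, I', P'
    ocv_measured_V: float | None = None

    @property
    def max_power_density_mW_m2(self) -> float:
        return float(self.power_curve["power_density_mW_m2"].max())


@dataclass(frozen=True)
class MFCMetrics:
    """Per-reactor performance summary derived from one voltage trace."""

    reactor_id: str
    treatment: str
    startup_time_h: float
    first_peak_mA_m2: float
    max_current_density_mA_m2: float
    charge_C: float
    mean_power_density_mW_m2: float


def current_density(voltage_V, resistance_ohm: float, area_m2: float):
    """Current density I' = U/(R*A) in mA m^-2."""
    if resistance_ohm <= 0 or area_m2 <= 0:
        raise ValueError("resistance and area must be positive")
    return np.asarray(voltage_V, dtype=float) / (resistance_ohm * area_m2) * 1e3


def power_density(voltage_V, resistance_ohm: float, area_m2: float):
    """Power density P' = U^2/(R*A) in mW m^-2."""
    if resistance_ohm <= 0 or area_m2 <= 0:
        raise ValueError("resistance and area must be positive")
    u = np.asarray(voltage_V, dtype=float)
    return u * u / (resistance_ohm * area_m2) * 1e3


def accumulate_charge(trace: VoltageTrace, method: str = "rectangle",
                      interval_s: float | None = None) -> float:
    """Accumulated charge Q = integral of U/R dt, in coulombs.

    The default rectangle rule mirrors the per-cycle bookkeeping of MFC
    data loggers: each sample contributes U*dt/R where dt is the gap to the
    next sample (left rule over intervals), making Q additive when traces
    are concatenated. A single-sample trace needs ``interval_s`` (or falls
    back to the 1800 s logging cycle). ``method="trapezoid"`` integrates
    the same samples trapezoidally.
    """
    u = trace.voltage_V
    t = trace.time_s
    if u.size == 0:
        raise ValueError("empty trace")
    if u.size == 1:
        dt = interval_s if interval_s is not None else DEFAULT_INTERVAL_S
        return float(u[0] * dt / trace.resistance_ohm)
    if method == "rectangle":
        dts = np.diff(t)
        return float(np.sum(u[:-1] * dts) / trace.resistance_ohm)
    if method == "trapezoid":
        return float(np.trapezoid(u, t) / trace.resistance_ohm)
    raise ValueError(f"unknown integration method {method!r}")


def startup_time(trace: VoltageTrace, threshold_V: float = 0.001) -> float:
    """First time (hours) the voltage exceeds ``threshold_V`` (default 1 mV).

    Returns ``nan`` when the trace never crosses the threshold.
    """
    above = trace.voltage_V > threshold_V
    if not above.any():
        return float("nan")
    return float(trace.time_s[int(np.argmax(above))] / 3600.0)


def fit_polarization(sweep: PolarizationSweep,
                     exclude_top_current_frac: float = 0.10,
                     ocv_measured_V: float | None = None) -> PolarizationFit:
    """Fit the ohmic region of a polarization sweep.

    Each point is converted to cell current I = U/R; OCV and internal
    resistance come from a least-squares line U = OCV - Rint*I fitted after
    discarding the highest-current ``exclude_top_current_frac`` of points
    (where activation/mass-transport losses bend the curve). The returned
    power curve reports current and power densities per point.
    """
    r = sweep.resistance_ohm
    u = sweep.voltage_V
    if r.size < 3:
        raise ValueError("polarization fit needs at least 3 sweep points")
    i = u / r  # amperes
    if np.ptp(i) == 0:
        raise ValueError("degenerate sweep: all points carry the same current")
    n_drop = int(np.floor(exclude_top_current_frac * i.size))
    keep = np.argsort(i)[: i.size - n_drop] if n_drop else np.arange(i.size)
    if keep.size < 2:
        keep = np.arange(i.size)
    slope, intercept = np.polyfit(i[keep], u[keep], 1)
    rint = -float(slope)
    ocv = float(intercept)
    if rint <= 0:
        raise ValueError("fitted internal resistance is non-positive")
    order = np.argsort(i)
    curve = pd.DataFrame(
        {
            "resistance_ohm": r[order],
            "voltage_V": u[order],
            "current_density_mA_m2": current_density(u[order], 1.0, sweep.cathode_area_m2) / r[order],
            "power_density_mW_m2": power_density(u[order], 1.0, sweep.cathode_area_m2) / r[order],
        }
    )
    return PolarizationFit(ocv, rint, curve, ocv_measured_V)


def percent_increase(a: float, b: float) -> float:
    """Relative change of ``a`` over baseline ``b``: (a - b)/b * 100."""
    if b == 0:
        raise ValueError("baseline must be non-zero")
    return (a - b) / b * 100.0


def percent_increase_int(a: float, b: float) -> int:
    """``percent_increase`` rounded to the nearest integer percent."""
    return int(round(percent_increase(a, b)))


def trace_metrics(trace: VoltageTrace, first_peak_window_days=(1.0, 3.0),
                  threshold_V: float = 0.001) -> MFCMetrics:
    """Summarise one trace: start-up, first/maximum current density, charge."""
    i = current_density(trace.voltage_V, trace.resistance_ohm,
                        trace.cathode_area_m2)
    t_days = trace.time_s / 86400.0
    lo, hi = first_peak_window_days
    win = (t_days >= lo) & (t_days <= hi)
    first_peak = float(i[win].max()) if win.any() else float("nan")
    p = power_density(trace.voltage_V, trace.resistance_ohm,
                      trace.cathode_area_m2)
    return MFCMetrics(
        reactor_id=trace.reactor_id,
        treatment=trace.treatment,
        startup_time_h=startup_time(trace, threshold_V),
        first_peak_mA_m2=first_peak,
        max_current_density_mA_m2=float(i.max()),
        charge_C=accumulate_charge(trace),
        mean_power_density_mW_m2=float(p.mean()),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_traces(path) -> list[VoltageTrace]:
    """Read a trace CSV (reactor, treatment, time_s, voltage_V, resistance_ohm
    [, cathode_area_m2]) into one VoltageTrace per reactor."""
    df = pd.read_csv(path)
    traces = []
    for reactor, sub in df.groupby("reactor", sort=True):
        sub = sub.sort_values("time_s")
        area = float(sub["cathode_area_m2"].iloc[0]) if "cathode_area_m2" in sub else 0.0036
        traces.append(
            VoltageTrace(
                reactor_id=str(reactor),
                treatment=str(sub["treatment"].iloc[0]) if "treatment" in sub else "",
                time_s=sub["time_s"].values,
                voltage_V=sub["voltage_V"].values,
                resistance_ohm=float(sub["resistance_ohm"].iloc[0]),
                cathode_area_m2=area,
            )
        )
    return traces


def read_sweeps(path) -> list[PolarizationSweep]:
    """Read a polarization CSV (treatment, resistance_ohm, voltage_V)."""
    df = pd.read_csv(path)
    sweeps = []
    for treatment, sub in df.groupby("treatment", sort=True):
        sweeps.append(
            PolarizationSweep(
                resistance_ohm=sub["resistance_ohm"].values,
                voltage_V=sub["voltage_V"].values,
                treatment=str(treatment),
            )
        )
    return sweeps


def write_metrics(metrics: list[MFCMetrics], path) -> None:
    pd.DataFrame([m.__dict__ for m in metrics]).to_csv(path, sep="\t", index=False)
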