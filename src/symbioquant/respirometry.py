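"""Flow-through respirometry: uptake rates and concentration-response slopes.

A vessel is perfused at constant flow; the animal's net removal of a
dissolved substrate (nitrate or ammonium) at each sampling time is the
steady-state mass balance

    removal(t) = flow * (c_in(t) - c_out(t))        [µmol / h]

and the uptake rate is the time-averaged removal over the steady-state
window, divided by the pooled animal wet weight (µmol g⁻¹ h⁻¹). Worms
acclimate before dosing, so only the final fraction of the trace (default
the last half) is averaged. An empty control vessel run under the same
regime estimates wall/tube effects; its time-averaged removal (unnormalized)
is subtracted before weight normalization. Negative rates indicate net
release (e.g. ammonia production by nitrate-reducing symbioses).

The concentration-response slope is an ordinary least-squares fit of rate
on mean ambient concentration; a quadratic-improvement diagnostic flags
saturation (a Michaelis-Menten-like plateau shows up as a negative
curvature capturing residual variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

SUBSTRATES = ("nitrate", "ammonium")


@dataclass
class RespirometryTrace:
    """Time series of inflow/outflow concentrations for one vessel."""

    vessel_id: str
    substrate: str
    times: np.ndarray  # hours, strictly increasing
    c_in: np.ndarray  # µM
    c_out: np.ndarray  # µM
    flow: float  # L/h
    wet_weight: float  # g; 0 allowed only for controls
    is_control: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.c_in = np.asarray(self.c_in, dtype=float)
        self.c_out = np.asarray(self.c_out, dtype=float)
        if self.substrate not in SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if not (np.diff(self.times) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if (self.c_in < 0).any() or (self.c_out < 0).any():
            raise ValidationError("concentrations must be nonnegative")
        if self.flow <= 0:
            raise ValidationError("flow must be positive")
        if not self.is_control and self.wet_weight <= 0:
            raise ValidationError("animal vessels need wet_weight > 0")

    @property
    def duration_h(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class UptakeResult:
    """Weight-normalized uptake rate for one vessel."""

    vessel_id: str
    substrate: str
    rate: float  # µmol g⁻¹ h⁻¹ (negative = net release)
    rate_se: float
    mean_ambient: float  # µM, mean effluent over the window
    control_corrected: bool


@dataclass
class SlopeResult:
    """Concentration-response regression of rate on ambient concentration."""

    slope: float  # µmol g⁻¹ h⁻¹ µM⁻¹
    intercept: float
    slope_se: float
    linearity: float  # fraction of linear-fit SSR removed by a quadratic term
    saturating: bool


def traces_from_table(df: pd.DataFrame) -> list[RespirometryTrace]:
    """Group a long-format trace table into RespirometryTrace objects."""
    traces = []
    for (vessel, substrate), grp in df.groupby(["vessel_id", "substrate"], sort=True):
        grp = grp.sort_values("time_h")
        traces.append(
            RespirometryTrace(
                vessel_id=str(vessel),
                substrate=str(substrate),
                times=grp["time_h"].to_numpy(),
                c_in=grp["c_in_uM"].to_numpy(),
                c_out=grp["c_out_uM"].to_numpy(),
                flow=float(grp["flow_L_h"].iloc[0]),
                wet_weight=float(grp["wet_weight_g"].iloc[0]),
                is_control=bool(grp["is_control"].iloc[0]),
            )
        )
    return traces


def _steady_window(trace: RespirometryTrace, steady_fraction: float) -> np.ndarray:
    if not (0 < steady_fraction <= 1):
        raise ValidationError("steady_fraction must lie in (0, 1]")
    t0, t1 = trace.times[0], trace.times[-1]
    start = t1 - steady_fraction * (t1 - t0)
    sel = trace.times >= start
    if sel.sum() < 2:  # degenerate window: fall back to the whole trace
        sel = np.ones_like(sel, dtype=bool)
    return sel


def _mean_removal(trace: RespirometryTrace, steady_fraction: float):
    sel = _steady_window(trace, steady_fraction)
    removal = trace.flow * (trace.c_in[sel] - trace.c_out[sel])
    n = removal.size
    se = float(removal.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(removal.mean()), se, float(trace.c_out[sel].mean())


def uptake_rate(
    trace: RespirometryTrace,
    control: RespirometryTrace | None = None,
    steady_fraction: float = 0.5,
) -> UptakeResult:
    """Weight-normalized, optionally control-corrected uptake rate.

    rate = (mean removal - mean control removal) / wet_weight over the
    steady-state window; rate_se propagates the time-series variance of the
    instantaneous removals (animal and control in quadrature).
    """
    if len(trace.times) < 3:
        raise ValidationError("need at least 3 time points")
    if not trace.is_control and trace.wet_weight <= 0:
        raise ValidationError("animal vessel needs wet_weight > 0")
    removal, removal_se, ambient = _mean_removal(trace, steady_fraction)
    corrected = False
    if control is not None:
        if control.substrate != trace.substrate:
            raise ValidationError(
                f"substrate mismatch: trace {trace.substrate} vs control {control.substrate}"
            )
        ctrl_removal, ctrl_se, _ = _mean_removal(control, steady_fraction)
        removal -= ctrl_removal
        removal_se = float(np.hypot(removal_se, ctrl_se))
        corrected = True
    weight = trace.wet_weight if trace.wet_weight > 0 else 1.0  # control-on-control check
    return UptakeResult(
        vessel_id=trace.vessel_id,
        substrate=trace.substrate,
        rate=removal / weight,
        rate_se=removal_se / weight,
        mean_ambient=ambient,
        control_corrected=corrected,
    )


def response_slope(results, saturation_threshold: float = 0.2) -> SlopeResult:
    """OLS fit of uptake rate on mean ambient concentration.

    *results* is a sequence of UptakeResult (or (ambient, rate) pairs) at
    >= 3 distinct ambient concentrations. The linearity diagnostic is the
    fractional reduction in residual sum of squares when a quadratic term
    is added; values above *saturation_threshold* flag saturation. A
    perfectly linear fit reports diagnostic 0.
    """
    pairs = [
        (r.mean_ambient, r.rate) if isinstance(r, UptakeResult) else (float(r[0]), float(r[1]))
        for r in results
    ]
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if len(np.unique(x)) < 3:
        raise ValidationError("need >= 3 distinct ambient concentrations")
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    X2 = sm.add_constant(np.column_stack([x, x * x]))
    quad = sm.OLS(y, X2).fit()
    ssr_lin = float(lin.ssr)
    ssr_quad = float(quad.ssr)
    linearity = 0.0 if ssr_lin <= 1e-300 else max(0.0, (ssr_lin - ssr_quad) / ssr_lin)
    # short series let a quadratic soak up residual by chance, so the flag
    # additionally requires concave-down curvature supported by an F-test
    saturating = linearity > saturation_threshold and float(quad.params[2]) < 0
    if saturating and len(x) > 3 and ssr_quad > 0:
        f_stat, p_value, _ = quad.compare_f_test(lin)
        saturating = bool(p_value < 0.05)
    return SlopeResult(
        slope=float(lin.params[1]),
        intercept=float(lin.params[0]),
        slope_se=float(lin.bse[1]),
        linearity=linearity,
        saturating=saturating,
    )


def rates_table(results) -> pd.DataFrame:
    """Tidy frame of UptakeResults for writing."""
    return pd.DataFrame(
        [
            {
                "vessel_id": r.vessel_id,
                "substrate": r.substrate,
                "rate_umol_g_h": r.rate,
                "rate_se": r.rate_se,
                "mean_ambient_uM": r.mean_ambient,
                "control_corrected": r.control_corrected,
            }
            for r in results
        ]
    )
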