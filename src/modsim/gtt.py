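"""Minimal glucose-insulin feedback model on top of the transport network.

The glucose tolerance test (GTT) is simulated by loading a 13 mM glucose dose
into the circulating loop and coupling two species on the device network:

* glucose (its own diffusivity), cleared in the liver chamber by
  insulin-dependent mass action on the excess over the resting media level:
  ``uptake_rate * I_LOC * (G_LOC - G_baseline)_+`` — net hepatic uptake
  ceases at euglycemia, so an undosed device stays at baseline;
* insulin, transported with the 4 kDa-dextran surrogate diffusivity,
  secreted in the pancreatic chamber with a biphasic threshold-linear law

      S(t) = amp * (G_POC - theta)_+ * exp(-lambda * t)
           + sustained_rate * (G_POC - theta)_+

  and relaxing everywhere toward the basal level at ``insulin_turnover``.

Disease and drug conditions scale secretion and uptake multiplicatively:
palmitate (pa) by ``pa_secretion_factor``/``pa_uptake_factor`` in (0, 1],
metformin additionally by boosts >= 1.

The glucose-stimulated insulin secretion (GSIS) assay is represented
off-device (organoids moved to a static well, as in the wet protocol):
alternating 1 h low / 1 h high glucose phases with the same secretion law,
the collected insulin integrated per phase.

None of these kinetic equations is measured directly; all magnitudes are
fitted to the sparse reported time courses (see :func:`fit_gtt_params`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize

from . import units
from .device import DeviceModel
from .transport import SolverFailure, rate_matrix

Condition = Literal["control", "pa", "pa_metformin"]

DEFAULT_DIFFUSIVITIES = {"glucose": 9.58e-10, "insulin": 1.35e-10}


class UnderdeterminedFitError(ValueError):
    """More free parameters than observations."""


class GlucoseInsulinParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    basal_insulin: float = Field(default=21.0, ge=0, description="ug/L")
    first_phase_amplitude: float = Field(default=2.0, ge=0, description="ug/(L*h) per mM above threshold")
    first_phase_decay: float = Field(default=0.2, ge=0, description="1/h")
    sustained_rate: float = Field(default=0.3, ge=0, description="ug/(L*h) per mM above threshold")
    glucose_threshold: float = Field(default=6.0, gt=2.8, lt=20.0, description="mM")
    uptake_rate: float = Field(default=0.02, ge=0, description="1/(h*(ug/L))")
    insulin_turnover: float = Field(default=0.005, ge=0, description="1/h")
    pa_secretion_factor: float = Field(default=1.0, gt=0, le=1)
    pa_uptake_factor: float = Field(default=0.1, gt=0, le=1)
    metformin_uptake_boost: float = Field(default=5.0, ge=1)
    metformin_secretion_boost: float = Field(default=1.2, ge=1)

    def condition_factors(self, condition: Condition) -> tuple[float, float]:
        """(secretion multiplier, uptake multiplier) for a culture condition."""
        if condition == "control":
            return 1.0, 1.0
        if condition == "pa":
            return self.pa_secretion_factor, self.pa_uptake_factor
        if condition == "pa_metformin":
            return (
                min(self.pa_secretion_factor * self.metformin_secretion_boost, 1.0),
                self.pa_uptake_factor * self.metformin_uptake_boost,
            )
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class GTTResult:
    condition: str
    glucose_trajectory: pd.DataFrame  # time_h, concentration (CC, mM)
    insulin_trajectory: pd.DataFrame  # time_h, concentration (CC, ug/L)
    peak_insulin: float
    auc_glucose: float
    auc_insulin_sustained: float
    provenance: dict = field(default_factory=dict)

    def glucose_at(self, t_h: float) -> float:
        return float(
            np.interp(t_h, self.glucose_trajectory["time_h"], self.glucose_trajectory["concentration"])
        )

    def insulin_at(self, t_h: float) -> float:
        return float(
            np.interp(t_h, self.insulin_trajectory["time_h"], self.insulin_trajectory["concentration"])
        )


@dataclass
class GSISResult:
    low_phase_insulin: list[float]   # ug/L per cycle
    high_phase_insulin: list[float]  # ug/L per cycle

    @property
    def stimulation_index(self) -> list[float]:
        return [h / l for h, l in zip(self.high_phase_insulin, self.low_phase_insulin)]


def trajectory_auc(
    traj: pd.DataFrame, t_start: float, t_end: float, reference: float | None = None
) -> float:
    """Trapezoidal AUC of a (time_h, concentration) trajectory over a window."""
    t = np.asarray(traj["time_h"], dtype=float)
    y = np.asarray(traj["concentration"], dtype=float)
    if not (t[0] <= t_start < t_end <= t[-1]):
        raise ValueError("AUC window is empty or outside the trajectory span")
    grid = np.unique(np.concatenate([[t_start, t_end], t[(t > t_start) & (t < t_end)]]))
    auc = float(np.trapezoid(np.interp(grid, t, y), grid))
    return auc / reference if reference is not None else auc


def simulate_gtt(
    device: DeviceModel,
    params: GlucoseInsulinParams,
    condition: Condition = "control",
    dose_mM: float = 13.0,
    duration_h: float = 24.0,
    baseline_glucose_mM: float = 5.5,
    diffusivities: Mapping[str, float] | None = None,
    sample_times_h: Sequence[float] | None = None,
) -> GTTResult:
    """Simulate a glucose tolerance test on the device.

    The dose fills the circulating loop (the injection-port protocol under
    flow); chambers start at the baseline media glucose.  Glucose and insulin
    are read out in the connecting channel, volume-weighted over its segments,
    mirroring where samples are drawn.
    """
    if dose_mM < 0:
        raise ValueError("dose must be non-negative")
    diff = dict(DEFAULT_DIFFUSIVITIES)
    if diffusivities:
        diff.update(diffusivities)

    f_sec, f_upt = params.condition_factors(condition)
    ids = device.ids
    ix = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    mg = rate_matrix(device, diff["glucose"], True) * units.H_TO_S   # per hour
    mi = rate_matrix(device, diff["insulin"], True) * units.H_TO_S
    i_poc, i_loc = ix["POC"], ix["LOC"]

    theta = params.glucose_threshold
    lam = params.first_phase_decay
    basal = params.basal_insulin

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        g, ins = y[:n], y[n:]
        dg = mg @ g
        dg[i_loc] -= f_upt * params.uptake_rate * ins[i_loc] * max(
            g[i_loc] - baseline_glucose_mM, 0.0
        )
        di = mi @ ins - params.insulin_turnover * (ins - basal)
        drive = max(g[i_poc] - theta, 0.0)
        di[i_poc] += f_sec * (
            params.first_phase_amplitude * drive * np.exp(-lam * t)
            + params.sustained_rate * drive
        )
        return np.concatenate([dg, di])

    g0 = np.full(n, baseline_glucose_mM)
    for c in device.compartments:
        if c.role != "organoid-chamber":
            g0[ix[c.id]] = dose_mM if dose_mM > 0 else baseline_glucose_mM
    y0 = np.concatenate([g0, np.full(n, basal)])

    t_grid = np.unique(
        np.concatenate([np.linspace(0.0, duration_h, int(duration_h * 10) + 1),
                        np.asarray(sample_times_h, dtype=float) if sample_times_h is not None else []])
    )
    if sample_times_h is not None and (min(sample_times_h) < 0 or max(sample_times_h) > duration_h):
        raise ValueError("sample times outside the simulated span")
    sol = solve_ivp(rhs, (0.0, duration_h), y0, t_eval=t_grid, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise SolverFailure(f"GTT integration failed: {sol.message}")

    cc = [c.id for c in device.compartments if c.role == "channel"]
    w = np.array([device.compartment(c).volume_uL for c in cc])
    w = w / w.sum()
    g_cc = sum(w[j] * sol.y[ix[c]] for j, c in enumerate(cc))
    i_cc = sum(w[j] * sol.y[n + ix[c]] for j, c in enumerate(cc))

    g_traj = pd.DataFrame({"time_h": t_grid, "concentration": np.maximum(g_cc, 0.0)})
    i_traj = pd.DataFrame({"time_h": t_grid, "concentration": np.maximum(i_cc, 0.0)})
    return GTTResult(
        condition=condition,
        glucose_trajectory=g_traj,
        insulin_trajectory=i_traj,
        peak_insulin=float(i_traj["concentration"].max()),
        auc_glucose=trajectory_auc(g_traj, 0.0, duration_h),
        auc_insulin_sustained=(
            trajectory_auc(i_traj, 4.0, min(24.0, duration_h)) if duration_h > 4 else float("nan")
        ),
        provenance={
            "condition": condition,
            "dose_mM": dose_mM,
            "baseline_glucose_mM": baseline_glucose_mM,
            "params": params.model_dump(),
        },
    )


CONTROL_FREE = ("basal_insulin", "first_phase_amplitude", "sustained_rate", "uptake_rate")
PA_FREE = ("pa_secretion_factor", "pa_uptake_factor")

_BOUNDS = {
    "basal_insulin": (5.0, 40.0),
    "first_phase_amplitude": (0.0, 50.0),
    "sustained_rate": (0.0, 20.0),
    "uptake_rate": (1e-4, 1.0),
    "pa_secretion_factor": (1e-3, 1.0),
    "pa_uptake_factor": (1e-3, 1.0),
}

_CONTROL_STARTS = (
    (20.8, 2.0, 0.3, 0.02),
    (21.5, 1.0, 0.6, 0.03),
    (19.0, 4.0, 0.1, 0.01),
)
_PA_STARTS = ((0.9, 0.02), (0.6, 0.1), (1.0, 0.003))


def fit_gtt_params(
    observed: pd.DataFrame,
    device: DeviceModel,
    base_params: GlucoseInsulinParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    dose_mM: float = 13.0,
) -> dict[str, GlucoseInsulinParams]:
    """Fit the minimal model to sparse observed GTT points, per condition.

    ``observed`` has columns ``condition, variable, time_h, value`` and
    optionally ``sd`` (weights are 1/sd when given, else uniform).  The
    control condition fixes the shared magnitudes (basal insulin, first-phase
    amplitude, sustained rate, uptake rate); the pa condition then fits only
    its two multiplicative factors with everything else held.  Kinetic shape
    parameters (threshold, first-phase decay, turnover) keep their defaults —
    with the sparse reported series they are not separately identifiable.

    Deterministic: a fixed multistart list, no randomness.
    """
    required = {"condition", "variable", "time_h", "value"}
    if observed is None or not required.issubset(getattr(observed, "columns", [])):
        raise ValueError(f"observed table must have columns {sorted(required)}")
    base = base_params or GlucoseInsulinParams()
    bnds = dict(_BOUNDS)
    if bounds:
        bnds.update(bounds)

    def weighted_residuals(params: GlucoseInsulinParams, condition: str, rows: pd.DataFrame):
        res = simulate_gtt(device, params, condition, dose_mM=dose_mM,
                           duration_h=float(rows["time_h"].max()) + 1e-9
                           if rows["time_h"].max() > 24 else 24.0)
        out = []
        for r in rows.itertuples():
            sim = res.glucose_at(r.time_h) if r.variable == "glucose" else res.insulin_at(r.time_h)
            sd = getattr(r, "sd", np.nan)
            w = 1.0 / sd if sd and np.isfinite(sd) and sd > 0 else 1.0
            out.append((sim - r.value) * w)
        return np.asarray(out)

    def minimize_stage(free, starts, make_params, rows, condition, polish_iter):
        """Multistart least squares in log-parameter space followed by a
        bounded simplex polish; the secretion magnitudes trade off along a
        shallow valley that gradient steps alone do not descend."""
        lo = np.log([max(bnds[p][0], 1e-8) for p in free])
        hi = np.log([bnds[p][1] for p in free])

        def resid(z):
            return weighted_residuals(make_params(np.exp(z)), condition, rows)

        best = None
        for start in starts:
            z0 = np.clip(np.log(np.asarray(start, dtype=float)), lo, hi)
            sol = least_squares(resid, z0, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
        if polish_iter:
            nm = minimize(
                lambda z: float(np.sum(resid(np.clip(z, lo, hi)) ** 2)),
                best.x,
                method="Nelder-Mead",
                options=dict(maxiter=polish_iter, xatol=1e-10, fatol=1e-12),
            )
            z = np.clip(nm.x, lo, hi)
            sol = least_squares(resid, z, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if sol.cost < best.cost:
                best = sol
        return np.exp(best.x)

    fitted: dict[str, GlucoseInsulinParams] = {}

    ctrl = observed[observed["condition"] == "control"]
    if len(ctrl) < len(CONTROL_FREE):
        raise UnderdeterminedFitError(
            f"{len(ctrl)} control observations cannot constrain {len(CONTROL_FREE)} free parameters"
        )
    x_ctrl = minimize_stage(
        CONTROL_FREE,
        _CONTROL_STARTS,
        lambda x: base.model_copy(update=dict(zip(CONTROL_FREE, x))),
        ctrl,
        "control",
        polish_iter=300,
    )
    control_params = base.model_copy(update=dict(zip(CONTROL_FREE, x_ctrl)))
    fitted["control"] = control_params

    pa = observed[observed["condition"] == "pa"]
    if len(pa) > 0:
        if len(pa) < len(PA_FREE):
            raise UnderdeterminedFitError(
                f"{len(pa)} pa observations cannot constrain {len(PA_FREE)} free parameters"
            )
        x_pa = minimize_stage(
            PA_FREE,
            _PA_STARTS,
            lambda x: control_params.model_copy(update=dict(zip(PA_FREE, x))),
            pa,
            "pa",
            polish_iter=100,
        )
        fitted["pa"] = control_params.model_copy(update=dict(zip(PA_FREE, x_pa)))
        fitted["pa_metformin"] = fitted["pa"]

    return fitted


def gsis_protocol(
    params: GlucoseInsulinParams,
    condition: Condition = "control",
    cycles: int = 3,
    low_mM: float = 2.8,
    high_mM: float = 20.0,
    phase_duration_h: float = 1.0,
) -> GSISResult:
    """Static glucose-stimulated insulin secretion assay.

    Alternating starvation (low) and stimulation (high) phases; the solution
    is collected and replaced after every phase, so each phase integrates
    secretion from zero.  The first-phase pool is assumed to re-prime during
    each starvation hour, so the rapid component restarts at every
    stimulation.  Basal release keeps the low phase positive.
    """
    if cycles < 1:
        raise ValueError("need at least one cycle")
    f_sec, _ = params.condition_factors(condition)
    theta, lam = params.glucose_threshold, params.first_phase_decay
    basal_release = params.basal_insulin * params.insulin_turnover * phase_duration_h

    def phase_insulin(g: float) -> float:
        drive = max(g - theta, 0.0)
        if lam > 0:
            first = params.first_phase_amplitude * drive * (1 - np.exp(-lam * phase_duration_h)) / lam
        else:
            first = params.first_phase_amplitude * drive * phase_duration_h
        sustained = params.sustained_rate * drive * phase_duration_h
        return basal_release + f_sec * (first + sustained)

    lows = [phase_insulin(low_mM) for _ in range(cycles)]
    highs = [phase_insulin(high_mM) for _ in range(cycles)]
    if any(l <= 0 for l in lows):
        raise ValueError("low-phase insulin must be positive (basal release required)")
    return GSISResult(low_phase_insulin=lows, high_phase_insulin=highs)
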