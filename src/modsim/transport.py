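"""Compartmental advection-diffusion solver and transport metrics.

Each compartment is well mixed.  For a species with diffusivity D the network
obeys

    V_i dC_i/dt =  sum_conv Q * (C_upstream - C_i)
                 + sum_membrane G_m * (C_j - C_i)
                 + sum_channel  G_c * (C_j - C_i)

with membrane conductance G_m = D*eps*A/(L*tau) and channel conductance
G_c = D*A_cc/L_path.  The system is linear; it is integrated with a
stiff-capable solver (LSODA, rtol 1e-8, atol 1e-12) because the diffusivities
of interest span almost two orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.integrate import solve_ivp

from . import units
from .device import DeviceModel, channel_conductance, membrane_conductance

MASS_BALANCE_RTOL = 1e-6
NEGATIVE_CLIP_ATOL = 1e-9


class SolverFailure(RuntimeError):
    """The ODE integrator failed; carries the solver message."""


class IntegrityError(RuntimeError):
    """A solution violates a physical invariant beyond tolerance."""


class UndefinedMetricError(ValueError):
    """A transport metric is requested for an undefined configuration."""


class Species(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    molecular_weight_kDa: float = Field(gt=0)
    diffusivity_m2_s: float = Field(gt=0)
    initial_loading: dict[str, float] = Field(default_factory=dict)

    @field_validator("initial_loading")
    @classmethod
    def _non_negative(cls, v: dict[str, float]) -> dict[str, float]:
        if any(c < 0 for c in v.values()):
            raise ValueError("initial loadings must be non-negative")
        return v


@dataclass
class TransportResult:
    """Per-compartment concentration trajectories on a shared time grid."""

    time_grid: np.ndarray
    compartments: list[str]
    species: str
    concentrations: pd.DataFrame  # tidy: time_s, compartment, species, concentration
    volumes_uL: dict[str, float]
    provenance: dict = field(default_factory=dict)
    _matrix: np.ndarray | None = None  # (n_times, n_compartments)

    def concentration(self, compartment: str, t: float) -> float:
        j = self.compartments.index(compartment)
        if not np.any(np.isclose(self.time_grid, t)):
            raise KeyError(f"t={t} is not on the output grid")
        i = int(np.argmin(np.abs(self.time_grid - t)))
        return float(self._matrix[i, j])

    def total_mass(self, t: float) -> float:
        """Total dissolved amount (concentration x volume, in input units x uL)."""
        i = int(np.argmin(np.abs(self.time_grid - t)))
        return float(
            sum(self._matrix[i, self.compartments.index(c)] * self.volumes_uL[c]
                for c in self.compartments)
        )


def rate_matrix(device: DeviceModel, diffusivity_m2_s: float, flow_enabled: bool) -> np.ndarray:
    """Exchange-rate matrix M (1/s) such that dC/dt = M @ C."""
    ids = device.ids
    ix = {cid: i for i, cid in enumerate(ids)}
    vol = np.array([device.compartment(cid).volume_uL * units.UL_TO_CM3 for cid in ids])
    n = len(ids)
    m = np.zeros((n, n))

    def add_exchange(a: str, b: str, g_cm3_s: float) -> None:
        ia, ib = ix[a], ix[b]
        m[ia, ia] -= g_cm3_s / vol[ia]
        m[ia, ib] += g_cm3_s / vol[ia]
        m[ib, ib] -= g_cm3_s / vol[ib]
        m[ib, ia] += g_cm3_s / vol[ib]

    for mi in device.membrane_interfaces:
        add_exchange(*mi.pair, membrane_conductance(mi.membrane, diffusivity_m2_s))
    for cp in device.channel_paths:
        add_exchange(*cp.pair, channel_conductance(cp, diffusivity_m2_s))
    if flow_enabled and device.flow.enabled:
        q = device.flow.effective_rate_cm3_s
        for e in device.convective_edges:
            ia, ib = ix[e.source], ix[e.target]
            m[ib, ia] += q / vol[ib]
            m[ia, ia] -= q / vol[ia]
    return m


def simulate_transport(
    device: DeviceModel,
    species: Species,
    flow_enabled: bool,
    duration_s: float,
    output_times: Sequence[float] | None = None,
) -> TransportResult:
    """Integrate the species over the device network.

    ``flow_enabled=False`` zeroes every convective term, leaving only membrane
    and channel diffusion, which is how the static (no-flow) arms of the
    tracer experiments are represented.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if output_times is None:
        output_times = np.linspace(0.0, duration_s, 181)
    times = np.asarray(sorted(set(float(t) for t in output_times)))
    if times[0] < 0 or times[-1] > duration_s:
        raise ValueError("output times must lie within [0, duration]")
    if np.any(np.diff(times) <= 0):
        raise ValueError("output times must be strictly increasing")

    ids = device.ids
    unknown = set(species.initial_loading) - set(ids)
    if unknown:
        raise KeyError(f"initial loading references unknown compartments: {sorted(unknown)}")
    c0 = np.array([species.initial_loading.get(cid, 0.0) for cid in ids])
    m = rate_matrix(device, species.diffusivity_m2_s, flow_enabled)

    sol = solve_ivp(
        lambda t, y: m @ y,
        (0.0, duration_s),
        c0,
        t_eval=times if times[0] == 0.0 else np.concatenate([[0.0], times]),
        method="LSODA",
        jac=lambda t, y: m,
        rtol=1e-8,
        atol=1e-12 * max(1.0, c0.max() if c0.size else 1.0),
    )
    if not sol.success:
        raise SolverFailure(f"integration failed: {sol.message}")

    conc = sol.y.T  # (n_times, n_comp)
    if times[0] != 0.0:
        conc = conc[1:]
    neg = conc < 0
    if np.any(conc < -NEGATIVE_CLIP_ATOL * max(1.0, abs(c0).max())):
        raise IntegrityError("negative concentrations beyond round-off tolerance")
    conc = np.where(neg, 0.0, conc)

    vols = np.array([device.compartment(cid).volume_uL for cid in ids])
    mass = conc @ vols
    m0 = float(c0 @ vols)
    if m0 > 0 and np.max(np.abs(mass - m0)) / m0 > MASS_BALANCE_RTOL:
        raise IntegrityError("mass balance violated beyond relative tolerance")

    tidy = pd.DataFrame(
        {
            "time_s": np.repeat(times, len(ids)),
            "compartment": np.tile(ids, len(times)),
            "species": species.name,
            "concentration": conc.ravel(),
        }
    )
    return TransportResult(
        time_grid=times,
        compartments=list(ids),
        species=species.name,
        concentrations=tidy,
        volumes_uL={cid: device.compartment(cid).volume_uL for cid in ids},
        provenance={
            "solver": "LSODA",
            "rtol": 1e-8,
            "atol": 1e-12,
            "flow_enabled": bool(flow_enabled and device.flow.enabled),
            "diffusivity_m2_s": species.diffusivity_m2_s,
            "duration_s": float(duration_s),
        },
        _matrix=conc,
    )


def percent_transferred(
    result: TransportResult,
    source: str,
    target: str | Sequence[str],
    t: float,
) -> float:
    """Percent of the source's initial mass found in the target compartment(s) at t.

    ``target`` may be a single compartment id, a list of ids, or the string
    ``"downstream"`` meaning every compartment except the source (the
    accumulated fraction delivered to the receiving circuit).
    """
    if isinstance(target, str):
        targets = [c for c in result.compartments if c != source] if target == "downstream" else [target]
    else:
        targets = list(target)
    m0 = result.concentration(source, result.time_grid[0]) * result.volumes_uL[source]
    if m0 <= 0:
        raise UndefinedMetricError("source compartment had zero initial mass")
    mass = sum(result.concentration(c, t) * result.volumes_uL[c] for c in targets)
    return 100.0 * mass / m0


def fold_enhancement(
    result_flow: TransportResult,
    result_noflow: TransportResult,
    compartment: str,
    species: str,
    t: float,
) -> float:
    """Ratio of flow to no-flow concentration in one compartment at time t."""
    if result_flow.species != species or result_noflow.species != species:
        raise ValueError("results do not match the requested species")
    if not np.array_equal(result_flow.time_grid, result_noflow.time_grid):
        raise ValueError("results must share a time grid")
    c_nf = result_noflow.concentration(compartment, t)
    c_f = result_flow.concentration(compartment, t)
    if c_nf == 0:
        raise OverflowError("no-flow concentration is zero; fold enhancement undefined")
    return c_f / c_nf


@dataclass
class PermeabilityEstimate:
    """Apparent membrane permeability P = C_t*V / (C_0*A*dt) in cm/s."""

    value_cm_s: float
    inputs: Mapping[str, float]
    sink_condition_ok: bool


def estimate_permeability(
    c_t: float, c0: float, volume_cm3: float, area_cm2: float, dt_s: float
) -> PermeabilityEstimate:
    """Estimate apparent permeability from a donor/receiver assay.

    C_t is the receiver concentration after the assay, C_0 the initial donor
    concentration, V the receiver medium volume, A the membrane contact area
    and dt the assay duration.  Valid (unbiased) only in the sink regime
    C_t << C_0; outside it the estimate is still returned with the sink flag
    cleared.
    """
    if c0 <= 0:
        raise ValueError("initial donor concentration must be positive")
    if area_cm2 <= 0 or dt_s <= 0:
        raise ValueError("area and duration must be positive")
    if c_t < 0:
        raise ValueError("receiver concentration must be non-negative")
    value = c_t * volume_cm3 / (c0 * area_cm2 * dt_s)
    return PermeabilityEstimate(
        value_cm_s=value,
        inputs={"C_t": c_t, "C0": c0, "V_cm3": volume_cm3, "A_cm2": area_cm2, "dt_s": dt_s},
        sink_condition_ok=c_t <= c0,
    )
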