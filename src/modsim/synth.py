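"""Synthetic assay generators.

Replicate tracer washout/accumulation tables and sparse GTT series with the
dispersion structure of the reported measurements: multiplicative Gaussian
noise with a coefficient of variation matched to the printed relative SDs
(about 13% for tracer percentages, 4% for insulin), floored at zero.  Same
seed, same design, same parameters -> byte-identical output.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .device import DeviceModel
from .gtt import Condition, GlucoseInsulinParams, simulate_gtt
from .transport import Species, simulate_transport

TRACER_CV_DEFAULT = 0.13
INSULIN_CV_DEFAULT = 0.04


class NoiseModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str = "multiplicative-gaussian"
    cv_or_sd: float = Field(default=TRACER_CV_DEFAULT, ge=0)
    seed: int = 0
    floor_at_zero: bool = True

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in {"multiplicative-gaussian", "additive-gaussian"}:
            raise ValueError(f"unknown noise kind {v!r}")
        return v

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "multiplicative-gaussian":
            noisy = values * (1.0 + self.cv_or_sd * rng.standard_normal(values.shape))
        else:
            noisy = values + self.cv_or_sd * rng.standard_normal(values.shape)
        if self.floor_at_zero:
            n_floored = int(np.sum(noisy < 0))
            if n_floored:
                noisy = np.maximum(noisy, 0.0)
        return noisy


class AssayDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")

    species: str
    loaded_compartment: str
    sampled_compartments: list[str]
    sample_times_s: list[float]
    flow_enabled: bool = True
    replicates: int = Field(default=3, ge=1)
    loading_concentration: float = Field(default=1.0, gt=0)

    @field_validator("sample_times_s")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sample times must be strictly increasing")
        return v


def generate_tracer_assay(
    device: DeviceModel,
    design: AssayDesign,
    noise: NoiseModel,
    diffusivity_m2_s: float,
) -> pd.DataFrame:
    """Replicate-resolved noisy tracer concentrations.

    Columns: ``time_s, compartment, species, replicate, concentration, units``
    — the observed-data schema the calibration routines read.
    """
    unknown = set(design.sampled_compartments) | {design.loaded_compartment}
    unknown -= set(device.ids)
    if unknown:
        raise ValueError(f"design references unknown compartments: {sorted(unknown)}")
    sp = Species(
        name=design.species,
        molecular_weight_kDa=1.0,
        diffusivity_m2_s=diffusivity_m2_s,
        initial_loading={design.loaded_compartment: design.loading_concentration},
    )
    times = [0.0] + [t for t in design.sample_times_s if t > 0]
    result = simulate_transport(
        device, sp, design.flow_enabled, max(design.sample_times_s), times
    )
    clean = np.array(
        [
            [result.concentration(c, t) for c in design.sampled_compartments]
            for t in design.sample_times_s
        ]
    )
    rng = np.random.default_rng(noise.seed)
    rows = []
    for rep in range(design.replicates):
        noisy = noise.apply(clean, rng)
        for i, t in enumerate(design.sample_times_s):
            for j, c in enumerate(design.sampled_compartments):
                rows.append((t, c, design.species, rep, noisy[i, j], "arb"))
    return pd.DataFrame(
        rows, columns=["time_s", "compartment", "species", "replicate", "concentration", "units"]
    )


def generate_gtt_series(
    device: DeviceModel,
    params: GlucoseInsulinParams,
    condition: Condition,
    noise: NoiseModel,
    sample_times_h: Sequence[float],
    dose_mM: float = 13.0,
) -> pd.DataFrame:
    """Noisy sparse GTT glucose + insulin series in the observed-data schema.

    Columns: ``condition, variable, time_h, value, sd`` matching the packaged
    reported-value fixture.
    """
    sample_times_h = list(sample_times_h)
    duration = 24.0
    if max(sample_times_h) > duration or min(sample_times_h) < 0:
        raise ValueError("sample times outside the simulated span")
    res = simulate_gtt(device, params, condition, dose_mM=dose_mM,
                       duration_h=duration, sample_times_h=sample_times_h)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for var, getter in (("glucose", res.glucose_at), ("insulin", res.insulin_at)):
        clean = np.array([getter(t) for t in sample_times_h])
        noisy = noise.apply(clean, rng)
        sd = noise.cv_or_sd * clean if noise.kind == "multiplicative-gaussian" else np.full_like(clean, noise.cv_or_sd)
        for t, v, s in zip(sample_times_h, noisy, sd):
            rows.append((condition, var, t, v, s))
    return pd.DataFrame(rows, columns=["condition", "variable", "time_h", "value", "sd"])
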