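"""Device description and closed-form hydraulic quantities.

The multi-organoid device (MOD) is reduced to a network of well-mixed
compartments: two organoid chambers (POC, LOC) sitting above a porous PTFE
membrane, the connecting channel beneath them (split into the segments under
each chamber), and a LOOP node for the tubing, injection port and the rest of
the recirculating volume.  Convective edges carry the pump flow around the
loop; membrane interfaces and channel-diffusion paths carry passive exchange.

Closed-form quantities (wall shear stress, circulation time, Darcy velocity,
membrane conductance) live here; the network solver is in
:mod:`modsim.transport`.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import units


class InvalidGeometryError(ValueError):
    """A geometric quantity violates its physical constraints."""


class UndefinedCirculationError(ValueError):
    """Circulation time is requested with no flow."""


class ChannelGeometry(BaseModel):
    """Rectangular channel cross-section and flow/diffusion path length (cm)."""

    model_config = ConfigDict(extra="forbid")

    width_cm: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    length_cm: float = Field(gt=0)

    @property
    def cross_section_cm2(self) -> float:
        return self.width_cm * self.height_cm


class Fluid(BaseModel):
    model_config = ConfigDict(extra="forbid")

    density_kg_m3: float = Field(gt=0)
    viscosity_pa_s: float = Field(gt=0)

    @property
    def viscosity_poise(self) -> float:
        """Dynamic viscosity in g/(cm.s)."""
        return self.viscosity_pa_s * units.PAS_TO_POISE


class Membrane(BaseModel):
    """Porous membrane separating a chamber from the channel beneath it."""

    model_config = ConfigDict(extra="forbid")

    pore_size_um: float = Field(gt=0)
    porosity: float = Field(gt=0, le=1)
    darcy_permeability_m2: float = Field(gt=0)
    thickness_um: float = Field(default=50.0, gt=0)
    exchange_area_cm2: float = Field(gt=0)
    tortuosity: float = Field(default=1.0, ge=1)


class Compartment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    volume_uL: float = Field(gt=0)
    role: Literal["organoid-chamber", "channel", "tubing"]


class FlowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rate_uL_min: float = Field(ge=0)
    enabled: bool = True

    @property
    def effective_rate_uL_min(self) -> float:
        return self.rate_uL_min if self.enabled else 0.0

    @property
    def effective_rate_cm3_s(self) -> float:
        return self.effective_rate_uL_min * units.UL_MIN_TO_CM3_S


class ConvectiveEdge(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: str
    target: str


class MembraneInterface(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pair: tuple[str, str]
    membrane: Membrane


class ChannelPath(BaseModel):
    """Diffusive path through open channel fluid between two compartments."""

    model_config = ConfigDict(extra="forbid")

    pair: tuple[str, str]
    cross_section_cm2: float = Field(gt=0)
    path_length_cm: float = Field(gt=0)


class DeviceModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    compartments: list[Compartment]
    convective_edges: list[ConvectiveEdge]
    membrane_interfaces: list[MembraneInterface]
    channel_paths: list[ChannelPath] = Field(default_factory=list)
    fluid: Fluid
    flow: FlowConfig
    channel: Optional[ChannelGeometry] = None
    shear_fluid: Optional[Fluid] = None
    surrogates: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_topology(self) -> "DeviceModel":
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ValueError("compartment ids must be unique")
        known = set(ids)
        for e in self.convective_edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"convective edge {e.source}->{e.target} references unknown compartment")
        for m in self.membrane_interfaces:
            for cid in m.pair:
                if cid not in known:
                    raise ValueError(f"membrane interface references unknown compartment {cid!r}")
        for p in self.channel_paths:
            for cid in p.pair:
                if cid not in known:
                    raise ValueError(f"channel path references unknown compartment {cid!r}")
        if self.flow.enabled and self.convective_edges:
            # mass balance: each compartment touched by flow needs inflow == outflow
            inflow: dict[str, int] = {}
            outflow: dict[str, int] = {}
            for e in self.convective_edges:
                outflow[e.source] = outflow.get(e.source, 0) + 1
                inflow[e.target] = inflow.get(e.target, 0) + 1
            touched = set(inflow) | set(outflow)
            for cid in touched:
                if inflow.get(cid, 0) != outflow.get(cid, 0):
                    raise ValueError(
                        f"convective edges do not close a loop at {cid!r} "
                        f"(in={inflow.get(cid, 0)}, out={outflow.get(cid, 0)})"
                    )
        return self

    # -- convenience -----------------------------------------------------
    def compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compartments]

    @property
    def total_volume_uL(self) -> float:
        return sum(c.volume_uL for c in self.compartments)

    @property
    def circulating_volume_uL(self) -> float:
        """Volume of the recirculating loop (channel + tubing compartments)."""
        return sum(c.volume_uL for c in self.compartments if c.role != "organoid-chamber")

    def volumes_cm3(self) -> dict[str, float]:
        return {c.id: c.volume_uL * units.UL_TO_CM3 for c in self.compartments}

    def resolve_species_name(self, name: str) -> str:
        """Map a biological species to its declared transport surrogate."""
        return self.surrogates.get(name, name)


def wall_shear_stress(flow: FlowConfig, channel: ChannelGeometry, fluid: Fluid) -> float:
    """Wall shear stress tau = 6*mu*Q / (w*h^2) for a rectangular channel.

    Inputs are converted to CGS (mu in g/(cm.s), Q in cm^3/s, w and h in cm)
    so the result is in dyne/cm^2.
    """
    if channel.width_cm <= 0 or channel.height_cm <= 0:
        raise InvalidGeometryError("channel width and height must be positive")
    mu = fluid.viscosity_poise
    q = flow.effective_rate_cm3_s
    return 6.0 * mu * q / (channel.width_cm * channel.height_cm**2)


def circulation_time(total_volume_uL: float, flow: FlowConfig) -> float:
    """Time (min) for the pump to turn over the given volume once."""
    rate = flow.effective_rate_uL_min
    if rate <= 0:
        raise UndefinedCirculationError("circulation time undefined at zero flow")
    return total_volume_uL / rate


def darcy_velocity(membrane: Membrane, fluid: Fluid, pressure_drop_pa: float) -> float:
    """Superficial Darcy velocity (m/s) through the membrane.

    v = (kappa / mu) * (dP / L); the sign follows the pressure drop.
    """
    thickness_m = membrane.thickness_um * units.UM_TO_CM * units.CM_TO_M
    return (membrane.darcy_permeability_m2 / fluid.viscosity_pa_s) * (
        pressure_drop_pa / thickness_m
    )


def membrane_conductance(membrane: Membrane, species_diffusivity_m2_s: float) -> float:
    """Lumped diffusive conductance G = D*eps*A / (L*tau) in cm^3/s.

    Reduces transport through the porous membrane to a single volumetric
    exchange coefficient: flux = G * (C_a - C_b).
    """
    if species_diffusivity_m2_s <= 0:
        raise ValueError("diffusivity must be positive")
    d_cm2_s = species_diffusivity_m2_s * units.M2S_TO_CM2S
    thickness_cm = membrane.thickness_um * units.UM_TO_CM
    return (
        d_cm2_s
        * membrane.porosity
        * membrane.exchange_area_cm2
        / (thickness_cm * membrane.tortuosity)
    )


def channel_conductance(path: ChannelPath, species_diffusivity_m2_s: float) -> float:
    """Diffusive conductance D*A/L (cm^3/s) of an open channel path."""
    d_cm2_s = species_diffusivity_m2_s * units.M2S_TO_CM2S
    return d_cm2_s * path.cross_section_cm2 / path.path_length_cm
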