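import pytest

from modsim import (
    Compartment,
    DeviceModel,
    FlowConfig,
    Fluid,
    Membrane,
    default_device,
    fit_gtt_params,
    reported_gtt_data,
    reported_tracer_data,
)
from modsim.calibrate import apply_geometry, calibrate_to_reported_metrics
from modsim.device import MembraneInterface
from modsim.io import DIFFUSIVITIES_M2_S


def make_membrane(area_cm2=1.0, porosity=0.8, thickness_um=50.0, tortuosity=1.0):
    return Membrane(
        pore_size_um=1.0,
        porosity=porosity,
        darcy_permeability_m2=2.5e-14,
        thickness_um=thickness_um,
        exchange_area_cm2=area_cm2,
        tortuosity=tortuosity,
    )


def make_two_compartment_device(v1_uL=300.0, v2_uL=300.0, area_cm2=0.1):
    """Closed donor/receiver pair joined by a single membrane."""
    return DeviceModel(
        compartments=[
            Compartment(id="A", volume_uL=v1_uL, role="organoid-chamber"),
            Compartment(id="B", volume_uL=v2_uL, role="channel"),
        ],
        convective_edges=[],
        membrane_interfaces=[
            MembraneInterface(pair=("A", "B"), membrane=make_membrane(area_cm2))
        ],
        fluid=Fluid(density_kg_m3=1030.0, viscosity_pa_s=0.0025),
        flow=FlowConfig(rate_uL_min=0.0, enabled=False),
    )


@pytest.fixture(scope="session")
def device():
    return default_device()


@pytest.fixture(scope="session")
def calibrated_device(device):
    report = calibrate_to_reported_metrics(
        device, reported_tracer_data(), DIFFUSIVITIES_M2_S
    )
    return apply_geometry(device, report.fitted)


@pytest.fixture(scope="session")
def fitted_gtt_params(device):
    return fit_gtt_params(reported_gtt_data(), device)


@pytest.fixture
def two_compartment_device():
    return make_two_compartment_device()
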