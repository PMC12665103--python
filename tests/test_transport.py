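"""Network transport solver against independent closed-form and
matrix-exponential oracles, transport metrics, permeability estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from modsim import (
    Compartment,
    DeviceModel,
    FlowConfig,
    Fluid,
    Species,
    estimate_permeability,
    fold_enhancement,
    percent_transferred,
    simulate_transport,
)
from modsim.device import ChannelPath, ConvectiveEdge, MembraneInterface, membrane_conductance
from modsim.io import DIFFUSIVITIES_M2_S
from modsim.transport import UndefinedMetricError

from conftest import make_membrane, make_two_compartment_device

D4 = DIFFUSIVITIES_M2_S["dextran_4k"]


def species(name="tracer", d=D4, loading=None):
    return Species(
        name=name, molecular_weight_kDa=4.0, diffusivity_m2_s=d,
        initial_loading=loading or {},
    )


class TestTwoCompartmentClosedForm:
    """Independent oracle: C1(t) = Ceq + (C1(0) - Ceq) exp(-k t),
    k = G (1/V1 + 1/V2), written out by hand here."""

    @pytest.mark.parametrize("v1,v2", [(300.0, 300.0), (150.0, 450.0)])
    def test_matches_exponential_relaxation(self, v1, v2):
        dev = make_two_compartment_device(v1, v2, area_cm2=0.1)
        g = membrane_conductance(dev.membrane_interfaces[0].membrane, D4)  # cm^3/s
        v1_cm3, v2_cm3 = v1 * 1e-3, v2 * 1e-3
        k = g * (1 / v1_cm3 + 1 / v2_cm3)
        c_eq = 1.0 * v1_cm3 / (v1_cm3 + v2_cm3)
        times = np.linspace(0.0, 3.0 / k, 30)
        res = simulate_transport(dev, species(loading={"A": 1.0}), False, times[-1], times)
        for t in times[1:]:
            expected = c_eq + (1.0 - c_eq) * math.exp(-k * t)
            assert res.concentration("A", t) == pytest.approx(expected, rel=1e-6)
            expected_b = c_eq * (1 - math.exp(-k * t))
            assert res.concentration("B", t) == pytest.approx(expected_b, rel=1e-5, abs=1e-12)

    def test_zero_loading_stays_zero(self, two_compartment_device):
        res = simulate_transport(
            two_compartment_device, species(loading={}), False, 1000.0, [0, 500.0, 1000.0]
        )
        assert np.all(res.concentrations["concentration"] == 0.0)

    def test_long_time_equilibrium_is_uniform(self, two_compartment_device):
        res = simulate_transport(
            two_compartment_device, species(loading={"A": 2.0}), False, 5e5, [0, 5e5]
        )
        c_eq = 2.0 * 300.0 / 600.0
        assert res.concentration("A", 5e5) == pytest.approx(c_eq, rel=1e-5)
        assert res.concentration("B", 5e5) == pytest.approx(c_eq, rel=1e-5)


@st.composite
def small_networks(draw):
    """Random closed devices with up to 3 compartments, membranes, channel
    paths, and an optional convective ring."""
    n = draw(st.integers(2, 3))
    vols = [draw(st.floats(20.0, 800.0)) for _ in range(n)]
    ids = [f"C{i}" for i in range(n)]
    roles = ["organoid-chamber", "channel", "tubing"]
    comps = [Compartment(id=i, volume_uL=v, role=roles[k % 3])
             for k, (i, v) in enumerate(zip(ids, vols))]
    membranes = []
    paths = []
    for a in range(n):
        for b in range(a + 1, n):
            kind = draw(st.integers(0, 2))
            if kind == 0:
                membranes.append(MembraneInterface(
                    pair=(ids[a], ids[b]),
                    membrane=make_membrane(area_cm2=draw(st.floats(0.01, 1.0))),
                ))
            elif kind == 1:
                paths.append(ChannelPath(
                    pair=(ids[a], ids[b]),
                    cross_section_cm2=draw(st.floats(0.05, 0.5)),
                    path_length_cm=draw(st.floats(0.05, 2.0)),
                ))
    with_flow = draw(st.booleans()) and n >= 2
    edges = (
        [ConvectiveEdge(source=ids[i], target=ids[(i + 1) % n]) for i in range(n)]
        if with_flow else []
    )
    rate = draw(st.floats(10.0, 1000.0)) if with_flow else 0.0
    dev = DeviceModel(
        compartments=comps,
        convective_edges=edges,
        membrane_interfaces=membranes,
        channel_paths=paths,
        fluid=Fluid(density_kg_m3=1030, viscosity_pa_s=0.0025),
        flow=FlowConfig(rate_uL_min=rate, enabled=with_flow),
    )
    loading = {ids[0]: draw(st.floats(0.5, 13.0))}
    return dev, loading


class TestMatrixExponentialOracle:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(network=small_networks())
    def test_solver_matches_expm(self, network):
        """Any <=3-compartment linear exchange system: LSODA trajectory equals
        the matrix exponential of an independently assembled rate matrix."""
        dev, loading = network
        ids = dev.ids
        vols = np.array([dev.compartment(i).volume_uL * 1e-3 for i in ids])
        n = len(ids)
        m = np.zeros((n, n))
        for mi in dev.membrane_interfaces:
            g = membrane_conductance(mi.membrane, D4)
            a, b = ids.index(mi.pair[0]), ids.index(mi.pair[1])
            m[a, a] -= g / vols[a]; m[a, b] += g / vols[a]
            m[b, b] -= g / vols[b]; m[b, a] += g / vols[b]
        for cp in dev.channel_paths:
            g = D4 * 1e4 * cp.cross_section_cm2 / cp.path_length_cm
            a, b = ids.index(cp.pair[0]), ids.index(cp.pair[1])
            m[a, a] -= g / vols[a]; m[a, b] += g / vols[a]
            m[b, b] -= g / vols[b]; m[b, a] += g / vols[b]
        if dev.flow.enabled:
            q = dev.flow.rate_uL_min * 1e-3 / 60.0
            for e in dev.convective_edges:
                a, b = ids.index(e.source), ids.index(e.target)
                m[b, a] += q / vols[b]
                m[a, a] -= q / vols[a]
        c0 = np.array([loading.get(i, 0.0) for i in ids])
        times = [0.0, 600.0, 3600.0, 10800.0]
        res = simulate_transport(dev, species(loading=loading), dev.flow.enabled,
                                 times[-1], times)
        for t in times:
            expected = expm(m * t) @ c0
            got = np.array([res.concentration(i, t) for i in ids])
            np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-10 * c0.max())

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(network=small_networks())
    def test_mass_conservation(self, network):
        dev, loading = network
        times = np.linspace(0.0, 7200.0, 13)
        res = simulate_transport(dev, species(loading=loading), dev.flow.enabled,
                                 times[-1], times)
        m0 = res.total_mass(0.0)
        for t in times:
            assert abs(res.total_mass(t) - m0) / m0 < 1e-6


class TestTransportMetrics:
    def test_nothing_transferred_at_start(self, two_compartment_device):
        res = simulate_transport(two_compartment_device, species(loading={"A": 1.0}),
                                 False, 100.0, [0.0, 100.0])
        assert percent_transferred(res, "A", "B", 0.0) == 0.0

    def test_equal_volume_equilibrium_is_half(self, two_compartment_device):
        res = simulate_transport(two_compartment_device, species(loading={"A": 1.0}),
                                 False, 5e5, [0.0, 5e5])
        assert percent_transferred(res, "A", "B", 5e5) == pytest.approx(50.0, rel=1e-4)
        assert percent_transferred(res, "A", "downstream", 5e5) == pytest.approx(50.0, rel=1e-4)

    def test_zero_initial_mass_is_undefined(self, two_compartment_device):
        res = simulate_transport(two_compartment_device, species(loading={"B": 1.0}),
                                 False, 100.0, [0.0, 100.0])
        with pytest.raises(UndefinedMetricError):
            percent_transferred(res, "A", "B", 100.0)

    def test_fold_enhancement_identity_and_scale_invariance(self, two_compartment_device):
        res1 = simulate_transport(two_compartment_device, species(loading={"A": 1.0}),
                                  False, 3600.0, [0.0, 3600.0])
        res2 = simulate_transport(two_compartment_device, species(loading={"A": 2.0}),
                                  False, 3600.0, [0.0, 3600.0])
        assert fold_enhancement(res1, res1, "B", "tracer", 3600.0) == pytest.approx(1.0)
        # doubling both numerator and denominator concentrations cancels
        assert fold_enhancement(res2, res1, "B", "tracer", 3600.0) == pytest.approx(2.0, rel=1e-6)

    def test_fold_enhancement_zero_reference_flagged(self, two_compartment_device):
        res = simulate_transport(two_compartment_device, species(loading={"A": 1.0}),
                                 False, 100.0, [0.0, 100.0])
        zero = simulate_transport(two_compartment_device, species(loading={}),
                                  False, 100.0, [0.0, 100.0])
        with pytest.raises(OverflowError):
            fold_enhancement(res, zero, "B", "tracer", 100.0)

    def test_monotone_flow_effect(self, device):
        """Percent transferred at fixed t is non-decreasing in flow rate."""
        sp = species(loading={"POC": 1.0})
        t = 10800.0
        previous = -1.0
        for rate in [0.0, 60.0, 600.0, 1800.0]:
            dev = device.model_copy(deep=True)
            dev.flow.rate_uL_min = rate
            res = simulate_transport(dev, sp, rate > 0, t, [0.0, t])
            pct = percent_transferred(res, "POC", "downstream", t)
            assert pct >= previous - 1e-9
            previous = pct

    def test_diffusivity_ordering_under_no_flow(self, device):
        """At equal loadings, faster-diffusing species transfer more:
        glucose >= 4 kDa >= 70 kDa."""
        t = 10800.0
        pcts = []
        for name in ("glucose", "dextran_4k", "dextran_70k"):
            sp = Species(name=name, molecular_weight_kDa=1.0,
                         diffusivity_m2_s=DIFFUSIVITIES_M2_S[name],
                         initial_loading={"POC": 1.0})
            res = simulate_transport(device, sp, False, t, [0.0, t])
            pcts.append(percent_transferred(res, "POC", "downstream", t))
        assert pcts[0] >= pcts[1] >= pcts[2]


class TestPermeabilityEstimator:
    def test_no_transport_no_permeability(self):
        assert estimate_permeability(0.0, 100.0, 0.6, 1.0, 600.0).value_cm_s == 0.0

    def test_reference_arithmetic(self):
        """(1 * 0.6) / (100 * 1 * 600) = 1e-5 cm/s."""
        est = estimate_permeability(1.0, 100.0, 0.6, 1.0, 600.0)
        assert est.value_cm_s == pytest.approx(1e-5, rel=1e-12)
        assert est.sink_condition_ok

    def test_sink_violation_flagged_not_fatal(self):
        est = estimate_permeability(150.0, 100.0, 0.6, 1.0, 600.0)
        assert not est.sink_condition_ok
        assert est.value_cm_s > 0

    @pytest.mark.parametrize("bad", [dict(c0=0.0), dict(a=0.0), dict(dt=0.0)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(c_t=1.0, c0=100.0, volume_cm3=0.6, area_cm2=1.0, dt_s=600.0)
        kwargs.update({{"c0": "c0", "a": "area_cm2", "dt": "dt_s"}[k]: v for k, v in bad.items()})
        with pytest.raises(ValueError):
            estimate_permeability(**kwargs)

    def test_simulate_then_estimate_recovers_conductance(self):
        """Early-time donor/receiver simulation fed to the estimator recovers
        the imposed G/A within 2% while C_t/C0 stays below 5% (sink regime)."""
        area = 0.1
        dev = make_two_compartment_device(600.0, 300.0, area_cm2=area)
        g = membrane_conductance(dev.membrane_interfaces[0].membrane, D4)
        p_true = g / area  # cm/s
        c0 = 100.0
        # choose dt so receiver stays deep in the sink regime
        dt = 0.02 * (300.0 * 1e-3) / g
        res = simulate_transport(dev, species(loading={"A": c0}), False, dt, [0.0, dt])
        c_t = res.concentration("B", dt)
        assert c_t / c0 < 0.05
        est = estimate_permeability(c_t, c0, 300.0 * 1e-3, area, dt)
        assert est.value_cm_s == pytest.approx(p_true, rel=0.02)
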