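"""Engine tests against closed-form and frequency-domain oracles."""

import numpy as np
import pytest

from cranioflow.circuit import (
    AssemblyError,
    Circuit,
    SolverConfig,
    TimeSeries,
    assemble,
    check_passivity,
    integrate,
)
from cranioflow.experiment import make_fixtures


def test_rc_discharge_matches_exponential():
    circuit, ref = make_fixtures("rc")
    res = integrate(circuit, SolverConfig(), (0.0, 5.0),
                    init_pressures={"n1": 1.0})
    err = np.max(np.abs(res["P"].v - ref["solution"](res["P"].t)))
    assert err < 1e-4


def test_ohm_analog_steady_flow():
    # 1 Pa source through R = 1 into ground: flow 1 m^3/s (algebraic)
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("a")
    c.add_node("b")
    c.pressure_source("V", "a", "gnd", 1.0)
    c.resistor("R", "a", "b", 1.0)
    c.capacitor("Cb", "b", "gnd", 1e-3)  # load settles to the source pressure
    c.add_probe("q", "element_flow", "R")
    res = integrate(c, SolverConfig(), (0.0, 0.001))
    assert res["q"].v[0] == pytest.approx(1.0, abs=1e-6)


def test_windkessel3_dc_steady_state():
    circuit, ref = make_fixtures("windkessel3")
    res = integrate(circuit, SolverConfig(), (0.0, 10.0))
    assert res["P_in"].v[-1] == pytest.approx(ref["dc_inlet_pressure"], rel=1e-4)


@pytest.mark.parametrize("freq_hz", [0.5, 1.25, 5.0])
def test_windkessel2_impedance(freq_hz):
    """Output amplitude matches |Z(w)| = R/sqrt(1+(wRC)^2) within 1 %."""
    circuit, ref = make_fixtures("windkessel2")
    R, C = ref["R"], ref["C"]
    w = 2 * np.pi * freq_hz
    circuit.elements["Q"].value = lambda t: np.sin(w * t)
    res = integrate(circuit, SolverConfig(), (0.0, 20.0))
    ts = res["P"]
    m = ts.t > 15.0
    amp = (ts.v[m].max() - ts.v[m].min()) / 2
    assert amp == pytest.approx(ref["impedance"](w), rel=0.01)


def test_diode_reverse_leakage_bound():
    cfg = SolverConfig()
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    for n in ("a", "m", "b"):
        c.add_node(n)
    c.pressure_source("V", "a", "gnd", -1.0)   # reverse bias 1 Pa
    c.resistor("R", "a", "m", 1.0)
    c.diode("D", "m", "b")
    c.capacitor("Cb", "b", "gnd", 1e-3)
    c.add_probe("qD", "element_flow", "D")
    res = integrate(c, cfg, (0.0, 0.5))
    assert np.max(np.abs(res["qD"].v)) <= cfg.diode_off_conductance * 1.0 + 1e-20


def test_diode_forward_reverse_asymmetry():
    """Forward/reverse flow ratio > 1e4 at |dP| = 100 Pa."""
    cfg = SolverConfig()
    system = assemble(rc_for_diode(), cfg)
    g_fwd = system._diode_g(100.0) * 100.0
    g_rev = system._diode_g(-100.0) * 100.0
    assert g_fwd / g_rev > 1e4


def rc_for_diode():
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("n")
    c.resistor("R", "n", "gnd", 1.0)
    c.capacitor("C", "n", "gnd", 1.0)
    return c


def test_valve_matches_series_resistor_when_forward():
    """A forward-conducting valve behaves as R_series + 1/g_on."""
    cfg = SolverConfig()
    system = assemble(rc_for_diode(), cfg)
    R = 1e9
    dp = 5000.0
    q = system.valve_flow(dp, R)
    expected = dp / (R + 1.0 / cfg.diode_on_conductance)
    assert q == pytest.approx(expected, rel=1e-6)
    assert abs(system.valve_flow(-dp, R)) <= cfg.diode_off_conductance * dp


def test_passivity_sourceless_rc_and_rlc():
    cfg = SolverConfig()
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("n1")
    c.resistor("R", "n1", "gnd", 1.0)
    c.capacitor("C", "n1", "gnd", 1.0)
    system = assemble(c, cfg)
    res = integrate(system, cfg, (0.0, 3.0), x0=system.initial_state({"n1": 1.0}))
    report = check_passivity(system, res)
    assert report["passive"]

    # decaying LC oscillation with small series R
    c2 = Circuit()
    c2.add_node("gnd", is_ground=True)
    c2.add_node("a")
    c2.add_node("b")
    c2.capacitor("C", "a", "gnd", 1.0)
    c2.resistor("R", "a", "b", 0.2)
    c2.inductor("L", "b", "gnd", 1.0)
    system2 = assemble(c2, cfg)
    res2 = integrate(system2, cfg, (0.0, 10.0),
                     x0=system2.initial_state({"a": 1.0, "b": 1.0}))
    report2 = check_passivity(system2, res2)
    assert report2["passive"]
    assert report2["energy"][-1] < report2["energy"][0]


def test_passivity_refuses_driven_circuit():
    circuit, _ = make_fixtures("windkessel3")
    cfg = SolverConfig()
    system = assemble(circuit, cfg)
    res = integrate(system, cfg, (0.0, 1.0))
    with pytest.raises(ValueError, match="zeroed sources"):
        check_passivity(system, res)


def test_flow_conservation_residual():
    circuit, _ = make_fixtures("diode_pump")
    cfg = SolverConfig()
    system = assemble(circuit, cfg)
    res = integrate(system, cfg, (0.0, 3.0))
    for k in range(0, res.t.size, 500):
        residual = system.flow_residuals(float(res.t[k]), res.states[:, k])
        assert np.max(np.abs(residual)) < cfg.abs_tol


def test_tolerance_refinement_convergence():
    """Halving rel/abs tolerances changes probes by < 0.1 % relative."""
    circuit, _ = make_fixtures("diode_pump")
    coarse = SolverConfig()
    fine = SolverConfig(rel_tol=coarse.rel_tol / 2, abs_tol=coarse.abs_tol / 2)
    r1 = integrate(circuit, coarse, (0.0, 3.0))
    r2 = integrate(circuit, fine, (0.0, 3.0))
    scale = np.max(np.abs(r1["P"].v))
    assert np.max(np.abs(r1["P"].v - r2["P"].v)) / scale < 1e-3


def test_integration_is_deterministic():
    circuit, _ = make_fixtures("diode_pump")
    cfg = SolverConfig()
    r1 = integrate(circuit, cfg, (0.0, 2.0))
    circuit2, _ = make_fixtures("diode_pump")
    r2 = integrate(circuit2, cfg, (0.0, 2.0))
    assert np.array_equal(r1.states, r2.states)


def test_capacitor_loop_rejected():
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("a")
    c.capacitor("C1", "a", "gnd", 1.0)
    c.capacitor("C2", "a", "gnd", 2.0)
    with pytest.raises(AssemblyError, match="loop"):
        assemble(c, SolverConfig())


def test_floating_node_rejected():
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("a")
    c.add_node("lost")
    c.resistor("R", "a", "gnd", 1.0)
    c.capacitor("C", "a", "gnd", 1.0)
    with pytest.raises(AssemblyError, match="floating"):
        assemble(c, SolverConfig())


def test_inductor_only_junction_rejected():
    c = Circuit()
    c.add_node("gnd", is_ground=True)
    c.add_node("a")
    c.add_node("j")
    c.capacitor("Ca", "a", "gnd", 1.0)
    c.inductor("L1", "a", "j", 1.0)
    c.inductor("L2", "j", "gnd", 1.0)
    with pytest.raises(AssemblyError, match="resistive"):
        assemble(c, SolverConfig())


def test_timeseries_invariants():
    with pytest.raises(ValueError, match="length"):
        TimeSeries(np.arange(3.0), np.arange(4.0), "Pa")
    with pytest.raises(ValueError, match="uniform|increasing"):
        TimeSeries(np.array([0.0, 0.1, 0.15]), np.zeros(3), "Pa")
    ts = TimeSeries(np.arange(5) / 10.0, np.ones(5), "Pa")
    assert ts.dt == pytest.approx(0.1)


def test_circuit_serialization_roundtrip_fields():
    circuit, _ = make_fixtures("windkessel3")
    d = circuit.to_dict()
    assert set(d) == {"nodes", "elements", "probes"}
    assert d["elements"]["Rp"] == {"kind": "resistor", "pos": "in", "neg": "m",
                                   "value": 0.25}
    assert d["probes"]["P_in"] == {"kind": "node_pressure", "target": "in"}
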