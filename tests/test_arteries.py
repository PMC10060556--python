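"""Age-dependent capacitance laws, inflow waveform and network construction."""

import math

import networkx as nx
import numpy as np
import pytest

from cranioflow.arteries import (
    AMAX_MALE,
    INTERMEDIATE_SEGMENTS,
    InflowWaveform,
    aorta_capacitance,
    build_network,
    cca_capacitance,
    load_parameter_set,
)
from cranioflow.circuit import MMHG, ML

L_AORTA = 0.099  # m, summed aortic segment lengths in the shipped table


class TestAortaCapacitance:
    def test_reference_pressures_at_age_20(self):
        # P0 = 76 - 0.98*20 = 56.4 mmHg; P1 = 57 - 0.44*20 = 48.2 mmHg;
        # at P = P0 the quadratic term vanishes and C peaks at Amax*L/(pi*P1)
        peak = aorta_capacitance(56.4, 20.0, L_AORTA)
        expected = AMAX_MALE * L_AORTA / (math.pi * 48.2) / MMHG
        assert peak == pytest.approx(expected, rel=1e-12)
        assert aorta_capacitance(56.4 + 1e-6, 20.0, L_AORTA) < peak

    @pytest.mark.parametrize("delta", [5.0, 17.3, 40.0])
    def test_symmetric_about_p0(self, delta):
        p0 = 76.0 - 0.98 * 35.0
        lo = aorta_capacitance(p0 - delta, 35.0, L_AORTA)
        hi = aorta_capacitance(p0 + delta, 35.0, L_AORTA)
        assert lo == pytest.approx(hi, rel=1e-12)

    def test_monotone_decreasing_with_age_at_100mmhg(self):
        vals = [aorta_capacitance(100.0, age, L_AORTA)
                for age in np.arange(20, 71)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_age_validity(self):
        with pytest.raises(ValueError, match="age"):
            aorta_capacitance(100.0, 19.0, L_AORTA)
        with pytest.raises(ValueError, match="age"):
            aorta_capacitance(100.0, 71.0, L_AORTA)


class TestCcaCapacitance:
    def test_reference_value_age_20(self):
        # 1.3 * 3.14 * e^-1.8 ml/mmHg at the reference pressure
        expected = 1.3 * 3.14 * math.exp(-1.8)
        got = cca_capacitance(100.0, 20.0) / (ML / MMHG)
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6748, abs=5e-4)

    def test_age_factor_at_60(self):
        ratio = cca_capacitance(100.0, 60.0) / cca_capacitance(100.0, 20.0)
        assert ratio == pytest.approx(0.82 / 1.3, rel=1e-12)

    def test_strictly_decreasing_with_age(self):
        vals = [cca_capacitance(90.0, a) for a in np.arange(20, 71, 1)]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestInflow:
    def test_period_integral_equals_stroke_volume(self):
        wf = InflowWaveform()
        t = np.linspace(0.0, wf.period, 20001)
        integral = np.trapezoid([wf(s) for s in t], t)
        assert integral == pytest.approx(wf.stroke_volume, rel=1e-3)

    def test_diastole_is_zero_and_flow_nonnegative(self):
        wf = InflowWaveform()
        ts = wf.systolic_fraction * wf.period
        for t in np.linspace(ts + 1e-9, wf.period, 50):
            assert wf(t) == 0.0
        assert all(wf(t) >= 0.0 for t in np.linspace(0, wf.period, 200))

    def test_periodicity(self):
        wf = InflowWaveform()
        for t in (0.05, 0.13, 0.31, 0.79):
            # equal up to the float representation of t + k*T
            assert wf(t + wf.period) == pytest.approx(wf(t), rel=1e-9, abs=1e-15)
            assert wf(t + 5 * wf.period) == pytest.approx(wf(t), rel=1e-9, abs=1e-15)


class TestNetwork:
    @pytest.fixture(scope="class")
    def pset(self):
        return load_parameter_set("scenario1")

    def test_exact_segment_and_terminal_inventory(self, pset):
        assert sorted(pset.segments["name"]) == sorted(INTERMEDIATE_SEGMENTS)
        assert len(pset.segments) == 22
        assert len(pset.terminals) == 11   # 33 segments in total

    def test_construction_audit(self, pset):
        c = build_network(40.0, pset)
        # per segment: R, L, C; per terminal: Rp, C, Rd; plus the two sources
        n_elem = len(c.elements)
        assert n_elem == 3 * 22 + 3 * 11 + 2 + 6  # + 6 cerebral ref sources
        kinds = [e.kind for e in c.elements.values()]
        assert kinds.count("capacitor") == 22 + 11
        assert kinds.count("inductor") == 22

    def test_age_changes_only_compliance_laws(self, pset):
        c20 = build_network(20.0, pset)
        c60 = build_network(60.0, pset)
        assert set(c20.elements) == set(c60.elements)
        for name in c20.elements:
            e20, e60 = c20.elements[name], c60.elements[name]
            if callable(e20.value) and e20.kind == "capacitor":
                assert name.split("_C")[0] in (
                    "asc_aorta", "aortic_arch_1", "aortic_arch_2", "cca_l", "cca_r")
            elif not callable(e20.value):
                assert e20.value == e60.value

    def _graph(self, circuit, drop=()):
        g = nx.Graph()
        for el in circuit.elements.values():
            if el.name in drop or el.kind in ("pressure_source", "flow_source",
                                              "capacitor"):
                continue
            g.add_edge(el.pos, el.neg)
        return g

    def test_circle_of_willis_dual_supply(self, pset):
        """Every cerebral outlet is reachable from both the carotid and the
        vertebrobasilar routes while the communicating arteries stand."""
        c = build_network(40.0, pset)
        g = self._graph(c)
        for outlet in ("mca_l_preart", "aca_l_preart", "pca_l_preart"):
            assert nx.has_path(g, "cca_l_d", outlet)
            assert nx.has_path(g, "bas_p", outlet)

    def test_acoa_removal_leaves_only_posterior_collateral(self, pset):
        """Within the Circle of Willis, removing the anterior communicating
        artery leaves the two ACA territories connected only through the
        posterior communicating route."""
        c = build_network(40.0, pset)
        circle = ("acoa", "pcoa_l", "pcoa_r", "aca_a1_l", "aca_a1_r",
                  "pca_p1_l", "pca_p1_r", "basilar")

        def circle_graph(drop=()):
            g = nx.Graph()
            for seg in circle:
                if seg in drop:
                    continue
                for suffix in ("_R", "_L"):
                    el = c.elements[seg + suffix]
                    g.add_edge(el.pos, el.neg)
            return g

        g = circle_graph(drop=("acoa",))
        assert nx.has_path(g, "aca_l_j", "aca_r_j")   # posterior route stands
        g2 = circle_graph(drop=("acoa", "pcoa_l", "pcoa_r"))
        assert "aca_r_j" not in nx.node_connected_component(g2, "aca_l_j")

    def test_cycle_volume_conservation(self, coupled_run_with_csf_probes):
        """In periodic steady state the cycle-mean outlet flows sum to the
        cycle-mean cardiac inflow within 1 %."""
        cfg, res = coupled_run_with_csf_probes
        n = int(round(cfg.heart_period / res["inflow"].dt))
        inflow = float(np.mean(res["inflow"].v[-n:]))
        outlets = [name for name in res.probes if name.startswith("outlet_")]
        assert len(outlets) == 11
        total = sum(float(np.mean(res[name].v[-n:])) for name in outlets)
        assert total == pytest.approx(inflow, rel=0.01)

    def test_missing_segment_rejected(self, pset):
        import cranioflow.arteries as arteries

        broken = arteries.ParameterSet(
            "broken", pset.segments[pset.segments["name"] != "basilar"],
            pset.terminals)
        with pytest.raises(Exception, match="basilar"):
            broken.validate()
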