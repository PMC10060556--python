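"""Territory microcirculation chains and the simulated PPG signal."""

import numpy as np
import pytest

from cranioflow.arteries import load_parameter_set
from cranioflow.circuit import MMHG, SolverConfig, integrate
from cranioflow.microcirculation import (
    MicrocirculationRatios,
    build_territory,
    load_ratios,
    ppg_signal,
)


def terminal_row(territory="MCA-L"):
    pset = load_parameter_set()
    row = dict(pset.terminals.set_index("territory").loc[territory])
    row["territory"] = territory
    row["name"] = {"MCA-L": "mca_l", "ACA-L": "aca_l", "PCA-L": "pca_l"}[territory]
    return row


def test_ratio_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        MicrocirculationRatios(r_arteriole=0.6, r_capillary=0.25, r_venule=0.25)
    with pytest.raises(ValueError, match="capacitance fraction"):
        MicrocirculationRatios(c_capillary_frac=1.2)
    assert load_ratios().rava_multiplier > 0


def test_partition_sums():
    row = terminal_row()
    frag = build_territory("MCA-L", row)
    rs = [frag.elements[f"mca_l_micro_{n}"].value
          for n in ("RA1", "RA2", "RC", "RV2", "RV1", "Rdrain")]
    assert sum(rs) == pytest.approx(float(row["Rd_si"]), rel=1e-3)
    cs = [frag.elements[f"mca_l_micro_{n}"].value for n in ("CC", "CV1", "CV2")]
    assert sum(cs) == pytest.approx(float(row["C_si"]), rel=1e-3)
    # equal splits
    assert frag.elements["mca_l_micro_RA1"].value == \
        frag.elements["mca_l_micro_RA2"].value
    assert frag.elements["mca_l_micro_CV1"].value == \
        frag.elements["mca_l_micro_CV2"].value


def _driven_chain(rava_multiplier=10.0, p_in_mmhg=70.0, ref_mmhg=5.0,
                  common_offset_pa=0.0):
    """Territory chain driven by constant pressures, compliances referenced
    to the (offsettable) reference source."""
    row = terminal_row()
    ratios = MicrocirculationRatios(rava_multiplier=rava_multiplier)
    frag = build_territory("MCA-L", row, ratios)
    frag.pressure_source("drive", "mca_l_preart", "gnd",
                         p_in_mmhg * MMHG + common_offset_pa)
    frag.pressure_source("ref_src", "mca_l_ref", "gnd",
                         ref_mmhg * MMHG + common_offset_pa)
    for cap in ("CC", "CV1", "CV2"):
        frag.elements[f"mca_l_micro_{cap}"].external_pressure_ref = "mca_l_ref"
    frag.add_probe("q_RA1", "element_flow", "mca_l_micro_RA1")
    frag.add_probe("q_RAVA", "element_flow", "mca_l_micro_RAVA")
    return frag, row


def steady(frag, t_end=30.0):
    return integrate(frag, SolverConfig(), (0.0, t_end),
                     init_pressures={n: 5 * MMHG for n in frag.nodes
                                     if not frag.nodes[n].is_ground})


def test_open_anastomosis_limit():
    """With RAVA -> infinity the shunt flow vanishes and the chain carries
    the plain series-resistance flow."""
    frag, row = _driven_chain(rava_multiplier=1e9)
    res = steady(frag)
    q_chain = res["q_RA1"].v[-1]
    q_series = (70.0 - 5.0) * MMHG / float(row["Rd_si"])
    assert res["q_RAVA"].v[-1] == pytest.approx(0.0, abs=1e-3 * q_chain)
    assert q_chain == pytest.approx(q_series, rel=1e-3)


def test_dc_divider_oracle():
    """Constant forcing: the PPG equals the algebraic resistive-divider
    solution, computed here independently with a nodal linear solve."""
    frag, row = _driven_chain()
    res = steady(frag)
    sig = ppg_signal(res, "MCA-L")

    ratios = load_ratios()
    rd = float(row["Rd_si"])
    ra = ratios.r_arteriole * rd / 2
    rc = ratios.r_capillary * rd
    rv2, rv1, rdr = (f * ratios.r_venule * rd for f in (0.4, 0.4, 0.2))
    rava = ratios.rava_multiplier * 2 * ra
    # nodes n1..n5; Dirichlet: preart, ref
    p_in, p_ref = 70.0 * MMHG, 5.0 * MMHG
    G = np.zeros((5, 5))
    b = np.zeros(5)
    links = [(0, None, ra, p_in), (0, 1, ra, None), (1, 2, rc, None),
             (2, 3, rv2, None), (3, 4, rv1, None), (4, None, rdr, p_ref),
             (0, 3, rava, None)]
    for a, c, r, fixed in links:
        g = 1.0 / r
        G[a, a] += g
        if c is None:
            b[a] += g * fixed
        else:
            G[c, c] += g
            G[a, c] -= g
            G[c, a] -= g
    p = np.linalg.solve(G, b)
    expected = (p[2] - p_ref) + (p[3] - p_ref) + (p[4] - p_ref)
    assert sig.v[-1] == pytest.approx(expected, rel=1e-3)


def test_transmural_invariance_under_common_offset():
    """Adding +100 Pa to both the drive and the reference leaves the PPG
    unchanged: the observable is built from pressure differences."""
    r0 = steady(_driven_chain()[0])
    r1 = steady(_driven_chain(common_offset_pa=100.0)[0])
    s0 = ppg_signal(r0, "MCA-L").v[-1]
    s1 = ppg_signal(r1, "MCA-L").v[-1]
    assert s1 == pytest.approx(s0, rel=1e-6)


def test_ppg_signal_modes_and_errors():
    frag, _ = _driven_chain()
    res = steady(frag, t_end=1.0)
    full = ppg_signal(res, "MCA-L", mode="sum")
    cap_only = ppg_signal(res, "MCA-L", mode="capillary")
    assert np.all(cap_only.v <= full.v)
    with pytest.raises(ValueError, match="mode"):
        ppg_signal(res, "MCA-L", mode="bogus")
    with pytest.raises(KeyError, match="probe"):
        ppg_signal(res, "PCA-L")


def test_unknown_territory_rejected():
    row = terminal_row()
    with pytest.raises(Exception, match="serves"):
        build_territory("PCA-L", row)


class TestCoupledPPG:
    def test_ppg_periodic_and_smooth(self, coupled_run_with_csf_probes):
        """Steady-state PPG: consecutive cycles < 1 % RMS apart and < 1 % of
        spectral power above 10 Hz (large-artery compliance absorbs the
        sharp systolic components before they reach the arterioles)."""
        cfg, res = coupled_run_with_csf_probes
        for terr in cfg.territories:
            sig = ppg_signal(res, terr)
            n = int(round(cfg.heart_period / sig.dt))
            last, prev = sig.v[-n:], sig.v[-2 * n:-n]
            rms = np.sqrt(np.mean((last - prev) ** 2)) / np.mean(last)
            assert rms < 0.01
            seg = sig.v[-2 * n:] - np.mean(sig.v[-2 * n:])
            spec = np.abs(np.fft.rfft(seg)) ** 2
            freq = np.fft.rfftfreq(seg.size, d=sig.dt)
            assert spec[freq > 10.0].sum() / spec[freq > 0].sum() < 0.01

    def test_raising_icp_lowers_value_features_everywhere(self, grid_summary):
        feats = grid_summary["features"]
        for (_, _), g in feats.groupby(["age_years", "territory"]):
            g = g.sort_values("ratio_cd", ascending=False)
            for col in ("maximum", "minimum", "mean"):
                assert g[col].is_monotonic_decreasing, col

    def test_mca_less_pulsatile_than_aca_and_pca(self, grid_summary):
        feats = grid_summary["features"]
        norm = feats[feats.ratio_cd == 1.0].set_index(["age_years", "territory"])
        for age in (20.0, 40.0, 60.0):
            mca = norm.loc[(age, "MCA-L")]
            for other in ("ACA-L", "PCA-L"):
                ref = norm.loc[(age, other)]
                assert mca["amplitude"] < ref["amplitude"]
                for col in ("PI", "RI", "MMR"):
                    assert mca[col] < ref[col]
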