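"""Regenerate the versioned parameter tables under src/cranioflow/data/.

Anatomy -> Windkessel element values: R = 8*mu*l/(pi r^4), L = rho*l/(pi r^2),
C = 3*pi*r^3*l/(2Eh) with an exponential wall-stiffness law; terminal
resistances sized from regional flow fractions at the design mean arterial
pressure.  The tuning knobs at the top are the committed calibration; run
this script after changing them to regenerate the CSVs.
"""
import math
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "cranioflow" / "data"

MU, RHO, MMHG = 4e-3, 1050.0, 133.3

# ----- knobs (updated during calibration) -----
MAP_TARGET = 92.0      # mmHg design point for terminal resistances
PV = 5.0               # mmHg venous reference
PICP = 11.0            # mmHg design ICP for cerebral terminal sizing
CO = 9.375e-5          # m3/s (75 ml stroke at 0.8 s)
RP_FRACTION = 0.2      # peripheral share of terminal resistance
TAU_TERMINAL = {"default": 1.2, "MCA": 1.6, "ACA": 1.05, "PCA": 0.95}  # s, Rd*C

SEGMENTS = [  # name, prox, dist, length_cm, radius_cm, law
    ("asc_aorta", "heart", "aorta1", 4.0, 1.2, "aorta"),
    ("aortic_arch_1", "aorta1", "aorta2", 2.0, 1.12, "aorta"),
    ("aortic_arch_2", "aorta2", "aorta3", 3.9, 1.07, "aorta"),
    ("brachiocephalic", "aorta1", "brach_j", 3.4, 0.62, ""),
    ("cca_r", "brach_j", "cca_r_d", 17.7, 0.37, "cca"),
    ("cca_l", "aorta2", "cca_l_d", 20.8, 0.37, "cca"),
    ("subclavian_r", "brach_j", "sub_r_d", 3.4, 0.42, ""),
    ("subclavian_l", "aorta3", "sub_l_d", 3.4, 0.42, ""),
    ("vertebral_r", "sub_r_d", "bas_p", 14.8, 0.136, ""),
    ("vertebral_l", "sub_l_d", "bas_p", 14.8, 0.136, ""),
    ("ica_r_1", "cca_r_d", "ica_r_m", 17.7, 0.25, ""),
    ("ica_l_1", "cca_l_d", "ica_l_m", 17.7, 0.25, ""),
    ("ica_r_2", "ica_r_m", "ica_r_d", 0.5, 0.2, ""),
    ("ica_l_2", "ica_l_m", "ica_l_d", 0.5, 0.2, ""),
    ("basilar", "bas_p", "bas_d", 2.9, 0.162, ""),
    ("pcoa_r", "ica_r_d", "pca_r_j", 1.5, 0.073, ""),
    ("pcoa_l", "ica_l_d", "pca_l_j", 1.5, 0.073, ""),
    ("aca_a1_r", "ica_r_d", "aca_r_j", 1.2, 0.117, ""),
    ("aca_a1_l", "ica_l_d", "aca_l_j", 1.2, 0.117, ""),
    ("acoa", "aca_l_j", "aca_r_j", 0.3, 0.074, ""),
    ("pca_p1_r", "bas_d", "pca_r_j", 0.5, 0.107, ""),
    ("pca_p1_l", "bas_d", "pca_l_j", 0.5, 0.107, ""),
]

TERMINALS = [  # name, attach, territory, reference, flow fraction of CO
    ("thoracic_aorta", "aorta3", "thoracic_aorta", "venous_source", 0.72),
    ("brachial_r", "sub_r_d", "brachial-R", "venous_source", 0.055),
    ("brachial_l", "sub_l_d", "brachial-L", "venous_source", 0.055),
    ("eca_r", "cca_r_d", "ECA-R", "venous_source", 0.04),
    ("eca_l", "cca_l_d", "ECA-L", "venous_source", 0.04),
    ("mca_r", "ica_r_d", "MCA-R", "icp_coupled", 0.0196),
    ("mca_l", "ica_l_d", "MCA-L", "icp_coupled", 0.0196),
    ("aca_r", "aca_r_j", "ACA-R", "icp_coupled", 0.0142),
    ("aca_l", "aca_l_j", "ACA-L", "icp_coupled", 0.0142),
    ("pca_r", "pca_r_j", "PCA-R", "icp_coupled", 0.0107),
    ("pca_l", "pca_l_j", "PCA-L", "icp_coupled", 0.0107),
]


def wall_Eh(r_cm: float) -> float:
    """E*h in Pa*m from an exponential stiffness-radius law."""
    r = r_cm * 1e-2
    return 0.1 * (2e7 * math.exp(-22.53 * r_cm) + 8.65e5) * r


def scenario(name: str, radius_scale: float, length_scale: float):
    seg_rows = ["name,prox,distal,length_cm,radius_cm,R_si,L_si,C_si,law,provenance"]
    for n, p, d, lc, rc, law in SEGMENTS:
        lc2 = lc * length_scale
        rc2 = rc * (radius_scale if law == "" else 1.0)  # aorta/CCA use printed laws
        l, r = lc2 * 1e-2, rc2 * 1e-2
        R = 8 * MU * l / (math.pi * r ** 4)
        L = RHO * l / (math.pi * r ** 2)
        C = 3 * math.pi * r ** 3 * l / (2 * wall_Eh(rc2))
        prov = ("anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); "
                "C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law")
        if law:
            prov = "R/L anatomy-derived; C replaced by age-dependent %s law" % law
        seg_rows.append(f"{n},{p},{d},{lc2:.6g},{rc2:.6g},{R:.9g},{L:.9g},{C:.9g},{law},{prov}")
    (DATA / f"segments_{name}.csv").write_text("\n".join(seg_rows) + "\n")

    term_rows = ["name,attach_node,territory,reference,Rp_si,Rd_si,C_si,provenance"]
    for n, at, terr, ref, f in TERMINALS:
        Q = f * CO
        Pout = PICP if ref == "icp_coupled" else PV
        Rt = (MAP_TARGET - Pout) * MMHG / Q
        Rp, Rd = RP_FRACTION * Rt, (1 - RP_FRACTION) * Rt
        key = terr.split("-")[0]
        tau = TAU_TERMINAL.get(key, TAU_TERMINAL["default"])
        C = tau / Rd
        prov = (f"calibrated: sized for {f*100:.2f}%% of cardiac output at "
                f"{MAP_TARGET:.0f} mmHg mean pressure; tau={tau} s")
        term_rows.append(f"{n},{at},{terr},{ref},{Rp:.9g},{Rd:.9g},{C:.9g},{prov}")
    (DATA / f"terminals_{name}.csv").write_text("\n".join(term_rows) + "\n")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    scenario("scenario1", 1.0, 1.0)
    # alternative anatomy: slightly narrower, longer vessels (distinct source model)
    scenario("scenario2", 0.92, 1.08)
    print("written to", DATA)
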