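"""The 33-segment cardiocerebral artery network.

Twenty-two intermediate segments (aorta to the Circle of Willis), each a
three-element Windkessel (series resistance and inertance with a compliance
at the segment midpoint), plus eleven outlet terminals: five extracranial
ones referenced to venous pressure and six cerebral ones whose distal
reference becomes the ICP once the network is coupled to the ICP model.

Ageing enters through two pressure-dependent compliance laws:

* the aortic capacitance ``C(P) = Amax*L / (pi*P1*(1 + ((P-P0)/P1)^2))``
  with age-dependent reference pressures ``P0 = 76 - 0.98*age`` and
  ``P1 = 57 - 0.44*age`` (mmHg, valid for ages 20-70); the total aortic
  capacitance is distributed over the three aortic segments proportionally
  to segment length;
* the common-carotid capacitance ``C(P) = a*exp(-b*P)`` (a = 3.14 ml/mmHg,
  b = 0.018 /mmHg) scaled by the age factor ``1.3 - 0.012*(age-20)``,
  anchored at the reference pressure Pref = 100 mmHg.

The cardiac inflow is a half-sine ejection of one stroke volume per beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from cranioflow.circuit import MMHG, ML, AssemblyError, Circuit

__all__ = [
    "AGE_RANGE",
    "AMAX_MALE",
    "AortaCapacitanceLaw",
    "CcaCapacitanceLaw",
    "InflowWaveform",
    "ParameterSet",
    "aorta_capacitance",
    "cca_capacitance",
    "inflow",
    "load_parameter_set",
    "build_network",
    "INTERMEDIATE_SEGMENTS",
    "CEREBRAL_TERRITORIES",
]

AGE_RANGE = (20.0, 70.0)
#: maximal aortic cross-sectional area for male adults, m^2 (5.8 cm^2)
AMAX_MALE = 5.8e-4
CCA_A = 3.14          # ml/mmHg
CCA_B = 0.018         # 1/mmHg
CCA_PREF = 100.0      # mmHg

INTERMEDIATE_SEGMENTS = (
    "asc_aorta", "aortic_arch_1", "aortic_arch_2", "brachiocephalic",
    "cca_r", "cca_l", "subclavian_r", "subclavian_l",
    "vertebral_r", "vertebral_l", "ica_r_1", "ica_l_1", "ica_r_2", "ica_l_2",
    "basilar", "pcoa_r", "pcoa_l", "aca_a1_r", "aca_a1_l", "acoa",
    "pca_p1_r", "pca_p1_l",
)

CEREBRAL_TERRITORIES = ("ACA-L", "ACA-R", "MCA-L", "MCA-R", "PCA-L", "PCA-R")

EXTRACRANIAL_TERRITORIES = ("ECA-L", "ECA-R", "brachial-L", "brachial-R",
                            "thoracic_aorta")


def _check_age(age: float):
    if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        raise ValueError(f"age {age} outside validity range {AGE_RANGE}")


def aorta_capacitance(P_mmhg: float, age: float, L_aorta: float,
                      amax: float = AMAX_MALE) -> float:
    """Aortic capacitance (m^3/Pa) at pressure ``P_mmhg`` for the whole aorta.

    The law peaks at P = P0(age) and falls off symmetrically; both reference
    pressures decrease linearly with age, which stiffens the aorta at any
    operating pressure above P0.
    """
    _check_age(age)
    if P_mmhg < 0:
        raise ValueError("pressure must be non-negative")
    p0 = 76.0 - 0.98 * age
    p1 = 57.0 - 0.44 * age
    c_mmhg = amax * L_aorta / (math.pi * p1 * (1.0 + ((P_mmhg - p0) / p1) ** 2))
    return c_mmhg / MMHG


def cca_capacitance(P_mmhg: float, age: float) -> float:
    """Common-carotid capacitance (m^3/Pa): exponential in pressure, with a
    linearly decreasing age factor anchored at Pref = 100 mmHg."""
    _check_age(age)
    c_ref = CCA_A * math.exp(-CCA_B * CCA_PREF)     # ml/mmHg at Pref
    age_factor = 1.3 - 0.012 * (age - 20.0)
    c_mmhg = c_ref * math.exp(-CCA_B * (P_mmhg - CCA_PREF)) * age_factor
    return c_mmhg * ML / MMHG


@dataclass(frozen=True)
class AortaCapacitanceLaw:
    """SI capacitance law C(P_trans) for one aortic segment.

    The whole-aorta law is evaluated at the local transmural pressure and
    scaled by this segment's share of the total aortic length.
    """

    age: float
    segment_length: float   # m
    total_length: float     # m
    amax: float = AMAX_MALE

    def __call__(self, p_trans_pa: float) -> float:
        p = max(p_trans_pa, 0.0) / MMHG
        return aorta_capacitance(p, self.age, self.total_length, self.amax) * (
            self.segment_length / self.total_length)

    def describe(self) -> dict:
        return {"law": "aorta_capacitance", "age": self.age,
                "segment_length_m": self.segment_length,
                "total_length_m": self.total_length, "amax_m2": self.amax}


@dataclass(frozen=True)
class CcaCapacitanceLaw:
    """SI capacitance law C(P_trans) for one common carotid artery."""

    age: float

    def __call__(self, p_trans_pa: float) -> float:
        return cca_capacitance(max(p_trans_pa, 0.0) / MMHG, self.age)

    def describe(self) -> dict:
        return {"law": "cca_capacitance", "age": self.age}


@dataclass(frozen=True)
class InflowWaveform:
    """Half-sine systolic ejection, T-periodic and non-negative.

    One period integrates exactly to the stroke volume; diastole carries
    zero flow.  Defaults give a cardiac output of about 5.6 L/min.
    """

    period: float = 0.8              # s
    stroke_volume: float = 75.0e-6   # m^3
    systolic_fraction: float = 0.35

    def __post_init__(self):
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic fraction must lie in (0, 1)")
        if self.period <= 0 or self.stroke_volume <= 0:
            raise ValueError("period and stroke volume must be positive")

    def __call__(self, t: float) -> float:
        ts = self.systolic_fraction * self.period
        phase = t % self.period
        if phase >= ts:
            return 0.0
        return math.pi * self.stroke_volume / (2.0 * ts) * math.sin(math.pi * phase / ts)

    def describe(self) -> dict:
        return {"law": "half_sine_inflow", "period_s": self.period,
                "stroke_volume_m3": self.stroke_volume,
                "systolic_fraction": self.systolic_fraction}


def inflow(t: float, waveform: InflowWaveform) -> float:
    """Cardiac inflow (m^3/s) at time ``t``."""
    return waveform(t)


@dataclass
class ParameterSet:
    """Named, versioned tables for segments and outlet terminals."""

    name: str
    segments: pd.DataFrame
    terminals: pd.DataFrame
    notes: dict = field(default_factory=dict)

    def validate(self):
        seg_names = list(self.segments["name"])
        if sorted(seg_names) != sorted(INTERMEDIATE_SEGMENTS):
            missing = set(INTERMEDIATE_SEGMENTS) - set(seg_names)
            extra = set(seg_names) - set(INTERMEDIATE_SEGMENTS)
            raise AssemblyError(
                f"segment table mismatch; missing={sorted(missing)}, "
                f"extra={sorted(extra)}")
        terr = list(self.terminals["territory"])
        expected = set(CEREBRAL_TERRITORIES) | set(EXTRACRANIAL_TERRITORIES)
        if set(terr) != expected or len(terr) != len(set(terr)):
            raise AssemblyError(f"terminal table territories invalid: {terr}")
        for col in ("Rp_si", "Rd_si", "C_si"):
            if not (self.terminals[col] > 0).all():
                raise AssemblyError(f"non-positive terminal {col}")
        if not ((self.segments["R_si"] > 0).all() and (self.segments["L_si"] > 0).all()):
            raise AssemblyError("non-positive segment R or L")
        refs = self.terminals.set_index("territory")["reference"]
        for terr_name in CEREBRAL_TERRITORIES:
            if refs[terr_name] != "icp_coupled":
                raise AssemblyError(f"cerebral terminal {terr_name} must be icp_coupled")
        for terr_name in EXTRACRANIAL_TERRITORIES:
            if refs[terr_name] != "venous_source":
                raise AssemblyError(f"extracranial terminal {terr_name} must be venous_source")
        return self


def load_parameter_set(name: str = "scenario1") -> ParameterSet:
    """Load a named parameter set shipped under ``cranioflow/data``."""
    pkg = resources.files("cranioflow") / "data"
    seg_path = pkg / f"segments_{name}.csv"
    term_path = pkg / f"terminals_{name}.csv"
    try:
        segments = pd.read_csv(seg_path.open())
        terminals = pd.read_csv(term_path.open())
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"unknown parameter set {name!r}") from exc
    segments["law"] = segments["law"].fillna("")
    return ParameterSet(name, segments, terminals).validate()


VENOUS_PRESSURE_MMHG = 5.0


def build_network(age: float, parameter_set: ParameterSet,
                  waveform: InflowWaveform | None = None) -> Circuit:
    """Assemble the artery network circuit for one age.

    Only the aortic and common-carotid capacitance laws depend on age; every
    other element is taken verbatim from the parameter tables.  Cerebral
    terminals are built with per-terminal reference pressure sources at
    venous pressure; coupling to the ICP model replaces those sources with
    trackers of the ICP node.
    """
    _check_age(age)
    parameter_set.validate()
    waveform = waveform or InflowWaveform()
    segs = parameter_set.segments.set_index("name")
    aorta_rows = segs[segs["law"] == "aorta"]
    total_aorta_length = float(aorta_rows["length_cm"].sum()) * 1e-2

    c = Circuit()
    c.add_node("gnd", "reference", is_ground=True)
    c.add_node("venous", "systemic venous pool")
    c.pressure_source("venous_src", "venous", "gnd", VENOUS_PRESSURE_MMHG * MMHG)
    c.add_node("heart", "aortic root")
    c.flow_source("cardiac_inflow", "heart", "gnd", waveform)

    for name, row in segs.iterrows():
        c.add_node(row["prox"])
        c.add_node(row["distal"])
        mid = f"{name}_mid"
        c.add_node(mid)
        c.resistor(f"{name}_R", row["prox"], mid, float(row["R_si"]))
        c.inductor(f"{name}_L", mid, row["distal"], float(row["L_si"]))
        law = row["law"]
        if law == "aorta":
            value = AortaCapacitanceLaw(age, float(row["length_cm"]) * 1e-2,
                                        total_aorta_length)
        elif law == "cca":
            value = CcaCapacitanceLaw(age)
        elif law == "":
            value = float(row["C_si"])
        else:
            raise AssemblyError(f"segment {name!r}: unknown law {law!r}")
        c.capacitor(f"{name}_C", mid, "gnd", value)

    for _, row in parameter_set.terminals.iterrows():
        name = row["name"]
        attach = row["attach_node"]
        if attach not in c.nodes:
            raise AssemblyError(f"terminal {name!r} attaches to missing node {attach!r}")
        pre = f"{name}_preart"
        c.add_node(pre, f"{name} prearteriole")
        c.resistor(f"{name}_Rp", attach, pre, float(row["Rp_si"]))
        c.capacitor(f"{name}_C", pre, "gnd", float(row["C_si"]))
        if row["reference"] == "venous_source":
            ref_node = "venous"
        else:
            # per-terminal reference source; re-pointed to ICP when coupled
            ref_node = f"{name}_ref"
            c.add_node(ref_node)
            c.pressure_source(f"{name}_ref_src", ref_node, "gnd",
                              VENOUS_PRESSURE_MMHG * MMHG)
        c.resistor(f"{name}_Rd", pre, ref_node, float(row["Rd_si"]))

    c.add_probe("abp_aorta", "node_pressure", "asc_aorta_mid")
    c.add_probe("inflow", "element_flow", "cardiac_inflow")
    return c


def initial_network_pressures(circuit: Circuit,
                              arterial_mmhg: float = 80.0,
                              venous_mmhg: float = 5.0) -> dict[str, float]:
    """Uniform initial pressures: arterial tree at 80 mmHg, venous at 5."""
    init = {}
    for node_id in circuit.nodes:
        if circuit.nodes[node_id].is_ground:
            continue
        if node_id == "venous" or node_id.endswith("_ref"):
            init[node_id] = venous_mmhg * MMHG
        else:
            init[node_id] = arterial_mmhg * MMHG
    return init
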