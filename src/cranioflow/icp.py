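"""Intracranial pressure dynamics.

The craniospinal compartment is an electrical-analogue circuit: a proximal
and a distal arterial bed (resistances with compliances referenced to the
ICP node), a CSF formation route (resistance plus one-way valve from the
capillary node into the CSF space) and an outflow route (one-way valve plus
resistance from the CSF space to the venous sinus), a venous drainage chain,
and the nonlinear intracranial tissue compliance on the ICP node itself.

The tissue compliance is a piecewise function of ICP (SI units)::

    C(ICP) = 7.502e-9 * ratio_cd               for ICP in [0, 666.5) Pa
    C(ICP) = (5e-6 / ICP) * ratio_cd           for ICP >= 666.5 Pa

continuous at the knot (666.5 Pa = 5 mmHg, the venous reference).
``ratio_cd`` scales the compliance down to emulate pathological loss of
intracranial capacitance (0.25 = a 75 % decrease).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import yaml

from cranioflow.circuit import MMHG, AssemblyError, Circuit

__all__ = [
    "ICP_KNOT_PA",
    "ICPParameters",
    "CapacitanceCondition",
    "IcpCapacitanceLaw",
    "intracranial_capacitance",
    "load_icp_parameters",
    "build_icp_circuit",
    "couple",
]

ICP_KNOT_PA = 666.5
_C_FLAT = 7.502e-9      # m^3/Pa below the knot
_C_INV = 5e-6           # m^3 in the inverse-proportional branch


def intracranial_capacitance(icp_pa: float, ratio_cd: float) -> float:
    """Piecewise intracranial tissue compliance (m^3/Pa)."""
    if not 0.0 < ratio_cd <= 1.0:
        raise ValueError(f"ratio_cd must lie in (0, 1], got {ratio_cd}")
    if icp_pa < 0:
        raise ValueError("ICP must be non-negative")
    if icp_pa < ICP_KNOT_PA:
        return _C_FLAT * ratio_cd
    return _C_INV / icp_pa * ratio_cd


@dataclass(frozen=True)
class CapacitanceCondition:
    """Intracranial capacitance reduction: ratio_cd = 1 - reduction."""

    ratio_cd: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.ratio_cd <= 1.0:
            raise ValueError("ratio_cd must lie in (0, 1]")

    @property
    def reduction_percent(self) -> float:
        return 100.0 * (1.0 - self.ratio_cd)


@dataclass(frozen=True)
class IcpCapacitanceLaw:
    """Callable SI law used as the ICP-node capacitor value.

    Slightly negative transient pressures are clamped to the flat branch so
    start-up transients cannot leave the law's domain.
    """

    ratio_cd: float

    def __call__(self, icp_pa: float) -> float:
        return intracranial_capacitance(max(icp_pa, 0.0), self.ratio_cd)

    def describe(self) -> dict:
        return {"law": "intracranial_capacitance", "ratio_cd": self.ratio_cd}


@dataclass(frozen=True)
class ICPParameters:
    """Element values of the ICP circuit (SI; pressures in mmHg)."""

    r1_1: float
    r1_2: float
    ci_1: float
    r2_1: float
    r2_2: float
    ci_2: float
    ci_c: float
    cvi: float
    cue: float
    rpv: float
    rdv: float
    rve: float
    rf: float
    ro: float
    pcv_mmhg: float = 5.0
    r_tap: float = 2.0e7
    # microvascular reference divider: fraction r_ref_b/(r_ref_a+r_ref_b) of
    # the ICP signal (mean and pulse alike) is transmitted to the territory
    # outlet; c_ref lightly smooths the divided signal
    r_ref_a: float = 1.15e9
    r_ref_b: float = 1.0e8
    c_ref: float = 3.0e-10

    def validate(self) -> "ICPParameters":
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "pcv_mmhg" and not v > 0:
                raise AssemblyError(f"ICP parameter {f.name} must be positive, got {v}")
        return self


def load_icp_parameters(name: str = "icp_default") -> ICPParameters:
    path = resources.files("cranioflow") / "data" / f"{name}.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return ICPParameters(**{k: float(v) for k, v in raw.items()}).validate()


def build_icp_circuit(params: ICPParameters,
                      condition: CapacitanceCondition) -> Circuit:
    """Build the ICP circuit fragment.

    Node map (all prefixed ``icp_``): ``inlet`` (arterial drive) -> R1_1 ->
    ``a1`` (Ci_1 to the ICP node) -> R1_2 -> ``a2`` -> R2_1 -> ``a3`` (Ci_2
    to the ICP node) -> R2_2 -> ``cap`` (capillary node, small compliance
    Ci_c).  CSF formation: ``cap`` -> Rf-plus-one-way-valve -> ``icp``.
    Outflow: ``icp`` -> Ro-plus-one-way-valve -> ``sinus``.  Venous chain:
    ``cap`` -> Rpv -> ``v1`` (Cvi to the ICP node) -> Rdv -> ``sinus``
    (Cue to ground) -> Rve -> central venous pressure source.  The ICP node
    carries the piecewise tissue compliance referenced to ground.

    Each CSF route (a resistance in series with a smoothed diode) is one
    composite valve element, so both its terminals are compliance nodes and
    the stiff solver never has to locate an ideal switching instant.
    Because the bed compliances are physically attached to the ICP node,
    each heartbeat's arterial volume excursion is pumped into the CSF space,
    which is what makes the ICP waveform pulsatile.
    """
    params.validate()
    c = Circuit()
    c.add_node("gnd", "reference", is_ground=True)
    for nid, label in [
        ("icp_inlet", "arterial drive"), ("icp_a1", "proximal bed"),
        ("icp_a2", "bed mid"), ("icp_a3", "distal bed"),
        ("icp_cap", "capillary node"), ("icp_icp", "CSF space / ICP"),
        ("icp_v1", "cerebral veins"), ("icp_sinus", "venous sinus"),
        ("icp_pcv", "central venous pressure"),
    ]:
        c.add_node(nid, label)

    c.capacitor("icp_Cic", "icp_icp", "gnd", IcpCapacitanceLaw(condition.ratio_cd))
    c.resistor("icp_R1_1", "icp_inlet", "icp_a1", params.r1_1)
    c.capacitor("icp_Ci_1", "icp_a1", "icp_icp", params.ci_1)
    c.resistor("icp_R1_2", "icp_a1", "icp_a2", params.r1_2)
    c.resistor("icp_R2_1", "icp_a2", "icp_a3", params.r2_1)
    c.capacitor("icp_Ci_2", "icp_a3", "icp_icp", params.ci_2)
    c.resistor("icp_R2_2", "icp_a3", "icp_cap", params.r2_2)
    c.capacitor("icp_Ci_c", "icp_cap", "icp_icp", params.ci_c)
    # CSF formation: capillary -> ICP, one-way
    c.valve("icp_Ff", "icp_cap", "icp_icp", params.rf)
    # CSF outflow: ICP -> sinus, one-way
    c.valve("icp_Fo", "icp_icp", "icp_sinus", params.ro)
    # venous pathway
    # Cvi is referenced to ground rather than to the ICP node: the
    # capacitance-reduction mechanism relies on the CSF space's effective
    # capacitance scaling with ratio_cd, which a large venous compliance
    # hanging on the ICP node would mask.
    c.resistor("icp_Rpv", "icp_cap", "icp_v1", params.rpv)
    c.capacitor("icp_Cvi", "icp_v1", "gnd", params.cvi)
    c.resistor("icp_Rdv", "icp_v1", "icp_sinus", params.rdv)
    c.capacitor("icp_Cue", "icp_sinus", "gnd", params.cue)
    c.resistor("icp_Rve", "icp_sinus", "icp_pcv", params.rve)
    c.pressure_source("icp_Pcv", "icp_pcv", "gnd", params.pcv_mmhg * MMHG)

    c.add_probe("icp", "node_pressure", "icp_icp")
    return c


#: artery-network nodes that drive the ICP circuit: the compliance nodes of
#: the distal internal-carotid segments and of the basilar artery (the three
#: intracranial supply trunks)
ICP_DRIVE_NODES = ("ica_l_2_mid", "ica_r_2_mid", "basilar_mid")


def couple(network: Circuit, icp_fragment: Circuit,
           territory_fragments: dict[str, Circuit] | None = None,
           params: "ICPParameters | None" = None) -> Circuit:
    """Join the artery network, the ICP circuit and territory models.

    The resulting monolithic circuit implements three couplings:

    1. the ICP circuit's arterial inlet is driven by the pressures at the
       distal internal-carotid and basilar junctions, averaged through
       equal resistive taps fed by unity-gain pressure trackers (the ICP
       bed re-represents the same cerebral vasculature, so it must not
       draw flow from the network);
    2. every (unprobed) cerebral outlet terminal's distal reference source
       tracks the ICP node instead of holding venous pressure;
    3. each territory fragment replaces its terminal's lumped distal branch;
       its chain drains into, and its compliances are referenced to, a
       *microvascular reference* node that carries a divided-down copy of
       the ICP signal (divider r_ref_a/r_ref_b toward the venous source,
       smoothed by c_ref).  Transmitting only a fraction of ICP to the
       territory outlet is what lets ICP shift the PPG operating point
       without overwhelming the microvascular pressure scale.

    ``territory_fragments`` maps terminal names (e.g. ``"mca_l"``) to
    fragments built by :func:`cranioflow.microcirculation.build_territory`.
    """
    for node in ICP_DRIVE_NODES:
        if node not in network.nodes:
            raise AssemblyError(f"network lacks ICP drive node {node!r}")
    if "icp_icp" not in icp_fragment.nodes:
        raise AssemblyError("ICP fragment lacks its ICP node")
    if params is None:
        params = load_icp_parameters()

    network.merge(icp_fragment)
    for node in ICP_DRIVE_NODES:
        buf = f"icp_tapbuf_{node}"
        network.add_node(buf, f"pressure tracker of {node}")
        network.pressure_source(f"icp_track_{node}", buf, "gnd", 0.0, tracks=node)
        network.resistor(f"icp_tap_{node}", buf, "icp_inlet", params.r_tap)

    if territory_fragments:
        network.add_node("icp_micro_buf", "ICP tracker for microvascular reference")
        network.pressure_source("icp_micro_track", "icp_micro_buf", "gnd", 0.0,
                                tracks="icp_icp")
        network.add_node("icp_micro_ref", "microvascular reference pressure")
        network.resistor("icp_Rref_a", "icp_micro_buf", "icp_micro_ref",
                         params.r_ref_a)
        network.resistor("icp_Rref_b", "icp_micro_ref", "venous", params.r_ref_b)
        network.capacitor("icp_Cref", "icp_micro_ref", "gnd", params.c_ref)

    for term_name, frag in (territory_fragments or {}).items():
        rd = f"{term_name}_Rd"
        ct = f"{term_name}_C"
        if rd not in network.elements or ct not in network.elements:
            raise AssemblyError(f"unknown terminal {term_name!r} for territory coupling")
        del network.elements[rd]
        del network.elements[ct]
        # the per-terminal reference source is superseded by the shared
        # microvascular reference node
        del network.elements[f"{term_name}_ref_src"]
        del network.nodes[f"{term_name}_ref"]
        frag.elements[f"{term_name}_micro_Rdrain"].neg = "icp_micro_ref"
        del frag.nodes[f"{term_name}_ref"]
        network.merge(frag)
        for el in network.elements.values():
            if el.name.startswith(f"{term_name}_micro_C"):
                el.external_pressure_ref = "icp_micro_ref"

    for el in list(network.elements.values()):
        if el.name.endswith("_ref_src") and el.kind == "pressure_source":
            name, pos = el.name, el.pos
            del network.elements[name]
            network.pressure_source(name, pos, "gnd", 0.0, tracks="icp_icp")
    return network
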