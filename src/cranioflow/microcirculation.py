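"""Per-territory cerebral microcirculation and the simulated PPG.

Each probed territory refines its outlet terminal's lumped distal branch
into an arteriole-capillary-venule chain::

    prearteriole -RA1- n1 -RA2- n2 -RC- n3(CC) -RV2- n4(CV1) -RV1- n5(CV2)
                                  -Rdrain-  territory reference source

with an arteriovenous-anastomosis resistance RAVA bridging the arteriole
midpoint (n1) to the venule midpoint (n4).  The chain resistances sum to
the terminal's distal resistance and the three compliances to the
terminal's capacitance, partitioned by the shipped component ratios.  A
small drainage resistor separates the most distal venular compliance from
the ideal reference source; without it that compliance would be
algebraically pinned to the source.

Once coupled, the compliances are referenced to the ICP node and the chain
drains into the ICP-tracking reference source, so a rise in ICP both shifts
the microvascular operating point down and couples the (small) ICP pulse
into the chain - the mechanism by which ICP moves the value-related PPG
features while barely touching the shape-related ones.

The simulated PPG is the summed transmural pressure across CC, CV1 and CV2
(pressure in Pa, not an optical unit): with fixed compliances it is
proportional to the stored microvascular blood volume, which is what a PPG
sensor transduces.  A capillary-only probe is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from cranioflow.circuit import AssemblyError, Circuit, SimulationResult, TimeSeries

__all__ = [
    "MicrocirculationRatios",
    "load_ratios",
    "build_territory",
    "ppg_signal",
    "TERRITORY_TERMINALS",
]

#: default probed territories (left side) and their terminal names
TERRITORY_TERMINALS = {"ACA-L": "aca_l", "MCA-L": "mca_l", "PCA-L": "pca_l",
                       "ACA-R": "aca_r", "MCA-R": "mca_r", "PCA-R": "pca_r"}

# split of the venule resistance share over RV2, RV1 and the drainage resistor
_VENULE_SPLIT = (0.4, 0.4, 0.2)


@dataclass(frozen=True)
class MicrocirculationRatios:
    r_arteriole: float = 0.55
    r_capillary: float = 0.25
    r_venule: float = 0.20
    c_capillary_frac: float = 0.20
    rava_multiplier: float = 10.0

    def __post_init__(self):
        s = self.r_arteriole + self.r_capillary + self.r_venule
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"resistance fractions must sum to 1, got {s}")
        if not 0.0 < self.c_capillary_frac < 1.0:
            raise ValueError("capillary capacitance fraction must lie in (0, 1)")
        if self.rava_multiplier <= 0:
            raise ValueError("rava_multiplier must be positive")


def load_ratios(name: str = "microcirculation_ratios") -> MicrocirculationRatios:
    path = resources.files("cranioflow") / "data" / f"{name}.yaml"
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return MicrocirculationRatios(**{k: float(v) for k, v in raw.items()})


def build_territory(territory: str, terminal_row,
                    ratios: MicrocirculationRatios | None = None) -> Circuit:
    """Build the microcirculation fragment for one territory.

    ``terminal_row`` is the matching cerebral terminal's row of the
    parameter table (needs ``name``, ``territory``, ``Rd_si``, ``C_si``).
    The fragment shares the terminal's prearteriole node and reference node
    with the network; compliances are initially referenced to their own
    negative terminal (ground) and re-referenced to the ICP node by
    :func:`cranioflow.icp.couple`.
    """
    ratios = ratios or MicrocirculationRatios()
    if terminal_row["territory"] != territory:
        raise AssemblyError(
            f"terminal {terminal_row['name']!r} serves {terminal_row['territory']!r}, "
            f"not {territory!r}")
    if territory not in TERRITORY_TERMINALS:
        raise AssemblyError(f"unknown territory {territory!r}")
    term = terminal_row["name"]
    rd = float(terminal_row["Rd_si"])
    ct = float(terminal_row["C_si"])

    ra = ratios.r_arteriole * rd / 2.0
    rc = ratios.r_capillary * rd
    rv2, rv1, rdrain = (f * ratios.r_venule * rd for f in _VENULE_SPLIT)
    cc = ratios.c_capillary_frac * ct
    cv = (1.0 - ratios.c_capillary_frac) * ct / 2.0
    rava = ratios.rava_multiplier * (2.0 * ra)

    c = Circuit()
    c.add_node("gnd", "reference", is_ground=True)
    pre = f"{term}_preart"
    ref = f"{term}_ref"
    c.add_node(pre)
    c.add_node(ref)
    nodes = {i: f"{term}_micro_n{i}" for i in range(1, 6)}
    for nid in nodes.values():
        c.add_node(nid)
    p = f"{term}_micro"
    c.resistor(f"{p}_RA1", pre, nodes[1], ra)
    c.resistor(f"{p}_RA2", nodes[1], nodes[2], ra)
    c.resistor(f"{p}_RC", nodes[2], nodes[3], rc)
    c.resistor(f"{p}_RV2", nodes[3], nodes[4], rv2)
    c.resistor(f"{p}_RV1", nodes[4], nodes[5], rv1)
    c.resistor(f"{p}_Rdrain", nodes[5], ref, rdrain)
    c.resistor(f"{p}_RAVA", nodes[1], nodes[4], rava)
    c.capacitor(f"{p}_CC", nodes[3], "gnd", cc)
    c.capacitor(f"{p}_CV1", nodes[4], "gnd", cv)
    c.capacitor(f"{p}_CV2", nodes[5], "gnd", cv)
    for cap in ("CC", "CV1", "CV2"):
        c.add_probe(f"ppg_{territory}_{cap}", "transmural_pressure", f"{p}_{cap}")
    return c


def ppg_signal(result: SimulationResult, territory: str,
               mode: str = "sum") -> TimeSeries:
    """Extract the territory's simulated PPG from a trajectory.

    ``mode='sum'`` (default) sums the transmural pressures of CC, CV1 and
    CV2; ``mode='capillary'`` returns the capillary compliance alone.
    """
    caps = ("CC", "CV1", "CV2") if mode == "sum" else ("CC",)
    if mode not in ("sum", "capillary"):
        raise ValueError(f"unknown PPG mode {mode!r}")
    series = []
    for cap in caps:
        name = f"ppg_{territory}_{cap}"
        if name not in result.probes:
            raise KeyError(f"trajectory lacks probe {name!r}; was the territory built?")
        series.append(result.probes[name])
    v = np.sum([s.v for s in series], axis=0)
    return TimeSeries(series[0].t, v, "Pa")
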