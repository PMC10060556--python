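"""Scenario orchestration: build, run and summarise the simulation grid.

The default grid crosses three ages (20/40/60 years), four intracranial
capacitance conditions (0/25/50/75 % reduction) and three left-side
cerebral perfusion territories (ACA/MCA/PCA).  Each run simulates 30 s and
measures the first cardiac cycle after 10 s, when the start-up transient
has died out.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from cranioflow.arteries import (
    InflowWaveform,
    ParameterSet,
    build_network,
    load_parameter_set,
)
from cranioflow.circuit import (
    MMHG,
    Circuit,
    IntegrationError,
    SimulationResult,
    SolverConfig,
    integrate,
)
from cranioflow.features import (
    CycleFeatures,
    extract_cycle,
    relative_difference_table,
)
from cranioflow.icp import (
    CapacitanceCondition,
    ICPParameters,
    build_icp_circuit,
    couple,
    load_icp_parameters,
)
from cranioflow.microcirculation import (
    TERRITORY_TERMINALS,
    MicrocirculationRatios,
    build_territory,
    load_ratios,
    ppg_signal,
)

logger = logging.getLogger("cranioflow")

__all__ = ["ScenarioConfig", "RunRecord", "build_scenario", "run_scenario",
           "run_grid", "grid_tables", "calibrate", "make_fixtures"]

DEFAULT_AGES = (20.0, 40.0, 60.0)
DEFAULT_RATIOS = (1.0, 0.75, 0.5, 0.25)
DEFAULT_TERRITORIES = ("ACA-L", "MCA-L", "PCA-L")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one grid of simulations."""

    ages: tuple = DEFAULT_AGES
    ratio_cd_list: tuple = DEFAULT_RATIOS
    territories: tuple = DEFAULT_TERRITORIES
    duration: float = 30.0
    measure_after: float = 10.0
    heart_period: float = 0.8
    stroke_volume_ml: float = 75.0
    systolic_fraction: float = 0.35
    parameter_set: str = "scenario1"
    icp_parameters: str = "icp_default"
    output_rate: float = 1000.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    ppg_mode: str = "sum"

    def __post_init__(self):
        if not self.duration > self.measure_after + self.heart_period:
            raise ValueError("duration must exceed measure_after + one heart period")
        for r in self.ratio_cd_list:
            if not 0.0 < r <= 1.0:
                raise ValueError(f"ratio_cd {r} outside (0, 1]")

    def waveform(self) -> InflowWaveform:
        return InflowWaveform(self.heart_period, self.stroke_volume_ml * 1e-6,
                              self.systolic_fraction)

    def solver(self) -> SolverConfig:
        return SolverConfig(rel_tol=self.rel_tol, abs_tol=self.abs_tol,
                            output_rate=self.output_rate)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunRecord:
    """Result of one (age, ratio_cd) simulation."""

    age: float
    ratio_cd: float
    icp_max: float          # mmHg, over the measured cycle
    icp_min: float
    icp_mean: float
    ppg_features: dict[str, CycleFeatures]
    abp_mean: float         # mmHg, ascending aorta, measured cycle
    stats: dict
    config_hash: str
    failed: bool = False
    error: str = ""


def build_scenario(age: float, ratio_cd: float,
                   config: ScenarioConfig | None = None,
                   parameter_set: ParameterSet | None = None,
                   icp_params: ICPParameters | None = None,
                   ratios: MicrocirculationRatios | None = None) -> tuple[Circuit, dict]:
    """Build the coupled circuit for one scenario; returns (circuit, init)."""
    config = config or ScenarioConfig()
    pset = parameter_set or load_parameter_set(config.parameter_set)
    ip = icp_params or load_icp_parameters(config.icp_parameters)
    ratios = ratios or load_ratios()

    network = build_network(age, pset, config.waveform())
    icp_frag = build_icp_circuit(ip, CapacitanceCondition(ratio_cd))
    terms = pset.terminals.set_index("territory")
    territory_frags = {}
    for terr in config.territories:
        row = terms.loc[terr]
        row = dict(row)
        row["territory"] = terr
        row["name"] = TERRITORY_TERMINALS[terr]
        territory_frags[TERRITORY_TERMINALS[terr]] = build_territory(terr, row, ratios)
    circuit = couple(network, icp_frag, territory_frags, params=ip)

    init = _initial_pressures(circuit)
    return circuit, init


_ARTERIAL_INIT = 80.0   # mmHg
_VENOUS_INIT = 5.0      # mmHg


def _initial_pressures(circuit: Circuit) -> dict[str, float]:
    """Arterial tree at 80 mmHg; CSF space, venous side and microcirculation
    start at the venous level with a graded chain so transients stay tame."""
    init = {}
    for nid in circuit.nodes:
        if circuit.nodes[nid].is_ground:
            continue
        arterial_side = ("icp_inlet", "icp_a1", "icp_a2", "icp_a3")
        if nid.startswith("icp_") and nid not in arterial_side \
                and not nid.startswith("icp_tapbuf"):
            init[nid] = _VENOUS_INIT * MMHG
        elif "_micro_n" in nid:
            level = int(nid[-1])
            init[nid] = (30.0 - 5.0 * level) * MMHG   # 25 .. 5 mmHg down the chain
        elif nid == "venous" or nid.endswith("_ref"):
            init[nid] = _VENOUS_INIT * MMHG
        else:
            init[nid] = _ARTERIAL_INIT * MMHG
    return init


def run_scenario(age: float, ratio_cd: float,
                 config: ScenarioConfig | None = None,
                 parameter_set: ParameterSet | None = None,
                 icp_params: ICPParameters | None = None,
                 ratios: MicrocirculationRatios | None = None,
                 keep_result: bool = False):
    """Simulate one scenario and extract the measured-cycle summaries.

    Returns a :class:`RunRecord` (and the raw :class:`SimulationResult` if
    ``keep_result``).
    """
    config = config or ScenarioConfig()
    circuit, init = build_scenario(age, ratio_cd, config, parameter_set,
                                   icp_params, ratios)
    t0 = time.perf_counter()
    try:
        result = integrate(circuit, config.solver(), (0.0, config.duration),
                           init_pressures=init)
    except IntegrationError as exc:
        rec = RunRecord(age, ratio_cd, np.nan, np.nan, np.nan, {}, np.nan,
                        {"t_last": exc.t_last}, config.config_hash(),
                        failed=True, error=str(exc))
        return (rec, None) if keep_result else rec
    wall = time.perf_counter() - t0

    t_meas = config.measure_after
    T = config.heart_period
    icp = result["icp"]
    icp_feat = extract_cycle(icp, t_meas, T)
    abp_feat = extract_cycle(result["abp_aorta"], t_meas, T)
    ppg_features = {}
    for terr in config.territories:
        sig = ppg_signal(result, terr, mode=config.ppg_mode)
        ppg_features[terr] = extract_cycle(sig, t_meas, T)
    rec = RunRecord(
        age=age, ratio_cd=ratio_cd,
        icp_max=icp_feat.maximum / MMHG,
        icp_min=icp_feat.minimum / MMHG,
        icp_mean=icp_feat.mean / MMHG,
        ppg_features=ppg_features,
        abp_mean=abp_feat.mean / MMHG,
        stats={**result.stats, "wall_s": round(wall, 3)},
        config_hash=config.config_hash(),
    )
    logger.info("scenario age=%g ratio_cd=%g: ICP %.2f/%.2f/%.2f mmHg, "
                "ABP mean %.1f mmHg, %d steps, %.1f s wall",
                age, ratio_cd, rec.icp_min, rec.icp_mean, rec.icp_max,
                rec.abp_mean, rec.stats.get("steps", -1), wall)
    if keep_result:
        return rec, result
    return rec


def run_grid(config: ScenarioConfig | None = None,
             parameter_set: ParameterSet | None = None,
             icp_params: ICPParameters | None = None,
             ratios: MicrocirculationRatios | None = None) -> list[RunRecord]:
    """Run the full (age x ratio_cd) grid; failures are recorded, not raised."""
    config = config or ScenarioConfig()
    pset = parameter_set or load_parameter_set(config.parameter_set)
    ip = icp_params or load_icp_parameters(config.icp_parameters)
    ratios = ratios or load_ratios()
    records = []
    for age in config.ages:
        for ratio_cd in config.ratio_cd_list:
            records.append(run_scenario(age, ratio_cd, config, pset, ip, ratios))
    return records


def grid_tables(records: list[RunRecord],
                config: ScenarioConfig | None = None) -> dict[str, pd.DataFrame]:
    """Summary tables of a grid run.

    Returns ``features`` (one row per age/condition/territory with the eight
    waveform features), ``icp_summary`` (per age/condition) and
    ``relative_differences`` (shape-feature spread across conditions, per
    age/territory/feature, in percent).
    """
    config = config or ScenarioConfig()
    feat_rows, icp_rows = [], []
    for rec in records:
        if rec.failed:
            continue
        icp_rows.append({"age_years": rec.age, "ratio_cd": rec.ratio_cd,
                         "icp_max_mmHg": rec.icp_max, "icp_min_mmHg": rec.icp_min,
                         "icp_mean_mmHg": rec.icp_mean,
                         "abp_mean_mmHg": rec.abp_mean})
        for terr, feat in rec.ppg_features.items():
            row = {"age_years": rec.age, "ratio_cd": rec.ratio_cd,
                   "territory": terr, "signal": "ppg"}
            d = feat.as_dict()
            d["min_to_max_time_s"] = d.pop("min_to_max_time")
            feat_rows.append({**row, **d})
    features = pd.DataFrame(feat_rows)
    icp_summary = pd.DataFrame(icp_rows)
    rel_rows = []
    if not features.empty:
        feats = dict(features.groupby(["age_years", "territory"]).__iter__())
        for (age, terr), group in feats.items():
            renamed = group.rename(columns={"min_to_max_time_s": "min_to_max_time"})
            table = relative_difference_table(renamed)
            for _, r in table.iterrows():
                rel_rows.append({"age_years": age, "territory": terr,
                                 "feature": r["feature"],
                                 "relative_difference_pct": r["relative_difference_pct"]})
    relative_differences = pd.DataFrame(rel_rows)
    return {"features": features, "icp_summary": icp_summary,
            "relative_differences": relative_differences}


def write_grid_outputs(records, out_dir, config: ScenarioConfig | None = None):
    """Write features.csv, icp_summary.csv and relative_differences.csv."""
    from pathlib import Path

    config = config or ScenarioConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = grid_tables(records, config)
    header = f"# config_hash={config.config_hash()}\n"
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.9g")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationTargets:
    """Bands a calibrated parameter set must satisfy."""

    icp_normal_mmhg: tuple = (10.0, 15.0)
    abp_mean_mmhg: tuple = (70.0, 110.0)
    icp_50pct_min_mmhg: float = 15.0
    icp_75pct_min_mmhg: float = 20.0
    icp_amplitude_max_mmhg: float = 5.0


def _violation(records: list[RunRecord], targets: CalibrationTargets) -> float:
    """Scalar band-violation score for a compact calibration grid."""
    score = 0.0
    for rec in records:
        if rec.failed:
            return 1e6
        if rec.ratio_cd == 1.0:
            lo, hi = targets.icp_normal_mmhg
            score += max(0.0, lo - rec.icp_mean) + max(0.0, rec.icp_mean - hi)
            lo, hi = targets.abp_mean_mmhg
            score += max(0.0, lo - rec.abp_mean) + max(0.0, rec.abp_mean - hi)
        if rec.ratio_cd == 0.5:
            score += max(0.0, targets.icp_50pct_min_mmhg - rec.icp_mean)
        if rec.ratio_cd == 0.25:
            score += max(0.0, targets.icp_75pct_min_mmhg - rec.icp_mean)
        score += max(0.0, (rec.icp_max - rec.icp_min) - targets.icp_amplitude_max_mmhg)
    return score


#: multiplicative steps tried for each knob, in fixed order (deterministic)
_CAL_KNOBS = ("rf", "ro", "stroke_volume", "terminal_scale")
_CAL_STEPS = (0.8, 0.9, 1.1, 1.25)


def calibrate(config: ScenarioConfig | None = None,
              targets: CalibrationTargets | None = None,
              max_rounds: int = 2,
              ages: tuple = (40.0,),
              ratio_cd_list: tuple = (1.0, 0.5, 0.25)) -> dict:
    """Deterministic bounded coordinate search over the free parameters.

    Adjusts CSF formation/outflow resistances, stroke volume and a global
    terminal-resistance scale to minimise band violations on a compact
    (age x condition) probe grid.  Returns a report with the adjusted
    values (before/after) and the achieved summaries; raises no exception
    when the bands are unreachable - the report carries the best found and
    ``converged=False``.
    """
    config = config or ScenarioConfig()
    targets = targets or CalibrationTargets()
    probe_cfg = ScenarioConfig(
        ages=ages, ratio_cd_list=ratio_cd_list, territories=config.territories,
        duration=config.measure_after + 2 * config.heart_period + 0.1,
        measure_after=config.measure_after, heart_period=config.heart_period,
        stroke_volume_ml=config.stroke_volume_ml,
        systolic_fraction=config.systolic_fraction,
        parameter_set=config.parameter_set, icp_parameters=config.icp_parameters)

    base_ip = load_icp_parameters(config.icp_parameters)
    base_pset = load_parameter_set(config.parameter_set)
    state = {"rf": 1.0, "ro": 1.0, "stroke_volume": 1.0, "terminal_scale": 1.0}
    bounds = (0.5, 2.0)

    def apply(scale: dict):
        import dataclasses

        ip = dataclasses.replace(base_ip, rf=base_ip.rf * scale["rf"],
                                 ro=base_ip.ro * scale["ro"])
        pset = ParameterSet(base_pset.name, base_pset.segments.copy(),
                            base_pset.terminals.copy())
        for col in ("Rp_si", "Rd_si"):
            pset.terminals[col] = base_pset.terminals[col] * scale["terminal_scale"]
        import dataclasses as dc
        cfg = dc.replace(probe_cfg, stroke_volume_ml=probe_cfg.stroke_volume_ml
                         * scale["stroke_volume"])
        return cfg, pset, ip

    def evaluate(scale: dict) -> tuple[float, list[RunRecord]]:
        cfg, pset, ip = apply(scale)
        recs = run_grid(cfg, pset, ip)
        return _violation(recs, targets), recs

    best_score, best_recs = evaluate(state)
    trace = [{"knobs": dict(state), "score": best_score}]
    for _ in range(max_rounds):
        if best_score == 0.0:
            break
        improved = False
        for knob in _CAL_KNOBS:
            for step in _CAL_STEPS:
                cand = dict(state)
                cand[knob] = float(np.clip(cand[knob] * step, *bounds))
                if cand[knob] == state[knob]:
                    continue
                score, recs = evaluate(cand)
                trace.append({"knobs": dict(cand), "score": score})
                if score < best_score - 1e-12:
                    best_score, best_recs, state = score, recs, cand
                    improved = True
        if not improved:
            break
    report = {
        "converged": best_score == 0.0,
        "score": best_score,
        "scales": dict(state),
        "adjusted": {
            "rf": {"before": base_ip.rf, "after": base_ip.rf * state["rf"]},
            "ro": {"before": base_ip.ro, "after": base_ip.ro * state["ro"]},
            "stroke_volume_ml": {
                "before": config.stroke_volume_ml,
                "after": config.stroke_volume_ml * state["stroke_volume"]},
            "terminal_scale": {"before": 1.0, "after": state["terminal_scale"]},
        },
        "achieved": [
            {"age": r.age, "ratio_cd": r.ratio_cd, "icp_mean_mmHg": r.icp_mean,
             "icp_amplitude_mmHg": r.icp_max - r.icp_min,
             "abp_mean_mmHg": r.abp_mean}
            for r in best_recs],
        "trace_length": len(trace),
    }
    return report


# ---------------------------------------------------------------------------
# Fixture circuits


def make_fixtures(kind: str):
    """Small self-contained circuits with analytic reference solutions.

    Returns ``(circuit, reference)`` where ``reference`` is a dict holding
    closed-form expectations used by the test suite.
    """
    from cranioflow.circuit import Circuit

    c = Circuit()
    c.add_node("gnd", is_ground=True)
    if kind == "rc":
        c.add_node("n1")
        c.resistor("R", "n1", "gnd", 1.0)
        c.capacitor("C", "n1", "gnd", 1.0)
        c.add_probe("P", "node_pressure", "n1")
        return c, {"init": {"n1": 1.0}, "solution": lambda t: np.exp(-t)}
    if kind == "windkessel2":
        R, C = 1.0, 0.5
        c.add_node("n")
        c.flow_source("Q", "n", "gnd", 1.0)
        c.resistor("R", "n", "gnd", R)
        c.capacitor("C", "n", "gnd", C)
        c.add_probe("P", "node_pressure", "n")
        return c, {"R": R, "C": C,
                   "impedance": lambda w: R / np.sqrt(1 + (w * R * C) ** 2)}
    if kind == "windkessel3":
        Rp, Rd, C, Q0, Pout = 0.25, 1.0, 0.5, 1.0, 0.1
        c.add_node("in"); c.add_node("m"); c.add_node("out")
        c.flow_source("Q", "in", "gnd", Q0)
        c.resistor("Rp", "in", "m", Rp)
        c.capacitor("C", "m", "gnd", C)
        c.resistor("Rd", "m", "out", Rd)
        c.pressure_source("Pout", "out", "gnd", Pout)
        c.add_probe("P_in", "node_pressure", "in")
        return c, {"dc_inlet_pressure": Q0 * (Rp + Rd) + Pout}
    if kind == "diode_pump":
        # half-wave rectifier: sinusoidal drive charges C through R + diode.
        # Scales chosen so the diode's on-conductance dwarfs 1/R.
        c.add_node("src"); c.add_node("m"); c.add_node("load")
        c.pressure_source("V", "src", "gnd",
                          lambda t: 100.0 * np.sin(2 * np.pi * t))
        c.resistor("R", "src", "m", 3e5)
        c.diode("D", "m", "load")
        c.capacitor("C", "load", "gnd", 1e-6)
        c.resistor("Rleak", "load", "gnd", 5e6)
        c.add_probe("P", "node_pressure", "load")
        c.add_probe("qD", "element_flow", "D")
        return c, {"note": "load pressure stays within (0, 100) Pa, pulsatile"}
    if kind == "mini_icp":
        # 6-element reduction of the ICP circuit with a closed-form DC point
        # (ideal one-way routes, hydraulic SI scales)
        Pa, Pcv = 25.0 * MMHG, 5.0 * MMHG
        Rf, Ro = 4e8, 2e8
        c.add_node("a"); c.add_node("icp"); c.add_node("v")
        c.pressure_source("Pa", "a", "gnd", Pa)
        c.valve("Ff", "a", "icp", Rf)
        c.capacitor("Cic", "icp", "gnd", 1e-9)
        c.valve("Fo", "icp", "v", Ro)
        c.pressure_source("Pcv", "v", "gnd", Pcv)
        c.add_probe("icp", "node_pressure", "icp")
        return c, {"dc_icp": (Pa / Rf + Pcv / Ro) / (1.0 / Rf + 1.0 / Ro),
                   "Pa": Pa, "Pcv": Pcv, "Rf": Rf, "Ro": Ro}
    raise ValueError(f"unknown fixture kind {kind!r}")
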