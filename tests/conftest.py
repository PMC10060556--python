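"""Shared fixtures.

The full default simulation grid (3 ages x 4 capacitance conditions, 30 s
each) is expensive, so it runs once per session and is shared by the
acceptance tests and the trend property tests.
"""

from __future__ import annotations

import pytest

from cranioflow.circuit import integrate
from cranioflow.experiment import (
    ScenarioConfig,
    build_scenario,
    grid_tables,
    run_grid,
)


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def grid_records(default_config):
    """The default 12-run grid (ages 20/40/60 x ratio_cd 1/0.75/0.5/0.25)."""
    records = run_grid(default_config)
    failed = [r for r in records if r.failed]
    assert not failed, f"grid runs failed: {[(r.age, r.ratio_cd, r.error) for r in failed]}"
    return records


@pytest.fixture(scope="session")
def grid_summary(grid_records, default_config):
    return grid_tables(grid_records, default_config)


@pytest.fixture(scope="session")
def coupled_run_with_csf_probes():
    """One normal-condition coupled run carrying CSF-route flow probes.

    Runs the full 30 s: the CSF space charges over the first ~20 s, so
    cycle-to-cycle periodicity is a property of the late portion.
    """
    cfg = ScenarioConfig(duration=30.0)
    circuit, init = build_scenario(40.0, 1.0, cfg)
    circuit.add_probe("csf_formation", "element_flow", "icp_Ff")
    circuit.add_probe("csf_outflow", "element_flow", "icp_Fo")
    circuit.add_probe("capillary", "node_pressure", "icp_cap")
    # outlet flows: lumped terminals measure their distal resistor, probed
    # territories the drainage resistor at the end of the chain
    for el in circuit.elements.values():
        if el.name.endswith("_Rd") or el.name.endswith("_Rdrain"):
            circuit.add_probe(f"outlet_{el.name}", "element_flow", el.name)
    result = integrate(circuit, cfg.solver(), (0.0, cfg.duration),
                       init_pressures=init)
    return cfg, result
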