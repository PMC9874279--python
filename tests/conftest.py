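"""Shared fixtures: steady-state runs are expensive, so the configurations
used by several tests are solved once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ferriflux as ff
from ferriflux.model import SteadyModel, run_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_model():
    """Baseline idealized shelf column (120 uM O2), solved to steady state."""
    cfg = ff.make_scenario("baseline", 120.0, n_cells=100)
    model = SteadyModel(cfg)
    state, diag = model.run()
    return model, state, diag


@pytest.fixture(scope="session")
def mc_run():
    cfg = ff.site_fixture("monterey_canyon")
    model = SteadyModel(cfg)
    state, diag = model.run()
    return model, state, diag


@pytest.fixture(scope="session")
def sbb_run():
    cfg = ff.site_fixture("santa_barbara_basin")
    model = SteadyModel(cfg)
    state, diag = model.run()
    return model, state, diag


@pytest.fixture(scope="session")
def scenario_sweep_runs():
    """The five bioturbation scenarios at 10 and 120 uM bottom-water O2."""
    out = {}
    for name in ("unbioturbated", "always_bioturbated"):
        cfgs = [ff.make_scenario(name, o2, n_cells=100) for o2 in (10.0, 120.0)]
        for o2, (state, diag) in zip((10.0, 120.0), run_grid(cfgs)):
            out[(name, o2)] = diag
    return out


@pytest.fixture(scope="session")
def reduced_grids():
    """Reduced 5 x 5 x 2 sensitivity grids (O2 x POC rain x oxide rain)
    for the modern and unbioturbated seafloors.

    Returns per kind an array of rows (cox, o2_uM, j_feooh, j_dfe, delta).
    """
    o2s = (2.0, 10.0, 25.0, 100.0, 200.0)
    jps = (1.0, 4.0, 8.0, 12.0, 16.0)
    jfs = (555.0, 1110.0)
    out = {}
    for kind, scen in (("modern", "baseline"), ("unbioturbated", "unbioturbated")):
        cfgs = [
            ff.make_scenario(scen, o2, j_poc=jp, j_feooh_total=jf, n_cells=100)
            for jf in jfs for jp in jps for o2 in o2s
        ]
        results = run_grid(cfgs)
        out[kind] = np.array([
            (d.cox, c.bottom_water["O2"] * 1.0e3, c.j_feooh_total,
             d.j_dfe, d.delta_jdfe)
            for c, (_s, d) in zip(cfgs, results)
        ])
    return out
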