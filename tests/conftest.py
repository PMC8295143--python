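"""Shared fixtures.

Heavy PDE solves are session-scoped and reused across test modules; the
coarse screening resolutions used here are chosen so the full suite stays
fast while every qualitative and banded assertion remains meaningful.
"""

from __future__ import annotations

import pytest

import ireplan as ip
from ireplan.pipeline import (
    RunConfig,
    fit_study_models,
    load_screening_table,
    optimize_protocol,
)


@pytest.fixture(scope="session")
def liver():
    return ip.bovine_liver()


@pytest.fixture(scope="session")
def blood():
    return ip.blood_defaults()


@pytest.fixture(scope="session")
def factors():
    return ip.default_factors()


@pytest.fixture(scope="session")
def l18(factors):
    return ip.taguchi_l18(factors)


@pytest.fixture(scope="session")
def table5():
    """The printed 18-run screening design with its responses."""
    return load_screening_table()


@pytest.fixture(scope="session")
def optimal_grid_coarse():
    """Optimal-protocol geometry at 0.5 mm screening resolution."""
    return ip.build_grid(
        ip.DomainSpec(spacing_mm=0.5), ip.ElectrodeConfig(10.0, 10.0, 3000.0)
    )


@pytest.fixture(scope="session")
def optimal_solution_coarse(optimal_grid_coarse, liver):
    return ip.solve_potential(optimal_grid_coarse, liver)


@pytest.fixture(scope="session")
def optimal_sim_coarse(optimal_grid_coarse, liver, blood):
    """Coupled simulation of the optimal protocol at 0.5 mm."""
    return ip.simulate_treatment(
        optimal_grid_coarse, liver, blood, ip.PulseProtocol(50, 41.21, 1.0)
    )


@pytest.fixture(scope="session")
def fullres_sim(liver, blood):
    """Coupled simulation of the optimal protocol at the 0.25 mm
    verification resolution (the calibration configuration)."""
    grid = ip.build_grid(
        ip.DomainSpec(spacing_mm=0.25), ip.ElectrodeConfig(10.0, 10.0, 3000.0)
    )
    return ip.simulate_treatment(grid, liver, blood, ip.PulseProtocol(50, 41.21, 1.0))


@pytest.fixture(scope="session")
def study_models(table5):
    """The three response surfaces fit on the printed screening table
    (field-strength responses simulated at the default 0.5 mm)."""
    cfg = RunConfig()
    return fit_study_models(cfg, table5)


@pytest.fixture(scope="session")
def study_optimum(table5, study_models):
    cfg = RunConfig()
    return optimize_protocol(cfg, table5, models=study_models)


@pytest.fixture(scope="session")
def coarse_cfg(tmp_path_factory):
    """Fast whole-study configuration: 1 mm screening grid."""
    cfg = RunConfig()
    cfg.screening_spacing_mm = 1.0
    cfg.output_dir = str(tmp_path_factory.mktemp("screen"))
    return cfg


@pytest.fixture(scope="session")
def screening18(coarse_cfg):
    """Full 18-run coupled screening at the fast resolution."""
    return ip.run_screening(coarse_cfg)
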