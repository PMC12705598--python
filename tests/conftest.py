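"""Shared fixtures: one small synthetic study system and fitted models.

Problem sizes are deliberately small (a few-hundred-meter grid, handful of
populations) so the whole suite runs on one CPU in minutes while still
exercising every code path.
"""

import numpy as np
import pytest

import fernfusion as ff
from fernfusion.synthetic import make_fixture

SMALL_MESH = {"max_edge_inner": 1200, "max_edge_outer": 2400,
              "extension": 1600, "cutoff": 300}


@pytest.fixture(scope="session")
def small_system():
    """4 km domain, 500 m cells, 6 years, 12 populations, 3 species."""
    return make_fixture(
        seed=11, extent_m=4000, cell_size_m=500, n_years=6,
        truth_hypers={"range_u": 3000, "sd_u": 0.5, "rho_u": 0.7,
                      "range_d": 2000, "sd_d": 0.6, "rho_d": 0.7,
                      "psi": 0.05},
        populations_spec={"counts": (5, 4, 3)},
        field_params={"bio01": {"range": 2000, "sd": 1.0, "trend": 0.05},
                      "tpi": {"range": 1000, "sd": 1.0}},
        beta=[0.4, -0.3],
        mesh_params=SMALL_MESH)


@pytest.fixture(scope="session")
def glm_system():
    """No random effects, all-Poisson truth: exact GLM territory."""
    return make_fixture(
        seed=7, extent_m=4000, cell_size_m=500, n_years=6,
        truth_hypers={"sd_u": 0.0, "sd_d": 0.0, "psi": 1e6},
        populations_spec={"counts": (8, 6, 5)},
        field_params={"bio01": {"range": 2000, "sd": 1.0},
                      "tpi": {"range": 1000, "sd": 1.0}},
        beta=[0.4, -0.3],
        mesh_params=SMALL_MESH)


@pytest.fixture(scope="session")
def fitted_m3(small_system):
    """An M3 (shared spatio-temporal field) fit reused across tests."""
    domain, mesh, cov, truth, obs = small_system
    est = ff.IntegratedSDM(model="M3", seed=5, max_outer=120,
                           n_theta_draws=5)
    est.fit(obs, domain, cov.X, mesh=mesh)
    return est


@pytest.fixture(scope="session")
def m3_samples(fitted_m3):
    return ff.sample_posterior(fitted_m3.result_, 300, seed=17)
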