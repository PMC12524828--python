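import numpy as np
import pytest

from vfarch.fields import SAP_III, SMP
from vfarch.grids import COMMON_42, P24_2, SMP_44, build_grid
from vfarch.synth import CohortConfig, generating_reference, make_templates, simulate_cohort


@pytest.fixture(scope="session")
def full_grid():
    return build_grid(P24_2)


@pytest.fixture(scope="session")
def smp_grid():
    return build_grid(SMP_44)


@pytest.fixture(scope="session")
def common_grid():
    return build_grid(COMMON_42)


@pytest.fixture(scope="session")
def templates():
    return make_templates()


@pytest.fixture(scope="session")
def defect_templates(templates):
    """The four focal defect morphologies used in recovery experiments."""
    return templates[1:5]


@pytest.fixture(scope="session")
def gen_refs():
    return {m: generating_reference(m) for m in (SAP_III, SMP)}


@pytest.fixture(scope="session")
def small_cohort(defect_templates):
    cfg = CohortConfig(n_eyes=6, visits_per_eye=3, seed=11)
    fields, truth = simulate_cohort(cfg, defect_templates)
    return fields, truth


@pytest.fixture(scope="session")
def noiseless_cohort(defect_templates):
    cfg = CohortConfig(
        n_eyes=5,
        visits_per_eye=3,
        seed=7,
        sap_noise_floor_sd=0.0,
        sap_noise_slope=0.0,
        smp_noise_sd=0.0,
        severity_median_db=5.0,
        severity_sigma=0.1,
        progression_rate_sd=0.0,
        progression_rate_mean=-0.5,
    )
    fields, truth = simulate_cohort(cfg, defect_templates)
    return fields, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
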