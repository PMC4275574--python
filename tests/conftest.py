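import numpy as np
import pytest
from hypothesis import settings

import sparseconn as sc

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def signal_study():
    """Small strong-signal two-group dataset (8 regions, 5+5 subjects)."""
    spec = sc.SimulationSpec(n_p=8, n_t=150, n_per_group=5, base_density=0.15,
                             n_diff_edges=3, effect=0.7, subject_noise=0.02,
                             seed=3)
    subjects, _, truth = sc.simulate_dataset(spec)
    data = sc.StudyData.from_timeseries(
        [sc.clean_timeseries(s) for s in subjects])
    return data, truth


@pytest.fixture(scope="session")
def fast_config():
    return sc.PipelineConfig(C_grid=(0.1, 1.0, 10.0), lambda_grid=(0.01,),
                             svm_tol=1e-4, svm_max_iter=5000)
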