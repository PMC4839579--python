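import numpy as np
import pandas as pd
import pytest

import kappafit as kf


@pytest.fixture(scope="session")
def small_design():
    """Reduced factorial design for fast tests: 5 separations, 10 trials."""
    return kf.DesignSpec(
        n_subjects=1,
        distances=tuple(1.414 * i for i in range(0, 17, 4)),
        trials_per_cell=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def mean_classical():
    return kf.published.classical_params("Mean")


@pytest.fixture(scope="session")
def mean_slowness():
    return kf.published.slowness_params("Mean")


@pytest.fixture(scope="session")
def exp1_classical_small(small_design, mean_classical):
    gen = kf.GeneratorSpec(model="classical", params=mean_classical)
    return kf.generate_exp1(small_design, gen)


@pytest.fixture(scope="session")
def exp1_classical_full(mean_classical):
    """One subject at the published mean parameters, full design."""
    gen = kf.GeneratorSpec(model="classical", params=mean_classical)
    return kf.generate_exp1(kf.DesignSpec(n_subjects=1, seed=7), gen)


def make_trials(t_p, t_s=0.8, distance=0.0, subject="S1", location=0.0, experiment="exp1"):
    """Hand-built trial table from a list of production times."""
    t_p = np.asarray(t_p, float)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "experiment": experiment,
            "sample_interval_s": t_s,
            "distance_deg": distance,
            "location_deg": location,
            "trial_index": np.arange(1, len(t_p) + 1),
            "production_time_s": t_p,
        }
    )
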