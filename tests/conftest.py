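import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def small_truth():
    from oncoprev import synthetic_cohorts as syn

    return syn.gen_truth(20, 5, seed=101)


@pytest.fixture()
def small_study(small_truth, tmp_path):
    """A small simulated study written to disk plus its in-memory objects."""
    from oncoprev import synthetic_cohorts as syn

    cohorts = syn.gen_cohort_profiles(
        small_truth, 80, seed=202, subtypes_per_site=2
    )
    paths = syn.write_study(small_truth, cohorts, tmp_path / "study")
    return {"truth": small_truth, "cohorts": cohorts, "paths": paths}


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
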