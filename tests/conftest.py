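import numpy as np
import pytest

from mpmap import phantom, pipeline


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort with boosted prevalences so every outcome has both classes."""
    return phantom.PhantomSpec(
        n_patients=6,
        shape=(32, 32, 32),
        spacing=(1.5, 1.5, 1.5),
        brain_radius=18.0,
        tumor_radius_range=(5.0, 7.0),
        tumor_center_max_offset=6.0,
        core_volume_mm3=(300.0, 50.0),
        prevalence={o: 0.5 for o in ("idh1", "mgmt", "cnec", "mvp")},
        triage_given_negative={o: 0.3 for o in ("idh1", "mgmt", "cnec", "mvp")},
        wm_roi_radius=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return phantom.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_cohort):
    return pipeline.prepare_cohort(tiny_cohort.as_pipeline_input())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
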