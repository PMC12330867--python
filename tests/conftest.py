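import numpy as np
import pytest

from cranioflow.synthetic import (SubjectSpec, make_cohort, render_cine,
                                  young_defaults)


@pytest.fixture(scope="session")
def young_subject() -> SubjectSpec:
    return SubjectSpec(subject_id="YA00", age_group="YA", sex="F",
                       weight_g=375.0, heart_rate_bpm=189.0, gm_ul=4084.0,
                       wm_ul=2669.0, csf_ul=941.0, rng_seed=7)


@pytest.fixture(scope="session")
def young_params():
    return young_defaults()


@pytest.fixture(scope="session")
def noiseless_arterial(young_subject, young_params):
    """Noiseless arterial render of the young-default subject."""
    params = [young_params[v] for v in ("BT", "RC", "LC")]
    return render_cine(young_subject, params, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_venous(young_subject, young_params):
    params = [young_params[v] for v in ("SS", "StS")]
    return render_cine(young_subject, params, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_arterial(young_subject, young_params):
    params = [young_params[v] for v in ("BT", "RC", "LC")]
    rng = np.random.default_rng(42)
    return render_cine(young_subject, params, noise_sd=0.06, rng=rng)


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    return make_cohort(2, 2, seed=3, noise_sd=0.0, n_frames=16)
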