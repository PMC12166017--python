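import warnings

import numpy as np
import pytest

from alps_glymph import (
    CohortParams,
    PhantomSettings,
    build_phantom,
    derive_maps,
    fit_tensor,
    make_scheme,
    phantom_spec_for,
    sample_records,
)

# The generator warns when it resamples an infeasible diffusivity draw;
# routine in the heavy-tailed patient group and irrelevant to most tests.
warnings.filterwarnings("ignore", message="infeasible diffusivity draw")


@pytest.fixture(scope="session")
def scheme():
    """The study's acquisition: 64 directions at b=1000 plus one b=0."""
    return make_scheme(64, 1000.0, seed=7)


@pytest.fixture(scope="session")
def small_scheme():
    return make_scheme(12, 1000.0, seed=3)


@pytest.fixture(scope="session")
def cohort_records():
    return sample_records(CohortParams(seed=3))


@pytest.fixture(scope="session")
def patient_record(cohort_records):
    return cohort_records[0]


@pytest.fixture(scope="session")
def smoke_settings():
    return PhantomSettings(grid_n=32, snr=40.0)


@pytest.fixture(scope="session")
def noiseless_subject(patient_record, smoke_settings, scheme):
    """One patient's noiseless phantom, fitted end to end at smoke scale."""
    spec = phantom_spec_for(patient_record, smoke_settings)
    phantom = build_phantom(spec, scheme)
    field = fit_tensor(phantom.stack, scheme, mask=spec.icv_mask)
    maps = derive_maps(field)
    return spec, phantom, field, maps


def random_psd_tensor(rng: np.random.Generator) -> np.ndarray:
    """Random symmetric PSD tensor with eigenvalues in a diffusivity-like range."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    lam = rng.uniform(0.05, 3.0, 3)
    return q @ np.diag(lam) @ q.T
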