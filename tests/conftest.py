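import dataclasses

import pytest

from iolcalib import GeneratorParams, convert_a_constant, generate_cohort


@pytest.fixture(scope="session")
def ulib_constants():
    """Catalog A-constant with tied conversions, as the un-optimized baseline."""
    return convert_a_constant(119.30)


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    """The default synthetic cohort: 201 patients, fixed seed."""
    return generate_cohort(default_params)


@pytest.fixture(scope="session")
def noisefree_params(default_params):
    """Deterministic cohort: no measurement or refraction noise, no bias."""
    return dataclasses.replace(
        default_params,
        paired_noise_sd=0.0,
        fellow_noise_sd=0.0,
        km_noise_sd_operated=0.0,
        km_noise_sd_fellow=0.0,
        refraction_noise_sd=0.0,
        constant_bias_d=0.0,
        stable_refraction_fraction=1.0,
    )


@pytest.fixture(scope="session")
def noisefree_cohort(noisefree_params):
    return generate_cohort(noisefree_params)
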