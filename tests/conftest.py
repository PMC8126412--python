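import dataclasses

import pytest

from ribcage import DLP_LIKE, LINC_LIKE, WILDTYPE, EmbryoSpec, GenotypePreset


def zero_noise(preset: GenotypePreset) -> GenotypePreset:
    """Remove all stochasticity so every draw equals its mean."""
    return dataclasses.replace(
        preset,
        ap_spacing_sd=0.0,
        lateral_jitter_sd=0.0,
        migration_step_sd=0.0,
        nuclei_count_sd=0.0,
        nuclei_count_mean=20.0,
    )


@pytest.fixture
def wt_zero_noise_spec() -> EmbryoSpec:
    return EmbryoSpec(preset=zero_noise(WILDTYPE), seed=1)


@pytest.fixture
def dlp_zero_noise_spec() -> EmbryoSpec:
    return EmbryoSpec(preset=zero_noise(DLP_LIKE), seed=1)


@pytest.fixture
def linc_zero_noise_spec() -> EmbryoSpec:
    return EmbryoSpec(preset=zero_noise(LINC_LIKE), seed=1)


@pytest.fixture
def wt_spec() -> EmbryoSpec:
    return EmbryoSpec(preset=WILDTYPE, seed=1)
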