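import numpy as np
import pytest

from organotrack.synth import generate_cohort_sequence


@pytest.fixture(scope="session")
def noisy_growth_phantom():
    """Shared small growth phantom: 8 frames, 10%/frame, 5-branch cohort."""
    return generate_cohort_sequence(8, growth_per_frame=0.1, n_branches=5,
                                    noise_sigma=5.0, seed=7, shape=(256, 256),
                                    base_radius=25)


@pytest.fixture(scope="session")
def segmented_growth_phantom(noisy_growth_phantom):
    from organotrack.fibro import segment_sequence

    seq, truth = noisy_growth_phantom
    return seq, truth, segment_sequence(seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
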