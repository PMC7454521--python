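import numpy as np
import pytest

from allokit.synthetic import (
    DEFAULT_UREA_GRID,
    DEFAULT_WAVELENGTHS,
    GroundTruth,
)


@pytest.fixture
def wt_truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture
def melt_noise_sd(wt_truth) -> float:
    """2% of the noiseless signal range, the study's melt noise level."""
    span = np.ptp(
        np.concatenate(
            [
                wt_truth.melt_signal(np.asarray(DEFAULT_UREA_GRID), wl)
                for wl in DEFAULT_WAVELENGTHS
            ]
        )
    )
    return 0.02 * float(span)
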