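import numpy as np
import pytest

from beamtune import BeamModelParams, SyntheticTruth


@pytest.fixture
def ideal_truth() -> SyntheticTruth:
    """Noise-free truth with no detector blur: every estimator should be exact."""
    return SyntheticTruth(
        params=BeamModelParams(
            sigma_x=0.7, sigma_y=0.35, dlg=0.55, transmission=0.0126
        ),
        tg_loss_measured=0.0,
        tg_loss_calculated=0.0,
        detector_sigma=0.0,
        noise_cv=0.0,
        seed=0,
    )


@pytest.fixture
def tg_mismatch_truth(ideal_truth) -> SyntheticTruth:
    """The TPS stand-in overestimates tongue-and-groove losses."""
    return ideal_truth.with_(tg_loss_measured=0.02, tg_loss_calculated=0.12)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
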