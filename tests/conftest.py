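import numpy as np
import pytest

from neurovasc.synthetic import SubjectTruth


@pytest.fixture
def example_truth() -> SubjectTruth:
    """A physiologically typical subject used across modality tests."""
    return SubjectTruth(
        true_dcbf_visact=77.1,
        true_dbold_visact=2.0,
        true_dcbf_bh=29.2,
        true_dcmro2_bh=5.1,
        true_gcbf=50.0,
        true_svo2=0.62,
        hgb=9.3,
        sao2=0.975,
        brain_volume=1150.0,
        lactate_rest=0.723,
        lactate_stim=0.783,
        naa=10.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
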