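import numpy as np
import pytest

from dcekin import AcquisitionConstants, AIFParams, ExperimentDesign


@pytest.fixture
def consts():
    return AcquisitionConstants()


@pytest.fixture
def aif_truth():
    """Generator default arterial truth (mM, min^-1)."""
    return AIFParams(A1=0.2, A2=0.1, m1=0.05, m2=0.4)


@pytest.fixture
def frame_times():
    """40-frame grid, 97 s per frame, 2 pre-contrast frames (minutes)."""
    return ExperimentDesign().times_min


@pytest.fixture
def post_times(frame_times):
    return frame_times[frame_times >= 0]


def pad_precontrast(times, post_values, n_pre=2):
    """Prepend exact-zero pre-contrast values on the full frame grid."""
    values = np.zeros_like(times)
    values[n_pre:] = post_values
    return values
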