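import numpy as np
import pytest

from sleeptes import HypnogramModel, StageSignalModel, simulate_hypnogram, simulate_recording
from sleeptes.hypnogram import STAGES
from sleeptes.stager import StagerInput
from sleeptes.synthetic import synthesize_epoch

STAGING_MONTAGE = ("C3", "C4", "M1", "M2", "EOGL", "EOGR", "EMG")
STAGING_ROLES = ("eeg", "eeg", "ref", "ref", "eog", "eog", "emg")


@pytest.fixture(scope="session")
def signal_model():
    return StageSignalModel()


@pytest.fixture(scope="session")
def hyp_model():
    return HypnogramModel()


def derive_block(raw7: np.ndarray) -> np.ndarray:
    """Montage block (7, n) -> staging block (5, n): the four bipolar
    derivations plus the auxiliary EMG, in classifier channel order."""
    c3, c4, m1, m2, eogl, eogr, emg = raw7
    return np.stack([c3 - m2, c4 - m1, eogl - m2, eogr - m1, emg])


def make_staging_blocks(signal_model, n_per_stage, seed0, stages=STAGES) -> StagerInput:
    """Balanced labelled staging blocks drawn straight from the generator."""
    X, y = [], []
    for code, stage in enumerate(STAGES):
        if stage not in stages:
            continue
        for k in range(n_per_stage):
            raw = synthesize_epoch(stage, signal_model, 7, 64.0,
                                   [seed0, code, k], STAGING_ROLES)
            X.append(derive_block(raw))
            y.append(code)
    return StagerInput(np.array(X, np.float32), np.array(y))


@pytest.fixture(scope="session")
def short_recording(signal_model, hyp_model):
    """A 10-minute recording with its reference hypnogram."""
    hyp = simulate_hypnogram(hyp_model, 20, seed=5)
    rec = simulate_recording(hyp, signal_model, montage=STAGING_MONTAGE,
                             rate=64.0, seed=5)
    return rec, hyp
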