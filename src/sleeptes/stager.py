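"""Automatic sleep staging.

Two stagers share one input contract: 30-s blocks of the five staging
channels (C3-M2, C4-M1, EOGL-M2, EOGR-M1, EMG) downsampled to 64 Hz.

* a convolutional network (strided 1-D conv stack, dense layer, five-way
  softmax; the most probable stage is the score for each block), trained
  with best-validation-accuracy checkpointing, and
* a deterministic rule-based stager (a band-power decision tree) so that
  pipeline tests do not depend on training.

Agreement with reference scoring is summarized by the confusion matrix,
accuracy, macro F1 and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sig

from .cnn import ConvNet, ConvNetSpec
from .hypnogram import STAGES, Hypnogram, stage_code
from .psg_io import PSGRecord, STAGING_DERIVATIONS, apply_derivations
from .spectral import WelchSpec, welch_band_power

__all__ = [
    "STAGER_RATE",
    "StagerInput",
    "StagerConfig",
    "StagingMetrics",
    "preprocess",
    "train",
    "predict_stages",
    "evaluate",
    "rule_based_stager",
    "RuleThresholds",
]

STAGER_RATE = 64.0
BLOCK_SAMPLES = int(30 * STAGER_RATE)  # 1920
N_STAGING_CHANNELS = 5


@dataclass
class StagerInput:
    """Stacked staging blocks: (n_epochs, 5, 1920) float32, μV, 64 Hz."""

    blocks: np.ndarray
    labels: np.ndarray | None = None  # optional integer stage codes

    def __post_init__(self) -> None:
        self.blocks = np.ascontiguousarray(self.blocks, dtype=np.float32)
        if self.blocks.ndim != 3 or self.blocks.shape[1] != N_STAGING_CHANNELS \
                or self.blocks.shape[2] != BLOCK_SAMPLES:
            raise ValueError(
                f"staging input must be (n, {N_STAGING_CHANNELS}, "
                f"{BLOCK_SAMPLES}); got {self.blocks.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.blocks.shape[0],):
                raise ValueError("one label per block required")

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]


@dataclass
class StagerConfig:
    """Network and training hyperparameters.

    The defaults reproduce the full architecture scale (10 conv layers, 384
    filters each, dense layer, five-way softmax); the reduced presets are
    what the synthetic-data experiments use.
    """

    n_conv_layers: int = 10
    filters: int = 384
    kernel_size: int = 7
    stride: int = 2
    dense_units: int = 128
    n_classes: int = 5
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 20
    seed: int = 0
    input_scale: float = 50.0  # μV scale dividing the raw blocks

    def __post_init__(self) -> None:
        if self.n_classes != 5:
            raise ValueError("the stager is a five-stage classifier")

    @classmethod
    def reduced(cls, **kw) -> "StagerConfig":
        """Desk-scale configuration: 4 conv layers, 32 filters."""
        return cls(**{"n_conv_layers": 4, "filters": 32, "dense_units": 64, **kw})

    @classmethod
    def tiny(cls, **kw) -> "StagerConfig":
        """Minimal configuration for two-class toy problems."""
        return cls(**{"n_conv_layers": 2, "filters": 16, "dense_units": 32, **kw})

    def build(self) -> ConvNet:
        spec = ConvNetSpec(
            in_channels=N_STAGING_CHANNELS, n_classes=self.n_classes,
            n_conv_layers=self.n_conv_layers, filters=self.filters,
            kernel_size=self.kernel_size, stride=self.stride,
            dense_units=self.dense_units, input_scale=self.input_scale,
        )
        return ConvNet(spec, seed=self.seed)


@dataclass
class StagingMetrics:
    """Agreement between predicted and reference staging."""

    confusion: np.ndarray  # 5x5 counts, true x predicted
    accuracy: float
    macro_f1: float
    kappa: float


def preprocess(record: PSGRecord, derivations=STAGING_DERIVATIONS) -> StagerInput:
    """Derive staging channels, resample to 64 Hz, cut into 30-s blocks.

    Resampling uses a polyphase anti-aliased filter; a trailing partial
    epoch is dropped.
    """
    if record.rate < STAGER_RATE:
        raise ValueError("record must be sampled at >= 64 Hz")
    derived = apply_derivations(record, derivations)
    if abs(record.rate - STAGER_RATE) < 1e-9:
        data = derived.data
    else:
        frac = Fraction(int(round(STAGER_RATE * 1000)),
                        int(round(record.rate * 1000)))
        data = sig.resample_poly(derived.data, frac.numerator,
                                 frac.denominator, axis=1)
    n_blocks = data.shape[1] // BLOCK_SAMPLES
    data = data[:, : n_blocks * BLOCK_SAMPLES]
    blocks = data.reshape(data.shape[0], n_blocks, BLOCK_SAMPLES).transpose(1, 0, 2)
    return StagerInput(blocks)


def train(config: StagerConfig, train_set: StagerInput, validation_set: StagerInput):
    """Fit the network; return (model, history) at the best checkpoint.

    After every training epoch the validation accuracy is evaluated and the
    most accurate model is kept; the returned model is that checkpoint.
    """
    if train_set.labels is None or validation_set.labels is None:
        raise ValueError("train() needs labeled StagerInput sets")
    model = config.build()
    history = model.fit(
        train_set.blocks, train_set.labels,
        validation_set.blocks, validation_set.labels,
        lr=config.lr, batch_size=config.batch_size,
        max_epochs=config.max_epochs, seed=config.seed,
    )
    return model, history


def predict_stages(model: ConvNet, stager_input: StagerInput) -> Hypnogram:
    """One label per block: the argmax of the softmax output."""
    labels = model.predict(stager_input.blocks)
    return Hypnogram(labels)


def evaluate(predicted: Hypnogram, truth: Hypnogram) -> StagingMetrics:
    """Confusion matrix, accuracy, macro F1 and Cohen's kappa.

    Epochs excluded in either hypnogram are removed from both before
    counting.
    """
    if predicted.n_epochs != truth.n_epochs:
        raise ValueError("predicted and reference hypnograms differ in length")
    keep = ~(predicted.excluded | truth.excluded)
    t = truth.labels[keep]
    p = predicted.labels[keep]
    k = len(STAGES)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (t, p), 1)
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)
    f1s = []
    for c in range(k):
        tp = confusion[c, c]
        denom = confusion[c, :].sum() + confusion[:, c].sum()
        f1s.append(0.0 if denom == 0 else 2.0 * tp / denom)
    po = accuracy
    pe = float((confusion.sum(axis=0) * confusion.sum(axis=1)).sum() / total ** 2)
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return StagingMetrics(confusion=confusion, accuracy=accuracy,
                          macro_f1=float(np.mean(f1s)), kappa=float(kappa))


# ---------------------------------------------------------------------------
# Rule-based stager


@dataclass
class RuleThresholds:
    """Band-power decision thresholds of the rule-based stager (μV²/Hz, μV).

    Calibrated once against the default synthetic signal model; they are
    deliberately coarse (each stage's signature differs by an order of
    magnitude on its discriminating feature).
    """

    sw_power: float = 400.0         # 0.5-1 Hz density marking N3
    spindle_power: float = 10.0     # 11-16 Hz density marking N2
    alpha_power: float = 15.0       # 8-12 Hz density marking W
    emg_wake_rms: float = 20.0      # muscle tone marking W
    emg_rem_rms: float = 5.0        # atonia marking REM
    eog_slow_power: float = 200.0   # 0.15-0.5 Hz EOG density marking REM
    silence_rms: float = 0.5        # below this the block is "no signal"
    default_stage: str = "W"        # label for silent blocks


_BANDS = {
    "sw": (0.5, 1.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "spindle": (11.0, 16.0),
    "eog_slow": (0.15, 0.5),
}


def _block_features(blocks: np.ndarray, rate: float = STAGER_RATE) -> dict[str, np.ndarray]:
    """Band-power features for a (n, 5, 1920) stack, one value per block."""
    blocks = blocks.astype(np.float64, copy=False)
    eeg = blocks[:, :2].mean(axis=1)
    eog = blocks[:, 2:4].mean(axis=1)
    spec = WelchSpec()
    nperseg = spec.nperseg(rate)
    f, pxx_eeg = sig.welch(eeg, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=spec.noverlap(rate), detrend=False,
                           scaling="density", axis=-1)
    _, pxx_eog = sig.welch(eog, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=spec.noverlap(rate), detrend=False,
                           scaling="density", axis=-1)
    feats: dict[str, np.ndarray] = {}
    for name, (lo, hi) in _BANDS.items():
        pxx = pxx_eog if name == "eog_slow" else pxx_eeg
        inband = (f >= lo - 1e-12) & (f <= hi + 1e-12)
        feats[name] = pxx[:, inband].mean(axis=1)
    feats["emg_rms"] = blocks[:, 4].std(axis=1)
    feats["rms"] = blocks[:, :2].reshape(blocks.shape[0], -1).std(axis=1)
    return feats


def rule_based_stager(stager_input: StagerInput,
                      thresholds: RuleThresholds | None = None) -> Hypnogram:
    """Deterministic band-power decision tree over the staging blocks.

    Order of tests: silence → N3 (slow-wave power) → W (muscle tone plus
    alpha) → N2 (spindle power) → REM (ocular slow activity with atonia) →
    N1 otherwise. Identical input always yields identical output.
    """
    th = thresholds or RuleThresholds()
    f = _block_features(stager_input.blocks)
    labels = np.full(stager_input.n_blocks, stage_code("N1"), dtype=np.int64)
    rem = (f["eog_slow"] > th.eog_slow_power) & (f["emg_rms"] < th.emg_rem_rms)
    labels[rem] = stage_code("REM")
    n2 = f["spindle"] > th.spindle_power
    labels[n2] = stage_code("N2")
    wake = (f["emg_rms"] > th.emg_wake_rms) & (f["alpha"] > th.alpha_power)
    labels[wake] = stage_code("W")
    n3 = f["sw"] > th.sw_power
    labels[n3] = stage_code("N3")
    silent = f["rms"] < th.silence_rms
    labels[silent] = stage_code(th.default_stage)
    return Hypnogram(labels)
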