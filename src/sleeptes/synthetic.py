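"""Synthetic overnight polysomnography with a configurable N3 effect.

Stage dynamics are a first-order Markov chain over the five AASM stages at
30-s epoch resolution. Each stage writes a characteristic spectral
signature into the EEG: wake carries alpha (8–12 Hz) and high muscle tone,
N1 low-amplitude theta, N2 sleep-spindle-band activity (11–16 Hz), N3 large
slow oscillations (0.5–1 Hz, peak amplitude above the 75 μV scoring
criterion), and REM low-amplitude mixed frequencies with slow eye-movement
deflections on the EOG channels and minimal EMG. A stimulation schedule can
overwrite the stimulated intervals with the 0.5 Hz stimulation artifact,
and a multiplicative boost on transitions into N3 after stimulation onset
emulates a within-night N3-enhancement effect.

None of this is a biophysical model; it reproduces the statistical
structure (stage-dependent band power, realistic hypnogram, artifact
blocks, paired effect) that the analysis pipeline assumes, so that every
downstream stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypnogram import EPOCH_S, STAGES, Hypnogram, stage_code
from .psg_io import PSGRecord
from .protocol import StimSchedule

__all__ = [
    "OscComponent",
    "HypnogramModel",
    "StageSignalModel",
    "simulate_hypnogram",
    "synthesize_epoch",
    "simulate_recording",
    "inject_tes_artifact",
    "DEFAULT_MONTAGE",
    "channel_roles",
    "DEFAULT_ARTIFACT_UV",
]

#: Staging electrodes + EMG + ten region-representative scalp channels.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "C3", "C4", "M1", "M2", "EOGL", "EOGR", "EMG",
    "F7", "F8", "Fpz", "Fz", "T5", "T6", "Pz", "O1", "O2", "Oz",
)

#: Peak amplitude (μV) of the injected 0.5 Hz stimulation artifact.
DEFAULT_ARTIFACT_UV = 5000.0

SW_BAND = (0.5, 1.0)


def channel_roles(montage) -> list[str]:
    """Infer each channel's role (eeg/eog/emg/ref) from its name."""
    roles = []
    for name in montage:
        u = name.upper()
        if u.startswith("EOG"):
            roles.append("eog")
        elif u.startswith("EMG"):
            roles.append("emg")
        elif u in ("M1", "M2", "A1", "A2"):
            roles.append("ref")
        else:
            roles.append("eeg")
    return roles


@dataclass(frozen=True)
class OscComponent:
    """A narrowband oscillation: frequency drawn uniformly in [f_lo, f_hi]."""

    f_lo: float
    f_hi: float
    rms: float  # μV

    def overlaps(self, band) -> bool:
        return self.f_lo <= band[1] and self.f_hi >= band[0]


# ---------------------------------------------------------------------------
# Hypnogram model


def _default_transition_matrix() -> np.ndarray:
    # rows/cols in STAGES order (W, N1, N2, N3, REM); self-transition ~0.9,
    # structure chosen to give a plausible stationary mix of stages
    # stationary mix ~ (W 9%, N1 9%, N2 46%, N3 15%, REM 21%): a healthy
    # adult night with N3 near the observed ~13-15% of sleep time. N3 bouts
    # are kept short (mean ~2 min) so that total N3 occupancy mixes fast and
    # night-to-night variance stays in a realistic range for paired designs.
    return np.array(
        [
            #  W     N1     N2     N3    REM
            [0.850, 0.120, 0.030, 0.000, 0.000],  # W
            [0.050, 0.700, 0.230, 0.000, 0.020],  # N1
            [0.010, 0.020, 0.845, 0.085, 0.040],  # N2
            [0.005, 0.005, 0.240, 0.740, 0.010],  # N3
            [0.020, 0.025, 0.055, 0.000, 0.900],  # REM
        ]
    )


@dataclass
class HypnogramModel:
    """First-order Markov stage dynamics with an optional N3 boost.

    ``n3_boost`` multiplies every transition probability into N3 (rows are
    then renormalized) for epochs at or after ``boost_onset_epoch``; 1.0
    means no effect. This is how a stimulation-induced N3 enhancement is
    injected.
    """

    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    initial_stage: str = "W"
    n3_boost: float = 1.0
    boost_onset_epoch: int | None = None
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if (P < 0).any() or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each transition row must be stochastic (sum to 1)")
        if self.n3_boost < 0:
            raise ValueError("n3_boost must be non-negative")
        self.transition_matrix = P

    def boosted_matrix(self) -> np.ndarray:
        """The transition matrix with the N3 boost applied and renormalized."""
        P = self.transition_matrix.copy()
        if self.n3_boost == 1.0:
            return P
        n3 = stage_code("N3")
        P[:, n3] *= self.n3_boost
        return P / P.sum(axis=1, keepdims=True)

    def stationary_distribution(self, boosted: bool = False) -> np.ndarray:
        """Stationary stage distribution by eigen-decomposition."""
        P = self.boosted_matrix() if boosted else self.transition_matrix
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def simulate_hypnogram(model: HypnogramModel, n_epochs: int, seed) -> Hypnogram:
    """Draw an overnight hypnogram from the stage Markov chain.

    Deterministic under identical (model, seed). Epochs at or after
    ``model.boost_onset_epoch`` use the boosted transition matrix.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    rng = np.random.default_rng(seed)
    base = model.transition_matrix
    boosted = model.boosted_matrix()
    onset = model.boost_onset_epoch
    labels = np.empty(n_epochs, dtype=np.int64)
    state = stage_code(model.initial_stage)
    labels[0] = state
    u = rng.random(n_epochs)
    for k in range(1, n_epochs):
        P = boosted if (onset is not None and k >= onset) else base
        state = int(np.searchsorted(np.cumsum(P[state]), u[k], side="right"))
        state = min(state, 4)
        labels[k] = state
    return Hypnogram(labels, epoch_s=model.epoch_s)


# ---------------------------------------------------------------------------
# Signal model


def _default_components() -> dict[str, list[OscComponent]]:
    return {
        "W": [OscComponent(8.0, 12.0, 18.0)],
        "N1": [OscComponent(4.0, 7.0, 12.0)],
        "N2": [OscComponent(11.0, 16.0, 14.0), OscComponent(0.5, 1.0, 6.0)],
        "N3": [OscComponent(0.5, 1.0, 60.0), OscComponent(1.0, 4.0, 20.0)],
        "REM": [OscComponent(4.0, 8.0, 10.0)],
    }


@dataclass
class StageSignalModel:
    """Per-stage oscillatory content of the synthetic EEG.

    components : per-stage narrowband oscillations written to every EEG and
        EOG channel (independent frequency/phase per channel).
    noise_rms : per-stage broadband (white) noise amplitude, μV.
    emg_rms : per-stage EMG-channel noise amplitude (muscle tone), μV.
    eog_components : extra oscillations on EOG channels only (slow eye
        movements during REM).
    """

    components: dict[str, list[OscComponent]] = field(default_factory=_default_components)
    noise_rms: dict[str, float] = field(
        default_factory=lambda: {"W": 10.0, "N1": 10.0, "N2": 10.0, "N3": 10.0, "REM": 8.0}
    )
    emg_rms: dict[str, float] = field(
        default_factory=lambda: {"W": 30.0, "N1": 12.0, "N2": 8.0, "N3": 5.0, "REM": 2.0}
    )
    eog_components: dict[str, list[OscComponent]] = field(
        default_factory=lambda: {"REM": [OscComponent(0.2, 0.45, 40.0)]}
    )
    ref_noise_rms: float = 5.0
    #: disable the realism checks below (for deliberately degenerate models)
    validate: bool = True

    def __post_init__(self) -> None:
        for stage in STAGES:
            if stage not in self.components or stage not in self.noise_rms \
                    or stage not in self.emg_rms:
                raise ValueError(f"signal model missing parameters for stage {stage!r}")
        if not self.validate:
            return
        sw = {s: self.sw_band_rms(s) for s in STAGES}
        if any(sw["N3"] <= sw[s] for s in STAGES if s != "N3"):
            raise ValueError(
                "N3 must have the largest slow-wave (0.5-1 Hz) component RMS"
            )
        so = max((c.rms for c in self.components["N3"] if c.overlaps(SW_BAND)),
                 default=0.0)
        if so * np.sqrt(2.0) <= 75.0:
            raise ValueError(
                "N3 slow-oscillation peak amplitude must exceed 75 uV"
            )

    def sw_band_rms(self, stage: str) -> float:
        """RMS of the stage's oscillatory content inside 0.5–1 Hz."""
        rmss = [c.rms for c in self.components[stage] if c.overlaps(SW_BAND)]
        return float(np.sqrt(np.sum(np.square(rmss)))) if rmss else 0.0


def synthesize_epoch(stage: str, signal_model: StageSignalModel, n_channels: int,
                     rate: float, seed, roles=None) -> np.ndarray:
    """One 30-s multi-channel signal block (μV) for the given stage.

    ``roles`` assigns each channel 'eeg', 'eog', 'emg' or 'ref'; default all
    'eeg'. Deterministic under a fixed seed.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown sleep stage {stage!r}")
    if rate < 64:
        raise ValueError("sampling rate must be at least 64 Hz")
    roles = list(roles) if roles is not None else ["eeg"] * n_channels
    if len(roles) != n_channels:
        raise ValueError("roles must have one entry per channel")
    rng = np.random.default_rng(seed)
    n = int(round(EPOCH_S * rate))
    t = np.arange(n) / rate
    block = np.empty((n_channels, n), dtype=np.float64)
    comps = signal_model.components[stage]
    eog_extra = signal_model.eog_components.get(stage, [])
    for i, role in enumerate(roles):
        if role == "emg":
            block[i] = rng.normal(0.0, signal_model.emg_rms[stage], n)
            continue
        if role == "ref":
            block[i] = rng.normal(0.0, signal_model.ref_noise_rms, n)
            continue
        x = rng.normal(0.0, signal_model.noise_rms[stage], n)
        use = comps + (eog_extra if role == "eog" else [])
        for c in use:
            f = rng.uniform(c.f_lo, c.f_hi)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            x += (c.rms * np.sqrt(2.0)) * np.sin(2.0 * np.pi * f * t + phi)
        block[i] = x
    return block


def simulate_recording(hypnogram: Hypnogram, signal_model: StageSignalModel,
                       montage=DEFAULT_MONTAGE, rate: float = 64.0,
                       schedule: StimSchedule | None = None, seed=0,
                       artifact_uv: float = DEFAULT_ARTIFACT_UV) -> PSGRecord:
    """Epoch-wise concatenation of stage blocks, plus stimulation artifact.

    If a schedule with condition='stim' is given, the stimulated intervals
    are overwritten by :func:`inject_tes_artifact`. Sham schedules leave
    the signal untouched (placeholders carry no current).
    """
    montage = list(montage)
    roles = channel_roles(montage)
    n_epochs = hypnogram.n_epochs
    n_per = int(round(hypnogram.epoch_s * rate))
    data = np.empty((len(montage), n_epochs * n_per), dtype=np.float64)
    children = np.random.SeedSequence(seed).spawn(n_epochs)
    for k in range(n_epochs):
        stage = STAGES[hypnogram.labels[k]]
        data[:, k * n_per:(k + 1) * n_per] = synthesize_epoch(
            stage, signal_model, len(montage), rate, children[k], roles)
    record = PSGRecord(data=data, rate=rate, channel_names=montage)
    if schedule is not None:
        if schedule.block_intervals()[-1][1] > record.duration_s + 1e-9:
            raise ValueError("stimulation schedule extends past the recording end")
        if schedule.condition == "stim":
            record = inject_tes_artifact(record, schedule, artifact_uv)
    return record


def inject_tes_artifact(record: PSGRecord, schedule: StimSchedule,
                        artifact_uv: float = DEFAULT_ARTIFACT_UV) -> PSGRecord:
    """Add a 0.5 Hz sine of the given peak amplitude inside each block.

    The artifact rides on every channel, mirroring how the stimulation
    current saturates the whole montage; amplitude defaults to dominate the
    EEG by well over an order of magnitude.
    """
    if schedule.condition != "stim":
        raise ValueError("artifacts are only injected for condition='stim'")
    blocks = schedule.block_intervals()
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("overlapping stimulation blocks")
    data = record.data.copy()
    rate = record.rate
    for s, e in blocks:
        i0, i1 = int(round(s * rate)), int(round(e * rate))
        if i1 > record.n_samples:
            raise ValueError("stimulation block extends past the recording end")
        t = np.arange(i0, i1) / rate
        data[:, i0:i1] += artifact_uv * np.sin(2.0 * np.pi * 0.5 * t)
    return PSGRecord(data=data, rate=rate, channel_names=list(record.channel_names),
                     start_time=record.start_time, annotations=list(record.annotations))
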