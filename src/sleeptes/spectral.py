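"""Slow-wave band spectral pipeline.

For each analysis window, artifact-free segments of at least 5 s are
selected, each segment is tapered with a Tukey window (α = 0.2), the tapered
segments are concatenated, and a Welch periodogram (Hanning window, 2.56-s
segments, 1.28-s overlap, one-sided density scaling) is computed on the
concatenated signal. Slow-wave band power is the mean of the PSD bins whose
frequency lies in [0.5, 1.0] Hz; regional power averages that quantity over
the channels of each scalp region; relative power is the percent increase
from the pre-stimulation to the post-stimulation window.

At the native 2.56-s resolution (0.390625 Hz bins) a single bin (0.78125 Hz)
falls in-band; ``WelchSpec.nfft_factor`` can zero-pad to densify the grid
but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .psg_io import PSGRecord, RegionMap
from .protocol import AnalysisWindows

__all__ = [
    "WelchSpec",
    "CleanSegmentSet",
    "mark_clean_segments",
    "taper_concatenate",
    "welch_band_power",
    "region_band_power",
    "relative_band_power",
    "band_power_spectrum",
]

MIN_SEGMENT_S = 5.0
DEFAULT_CLEAN_THRESHOLD_UV = 300.0


@dataclass
class WelchSpec:
    """Parameters of the slow-wave Welch analysis."""

    segment_s: float = 2.56
    overlap_s: float = 1.28
    band: tuple[float, float] = (0.5, 1.0)
    tukey_alpha: float = 0.2
    nfft_factor: int | None = None  # zero-pad factor for denser bins

    def __post_init__(self) -> None:
        if self.overlap_s >= self.segment_s:
            raise ValueError("overlap must be shorter than the segment")
        if self.band[0] < 0 or self.band[0] >= self.band[1]:
            raise ValueError("band must be an increasing non-negative pair")

    def nperseg(self, rate: float) -> int:
        return int(round(self.segment_s * rate))

    def noverlap(self, rate: float) -> int:
        return int(round(self.overlap_s * rate))

    def nfft(self, rate: float) -> int | None:
        if self.nfft_factor is None:
            return None
        return self.nfft_factor * self.nperseg(rate)


@dataclass
class CleanSegmentSet:
    """Disjoint, ordered artifact-free intervals, each at least 5 s long."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(tuple(map(float, iv)) for iv in self.intervals)
        for (s, e) in self.intervals:
            if e - s < MIN_SEGMENT_S - 1e-9:
                raise ValueError(f"segment ({s}, {e}) shorter than {MIN_SEGMENT_S} s")
        for (_, e1), (s2, _) in zip(self.intervals, self.intervals[1:]):
            if s2 < e1:
                raise ValueError("clean segments must be disjoint")

    @property
    def total_s(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def mark_clean_segments(record: PSGRecord, intervals, threshold_uv: float = DEFAULT_CLEAN_THRESHOLD_UV,
                        channels=None) -> CleanSegmentSet:
    """Automated surrogate for hand-marked clean-data selection.

    Within each analysis interval, finds the maximal sub-intervals where
    every analysis channel stays within ±threshold μV, and keeps those at
    least 5 s long. ``intervals`` is a list of (start_s, end_s); pass
    ``windows.immediate`` or ``[windows.pre_stim]`` from
    :func:`sleeptes.protocol.spectral_windows` (which already removes the
    20-s post-block artifact zones).

    An empty result is not an error — the study design drops subjects who
    lack clean post-stimulation data — callers should check ``total_s``.
    """
    if isinstance(intervals, AnalysisWindows):
        intervals = ([intervals.pre_stim] if intervals.pre_stim else []) + list(intervals.immediate)
    data = record.data if channels is None else np.vstack(
        [record.channel(c) for c in channels])
    clean = np.all(np.abs(data) <= threshold_uv, axis=0)
    rate = record.rate
    out: list[tuple[float, float]] = []
    min_len = int(round(MIN_SEGMENT_S * rate))
    for s, e in intervals:
        i0 = max(0, int(round(s * rate)))
        i1 = min(record.n_samples, int(round(e * rate)))
        if i1 - i0 < min_len:
            continue
        mask = clean[i0:i1]
        # run-length scan for True runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a >= min_len:
                out.append(((i0 + a) / rate, (i0 + b) / rate))
    return CleanSegmentSet(out)


def taper_concatenate(record: PSGRecord, segments: CleanSegmentSet,
                      spec: WelchSpec | None = None, channels=None) -> np.ndarray:
    """Taper each clean segment with a Tukey window and concatenate.

    Returns an (n_channels, total_samples) array in time order. Channel
    order follows ``channels`` if given, else the record's.
    """
    spec = spec or WelchSpec()
    data = record.data if channels is None else np.vstack(
        [record.channel(c) for c in channels])
    rate = record.rate
    pieces = []
    for s, e in segments.intervals:
        i0, i1 = int(round(s * rate)), int(round(e * rate))
        w = sig.windows.tukey(i1 - i0, alpha=spec.tukey_alpha)
        pieces.append(data[:, i0:i1] * w[None, :])
    if not pieces:
        return np.empty((data.shape[0], 0))
    return np.concatenate(pieces, axis=1)


def _welch(x: np.ndarray, rate: float, spec: WelchSpec):
    nperseg = spec.nperseg(rate)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is shorter than one Welch "
            f"segment ({nperseg} samples)"
        )
    return sig.welch(
        x, fs=rate, window="hann", nperseg=nperseg,
        noverlap=spec.noverlap(rate), nfft=spec.nfft(rate),
        detrend=False, scaling="density", axis=-1,
    )


def welch_band_power(x: np.ndarray, rate: float, spec: WelchSpec | None = None) -> float:
    """Mean one-sided PSD (μV²/Hz) over bins with band[0] ≤ f ≤ band[1]."""
    spec = spec or WelchSpec()
    f, pxx = _welch(np.asarray(x, dtype=float), rate, spec)
    lo, hi = spec.band
    inband = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    if not inband.any():
        raise ValueError(f"no frequency bin falls in the {spec.band} Hz band")
    return float(np.mean(pxx[..., inband], axis=-1).mean())


def band_power_spectrum(x: np.ndarray, rate: float, spec: WelchSpec | None = None):
    """Full Welch spectrum (f, PSD) for percent-change-by-frequency plots."""
    spec = spec or WelchSpec()
    return _welch(np.asarray(x, dtype=float), rate, spec)


def region_band_power(record: PSGRecord, region_map: RegionMap,
                      segments: CleanSegmentSet, spec: WelchSpec | None = None
                      ) -> dict[str, float]:
    """Per-region slow-wave band power: channel band powers averaged."""
    spec = spec or WelchSpec()
    out: dict[str, float] = {}
    for region, chans in region_map.items():
        for ch in chans:
            if ch not in record.channel_names:
                raise KeyError(f"region {region!r}: channel {ch!r} missing")
        concat = taper_concatenate(record, segments, spec, channels=chans)
        powers = [welch_band_power(concat[i], record.rate, spec)
                  for i in range(concat.shape[0])]
        out[region] = float(np.mean(powers))
    return out


def relative_band_power(pre: dict[str, float], post: dict[str, float]) -> dict[str, float]:
    """Percent increase in band power from pre- to post-stimulation."""
    if set(pre) != set(post):
        raise ValueError("pre and post region sets differ")
    out = {}
    for region, p in pre.items():
        if p <= 0:
            raise ValueError(f"non-positive pre-stimulation power in {region!r}")
        out[region] = (post[region] - p) / p * 100.0
    return out
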