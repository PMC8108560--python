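"""Stimulation-night timing rules and the exclusion windows they imply.

The stimulation protocol delivers five 5-minute blocks of 0.5 Hz current
separated by 1-minute rests, triggered once the sleeper shows four minutes
(eight 30-s epochs) of stable N2. If the sleeper shows signs of waking the
protocol is paused and the remaining protocol time resumes later, shifting
every subsequent interval by the pause duration. Sham nights carry the same
interval geometry as placeholders, so that exactly the same epochs are
excluded in both conditions.

All intervals are half-open ``[start, end)`` seconds from recording start;
epoch ``k`` covers ``[30k, 30(k+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypnogram import EPOCH_S, Hypnogram, stage_code

__all__ = [
    "StimSchedule",
    "AnalysisWindows",
    "BLOCK_S",
    "REST_S",
    "N_BLOCKS",
    "POST_FINAL_S",
    "POST_BLOCK_EXCLUDE_S",
    "detect_stable_n2",
    "build_schedule",
    "stimulation_epoch_mask",
    "immediate_window",
    "spectral_windows",
    "epochs_overlapping",
    "epochs_within",
]

BLOCK_S = 300.0          # each stimulation block: 5 min
REST_S = 60.0            # rest between blocks: 1 min
N_BLOCKS = 5
POST_FINAL_S = 300.0     # immediate window extends 5 min past the last block
POST_BLOCK_EXCLUDE_S = 20.0  # artifact settle time dropped after each block
STABLE_N2_EPOCHS = 8     # "stable N2 for 4 min" = eight 30-s epochs


@dataclass
class StimSchedule:
    """Block/rest/pause intervals for one stimulation (or sham) night.

    ``blocks`` holds one entry per protocol block; a block split by a pause
    is a list of sub-intervals whose durations sum to 300 s.
    """

    condition: str
    blocks: list
    rests: list[tuple[float, float]]
    pauses: list[tuple[float, float]] = field(default_factory=list)
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in ("stim", "sham"):
            raise ValueError("condition must be 'stim' or 'sham'")
        # normalize: each block is a list of (start, end) sub-intervals
        norm = []
        for b in self.blocks:
            if b and isinstance(b[0], (int, float)):
                norm.append([tuple(b)])
            else:
                norm.append([tuple(iv) for iv in b])
        self.blocks = norm
        flat = self.block_intervals()
        for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
            if s2 < e1:
                raise ValueError("stimulation blocks must be disjoint and ordered")

    def block_intervals(self) -> list[tuple[float, float]]:
        """All stimulated sub-intervals, flattened and in time order."""
        return sorted(iv for b in self.blocks for iv in b)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def stimulated_s(self) -> float:
        return sum(e - s for s, e in self.block_intervals())

    @property
    def end_s(self) -> float:
        return self.block_intervals()[-1][1]

    @property
    def is_complete(self) -> bool:
        return self.n_blocks == N_BLOCKS

    def as_sham(self) -> "StimSchedule":
        """The identical interval geometry flagged as a sham placeholder."""
        return StimSchedule(
            condition="sham",
            blocks=[list(b) for b in self.blocks],
            rests=list(self.rests),
            pauses=list(self.pauses),
            onset_s=self.onset_s,
        )


@dataclass
class AnalysisWindows:
    """Analysis windows derived from a schedule.

    pre_stim : the 300-s interval ending at the first block start (spectral
        analysis only; None for the immediate-window variant)
    immediate : included intervals — the rests plus the 300 s after the
        final block (trimmed for spectral use)
    excluded_intervals : intervals dropped by the pause rule
    """

    pre_stim: tuple[float, float] | None
    immediate: list[tuple[float, float]]
    excluded_intervals: list[tuple[float, float]] = field(default_factory=list)

    def total_immediate_s(self) -> float:
        return sum(e - s for s, e in self.immediate)


def detect_stable_n2(hypnogram: Hypnogram) -> int | None:
    """First epoch index immediately after 8 consecutive N2 epochs.

    Returns None if the hypnogram never shows a 4-minute stable N2 run.
    """
    n2 = stage_code("N2")
    run = 0
    for k, lab in enumerate(hypnogram.labels):
        run = run + 1 if lab == n2 else 0
        if run == STABLE_N2_EPOCHS:
            return k + 1
    return None


def build_schedule(onset_s: float, condition: str = "stim", pauses=()) -> StimSchedule:
    """Construct the five-block schedule starting at ``onset_s``.

    ``pauses`` is a list of (pause_start_s, resume_s) in real recording time.
    A pause freezes the protocol clock: the un-delivered remainder of the
    interval the pause lands in resumes at ``resume_s`` and every later
    interval shifts by the pause duration, so total stimulated time is
    conserved (1500 s for a complete protocol).
    """
    if onset_s < 0:
        raise ValueError("onset must be non-negative")
    pauses = sorted((float(p), float(r)) for p, r in pauses)
    for p, r in pauses:
        if r <= p:
            raise ValueError("pause resume time must follow its start")

    # nominal protocol segments in protocol-relative time
    segments = []
    for i in range(N_BLOCKS):
        segments.append(("block", i, BLOCK_S))
        if i < N_BLOCKS - 1:
            segments.append(("rest", i, REST_S))

    blocks: list[list[tuple[float, float]]] = [[] for _ in range(N_BLOCKS)]
    rests: list[tuple[float, float]] = []
    t = float(onset_s)
    pending = list(pauses)
    for kind, idx, dur in segments:
        remaining = dur
        while remaining > 0:
            if pending and pending[0][0] < t:
                raise ValueError(
                    f"pause at {pending[0][0]} s lies before the running "
                    "protocol position"
                )
            if pending and pending[0][0] < t + remaining:
                p, r = pending.pop(0)
                if p > t:
                    _append(kind, idx, (t, p), blocks, rests)
                remaining -= p - t
                t = r
            else:
                _append(kind, idx, (t, t + remaining), blocks, rests)
                t += remaining
                remaining = 0.0
    if pending:
        raise ValueError(f"pause at {pending[0][0]} s lies outside the protocol span")
    # merge rest sub-intervals split by a pause boundary bookkeeping
    return StimSchedule(
        condition=condition,
        blocks=blocks,
        rests=rests,
        pauses=list(pauses),
        onset_s=float(onset_s),
    )


def _append(kind, idx, interval, blocks, rests):
    if interval[1] <= interval[0]:
        return
    if kind == "block":
        blocks[idx].append(interval)
    else:
        rests.append(interval)


def epochs_overlapping(intervals, n_epochs: int, epoch_s: float = EPOCH_S) -> set[int]:
    """Epoch indices whose [30k, 30k+30) interval overlaps any interval."""
    out: set[int] = set()
    for s, e in intervals:
        k0 = max(0, int(np.floor(s / epoch_s)))
        k1 = min(n_epochs, int(np.ceil(e / epoch_s)))
        for k in range(k0, k1):
            if s < (k + 1) * epoch_s and e > k * epoch_s:
                out.add(k)
    return out


def epochs_within(intervals, n_epochs: int, epoch_s: float = EPOCH_S) -> set[int]:
    """Epoch indices whose full epoch interval lies inside some interval."""
    out: set[int] = set()
    for s, e in intervals:
        k0 = max(0, int(np.ceil(s / epoch_s - 1e-9)))
        k1 = min(n_epochs, int(np.floor(e / epoch_s + 1e-9)))
        for k in range(k0, k1):
            if k * epoch_s >= s - 1e-9 and (k + 1) * epoch_s <= e + 1e-9:
                out.add(k)
    return out


def stimulation_epoch_mask(schedule: StimSchedule, n_epochs: int) -> set[int]:
    """Epochs overlapping any stimulation block (or sham placeholder).

    These epochs carry stimulation artifact (or its placeholder) and are
    excluded from all duration statistics.
    """
    return epochs_overlapping(schedule.block_intervals(), n_epochs)


def immediate_window(schedule: StimSchedule, exclude_after_pause: bool = True,
                     allow_truncated: bool = False) -> AnalysisWindows:
    """Rest intervals plus the 5 min after the final block.

    With ``exclude_after_pause``, every immediate-window interval beginning
    at or after the first pause's resume time is moved to
    ``excluded_intervals`` — once the protocol has been interrupted, the
    following windows no longer reflect an uninterrupted stimulation run.
    """
    if not schedule.is_complete and not allow_truncated:
        raise ValueError(
            f"truncated protocol ({schedule.n_blocks} blocks); "
            "pass allow_truncated=True to analyze anyway"
        )
    intervals = sorted(schedule.rests) + [
        (schedule.end_s, schedule.end_s + POST_FINAL_S)
    ]
    included, excluded = [], []
    cutoff = min((r for _, r in schedule.pauses), default=None)
    for iv in intervals:
        if exclude_after_pause and cutoff is not None and iv[0] >= cutoff:
            excluded.append(iv)
        else:
            included.append(iv)
    return AnalysisWindows(pre_stim=None, immediate=included,
                           excluded_intervals=excluded)


def spectral_windows(schedule: StimSchedule) -> AnalysisWindows:
    """Pre- and post-stimulation windows for the spectral analysis.

    pre: the 300 s before the first block. post: the rests plus the 300 s
    after the final block, each with its first 20 s (stimulation artifact
    settle time) removed.
    """
    first_start = schedule.block_intervals()[0][0]
    if first_start < BLOCK_S:
        raise ValueError(
            "first stimulation block starts less than 300 s into the "
            "recording; no pre-stimulation window exists"
        )
    pre = (first_start - BLOCK_S, first_start)
    post = []
    block_ends = {e for _, e in schedule.block_intervals()}
    for s, e in sorted(schedule.rests) + [(schedule.end_s, schedule.end_s + POST_FINAL_S)]:
        start = s + POST_BLOCK_EXCLUDE_S if s in block_ends else s
        if start < e:
            post.append((start, e))
    return AnalysisWindows(pre_stim=pre, immediate=post)
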