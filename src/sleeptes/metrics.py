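"""Stage-duration outcome measures.

Whole-night time per stage (minutes), time per stage as a percentage of
total sleep time, and time per stage inside the immediate post-stimulation
window (seconds). Excluded epochs (stimulation blocks and their sham
placeholders, plus any scorer exclusions) never contribute to any duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypnogram import STAGES, Hypnogram
from .protocol import AnalysisWindows, epochs_within

__all__ = ["StageDurations", "stage_minutes", "stage_percent",
           "immediate_stage_seconds", "durations_frame"]

#: Stages counted as sleep for the total-sleep-time denominator.
SLEEP_STAGES = ("N1", "N2", "N3", "REM")


@dataclass
class StageDurations:
    """Per-stage durations in seconds plus exclusion bookkeeping."""

    seconds: dict[str, float]
    n_excluded_epochs: int = 0

    @property
    def minutes(self) -> dict[str, float]:
        return {s: v / 60.0 for s, v in self.seconds.items()}

    @property
    def total_sleep_s(self) -> float:
        return sum(self.seconds[s] for s in SLEEP_STAGES)


def _stage_seconds(hyp: Hypnogram, included: np.ndarray) -> dict[str, float]:
    secs = {}
    for code, name in enumerate(STAGES):
        secs[name] = float(np.sum(included & (hyp.labels == code))) * hyp.epoch_s
    return secs


def _combine_excluded(hyp: Hypnogram, excluded) -> np.ndarray:
    mask = hyp.excluded.copy()
    if excluded is not None:
        idx = np.fromiter(excluded, dtype=np.int64) if len(excluded) else np.empty(0, np.int64)
        if idx.size:
            if idx.min() < 0 or idx.max() >= hyp.n_epochs:
                raise IndexError("excluded epoch index out of range")
            mask[idx] = True
    return mask


def stage_minutes(hyp: Hypnogram, excluded=None) -> StageDurations:
    """Whole-night time per stage; each included epoch counts 0.5 min.

    ``excluded`` is an additional set of epoch indices (typically the
    stimulation-block mask) combined with the hypnogram's own mask.
    """
    mask = _combine_excluded(hyp, excluded)
    return StageDurations(
        seconds=_stage_seconds(hyp, ~mask),
        n_excluded_epochs=int(mask.sum()),
    )


def stage_percent(durations: StageDurations) -> dict[str, float]:
    """Per-stage percentage of total sleep time (W excluded from both)."""
    tst = durations.total_sleep_s
    if tst <= 0:
        raise ValueError("total sleep time is zero; percentages undefined")
    return {s: durations.seconds[s] / tst * 100.0 for s in SLEEP_STAGES}


def immediate_stage_seconds(hyp: Hypnogram, windows: AnalysisWindows,
                            excluded=None) -> StageDurations:
    """Time per stage inside the immediate window, in seconds.

    An epoch counts (30 s) iff its full interval lies inside one of the
    included immediate-window intervals and it is not excluded.
    """
    inside = epochs_within(windows.immediate, hyp.n_epochs, hyp.epoch_s)
    mask = _combine_excluded(hyp, excluded)
    included = np.zeros(hyp.n_epochs, dtype=bool)
    if inside:
        included[sorted(inside)] = True
    included &= ~mask
    return StageDurations(
        seconds=_stage_seconds(hyp, included),
        n_excluded_epochs=int((~included)[sorted(inside)].sum()) if inside else 0,
    )


def durations_frame(rows) -> pd.DataFrame:
    """Assemble per-subject/condition duration rows into a tidy table.

    ``rows``: iterable of (subject, condition, StageDurations, percents|None,
    immediate StageDurations|None). One output row per stage.
    """
    out = []
    for subject, condition, night, pct, imm in rows:
        for stage in STAGES:
            out.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "stage": stage,
                    "minutes": night.minutes[stage] if night else np.nan,
                    "percent": (pct or {}).get(stage, np.nan),
                    "immediate_seconds": imm.seconds[stage] if imm else np.nan,
                }
            )
    return pd.DataFrame(out)
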