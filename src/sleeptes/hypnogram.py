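"""Sleep-stage label sequences scored in 30-second epochs.

The hypnogram is the unit of every duration statistic in the pipeline: one
label per 30-s epoch, five AASM stages (W, N1, N2, N3, REM), plus an
exclusion mask for epochs that cannot be scored (e.g. epochs overlapping a
stimulation block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical stage order. Index into this tuple is the integer stage code
#: used everywhere (including the classifier's class index).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: The 30-s scoring epoch, in seconds.
EPOCH_S: float = 30.0


def stage_code(stage: str) -> int:
    """Map a stage name to its integer code, raising on unknown stages."""
    try:
        return STAGE_TO_CODE[stage]
    except KeyError:
        raise ValueError(
            f"unknown sleep stage {stage!r}; expected one of {STAGES}"
        ) from None


@dataclass
class Hypnogram:
    """A sequence of per-epoch sleep-stage labels with an exclusion mask.

    Parameters
    ----------
    labels
        Integer stage codes (indices into :data:`STAGES`), one per epoch.
    excluded
        Boolean mask, True for epochs excluded from analysis. Defaults to
        all-False.
    epoch_s
        Epoch length in seconds (30 s by scoring convention).
    """

    labels: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(STAGES)):
            raise ValueError("stage codes must lie in [0, 4]")
        if self.excluded is None:
            self.excluded = np.zeros(self.labels.shape, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != self.labels.shape:
            raise ValueError("excluded mask must have one entry per epoch")

    @classmethod
    def from_stages(cls, stages, excluded=None, epoch_s: float = EPOCH_S) -> "Hypnogram":
        """Build from an iterable of stage names such as ["W", "N2", ...]."""
        codes = np.array([stage_code(s) for s in stages], dtype=np.int64)
        return cls(codes, excluded, epoch_s)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    def __len__(self) -> int:
        return self.n_epochs

    def stage_names(self) -> list[str]:
        return [STAGES[c] for c in self.labels]

    def onsets_s(self) -> np.ndarray:
        """Start time of each epoch, in seconds from recording start."""
        return np.arange(self.n_epochs, dtype=float) * self.epoch_s

    def with_excluded(self, epochs) -> "Hypnogram":
        """Return a copy with the given epoch indices additionally excluded."""
        mask = self.excluded.copy()
        idx = np.asarray(sorted(epochs), dtype=np.int64)
        if idx.size:
            if idx.min() < 0 or idx.max() >= self.n_epochs:
                raise IndexError("excluded epoch index out of range")
            mask[idx] = True
        return Hypnogram(self.labels.copy(), mask, self.epoch_s)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_s == other.epoch_s
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.excluded, other.excluded)
        )
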