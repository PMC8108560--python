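"""Reading and writing the formats the pipeline touches.

Signals travel as EDF (the polysomnography interchange standard), hypnograms
and stimulation schedules as CSV, and the scalp-region channel map as YAML.
EDF reading goes through MNE; writing uses a small plain-EDF (16-bit) writer
because the one thing the analysis needs from the container is a lossless
round-trip up to the format's integer quantization, which is tested.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hypnogram import STAGES, Hypnogram, stage_code

__all__ = [
    "PSGRecord",
    "Derivation",
    "RegionMap",
    "REGION_NAMES",
    "read_edf",
    "write_edf",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "apply_derivations",
    "load_region_map",
    "default_region_map",
    "STAGING_DERIVATIONS",
]


@dataclass
class PSGRecord:
    """A multi-channel polysomnographic recording in microvolts.

    data : (n_channels, n_samples) array, μV
    rate : sampling rate, Hz
    channel_names : one name per row of ``data``
    start_time : seconds offset of the first sample
    annotations : list of (label, start_s, end_s)
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    start_time: float = 0.0
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in record "
                           f"(have {self.channel_names})") from None


@dataclass(frozen=True)
class Derivation:
    """A bipolar derivation: ``active`` minus ``reference`` electrode."""

    name: str
    active: str
    reference: str | None


#: The five staging inputs, in the fixed channel order the classifier expects.
#: EMG is a dedicated auxiliary channel, not a derivation.
STAGING_DERIVATIONS: tuple[Derivation, ...] = (
    Derivation("C3-M2", "C3", "M2"),
    Derivation("C4-M1", "C4", "M1"),
    Derivation("EOGL-M2", "EOGL", "M2"),
    Derivation("EOGR-M1", "EOGR", "M1"),
    Derivation("EMG", "EMG", None),
)

#: The ten scalp regions used for regional band-power averaging.
REGION_NAMES: tuple[str, ...] = (
    "Left Frontal",
    "Right Frontal",
    "Medial Prefrontal",
    "Medial Frontal",
    "Left Temporoparietal",
    "Right Temporoparietal",
    "Posterior Parietal",
    "Left Occipital",
    "Right Occipital",
    "Medial Occipital",
)

_LR_PAIRS = (
    ("Left Frontal", "Right Frontal"),
    ("Left Temporoparietal", "Right Temporoparietal"),
    ("Left Occipital", "Right Occipital"),
)


@dataclass
class RegionMap:
    """Mapping from each of the ten scalp regions to its channel cluster."""

    regions: dict[str, list[str]]

    def __post_init__(self) -> None:
        missing = [r for r in REGION_NAMES if r not in self.regions]
        if missing:
            raise ValueError(f"region map is missing regions: {missing}")
        extra = [r for r in self.regions if r not in REGION_NAMES]
        if extra:
            raise ValueError(f"unknown regions in map: {extra}")
        for region, chans in self.regions.items():
            if len(set(chans)) != len(chans):
                raise ValueError(f"duplicate channel within region {region!r}")
            if not chans:
                raise ValueError(f"region {region!r} has no channels")
        for left, right in _LR_PAIRS:
            if len(self.regions[left]) != len(self.regions[right]):
                raise ValueError(
                    f"left/right cluster sizes differ: {left} vs {right}"
                )

    def validate_channels(self, channel_names) -> None:
        """Check every mapped channel exists in the given montage."""
        have = set(channel_names)
        for region, chans in self.regions.items():
            for ch in chans:
                if ch not in have:
                    raise KeyError(
                        f"region {region!r} requires channel {ch!r}, "
                        "absent from the record"
                    )

    def items(self):
        return self.regions.items()


# ---------------------------------------------------------------------------
# EDF


def write_edf(record: PSGRecord, path) -> None:
    """Write a record as plain EDF (16-bit, 1-second data records).

    The number of samples must be a whole number of 1-s records and the rate
    an integer. Physical range is chosen per channel to cover the data, so
    the quantization step is ``(2 * max|x|) / 65535`` for that channel.
    """
    path = Path(path)
    if record.n_channels == 0:
        raise ValueError("cannot write an EDF with no channels")
    rate = record.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    if record.n_samples % rate != 0:
        raise ValueError("recording length must be a whole number of seconds")
    n_records = record.n_samples // rate
    ns = record.n_channels

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r} > {width}")
        return b.ljust(width)

    header = b"".join(
        [
            f("0", 8),                       # version
            f("X X X X", 80),                # patient id (anonymous)
            f("Startdate X X X X", 80),      # recording id
            f("01.01.00", 8),                # start date
            f("00.00.00", 8),                # start time
            f(str(256 + ns * 256), 8),       # header bytes
            f("", 44),                       # reserved
            f(str(n_records), 8),
            f("1", 8),                       # record duration, seconds
            f(str(ns), 4),
        ]
    )
    phys_min, phys_max, dig = [], [], np.empty((ns, record.n_samples), dtype="<i2")
    for i in range(ns):
        x = record.data[i]
        span = float(np.max(np.abs(x))) if x.size else 0.0
        span = max(span, 1.0)
        pm = math.ceil(span)
        phys_min.append(-pm)
        phys_max.append(pm)
        # EDF decoding is phys = pmin + (dig - dmin) * (pmax-pmin)/(dmax-dmin);
        # encode with the exact inverse so the round-trip error is <= step/2
        scale = 65535.0 / (2.0 * pm)
        dig[i] = np.clip(np.rint((x + pm) * scale) - 32768, -32768, 32767).astype("<i2")

    sig_header = b"".join(
        [
            b"".join(f(name[:16], 16) for name in record.channel_names),
            b"".join(f("", 80) for _ in range(ns)),          # transducer
            b"".join(f("uV", 8) for _ in range(ns)),          # physical dim
            b"".join(f(str(phys_min[i]), 8) for i in range(ns)),
            b"".join(f(str(phys_max[i]), 8) for i in range(ns)),
            b"".join(f("-32768", 8) for _ in range(ns)),
            b"".join(f("32767", 8) for _ in range(ns)),
            b"".join(f("", 80) for _ in range(ns)),          # prefiltering
            b"".join(f(str(rate), 8) for _ in range(ns)),     # samples/record
            b"".join(f("", 32) for _ in range(ns)),          # reserved
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records are channel-blocked: all of channel 0's samples for the
        # record, then channel 1's, ...
        blocks = dig.reshape(ns, n_records, rate)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path) -> PSGRecord:
    """Read an EDF file into a :class:`PSGRecord` (data in μV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    annotations = [
        (desc, float(onset), float(onset + dur))
        for desc, onset, dur in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
    ]
    return PSGRecord(
        data=np.asarray(data, dtype=np.float64),
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Hypnogram and schedule CSV


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    """Write epoch_index, onset_s, stage, excluded rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "onset_s", "stage", "excluded"])
        for k in range(hyp.n_epochs):
            w.writerow(
                [k, k * hyp.epoch_s, STAGES[hyp.labels[k]], int(hyp.excluded[k])]
            )


def read_hypnogram_csv(path) -> Hypnogram:
    labels: list[int] = []
    excluded: list[bool] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                labels.append(stage_code(row["stage"]))
            except ValueError as err:
                raise ValueError(f"{path}, row {rownum}: {err}") from None
            excluded.append(bool(int(row.get("excluded") or 0)))
    return Hypnogram(np.array(labels, dtype=np.int64), np.array(excluded, dtype=bool))


def write_schedule_csv(schedule, path) -> None:
    """Write a stimulation schedule as kind,start_s,end_s,condition rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "start_s", "end_s", "condition"])
        for s, e in schedule.block_intervals():
            w.writerow(["block", s, e, schedule.condition])
        for s, e in schedule.rests:
            w.writerow(["rest", s, e, schedule.condition])
        for s, e in schedule.pauses:
            w.writerow(["pause", s, e, schedule.condition])


def read_schedule_csv(path):
    """Read a schedule CSV written by :func:`write_schedule_csv`."""
    from .protocol import StimSchedule

    blocks, rests, pauses = [], [], []
    condition = "stim"
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            iv = (float(row["start_s"]), float(row["end_s"]))
            condition = row["condition"]
            kind = row["kind"]
            if kind == "block":
                blocks.append(iv)
            elif kind == "rest":
                rests.append(iv)
            elif kind == "pause":
                pauses.append(iv)
            else:
                raise ValueError(f"unknown schedule row kind {kind!r}")
    onset = min(s for s, _ in blocks) if blocks else 0.0
    return StimSchedule(
        condition=condition,
        blocks=blocks,
        rests=rests,
        pauses=pauses,
        onset_s=onset,
    )


# ---------------------------------------------------------------------------
# Derivations and regions


def apply_derivations(record: PSGRecord, derivations) -> PSGRecord:
    """Build a bipolar-referenced record: channel i = active − reference.

    A derivation with ``reference=None`` copies the active channel (used for
    the auxiliary EMG channel).
    """
    rows, names = [], []
    for d in derivations:
        act = record.channel(d.active)
        rows.append(act - record.channel(d.reference) if d.reference else act.copy())
        names.append(d.name)
    return PSGRecord(
        data=np.vstack(rows),
        rate=record.rate,
        channel_names=names,
        start_time=record.start_time,
        annotations=list(record.annotations),
    )


def load_region_map(config_path, channel_names=None) -> RegionMap:
    """Load and validate a region→channels YAML map.

    If ``channel_names`` is given, every mapped channel must exist in it.
    """
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "regions" not in raw:
        raise ValueError("region map YAML must have a top-level 'regions' key")
    rm = RegionMap({str(k): list(v) for k, v in raw["regions"].items()})
    if channel_names is not None:
        rm.validate_channels(channel_names)
    return rm


def default_region_map() -> RegionMap:
    """The shipped 10-20-system default region map."""
    return load_region_map(Path(__file__).parent / "data" / "region_map.yaml")
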