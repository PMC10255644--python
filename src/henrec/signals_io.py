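"""Sensor/label file I/O, decimation, magnitude axis, and label summaries.

Recordings are six-channel inertial time series (three-axis acceleration in
m/s^2, three-axis angular velocity in deg/s) captured per hen at a nominal
sampling frequency. Behavior labels are closed intervals in seconds tagged
with one of the twelve ethogram symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ethogram symbols, in the fixed reporting order used throughout the package:
#: moving, eating, drinking, preening, body shaking, head scratching,
#: tail flapping, stopping (standing still), resting (lying), dust-bathing,
#: litter scratching, and the miscellaneous "others" class.
BEHAVIORS: tuple[str, ...] = (
    "MV", "ET", "DK", "PR", "BS", "HS", "TF", "ST", "RS", "DB", "LS", "OT",
)

#: Sensor full-scale ranges: +-2 g accelerometer, +-500 deg/s gyro.
ACC_RANGE = 19.62
GYR_RANGE = 500.0

SENSOR_COLUMNS = [
    "hen_id", "timestamp_s",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
]
LABEL_COLUMNS = ["hen_id", "behavior", "start_s", "end_s"]

_CHANNELS = ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


class SchemaError(ValueError):
    """Raised when a CSV header does not match the documented schema."""


@dataclass
class InertialRecording:
    """One hen's six-channel signal at a known sampling frequency.

    ``data`` holds columns ``timestamp_s`` plus the six channels, one row
    per sample, timestamps strictly increasing.
    """

    hen_id: str
    sampling_frequency: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.data["timestamp_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"timestamps not strictly increasing for hen {self.hen_id!r}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> np.ndarray:
        return self.data["timestamp_s"].to_numpy()

    def channels(self) -> np.ndarray:
        """(N, 6) array in channel order acc x/y/z, gyr x/y/z."""
        return self.data[_CHANNELS].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InertialRecording):
            return NotImplemented
        return (
            self.hen_id == other.hen_id
            and self.sampling_frequency == other.sampling_frequency
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


@dataclass(frozen=True)
class LabelInterval:
    """One behavior occurrence: [start_s, end_s) for one hen."""

    hen_id: str
    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior symbol {self.behavior!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"interval end {self.end_s} must exceed start {self.start_s}"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def read_recording(path, hen_id: str, sampling_frequency: float) -> InertialRecording:
    """Read one hen's sensor CSV.

    The header must match ``hen_id,timestamp_s,acc_x,...,gyr_z`` exactly;
    rows are returned in file order. Out-of-range sensor values are accepted
    with a warning (real sensors saturate rather than fail).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != SENSOR_COLUMNS:
        raise SchemaError(
            f"sensor CSV header {list(df.columns)} != expected {SENSOR_COLUMNS}"
        )
    numeric = df.columns.drop("hen_id")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    t = df["timestamp_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"timestamps not strictly increasing in {path}")
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy()
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy()
    if np.any(np.abs(acc) > ACC_RANGE) or np.any(np.abs(gyr) > GYR_RANGE):
        logger.warning("out-of-range sensor values in %s (accepted; sensor may saturate)", path)
    return InertialRecording(
        hen_id=hen_id,
        sampling_frequency=sampling_frequency,
        data=df.drop(columns="hen_id").reset_index(drop=True),
    )


def write_recording(rec: InertialRecording, path) -> None:
    """Write a recording as a sensor CSV (full-precision decimal repr)."""
    out = rec.data.copy()
    out.insert(0, "hen_id", rec.hen_id)
    out.to_csv(path, index=False, float_format="%.17g")


def read_labels(path) -> list[LabelInterval]:
    """Read a label CSV (``hen_id,behavior,start_s,end_s``).

    Behavior symbols are case-sensitive and closed-world; anything outside
    the twelve-symbol ethogram is a parse error.
    """
    df = pd.read_csv(path)
    if list(df.columns) != LABEL_COLUMNS:
        raise SchemaError(
            f"label CSV header {list(df.columns)} != expected {LABEL_COLUMNS}"
        )
    labels = [
        LabelInterval(str(r.hen_id), str(r.behavior), float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]
    _check_no_overlap(labels)
    return labels


def write_labels(labels: Iterable[LabelInterval], path) -> None:
    df = pd.DataFrame(
        [(l.hen_id, l.behavior, l.start_s, l.end_s) for l in labels],
        columns=LABEL_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _check_no_overlap(labels: Sequence[LabelInterval]) -> None:
    by_hen: dict[str, list[LabelInterval]] = {}
    for l in labels:
        by_hen.setdefault(l.hen_id, []).append(l)
    for hen, ls in by_hen.items():
        ls = sorted(ls, key=lambda l: l.start_s)
        for a, b in zip(ls, ls[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValueError(
                    f"overlapping label intervals for hen {hen!r}: "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )


def downsample(rec: InertialRecording, target: float) -> InertialRecording:
    """Decimate by keeping the first sample of every d = SF/target samples.

    No filtering or interpolation is applied; kept samples retain their
    original timestamps. ``target`` must divide the recording's sampling
    frequency to an integer factor.
    """
    factor = rec.sampling_frequency / target
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target {target} Hz does not integer-divide {rec.sampling_frequency} Hz"
        )
    d = int(round(factor))
    if d == 1:
        return InertialRecording(rec.hen_id, target, rec.data.copy())
    return InertialRecording(
        hen_id=rec.hen_id,
        sampling_frequency=target,
        data=rec.data.iloc[::d].reset_index(drop=True),
    )


def magnitude(acc_x, acc_y, acc_z):
    """l2-norm of the three acceleration components (orientation-independent)."""
    return np.sqrt(np.square(acc_x) + np.square(acc_y) + np.square(acc_z))


def summarize_labels(labels: Sequence[LabelInterval]) -> pd.DataFrame:
    """Per-class interval count and sum/mean/SD of durations, in seconds.

    Rows: ``count``, ``sum_s``, ``mean_s``, ``sd_s``; columns: the twelve
    behavior symbols in fixed order. SD is the population form. Classes with
    no intervals get count 0 and NaN mean/SD (flagged undefined).
    """
    durations: dict[str, list[float]] = {b: [] for b in BEHAVIORS}
    for l in labels:
        durations[l.behavior].append(l.duration)
    out = {}
    for b in BEHAVIORS:
        d = np.asarray(durations[b], dtype=float)
        if d.size == 0:
            out[b] = [0, 0.0, np.nan, np.nan]
        else:
            out[b] = [d.size, d.sum(), d.mean(), d.std()]  # population SD
    df = pd.DataFrame(out, index=["count", "sum_s", "mean_s", "sd_s"])
    return df
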