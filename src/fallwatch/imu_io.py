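"""Data model and file I/O for raw 9-DOF IMU streams and derived RMS/Euler traces.

Two delimited-text dialects are used, both UTF-8 comma-separated with a header
row and a ``.`` decimal separator:

* raw streams:     ``t_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps, mx_uT, my_uT, mz_uT``
* derived traces:  ``t_s, rms_g, yaw_deg, pitch_deg, roll_deg``

Units are fixed at the file boundary: seconds, g, deg/s, microtesla, degrees.
Timestamps are stored explicitly (not implied by the sampling rate) so that
dropped or duplicated samples can be detected at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENTS",
    "RAW_COLUMNS",
    "DERIVED_COLUMNS",
    "FormatError",
    "ParseError",
    "StreamValidationError",
    "IMUSample",
    "IMUStream",
    "DerivedSample",
    "DerivedTrace",
    "read_imu_stream",
    "write_imu_stream",
    "read_derived_trace",
    "write_derived_trace",
]

SEGMENTS = ("shoulder", "waist", "foot")

RAW_COLUMNS = [
    "t_s",
    "ax_g",
    "ay_g",
    "az_g",
    "gx_dps",
    "gy_dps",
    "gz_dps",
    "mx_uT",
    "my_uT",
    "mz_uT",
]
DERIVED_COLUMNS = ["t_s", "rms_g", "yaw_deg", "pitch_deg", "roll_deg"]

#: sensor full-scale range of the accelerometer, in g
ACCEL_RANGE_G = 16.0

#: relative tolerance on the sample spacing (fraction of 1/rate)
TIMING_TOLERANCE = 0.01


class FormatError(ValueError):
    """The file header does not name the expected columns."""


class ParseError(ValueError):
    """A data cell could not be parsed as a number."""


class StreamValidationError(ValueError):
    """Stream or trace contents violate a structural invariant."""


class IMUSample(NamedTuple):
    """One timestamped 9-DOF reading (accel in g, gyro in deg/s, mag in uT)."""

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray


class DerivedSample(NamedTuple):
    """One timestamped detector input: RMS acceleration plus Euler angles."""

    t: float
    rms: float
    yaw: float
    pitch: float
    roll: float


def _check_timing(t: np.ndarray, rate: float) -> None:
    if rate <= 0:
        raise StreamValidationError(f"sampling rate must be positive, got {rate}")
    if t.size < 2:
        return
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise StreamValidationError(
            f"timestamps must be strictly increasing (violation at sample {i + 1}, "
            f"t={t[i]!r} -> {t[i + 1]!r})"
        )
    nominal = 1.0 / rate
    if np.any(np.abs(dt - nominal) > TIMING_TOLERANCE * nominal):
        i = int(np.argmax(np.abs(dt - nominal) > TIMING_TOLERANCE * nominal))
        raise StreamValidationError(
            f"sample spacing deviates more than {TIMING_TOLERANCE:.0%} from 1/rate "
            f"at sample {i + 1}: dt={dt[i]:.6g}, expected {nominal:.6g}"
        )


def _check_segment(segment: str) -> None:
    if segment not in SEGMENTS:
        raise StreamValidationError(
            f"segment must be one of {SEGMENTS}, got {segment!r}"
        )


@dataclass
class IMUStream:
    """An ordered raw 9-DOF recording at a fixed sampling rate.

    Parameters
    ----------
    t : array of shape (n,)
        Seconds from stream start, strictly increasing, spaced 1/rate.
    accel, gyro, mag : arrays of shape (n, 3)
        Tri-axis accelerometer (g), gyroscope (deg/s) and magnetometer (uT).
    rate : float
        Sampling frequency in Hz (100 Hz for the wearable unit modelled here).
    segment : str
        Body placement tag: ``shoulder``, ``waist`` or ``foot``.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    rate: float = 100.0
    segment: str = "waist"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        self.mag = np.asarray(self.mag, dtype=float).reshape(-1, 3)
        n = self.t.size
        if not (len(self.accel) == len(self.gyro) == len(self.mag) == n):
            raise StreamValidationError("channel arrays have mismatched lengths")
        for name in ("t", "accel", "gyro", "mag"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise StreamValidationError(f"non-finite value in {name}")
        _check_segment(self.segment)
        _check_timing(self.t, self.rate)

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> IMUSample:
        return IMUSample(float(self.t[i]), self.accel[i], self.gyro[i], self.mag[i])

    def __iter__(self) -> Iterator[IMUSample]:
        for i in range(len(self)):
            yield self[i]


@dataclass
class DerivedTrace:
    """Per-timestamp RMS acceleration plus Euler angles — the detector's input.

    ``rms`` is in g and nonnegative; ``pitch`` lies in [-90, 90] degrees and
    ``yaw``/``roll`` in (-180, 180].
    """

    t: np.ndarray
    rms: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    rate: float = 100.0
    segment: str = "waist"

    def __post_init__(self) -> None:
        for name in ("t", "rms", "yaw", "pitch", "roll"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        n = self.t.size
        if not all(
            getattr(self, name).size == n for name in ("rms", "yaw", "pitch", "roll")
        ):
            raise StreamValidationError("channel arrays have mismatched lengths")
        for name in ("t", "rms", "yaw", "pitch", "roll"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise StreamValidationError(f"non-finite value in {name}")
        if np.any(self.rms < 0):
            raise StreamValidationError("rms must be nonnegative")
        if np.any(np.abs(self.pitch) > 90):
            raise StreamValidationError("pitch must lie in [-90, 90] degrees")
        for name in ("yaw", "roll"):
            v = getattr(self, name)
            if np.any((v <= -180) | (v > 180)):
                raise StreamValidationError(f"{name} must lie in (-180, 180] degrees")
        _check_segment(self.segment)
        _check_timing(self.t, self.rate)

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, i: int) -> DerivedSample:
        return DerivedSample(
            float(self.t[i]),
            float(self.rms[i]),
            float(self.yaw[i]),
            float(self.pitch[i]),
            float(self.roll[i]),
        )

    def __iter__(self) -> Iterator[DerivedSample]:
        for i in range(len(self)):
            yield self[i]


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    got = [c.strip() for c in df.columns]
    if got != list(columns):
        raise FormatError(
            f"{path}: expected columns {list(columns)}, found {got}"
        )
    out = pd.DataFrame(index=df.index)
    for c, raw in zip(columns, df.columns):
        converted = pd.to_numeric(df[raw], errors="coerce")
        bad = converted.isna() & df[raw].notna()
        if df[raw].isna().any():
            row = int(df.index[df[raw].isna()][0]) + 2  # 1-based incl. header
            raise ParseError(f"{path}: empty cell in column {c!r} at line {row}")
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ParseError(
                f"{path}: non-numeric value {df[raw][bad].iloc[0]!r} in column "
                f"{c!r} at line {row}"
            )
        # numpy's string parser is round-trip precise; pandas' fast path is not
        out[c] = df[raw].to_numpy(dtype=float)
    return out


def read_imu_stream(
    path: str | Path, rate: float = 100.0, segment: str = "waist"
) -> IMUStream:
    """Read a raw 9-DOF stream from a delimited-text file.

    Raises :class:`FormatError` for a wrong header, :class:`ParseError` (with
    the offending line number) for non-numeric cells and
    :class:`StreamValidationError` for non-monotone or mis-spaced timestamps.
    """
    df = _read_table(path, RAW_COLUMNS)
    return IMUStream(
        t=df["t_s"].to_numpy(),
        accel=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
        gyro=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
        mag=df[["mx_uT", "my_uT", "mz_uT"]].to_numpy(),
        rate=rate,
        segment=segment,
    )


def write_imu_stream(stream: IMUStream, path: str | Path) -> Path:
    """Write a raw stream; ``read_imu_stream`` inverts this bit-for-value."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.accel, stream.gyro, stream.mag]),
        columns=RAW_COLUMNS,
    )
    # %.17g guarantees bit-exact float round-trips through the text format
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_derived_trace(
    path: str | Path, rate: float = 100.0, segment: str = "waist"
) -> DerivedTrace:
    """Read a derived RMS/Euler trace from a delimited-text file."""
    df = _read_table(path, DERIVED_COLUMNS)
    return DerivedTrace(
        t=df["t_s"].to_numpy(),
        rms=df["rms_g"].to_numpy(),
        yaw=df["yaw_deg"].to_numpy(),
        pitch=df["pitch_deg"].to_numpy(),
        roll=df["roll_deg"].to_numpy(),
        rate=rate,
        segment=segment,
    )


def write_derived_trace(trace: DerivedTrace, path: str | Path) -> Path:
    """Write a derived trace; ``read_derived_trace`` inverts this."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([trace.t, trace.rms, trace.yaw, trace.pitch, trace.roll]),
        columns=DERIVED_COLUMNS,
    )
    # %.17g guarantees bit-exact float round-trips through the text format
    df.to_csv(path, index=False, float_format="%.17g")
    return path
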