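"""Three-phase threshold fall detection.

A fall has three phases: a weightless *start* (the body descends, RMS
acceleration drops toward 0 g), an *impact* (contact with the ground, a sharp
RMS spike) and a *posture* phase (the body lies on the ground, |roll| or
|pitch| near 90 degrees).  The start phase does not separate falls from
benign movements, so the detector keys on the last two:

* **impact**: the RMS acceleration ``sqrt(Ax^2 + Ay^2 + Az^2)`` crosses above
  the impact threshold ``A_ti`` (default 2.3 g);
* **posture**: within ``T_tp`` seconds (default 2 s) after the impact, the
  absolute value of roll or pitch exceeds the orientation threshold ``O_tp``
  (default 50 degrees).

Both conditions use strict ``>`` comparison, and the impact is a *crossing*
(below to above), so a plateau above threshold opens a single candidate.
While a posture window is open no new candidate is opened: secondary spikes
(e.g. the body bouncing after impact) are absorbed into the current candidate
rather than raising duplicate alarms.  Absolute angles are used without
baseline subtraction, so the mounting convention must put the worn device
near 0 degrees tilt when the wearer is upright.

Setting ``o_tp = 0`` disables the posture gate (any post-impact sample
triggers), reducing the detector to a pure-accelerometer detector — useful
for demonstrating why the angle test is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .imu_io import DerivedSample, DerivedTrace

__all__ = [
    "DetectorConfig",
    "FallEvent",
    "PostureResult",
    "compute_rms",
    "detect_impacts",
    "detect_posture",
    "detect_falls",
    "StreamingDetector",
    "run_streaming",
    "ThresholdFallDetector",
    "write_events_csv",
    "write_events_jsonl",
]


def compute_rms(accel) -> np.ndarray | float:
    """Acceleration magnitude ``sqrt(Ax^2 + Ay^2 + Az^2)`` in g.

    Accepts a single 3-vector or an (n, 3) array.  Reads 1 g for a stationary
    device (gravity), near 0 g in free fall.
    """
    a = np.asarray(accel, dtype=float)
    if a.ndim == 1:
        return float(np.sqrt(np.sum(a * a)))
    return np.sqrt(np.sum(a * a, axis=-1))


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds.

    ``a_ti``: impact acceleration threshold in g (default 2.3, identified
    experimentally for shoulder/waist/foot placements).  ``o_tp``: posture
    orientation threshold in degrees (default 50; 0 disables the angle gate).
    ``t_tp``: posture time window in seconds after the impact (default 2).
    """

    a_ti: float = 2.3
    o_tp: float = 50.0
    t_tp: float = 2.0

    def __post_init__(self) -> None:
        if self.a_ti <= 0:
            raise ValueError(f"a_ti must be positive, got {self.a_ti}")
        if not 0.0 <= self.o_tp <= 90.0:
            raise ValueError(f"o_tp must lie in [0, 90] degrees, got {self.o_tp}")
        if self.t_tp <= 0:
            raise ValueError(f"t_tp must be positive, got {self.t_tp}")

    def window_samples(self, rate: float) -> int:
        return int(round(self.t_tp * rate))


@dataclass(frozen=True)
class FallEvent:
    """One detected fall.

    ``impact_time``/``alarm_time`` in seconds from trace start; ``peak_rms``
    is the largest RMS between impact and alarm (g); ``max_angle`` the largest
    |roll| or |pitch| observed in the posture window up to the alarm sample
    (degrees) and ``channel`` names which of the two attained it.
    ``truncated`` is False for confirmed alarms; windows that end undecided
    surface their truncation through :class:`PostureResult` instead.
    """

    impact_time: float
    alarm_time: float
    peak_rms: float
    max_angle: float
    channel: str
    truncated: bool = False

    def validate(self, cfg: DetectorConfig) -> None:
        """Check the event satisfies its defining invariants for ``cfg``."""
        if not self.impact_time <= self.alarm_time <= self.impact_time + cfg.t_tp + 1e-9:
            raise ValueError(
                f"alarm_time {self.alarm_time} outside "
                f"({self.impact_time}, {self.impact_time + cfg.t_tp}]"
            )
        if not self.peak_rms > cfg.a_ti:
            raise ValueError(f"peak_rms {self.peak_rms} not above a_ti {cfg.a_ti}")
        if not self.max_angle > cfg.o_tp:
            raise ValueError(f"max_angle {self.max_angle} not above o_tp {cfg.o_tp}")
        if self.channel not in ("pitch", "roll"):
            raise ValueError(f"channel must be 'pitch' or 'roll', got {self.channel}")


class PostureResult(NamedTuple):
    """Outcome of the posture scan after one impact candidate."""

    index: Optional[int]
    truncated: bool


def detect_impacts(trace: DerivedTrace, cfg: DetectorConfig | None = None) -> list[int]:
    """Indices where RMS first crosses above ``a_ti`` (crossing semantics).

    A crossing requires the previous sample at or below threshold (the first
    sample of a trace counts if already above).  While the posture window of
    a previous candidate is open, no new candidate is recorded.
    """
    cfg = cfg or DetectorConfig()
    rms = trace.rms
    n = rms.size
    window = cfg.window_samples(trace.rate)
    out: list[int] = []
    blocked_until = -1  # last index inside an open window
    i = 0
    while i < n:
        above = rms[i] > cfg.a_ti
        crossed = above and (i == 0 or rms[i - 1] <= cfg.a_ti)
        if crossed and i > blocked_until:
            out.append(i)
            blocked_until = i + window
            i = blocked_until + 1
            continue
        i += 1
    return out


def detect_posture(
    trace: DerivedTrace, impact_index: int, cfg: DetectorConfig | None = None
) -> PostureResult:
    """First in-window sample whose |roll| or |pitch| exceeds ``o_tp``.

    The window is half-open, ``(impact, impact + T_tp * rate]``: the impact
    sample itself is not eligible.  A window truncated by the end of the trace
    is evaluated on the available samples and flagged.
    """
    cfg = cfg or DetectorConfig()
    n = len(trace)
    if not 0 <= impact_index < n:
        raise IndexError(f"impact index {impact_index} out of range for {n} samples")
    window = cfg.window_samples(trace.rate)
    stop = impact_index + window + 1  # exclusive
    truncated = stop > n
    stop = min(stop, n)
    for j in range(impact_index + 1, stop):
        if max(abs(trace.roll[j]), abs(trace.pitch[j])) > cfg.o_tp:
            return PostureResult(j, truncated)
    return PostureResult(None, truncated)


def _make_event(
    trace: DerivedTrace, k: int, j: int, truncated: bool, cfg: DetectorConfig
) -> FallEvent:
    peak = float(np.max(trace.rms[k : j + 1]))
    roll_max = float(np.max(np.abs(trace.roll[k + 1 : j + 1])))
    pitch_max = float(np.max(np.abs(trace.pitch[k + 1 : j + 1])))
    if pitch_max >= roll_max:
        channel, max_angle = "pitch", pitch_max
    else:
        channel, max_angle = "roll", roll_max
    return FallEvent(
        impact_time=float(trace.t[k]),
        alarm_time=float(trace.t[j]),
        peak_rms=peak,
        max_angle=max_angle,
        channel=channel,
        truncated=truncated,
    )


def detect_falls(
    trace: DerivedTrace, cfg: DetectorConfig | None = None
) -> list[FallEvent]:
    """Batch detection: impact candidates composed with the posture scan.

    At most one event per impact candidate; the alarm is raised at the first
    in-window posture sample, so the alarm never lags the impact by more than
    ``T_tp`` seconds (the detector is online in spirit and exactly equivalent
    to :class:`StreamingDetector`).
    """
    cfg = cfg or DetectorConfig()
    events: list[FallEvent] = []
    for k in detect_impacts(trace, cfg):
        res = detect_posture(trace, k, cfg)
        if res.index is not None:
            # a confirmed alarm is never marked truncated: truncation only
            # matters when the window ends before a decision (PostureResult)
            events.append(_make_event(trace, k, res.index, False, cfg))
    return events


class StreamingDetector:
    """Sample-at-a-time detector with O(1) state.

    ``push`` consumes one derived sample and returns a :class:`FallEvent` the
    moment a fall is confirmed, else ``None``.  Decisions are identical to
    :func:`detect_falls` on the same trace.
    """

    def __init__(self, cfg: DetectorConfig | None = None, rate: float = 100.0):
        self.cfg = cfg or DetectorConfig()
        self.rate = rate
        self._window = self.cfg.window_samples(rate)
        self._i = -1
        self._prev_rms: Optional[float] = None
        # open candidate state
        self._impact_i: Optional[int] = None
        self._impact_t = 0.0
        self._peak = 0.0
        self._max_angle = 0.0
        self._max_channel = "pitch"
        self._alarmed = False

    def push(self, sample: DerivedSample) -> Optional[FallEvent]:
        self._i += 1
        i = self._i
        cfg = self.cfg
        event: Optional[FallEvent] = None

        open_window = (
            self._impact_i is not None and i <= self._impact_i + self._window
        )
        if open_window and not self._alarmed:
            self._peak = max(self._peak, sample.rms)
            roll_a, pitch_a = abs(sample.roll), abs(sample.pitch)
            if pitch_a >= roll_a and pitch_a >= self._max_angle:
                self._max_angle, self._max_channel = pitch_a, "pitch"
            elif roll_a > self._max_angle:
                self._max_angle, self._max_channel = roll_a, "roll"
            if max(roll_a, pitch_a) > cfg.o_tp:
                self._alarmed = True
                event = FallEvent(
                    impact_time=self._impact_t,
                    alarm_time=sample.t,
                    peak_rms=self._peak,
                    max_angle=self._max_angle,
                    channel=self._max_channel,
                    truncated=False,
                )
        elif not open_window:
            crossed = sample.rms > cfg.a_ti and (
                self._prev_rms is None or self._prev_rms <= cfg.a_ti
            )
            if crossed:
                self._impact_i = i
                self._impact_t = sample.t
                self._peak = sample.rms
                self._max_angle = 0.0
                self._max_channel = "pitch"
                self._alarmed = False

        self._prev_rms = sample.rms
        return event


def run_streaming(
    samples: Iterable[DerivedSample],
    cfg: DetectorConfig | None = None,
    rate: float = 100.0,
) -> Iterator[FallEvent]:
    """Drive a :class:`StreamingDetector` over an iterable of samples."""
    det = StreamingDetector(cfg, rate)
    for s in samples:
        ev = det.push(s)
        if ev is not None:
            yield ev


class ThresholdFallDetector(BaseEstimator):
    """Three-phase threshold fall detector with a scikit-learn estimator API.

    The thresholds are fixed domain parameters rather than learned, so ``fit``
    only validates them (recording the assembled :class:`DetectorConfig` as
    ``config_``); ``get_params``/``set_params`` make the thresholds tunable by
    sklearn model-selection tooling.  ``predict`` maps traces to 0/1 alarm
    labels; ``detect`` returns the full event list for one trace.
    """

    def __init__(self, a_ti: float = 2.3, o_tp: float = 50.0, t_tp: float = 2.0):
        self.a_ti = a_ti
        self.o_tp = o_tp
        self.t_tp = t_tp

    def fit(self, X=None, y=None) -> "ThresholdFallDetector":
        self.config_ = DetectorConfig(a_ti=self.a_ti, o_tp=self.o_tp, t_tp=self.t_tp)
        return self

    def detect(self, trace: DerivedTrace) -> list[FallEvent]:
        if not hasattr(self, "config_"):
            self.fit()
        return detect_falls(trace, self.config_)

    def predict(self, X) -> np.ndarray:
        """1 where a trace raises at least one fall alarm, else 0."""
        if isinstance(X, DerivedTrace):
            X = [X]
        return np.array([1 if self.detect(tr) else 0 for tr in X], dtype=int)


def _event_row(ev: FallEvent) -> dict:
    return {
        "impact_t_s": ev.impact_time,
        "alarm_t_s": ev.alarm_time,
        "peak_rms_g": ev.peak_rms,
        "max_angle_deg": ev.max_angle,
        "angle_name": ev.channel,
        "truncated": ev.truncated,
    }


def write_events_csv(events: Sequence[FallEvent], path: str | Path) -> Path:
    path = Path(path)
    cols = ["impact_t_s", "alarm_t_s", "peak_rms_g", "max_angle_deg", "angle_name", "truncated"]
    pd.DataFrame([_event_row(e) for e in events], columns=cols).to_csv(path, index=False)
    return path


def write_events_jsonl(events: Sequence[FallEvent], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(_event_row(e)) + "\n")
    return path
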