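"""Outcome classification and per-segment detection metrics.

One trial is one recorded trace with one ground-truth label.  A fall trial
that raises at least one alarm anywhere in the trace is a true positive (TP);
multiple alarms within one fall trial still count as a single TP.  A fall
trial with no alarm is a false negative (FN).  An ADL trial with any alarm is
a false positive (FP), with none a true negative (TN).

Per-activity *correct rate* is the percentage of trials of that activity that
were classified correctly (TP or TN).  Per segment,

* sensitivity = 100 * TP / (TP + FN)  — correct rate over fall trials,
* specificity = 100 * TN / (TN + FP)  — correct rate over ADL trials,
* accuracy    = 100 * (TP + TN) / total trials.

Rates are reported to one decimal place.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .detection import DetectorConfig, detect_falls
from .simulator import ADL_ACTIVITIES, FALL_ACTIVITIES, LabeledTrace

__all__ = [
    "OUTCOMES",
    "TrialResult",
    "SegmentReport",
    "classify_outcome",
    "correct_rate",
    "segment_report",
    "evaluate_trials",
    "trials_from_rates",
    "ACTIVITY_CATEGORY",
    "REFERENCE_CORRECT_RATES",
    "REFERENCE_TRIALS_PER_ACTIVITY",
]

OUTCOMES = ("TP", "FP", "TN", "FN")

#: ground-truth category of each protocol activity
ACTIVITY_CATEGORY: dict[str, str] = {
    **{name: "fall" for name in FALL_ACTIVITIES},
    **{name: "adl" for name in ADL_ACTIVITIES},
}

#: published per-activity correct detection rates (%) of the wearable
#: validation study this package models, per sensor placement
REFERENCE_CORRECT_RATES: dict[str, dict[str, float]] = {
    "shoulder": {
        **{name: 100.0 for name in FALL_ACTIVITIES},
        "walking": 100.0,
        "bending_over": 60.0,
        "taking_stairs": 100.0,
        "sit_chair": 100.0,
        "sit_lie_mattress": 100.0,
        "stretching_shoulder": 100.0,
        "staggering_forward": 60.0,
        "staggering_backward": 100.0,
        "twisting_waist": 100.0,
    },
    "waist": {
        **{name: 100.0 for name in FALL_ACTIVITIES},
        **{name: 100.0 for name in ADL_ACTIVITIES},
    },
    "foot": {
        **{name: 100.0 for name in FALL_ACTIVITIES},
        "walking": 6.7,
        "bending_over": 100.0,
        "taking_stairs": 0.0,
        "sit_chair": 100.0,
        "sit_lie_mattress": 100.0,
        "stretching_shoulder": 100.0,
        "staggering_forward": 100.0,
        "staggering_backward": 100.0,
        "twisting_waist": 100.0,
    },
}

#: trials per activity per segment in the reference protocol
#: (15 subjects x 3 repetitions)
REFERENCE_TRIALS_PER_ACTIVITY = 45


def classify_outcome(truth: str, alarmed: bool) -> str:
    """Map (ground truth, alarm raised?) to TP / FP / TN / FN."""
    if truth not in ("fall", "adl"):
        raise ValueError(f"truth must be 'fall' or 'adl', got {truth!r}")
    if truth == "fall":
        return "TP" if alarmed else "FN"
    return "FP" if alarmed else "TN"


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial (one trace)."""

    activity: str
    segment: str
    truth: str
    alarmed: bool
    outcome: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", classify_outcome(self.truth, self.alarmed))


def correct_rate(results: Sequence[TrialResult]) -> float:
    """Percent of trials classified correctly (TP or TN), to one decimal."""
    if not results:
        raise ValueError("correct_rate requires at least one trial")
    good = sum(1 for r in results if r.outcome in ("TP", "TN"))
    return round(100.0 * good / len(results), 1)


@dataclass
class SegmentReport:
    """Per-activity correct rates and pooled metrics for one placement.

    Metrics are ``None`` when the corresponding trial category is absent
    (a partial report).
    """

    segment: str
    per_activity: dict[str, float]
    counts: dict[str, int]
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        """Per-activity table mirroring the reference report layout."""
        rows = [
            {"activity": a, "category": ACTIVITY_CATEGORY.get(a, "?"),
             "correct_rate_pct": r}
            for a, r in self.per_activity.items()
        ]
        return pd.DataFrame(rows, columns=["activity", "category", "correct_rate_pct"])


def segment_report(results: Sequence[TrialResult]) -> SegmentReport:
    """Aggregate trial outcomes for one segment into a report.

    Sensitivity and specificity are computed from pooled counts, not from the
    unweighted mean of per-activity rates (the two agree when every activity
    has the same trial count, as in the balanced protocol).
    """
    if not results:
        raise ValueError("segment_report requires at least one trial")
    segments = {r.segment for r in results}
    if len(segments) != 1:
        raise ValueError(f"results span multiple segments: {sorted(segments)}")
    (segment,) = segments

    counts = Counter(r.outcome for r in results)
    tp, fp = counts.get("TP", 0), counts.get("FP", 0)
    tn, fn = counts.get("TN", 0), counts.get("FN", 0)

    per_activity: dict[str, float] = {}
    for activity in dict.fromkeys(r.activity for r in results):
        per_activity[activity] = correct_rate(
            [r for r in results if r.activity == activity]
        )

    sensitivity = round(100.0 * tp / (tp + fn), 1) if tp + fn else None
    specificity = round(100.0 * tn / (tn + fp), 1) if tn + fp else None
    accuracy = round(100.0 * (tp + tn) / len(results), 1)
    return SegmentReport(
        segment=segment,
        per_activity=per_activity,
        counts={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
    )


def evaluate_trials(
    traces: Sequence[LabeledTrace], cfg: DetectorConfig | None = None
) -> list[TrialResult]:
    """Run the detector over labelled traces and classify each trial."""
    cfg = cfg or DetectorConfig()
    return [
        TrialResult(
            activity=lt.spec.name,
            segment=lt.spec.segment,
            truth=lt.truth,
            alarmed=bool(detect_falls(lt.trace, cfg)),
        )
        for lt in traces
    ]


def trials_from_rates(
    segment: str,
    rates: Mapping[str, float],
    n_per_activity: int = REFERENCE_TRIALS_PER_ACTIVITY,
    categories: Mapping[str, str] = ACTIVITY_CATEGORY,
) -> list[TrialResult]:
    """Reconstruct balanced-count trial outcomes from printed correct rates.

    Each activity contributes ``n_per_activity`` trials of which
    ``round(rate / 100 * n)`` were classified correctly — the inverse of how
    the printed per-activity rates were produced under the balanced protocol.
    Feeding the result to :func:`segment_report` recomputes the study's
    aggregate sensitivity/specificity/accuracy from its printed table.
    """
    out: list[TrialResult] = []
    for activity, rate in rates.items():
        truth = categories[activity]
        n_correct = int(round(rate / 100.0 * n_per_activity))
        correct_alarm = truth == "fall"  # a correct fall trial alarmed; ADL did not
        for i in range(n_per_activity):
            correct = i < n_correct
            alarmed = correct_alarm if correct else not correct_alarm
            out.append(
                TrialResult(activity=activity, segment=segment, truth=truth,
                            alarmed=alarmed)
            )
    return out
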