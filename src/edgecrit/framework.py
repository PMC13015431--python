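"""Edge-of-synchrony prediction table and regime-shift classification.

The edge-of-synchrony model makes signed predictions for how four metric
families move when the system shifts between the asynchronous regime, the
critical point, and the synchronous regime:

* LRTCs (first log-cumulant) index *distance* from criticality only — they
  increase when moving toward the critical point from either side;
* the spectral slope indexes *direction* — steeper toward the synchronous
  regime, flatter toward the asynchronous one;
* under edge-of-synchrony, low-frequency oscillatory power and variability
  move inversely: synchronous-ward shifts raise power and reduce
  variability, asynchronous-ward shifts do the opposite.

``classify_shift`` matches an observed direction pattern against these
predictions; the empirically salient "LRTC up + slope steeper + variability
up" combination is labeled inconsistent with edge-of-synchrony criticality
(variability should have dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from collections.abc import Iterable, Mapping


class Metric(str, Enum):
    LRTC_C1 = "lrtc_c1"
    SPECTRAL_SLOPE = "spectral_slope"   # chi; increase = steeper
    LF_POWER = "lf_power"
    LF_CV = "lf_cv"


class Direction(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"


class Shift(str, Enum):
    """Hypothesized regime shifts (the model's vocabulary)."""

    TOWARD_CRITICALITY_FROM_ASYNCHRONOUS = "toward_criticality_from_asynchronous"
    TOWARD_ASYNCHRONOUS = "toward_asynchronous"
    TOWARD_SYNCHRONOUS_PAST_CRITICAL = "toward_synchronous_past_critical"
    NO_SHIFT = "no_shift"


class Verdict(str, Enum):
    TOWARD_CRITICALITY_FROM_ASYNCHRONOUS = Shift.TOWARD_CRITICALITY_FROM_ASYNCHRONOUS.value
    TOWARD_ASYNCHRONOUS = Shift.TOWARD_ASYNCHRONOUS.value
    TOWARD_SYNCHRONOUS_PAST_CRITICAL = Shift.TOWARD_SYNCHRONOUS_PAST_CRITICAL.value
    NO_SHIFT = Shift.NO_SHIFT.value
    INCONSISTENT = "inconsistent_with_edge_of_synchrony"


@dataclass(frozen=True)
class MetricDelta:
    metric: Metric
    direction: Direction
    magnitude: float | None = None  # optional standardized effect


@dataclass(frozen=True)
class RegimeVerdict:
    verdict: Verdict
    matched_predictions: Mapping[Metric, bool]
    confident: bool = True  # False when power/cv were unavailable

    def to_json(self) -> str:
        import json

        return json.dumps(dict(
            verdict=self.verdict.value, confident=self.confident,
            matched_predictions={m.value: bool(v)
                                 for m, v in self.matched_predictions.items()}))

    def report(self) -> str:
        flags = ", ".join(f"{m.value}:{'ok' if v else 'x'}"
                          for m, v in self.matched_predictions.items())
        conf = "" if self.confident else " (partial pattern)"
        return f"verdict={self.verdict.value}{conf}; agreement: {flags}"


_PATTERNS: dict[Shift, dict[Metric, Direction]] = {
    # starting at criticality, drifting into the asynchronous regime:
    Shift.TOWARD_ASYNCHRONOUS: {
        Metric.LRTC_C1: Direction.DECREASE,
        Metric.SPECTRAL_SLOPE: Direction.DECREASE,  # flatter
        Metric.LF_POWER: Direction.DECREASE,
        Metric.LF_CV: Direction.INCREASE,
    },
    # from the asynchronous regime toward the critical point:
    Shift.TOWARD_CRITICALITY_FROM_ASYNCHRONOUS: {
        Metric.LRTC_C1: Direction.INCREASE,
        Metric.SPECTRAL_SLOPE: Direction.INCREASE,  # steeper
        Metric.LF_POWER: Direction.INCREASE,
        Metric.LF_CV: Direction.DECREASE,
    },
    # crossing from critical into the synchronous regime:
    Shift.TOWARD_SYNCHRONOUS_PAST_CRITICAL: {
        Metric.LRTC_C1: Direction.DECREASE,
        Metric.SPECTRAL_SLOPE: Direction.INCREASE,
        Metric.LF_POWER: Direction.INCREASE,
        Metric.LF_CV: Direction.DECREASE,
    },
    Shift.NO_SHIFT: {m: Direction.NONE for m in Metric},
}


def predicted_pattern(shift: Shift | str) -> tuple[MetricDelta, ...]:
    """The edge-of-synchrony sign table for a hypothesized regime shift."""
    try:
        shift = Shift(shift)
    except ValueError as exc:
        raise ValueError(f"unknown shift {shift!r}; vocabulary: "
                         f"{[s.value for s in Shift]}") from exc
    return tuple(MetricDelta(metric=m, direction=d)
                 for m, d in _PATTERNS[shift].items())


def classify_shift(observed: Iterable[MetricDelta]) -> RegimeVerdict:
    """Classify an observed pattern of metric changes.

    LRTC and slope entries are required; power/cv are optional (their
    absence lowers confidence but still permits classification on the
    available metrics).  An exact match to a predicted pattern returns that
    shift's verdict; a pattern whose LRTC/slope agree with a candidate shift
    but whose power or variability contradicts it — notably LRTC up + slope
    steeper + variability up — is inconsistent with edge-of-synchrony.
    """
    obs = {d.metric: d.direction for d in observed}
    if Metric.LRTC_C1 not in obs or Metric.SPECTRAL_SLOPE not in obs:
        raise ValueError("lrtc_c1 and spectral_slope entries are required")
    confident = Metric.LF_POWER in obs and Metric.LF_CV in obs

    if all(d == Direction.NONE for d in obs.values()):
        matched = {m: True for m in obs}
        return RegimeVerdict(Verdict.NO_SHIFT, matched, confident)

    best = None
    for shift, pattern in _PATTERNS.items():
        if shift is Shift.NO_SHIFT:
            continue
        agree = {m: (obs[m] == pattern[m]) for m in obs}
        core_ok = agree[Metric.LRTC_C1] and agree[Metric.SPECTRAL_SLOPE]
        if all(agree.values()):
            return RegimeVerdict(Verdict(shift.value), agree, confident)
        if core_ok and best is None:
            best = agree
    if best is not None:
        # core metrics fit a shift but power/variability contradict it
        return RegimeVerdict(Verdict.INCONSISTENT, best, confident)
    return RegimeVerdict(Verdict.INCONSISTENT,
                         {m: False for m in obs}, confident)
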