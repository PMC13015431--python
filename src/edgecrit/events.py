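"""Event typing by RT quartiles and pre-stimulus epoch extraction.

Responses are split per subject and modality into three event types by the
quartiles of the RT distribution — fast (rt <= Q1), slow (rt >= Q3), average
(in between) — plus a fourth "passive" type drawn at random from the
no-response condition as a non-task reference.  The analysis window is the
10 s immediately preceding each stimulus (-10 s to -0.005 s), so epochs of
nearby events deliberately overlap.

Quartiles use the linear-interpolation ("type 7") convention by default;
ties at the boundaries are inclusive via <= / >=.  Only correct, responded
trials enter the quantile computation.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .synth import ResponseRecord, StimulusSchedule

logger = logging.getLogger(__name__)

EVENT_TYPES = ("fast", "average", "slow", "passive")


class TooFewTrialsError(ValueError):
    """Raised when too few responded trials exist to define quartiles."""


class EmptyEpochSetError(ValueError):
    """Raised when no event leaves a full pre-stimulus window."""


@dataclass(frozen=True)
class Recording:
    """A continuous multichannel signal segment.

    ``valid_intervals`` (seconds, in recording time) restricts epoch
    extraction: a window must fit entirely inside one interval, so windows
    reaching into inter-run breaks are dropped.  Defaults to the whole
    recording.
    """

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    ch_names: tuple[str, ...]
    start_time: float = 0.0
    valid_intervals: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class EpochSet:
    """Per-event pre-stimulus windows with event-type labels.

    ``data`` is (n_epochs, n_channels, n_times); ``window`` is relative to
    stimulus onset and must end strictly before it.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    labels: list[str]
    ch_names: tuple[str, ...]
    subject_id: str = ""
    modality: str = ""
    group: str = ""
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.window[1] >= 0:
            raise ValueError("window must end strictly before stimulus onset")
        if self.data.ndim != 3 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_epochs, n_channels, n_times)")

    def __len__(self) -> int:
        return self.data.shape[0]

    def save(self, path) -> None:
        """Write samples to .npz with a JSON sidecar of the metadata."""
        np.savez(path, data=self.data, onsets=self.onsets)
        meta = dict(fs=self.fs, window=list(self.window), labels=self.labels,
                    ch_names=list(self.ch_names), subject_id=self.subject_id,
                    modality=self.modality, group=self.group)
        with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "EpochSet":
        arrs = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        with open(str(path).removesuffix(".npz") + ".json") as fh:
            meta = json.load(fh)
        return cls(data=arrs["data"], fs=meta["fs"], window=tuple(meta["window"]),
                   labels=meta["labels"], ch_names=tuple(meta["ch_names"]),
                   subject_id=meta["subject_id"], modality=meta["modality"],
                   group=meta["group"], onsets=arrs["onsets"])


def rt_quartiles(rts: Sequence[float],
                 method: str = "linear") -> tuple[float, float]:
    """(Q1, Q3) of the responded RTs under the given quantile convention."""
    arr = np.asarray([r for r in rts if r is not None and np.isfinite(r)],
                     dtype=float)
    if arr.size < 8:
        raise TooFewTrialsError(
            f"need >= 8 responded trials to define quartiles, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    return float(q1), float(q3)


def classify_rts(rts: Sequence[float | None],
                 method: str = "linear") -> list[str | None]:
    """Label each responded trial fast / average / slow by RT quartiles.

    fast: rt <= Q1; slow: rt >= Q3; average otherwise.  Missing RTs
    (None/NaN, i.e. omissions) are excluded from the quantiles and receive
    a ``None`` label.
    """
    q1, q3 = rt_quartiles([r for r in rts if r is not None], method=method)
    labels: list[str | None] = []
    for r in rts:
        if r is None or not np.isfinite(r):
            labels.append(None)
        elif r <= q1:
            labels.append("fast")
        elif r >= q3:
            labels.append("slow")
        else:
            labels.append("average")
    return labels


def classify_responses(records: Sequence[ResponseRecord],
                       method: str = "linear") -> list[str | None]:
    """Label :class:`ResponseRecord` trials; incorrect or omitted trials are
    excluded from the quantile computation and labeled ``None``."""
    usable = [r.rt if (r.correct and r.rt is not None) else None
              for r in records]
    return classify_rts(usable, method=method)


def select_passive(passive_schedule: StimulusSchedule, n: int = 25,
                   seed: int | None = None) -> np.ndarray:
    """Uniformly sample ``n`` stimulus onsets (both streams, stratified
    evenly) from a passive run, without replacement, seed-reproducible."""
    rng = np.random.default_rng(seed)
    streams = [passive_schedule.onsets(s) for s in ("auditory", "visual")]
    total = sum(len(s) for s in streams)
    if total < n:
        warnings.warn(f"only {total} passive stimuli available; selecting all",
                      stacklevel=2)
        return np.sort(np.concatenate(streams))
    take = [min(n // 2, len(streams[0])), 0]
    take[1] = min(n - take[0], len(streams[1]))
    take[0] = n - take[1]
    chosen = [rng.choice(s, size=t, replace=False)
              for s, t in zip(streams, take)]
    return np.sort(np.concatenate(chosen))


def extract_epochs(recording: Recording,
                   onsets: Sequence[float],
                   labels: Sequence[str] | None = None,
                   window: tuple[float, float] = (-10.0, -0.005),
                   **metadata) -> EpochSet:
    """Cut fixed-length pre-stimulus windows out of a continuous recording.

    Events whose window extends before the recording (or outside a valid
    interval, e.g. into an inter-run break) are dropped with a logged count.
    The per-epoch sample count is round((window[1]-window[0]) * fs); samples
    are copied bit-for-bit from the recording.  Overlapping windows are
    allowed.  Raises :class:`EmptyEpochSetError` when nothing survives.
    """
    if labels is None:
        labels = ["" for _ in onsets]
    if len(labels) != len(onsets):
        raise ValueError("labels and onsets must align")
    n_times = int(round((window[1] - window[0]) * recording.fs))
    intervals = recording.valid_intervals or \
        ((recording.start_time, recording.end_time),)

    kept_data, kept_labels, kept_onsets, dropped = [], [], [], 0
    for onset, label in zip(onsets, labels):
        t0, t1 = onset + window[0], onset + window[1]
        if not any(a - 1e-9 <= t0 and t1 <= b + 1e-9 for a, b in intervals):
            dropped += 1
            continue
        i0 = int(round((t0 - recording.start_time) * recording.fs))
        if i0 < 0 or i0 + n_times > recording.data.shape[1]:
            dropped += 1
            continue
        kept_data.append(recording.data[:, i0:i0 + n_times])
        kept_labels.append(label)
        kept_onsets.append(onset)
    if dropped:
        logger.info("extract_epochs: dropped %d/%d events with incomplete "
                    "pre-stimulus windows", dropped, len(onsets))
    if not kept_data:
        raise EmptyEpochSetError("no event leaves a complete pre-stimulus window")
    return EpochSet(data=np.stack(kept_data), fs=recording.fs, window=window,
                    labels=kept_labels, ch_names=recording.ch_names,
                    onsets=np.asarray(kept_onsets), **metadata)
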