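"""Binarization of continuous multichannel recordings into event rasters.

Continuous signals (e.g. MEG magnetometer traces) are z-scored per channel
and thresholded at +/- ``threshold_sd`` standard deviations; each maximal
excursion beyond the threshold contributes one event at the sample of
largest absolute amplitude, treating both polarities symmetrically.  Events
are then collected into time bins to form the binary raster on which
avalanches are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cbm import Raster
from .errors import DegenerateChannelError, InvalidArgumentError

__all__ = [
    "Recording",
    "EventTrain",
    "zscore",
    "detect_events",
    "bin_events",
    "mean_inter_event_interval",
    "auto_bin_width",
]


@dataclass
class Recording:
    """Continuous channels x samples data with its sampling rate."""

    samples: np.ndarray  # (n_channels, n_samples) float64
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidArgumentError("samples must be channels x time")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if np.isnan(self.samples).any():
            raise InvalidArgumentError("recording contains NaN samples")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise InvalidArgumentError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EventTrain:
    """Per-channel sorted event sample indices."""

    events: list[np.ndarray]
    n_samples: int
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [np.asarray(e, dtype=np.int64) for e in self.events]
        for e in self.events:
            if e.size and (np.any(np.diff(e) <= 0) or e[0] < 0 or e[-1] >= self.n_samples):
                raise InvalidArgumentError(
                    "event indices must be strictly increasing within [0, n_samples)"
                )

    @property
    def n_channels(self) -> int:
        return len(self.events)

    @property
    def n_events(self) -> int:
        return sum(e.size for e in self.events)


def zscore(recording: Recording) -> Recording:
    """Standardise each channel to mean 0 and SD 1 (population SD).

    Raises :class:`DegenerateChannelError` naming the first constant channel.
    """
    x = recording.samples
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateChannelError(recording.channel_ids[int(bad[0])])
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return Recording(
        samples=z,
        sampling_rate=recording.sampling_rate,
        channel_ids=list(recording.channel_ids),
    )


def detect_events(recording: Recording, threshold_sd: float = 3.0) -> EventTrain:
    """One event per supra-threshold excursion, at its absolute extremum.

    The recording is assumed z-scored.  An excursion is a maximal run of
    samples with ``|value| > threshold_sd``; the event is placed at the
    sample of maximum absolute amplitude in the run (earliest sample on
    ties).  Positive and negative deflections are treated alike.
    """
    if threshold_sd <= 0:
        raise InvalidArgumentError("threshold_sd must be positive")
    trains = []
    for ch in np.abs(recording.samples):
        above = ch > threshold_sd
        if not above.any():
            trains.append(np.empty(0, dtype=np.int64))
            continue
        padded = np.concatenate(([False], above, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        peaks = np.array(
            [s + int(np.argmax(ch[s:e])) for s, e in zip(starts, ends)],
            dtype=np.int64,
        )
        trains.append(peaks)
    return EventTrain(
        events=trains,
        n_samples=recording.n_samples,
        channel_ids=list(recording.channel_ids),
    )


def mean_inter_event_interval(events: EventTrain) -> float:
    """Mean interval between consecutive events pooled across channels.

    This is the population inter-event interval conventionally used to set
    the avalanche bin width: all channels' event times are merged and the
    mean gap between successive events taken, in samples.
    """
    merged = np.sort(np.concatenate([e for e in events.events]))
    if merged.size < 2:
        return float("nan")
    return float(np.diff(merged).mean())


def auto_bin_width(events: EventTrain) -> int:
    """Default bin width: the rounded mean inter-event interval (floor 1)."""
    iei = mean_inter_event_interval(events)
    if not np.isfinite(iei):
        return 1
    return max(1, int(round(iei)))


def bin_events(
    events: EventTrain,
    bin_width: int,
    sampling_rate: float | None = None,
) -> Raster:
    """Binary raster: entry (c, b) is 1 iff channel c has an event in bin b."""
    if bin_width < 1:
        raise InvalidArgumentError("bin_width must be >= 1")
    n_bins = int(np.ceil(events.n_samples / bin_width))
    data = np.zeros((events.n_channels, max(n_bins, 1)), dtype=np.uint8)
    for c, e in enumerate(events.events):
        if e.size:
            data[c, e // bin_width] = 1
    return Raster(data=data, bin_width=int(bin_width), sampling_rate=sampling_rate)
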