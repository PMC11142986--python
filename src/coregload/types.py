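"""Core data containers shared across the pipeline.

A :class:`Recording` is a uniformly sampled channels-by-samples matrix with a
rate, channel labels and per-channel physical units.  An :class:`EventTable`
is an ordered list of (sample, label, attributes) markers on the timeline of
one recording.  Gaze events (fixations, saccades, blinks) and epoch stacks
get small dedicated dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Dropout value written into the pupil channel while the eye is closed.
#: Zero is the common eye-tracker convention for lost samples.
PUPIL_SENTINEL = 0.0


class FormatError(ValueError):
    """Malformed interchange file (carries a line number when known)."""


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array.
    rate
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per row of ``data``.
    units
        One physical-unit string per channel (e.g. ``uV``, ``px``, ``au``).
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    units: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(self.units) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.units)} unit strings for {self.data.shape[0]} channels"
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

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D data row for ``label``."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.rate, list(self.channel_labels), list(self.units)
        )


@dataclass
class EventTable:
    """Ordered event markers on a recording's sample timeline."""

    sample: np.ndarray  # int64, nondecreasing
    label: list[str]
    attributes: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample = np.asarray(self.sample, dtype=np.int64)
        if self.sample.ndim != 1:
            raise ValueError("sample must be 1-D")
        if len(self.label) != self.sample.size:
            raise ValueError("label count must match sample count")
        if not self.attributes:
            self.attributes = [{} for _ in range(self.sample.size)]
        if len(self.attributes) != self.sample.size:
            raise ValueError("attributes count must match sample count")
        if self.sample.size > 1 and np.any(np.diff(self.sample) < 0):
            raise ValueError("event samples must be nondecreasing")

    def __len__(self) -> int:
        return int(self.sample.size)

    def __iter__(self):
        for i in range(len(self)):
            yield int(self.sample[i]), self.label[i], self.attributes[i]

    def select(self, labels) -> "EventTable":
        """Subset of rows whose label is in ``labels`` (order preserved)."""
        wanted = set(labels) if not isinstance(labels, str) else {labels}
        keep = [i for i, lab in enumerate(self.label) if lab in wanted]
        return EventTable(
            self.sample[keep],
            [self.label[i] for i in keep],
            [self.attributes[i] for i in keep],
        )

    def validate_against(self, rec: Recording) -> None:
        if len(self) and (self.sample.min() < 0 or self.sample.max() >= rec.n_samples):
            raise ValueError("event sample outside recording length")


@dataclass
class AffineMap:
    """Affine sample map from one timeline to another: ``dst = offset + scale*src``."""

    offset: float
    scale: float
    residuals: np.ndarray | None = None

    def apply(self, src_sample) -> np.ndarray:
        """Map source samples to destination samples, rounding half away from zero."""
        exact = self.offset + self.scale * np.asarray(src_sample, dtype=float)
        return np.asarray(
            np.sign(exact) * np.floor(np.abs(exact) + 0.5), dtype=np.int64
        )


@dataclass
class CoRegisteredSession:
    """EEG recording with eye-tracking channels appended on the EEG timeline."""

    eeg: Recording
    events: EventTable
    mapping: AffineMap
    et_channel_labels: list[str] = field(default_factory=list)


@dataclass
class BlinkEvent:
    onset: int
    offset: int  # half-open [onset, offset) in ET samples
    eye: str = "binocular"


@dataclass
class SaccadeEvent:
    onset: int
    offset: int
    peak_velocity: float
    amplitude: float
    eye: str = "binocular"

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValueError("saccade onset must precede offset")


@dataclass
class FixationEvent:
    onset: int
    offset: int
    duration_ms: float
    centroid: tuple[float, float]
    aoi: str | None = None

    def with_aoi(self, label: str | None) -> "FixationEvent":
        return replace(self, aoi=label)


@dataclass
class EpochSet:
    """Stack of fixed-length epochs plus per-epoch metadata."""

    epochs: np.ndarray  # (n, channels, samples)
    rate: float
    channel_labels: list[str]
    lock: str  # "stimulus" | "fixation"
    condition: list[str]
    anchor_sample: np.ndarray
    length_s: float = 2.0
    keep: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n, channels, samples)")
        n = self.epochs.shape[0]
        expected = int(round(self.length_s * self.rate))
        if n and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != length_s*rate = {expected}"
            )
        if len(self.condition) != n:
            raise ValueError("condition labels must match epoch count")
        self.anchor_sample = np.asarray(self.anchor_sample, dtype=np.int64)
        if self.anchor_sample.size != n:
            raise ValueError("anchor_sample must match epoch count")
        if self.keep is None:
            self.keep = np.ones(n, dtype=bool)
        else:
            self.keep = np.asarray(self.keep, dtype=bool)
            if self.keep.size != n:
                raise ValueError("keep mask must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self) -> "EpochSet":
        """Subset with keep == True."""
        m = self.keep
        return EpochSet(
            self.epochs[m],
            self.rate,
            list(self.channel_labels),
            self.lock,
            [c for c, k in zip(self.condition, m) if k],
            self.anchor_sample[m],
            self.length_s,
        )
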