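"""Core domain types shared across the pipeline.

All timestamps are seconds from recording start; all sample indices are
0-based integers on the common sample grid of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Channel identities of the armchair setup plus the two reference sensors.
MODALITIES = (
    "cECG",       # capacitively coupled ECG (backrest electrodes)
    "PPG",        # reflective photoplethysmography through cloth
    "BCG_OPT",    # optical ballistocardiogram against the backrest padding
    "BCG_EMFI",   # EMFi pressure-mat ballistocardiogram (seat)
    "HF_IMP_1",   # high-frequency impedance sensor 1
    "HF_IMP_2",   # high-frequency impedance sensor 2
    "ECG_REF",    # adhesive-electrode reference ECG
    "RESP_REF",   # pneumotachograph respiration reference
)

#: Cardiac channels the interval estimator may consume.
CARDIAC_MODALITIES = ("cECG", "PPG", "BCG_OPT", "BCG_EMFI")

#: Maneuver acronyms of the motion protocol.
MANEUVERS = ("TSL", "TSR", "S/S", "TT", "TTc", "HT", "LA", "RA", "REST")

AMPLITUDE_CLASSES = ("none", "low", "high")

#: Physiologic beat-to-beat interval range in ms (30-180 bpm).
INTERVAL_RANGE_MS = (333.0, 2000.0)

#: Marker ids attributed to the thorax (head=1 and arms=5,7 are excluded
#: from thorax motion estimation).
THORAX_MARKERS = (2, 3, 4, 6)


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class SignalChannel:
    """One sampled signal channel in arbitrary amplitude units."""

    modality: str
    samples: np.ndarray
    fs: float

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.samples = _as_float_array(self.samples, "samples")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.samples.size == 0:
            raise ValidationError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite (clip to rails, never NaN)")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def __eq__(self, other):
        return (
            isinstance(other, SignalChannel)
            and self.modality == other.modality
            and self.fs == other.fs
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class BeatAnnotations:
    """R-peak sample indices (0-based) on the common sample grid."""

    beat_samples: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.beat_samples, dtype=np.int64)
        if arr.ndim != 1:
            raise ValidationError("beat_samples must be one-dimensional")
        if arr.size and (np.any(np.diff(arr) <= 0) or arr[0] < 0):
            raise ValidationError("beat_samples must be strictly increasing and >= 0")
        self.beat_samples = arr

    def __len__(self):
        return self.beat_samples.size

    def times(self, fs: float) -> np.ndarray:
        return self.beat_samples / fs

    def __eq__(self, other):
        return isinstance(other, BeatAnnotations) and np.array_equal(
            self.beat_samples, other.beat_samples
        )


@dataclass
class MarkerTrajectory:
    """3-D displacement of one reflective marker, in mm."""

    marker_id: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self):
        if not 1 <= int(self.marker_id) <= 7:
            raise ValidationError("marker_id must be in 1..7")
        self.marker_id = int(self.marker_id)
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.z = _as_float_array(self.z, "z")
        if not (self.x.size == self.y.size == self.z.size):
            raise ValidationError("marker axes must have equal lengths")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")

    @property
    def n(self) -> int:
        return self.x.size

    def __eq__(self, other):
        return (
            isinstance(other, MarkerTrajectory)
            and self.marker_id == other.marker_id
            and self.fs == other.fs
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.z, other.z)
        )


@dataclass(frozen=True)
class ProtocolEpisode:
    """One entry of the motion protocol: a maneuver and its time slot."""

    maneuver: str
    amplitude_class: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.maneuver not in MANEUVERS:
            raise ValidationError(f"unknown maneuver {self.maneuver!r}")
        if self.amplitude_class not in AMPLITUDE_CLASSES:
            raise ValidationError(f"unknown amplitude class {self.amplitude_class!r}")
        if not self.t_start < self.t_end:
            raise ValidationError("episode must satisfy t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Recording:
    """A synchronized multimodal session.

    All channels and marker trajectories share one sampling rate and
    length; reference beats index into that common grid.
    """

    channels: dict
    ref_beats: Optional[BeatAnnotations] = None
    markers: list = field(default_factory=list)
    episodes: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not self.channels:
            raise ValidationError("Recording must contain at least one channel")
        fss = {c.fs for c in self.channels.values()}
        lens = {c.n for c in self.channels.values()}
        if len(fss) > 1 or len(lens) > 1:
            raise ValidationError("all channels must share fs and length")
        for name, ch in self.channels.items():
            if name != ch.modality:
                raise ValidationError(
                    f"channel key {name!r} does not match modality {ch.modality!r}"
                )
        n = lens.pop()
        fs = fss.pop()
        if self.ref_beats is not None and len(self.ref_beats):
            if self.ref_beats.beat_samples[-1] >= n:
                raise ValidationError("ref_beats index beyond channel length")
        for m in self.markers:
            if m.fs != fs or m.n != n:
                raise ValidationError(
                    f"marker {m.marker_id} not aligned to channels "
                    f"(fs {m.fs} vs {fs}, length {m.n} vs {n})"
                )
        eps = sorted(self.episodes, key=lambda e: e.t_start)
        for a, b in zip(eps, eps[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValidationError(
                    f"episodes overlap: {a.maneuver}@{a.t_start} and {b.maneuver}@{b.t_start}"
                )

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).n

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def __eq__(self, other):
        return (
            isinstance(other, Recording)
            and self.channels == other.channels
            and self.ref_beats == other.ref_beats
            and self.markers == other.markers
            and self.episodes == other.episodes
            and self.meta == other.meta
        )


@dataclass
class IntervalEstimate:
    """A timestamped beat-to-beat interval estimate.

    ``source`` is LIE (self-similarity estimator), PT (Pan-Tompkins on
    cECG), FUSED (mixed-level decision rule) or REF (derived from
    reference annotations). ``reliability`` is the LIE gating ratio;
    ``provenance`` records which estimator supplied a FUSED value.
    """

    t: float
    interval_ms: float
    source: str
    reliability: Optional[float] = None
    provenance: Optional[str] = None

    def __post_init__(self):
        if self.source not in ("LIE", "PT", "FUSED", "REF"):
            raise ValidationError(f"unknown source {self.source!r}")
        if self.reliability is not None and self.reliability < 0:
            raise ValidationError("reliability must be >= 0")
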