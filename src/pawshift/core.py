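"""Shared domain types: trial timeline, tracked-point series, condition labels.

The experiment these types describe: a head-fixed mouse sits idle for 120 s
(baseline), receives 120 s of paired brush strokes on its hidden forelimb and
on a visible artificial forelimb (pairing), and at 240 s a sharp object is
rapidly moved next to the artificial limb and held there for 10 s (threat).
Two high-speed cameras image the face at 200 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ParameterError

#: Valid object conditions: a limb-shaped replica, a white block, or nothing.
OBJECT_CONDITIONS = ("artificial_limb", "block", "none")
#: Valid brush-pairing conditions; "none" means threat-only (no stroking).
PAIRING_CONDITIONS = ("synchronous", "asynchronous", "none")
#: Camera sides; body-part names are namespaced by side (e.g. "right_pupil_center").
CAMERA_SIDES = ("right", "left")


def validate_conditions(object_condition: str, pairing_condition: str) -> None:
    """Check condition labels and their coupling (object none => pairing none)."""
    if object_condition not in OBJECT_CONDITIONS:
        raise ParameterError(
            f"unknown object condition {object_condition!r}; "
            f"expected one of {OBJECT_CONDITIONS}"
        )
    if pairing_condition not in PAIRING_CONDITIONS:
        raise ParameterError(
            f"unknown pairing condition {pairing_condition!r}; "
            f"expected one of {PAIRING_CONDITIONS}"
        )
    if (object_condition == "none") != (pairing_condition == "none"):
        raise ParameterError(
            "object condition 'none' requires pairing condition 'none' and "
            f"vice versa; got ({object_condition!r}, {pairing_condition!r})"
        )


@dataclass(frozen=True)
class TrialTimeline:
    """Timing of one trial, in seconds from trial start.

    Baseline runs over [0, pairing_start), brush pairing over
    [pairing_start, threat_onset), and the threat is presented at
    ``threat_onset`` and held for ``threat_hold`` seconds.  ``frame_rate``
    is the camera rate in Hz; the recording covers exactly
    ``threat_onset + threat_hold`` seconds.
    """

    pairing_start: float = 120.0
    threat_onset: float = 240.0
    threat_hold: float = 10.0
    frame_rate: float = 200.0

    #: Baseline always starts at t = 0.
    baseline_start: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.pairing_start < self.threat_onset:
            raise ParameterError(
                "require 0 < pairing_start < threat_onset; got "
                f"pairing_start={self.pairing_start}, threat_onset={self.threat_onset}"
            )
        if self.threat_hold <= 0:
            raise ParameterError(f"threat_hold must be > 0, got {self.threat_hold}")
        if self.frame_rate <= 0:
            raise ParameterError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def duration(self) -> float:
        """Total recorded duration in seconds."""
        return self.threat_onset + self.threat_hold

    @property
    def pairing_duration(self) -> float:
        return self.threat_onset - self.pairing_start

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from trial start."""
        return np.arange(self.n_frames) / self.frame_rate

    def frame_of(self, t: float) -> int:
        """Index of the frame at time ``t`` (frames are left-aligned)."""
        return int(round(t * self.frame_rate))

    def to_dict(self) -> dict:
        return {
            "pairing_start": self.pairing_start,
            "threat_onset": self.threat_onset,
            "threat_hold": self.threat_hold,
            "frame_rate": self.frame_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialTimeline":
        return cls(
            pairing_start=float(d["pairing_start"]),
            threat_onset=float(d["threat_onset"]),
            threat_hold=float(d["threat_hold"]),
            frame_rate=float(d["frame_rate"]),
        )


@dataclass
class PointTrack:
    """Per-frame coordinates of one tracked body point.

    ``x``/``y`` are image coordinates in pixels, ``confidence`` is the
    tracker's per-frame likelihood in [0, 1].
    """

    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.x)
        if len(self.y) != n or len(self.confidence) != n:
            raise ParameterError("x, y and confidence must have equal length")
        finite = self.confidence[np.isfinite(self.confidence)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ParameterError("confidence values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)

    def __iter__(self) -> Iterator[np.ndarray]:  # allows x, y, c = track
        return iter((self.x, self.y, self.confidence))
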