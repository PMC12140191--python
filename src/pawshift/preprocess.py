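"""Turn raw tracks into analysis-ready signals.

Pipeline order is interpolate -> derive -> normalize: low-confidence samples
are filled first, derived signals (pupil diameter, point speed) are computed
from filled tracks, and normalization is applied last.  Two normalizations
are used in the paradigm: subtraction of the mean over the 120 s pre-pairing
baseline (for whole-trial displays) and subtraction of the mean over the 1 s
preceding threat onset (to isolate the threat-evoked response).  The
significance analysis itself runs on unnormalized traces; see
:mod:`pawshift.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .core import PointTrack, TrialTimeline
from .errors import NoUsableTrialsError, ParameterError, UnusableTrackError

_EPS = 1e-9

#: Analysis signals: name -> (camera side, body part(s), kind, signed flag).
#: ``signed`` signals are multiplied by the per-eye toward-threat sign so that
#: positive values always mean "gaze toward the threat".
SIGNAL_DEFS = {
    "right_pupil_x": ("right", "right_pupil_center", "x", True),
    "right_pupil_y": ("right", "right_pupil_center", "y", False),
    "left_pupil_x": ("left", "left_pupil_center", "x", True),
    "left_pupil_y": ("left", "left_pupil_center", "y", False),
    "right_pupil_diameter": ("right", ("right_pupil_top", "right_pupil_bottom"), "diameter", False),
    "left_pupil_diameter": ("left", ("left_pupil_top", "left_pupil_bottom"), "diameter", False),
    "left_ear_speed": ("left", "left_ear", "speed", False),
    "left_whisker_speed": ("left", "left_whisker", "speed", False),
}

DEFAULT_SIGNALS = tuple(SIGNAL_DEFS)


@dataclass
class NormalizedSignal:
    """A per-trial scalar time series with its normalization state.

    ``times`` are seconds from trial start; ``values`` are px (positions,
    diameter) or px/s (speeds).
    """

    times: np.ndarray
    values: np.ndarray
    normalization: str = "none"  # none | baseline_mean | prethreat_1s
    source: str = ""
    mouse_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ParameterError("times and values must have the same shape")


class InterpolationResult(NamedTuple):
    values: np.ndarray
    fraction_replaced: float


def interpolate_low_confidence(
    values, confidence, confidence_threshold: float = 0.9
) -> InterpolationResult:
    """Replace low-confidence samples by linear interpolation.

    Samples with confidence below the threshold (or NaN value) are replaced
    by linear interpolation between the flanking valid samples; leading and
    trailing gaps are held at the nearest valid value.  Returns the filled
    series and the fraction of samples replaced.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ParameterError(f"confidence_threshold must be in [0, 1], got {confidence_threshold}")
    values = np.asarray(values, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    if values.shape != confidence.shape:
        raise ParameterError("values and confidence must have the same shape")
    bad = (confidence < confidence_threshold) | np.isnan(values)
    if bad.all():
        raise UnusableTrackError(
            f"all {values.size} samples fall below confidence threshold {confidence_threshold}"
        )
    if not bad.any():
        return InterpolationResult(values.copy(), 0.0)
    idx = np.arange(values.size)
    filled = values.copy()
    filled[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return InterpolationResult(filled, float(bad.mean()))


def interpolate_track(
    track: PointTrack, confidence_threshold: float = 0.9
) -> tuple[PointTrack, float]:
    """Apply :func:`interpolate_low_confidence` to both coordinates of a track."""
    fx = interpolate_low_confidence(track.x, track.confidence, confidence_threshold)
    fy = interpolate_low_confidence(track.y, track.confidence, confidence_threshold)
    conf = np.clip(track.confidence, 0.0, 1.0)
    frac = max(fx.fraction_replaced, fy.fraction_replaced)
    return PointTrack(fx.values, fy.values, conf), frac


def _as_signal(signal, timeline: TrialTimeline) -> NormalizedSignal:
    if isinstance(signal, NormalizedSignal):
        return signal
    values = np.asarray(signal, dtype=float)
    times = np.arange(values.size) / timeline.frame_rate
    return NormalizedSignal(times=times, values=values)


def _window_mean(sig: NormalizedSignal, start: float, stop: float, what: str) -> float:
    mask = (sig.times >= start - _EPS) & (sig.times < stop - _EPS)
    if not mask.any():
        raise ParameterError(f"{what} window [{start}, {stop}) s contains no samples")
    dt = float(np.median(np.diff(sig.times))) if sig.times.size > 1 else 0.0
    # the signal must cover the window, not merely intersect it
    if sig.times[0] > start + _EPS or sig.times[-1] < stop - dt - _EPS:
        raise ParameterError(
            f"signal [{sig.times[0]}, {sig.times[-1]}] s does not cover the "
            f"{what} window [{start}, {stop}) s"
        )
    return float(sig.values[mask].mean())


def baseline_normalize(signal, timeline: TrialTimeline) -> NormalizedSignal:
    """Subtract the mean over the 120 s pre-pairing baseline [0, pairing_start)."""
    sig = _as_signal(signal, timeline)
    if sig.times.size == 0:
        raise ParameterError("empty signal")
    mean = _window_mean(sig, 0.0, timeline.pairing_start, "baseline")
    return replace(sig, values=sig.values - mean, normalization="baseline_mean")


def prethreat_normalize(signal, timeline: TrialTimeline) -> NormalizedSignal:
    """Subtract the mean over the 1 s window preceding threat onset."""
    sig = _as_signal(signal, timeline)
    if sig.times.size == 0:
        raise ParameterError("empty signal")
    mean = _window_mean(sig, timeline.threat_onset - 1.0, timeline.threat_onset, "pre-threat")
    return replace(sig, values=sig.values - mean, normalization="prethreat_1s")


def pupil_diameter(top, bottom) -> np.ndarray:
    """Per-frame pupil diameter |y_top - y_bottom| in px.

    Accepts :class:`PointTrack` objects or bare y arrays.
    """
    ty = top.y if isinstance(top, PointTrack) else np.asarray(top, dtype=float)
    by = bottom.y if isinstance(bottom, PointTrack) else np.asarray(bottom, dtype=float)
    if ty.shape != by.shape:
        raise ParameterError(f"length mismatch: {ty.shape} vs {by.shape}")
    return np.abs(ty - by)


def point_speed(track, frame_rate: float) -> np.ndarray:
    """Per-frame speed (px/s): Euclidean frame-to-frame displacement x rate.

    The first sample is duplicated so the output keeps the input length.
    Accepts a :class:`PointTrack` or an (n, 2) array of x/y coordinates.
    """
    if isinstance(track, PointTrack):
        x, y = track.x, track.y
    else:
        arr = np.asarray(track, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ParameterError("expected a PointTrack or an (n, 2) coordinate array")
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 2:
        raise ParameterError("point_speed requires at least 2 frames")
    speed = np.hypot(np.diff(x), np.diff(y)) * frame_rate
    return np.concatenate([speed[:1], speed])


def boxcar_smooth(values, width_frames: int) -> np.ndarray:
    """Optional boxcar smoothing (off by default throughout the pipeline)."""
    if width_frames < 1:
        raise ParameterError("width_frames must be >= 1")
    values = np.asarray(values, dtype=float)
    kernel = np.ones(width_frames) / width_frames
    pad = width_frames // 2
    padded = np.pad(values, (pad, width_frames - 1 - pad), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def extract_signal(
    tracks: Mapping[str, PointTrack],
    name: str,
    timeline: TrialTimeline,
    toward_threat_sign: Mapping[str, float] | None = None,
    confidence_threshold: float = 0.9,
) -> np.ndarray:
    """Compute one raw analysis signal from a trial's tracks.

    Low-confidence samples are interpolated first; derived signals (diameter,
    speed) are computed from the filled tracks; signed signals are multiplied
    by the per-eye toward-threat sign.  No normalization is applied.
    """
    if name not in SIGNAL_DEFS:
        raise ParameterError(f"unknown signal {name!r}; known: {sorted(SIGNAL_DEFS)}")
    side, parts, kind, signed = SIGNAL_DEFS[name]
    sign = 1.0
    if signed and toward_threat_sign is not None:
        sign = float(toward_threat_sign.get(side, 1.0))

    def filled(part: str) -> PointTrack:
        if part not in tracks:
            raise ParameterError(f"signal {name!r} needs track {part!r}, not present")
        track, _ = interpolate_track(tracks[part], confidence_threshold)
        return track

    if kind == "x":
        return sign * filled(parts).x
    if kind == "y":
        return filled(parts).y
    if kind == "diameter":
        top, bottom = parts
        return pupil_diameter(filled(top), filled(bottom))
    if kind == "speed":
        return point_speed(filled(parts), timeline.frame_rate)
    raise ParameterError(f"unknown signal kind {kind!r}")  # pragma: no cover


def analysis_window(
    values, timeline: TrialTimeline, window: tuple = (-1.0, 10.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a frame-aligned series to the threat-centered analysis window.

    Returns ``(times_rel_threat, values)`` over ``[window[0], window[1])``
    seconds relative to threat onset.
    """
    values = np.asarray(values, dtype=float)
    i0 = timeline.frame_of(timeline.threat_onset + window[0])
    i1 = timeline.frame_of(timeline.threat_onset + window[1])
    if i0 < 0 or i1 > values.size:
        raise ParameterError(
            f"series of {values.size} frames does not cover the analysis window {window}"
        )
    times = np.arange(i0, i1) / timeline.frame_rate - timeline.threat_onset
    return times, values[i0:i1]


def baseline_segment(values, timeline: TrialTimeline) -> np.ndarray:
    """The pre-pairing baseline portion [0, pairing_start) of a series."""
    values = np.asarray(values, dtype=float)
    i1 = timeline.frame_of(timeline.pairing_start)
    if values.size < i1:
        raise ParameterError("series shorter than the baseline window")
    return values[:i1]


@dataclass
class TrialAverage:
    """Per-mouse, per-condition mean trace with its trial bookkeeping."""

    times: np.ndarray
    values: np.ndarray
    n_trials: int
    n_excluded: int = 0


def average_trials_per_mouse(
    signals: Sequence[NormalizedSignal],
    excluded: Sequence[bool] | None = None,
) -> TrialAverage:
    """Pointwise mean of one mouse's trial traces for one condition.

    Excluded trials are skipped but counted; zero usable trials raises
    :class:`NoUsableTrialsError` so a missing mouse is flagged rather than
    silently dropped.
    """
    if excluded is None:
        excluded = [False] * len(signals)
    if len(excluded) != len(signals):
        raise ParameterError("excluded flags must match the number of trials")
    usable = [s for s, ex in zip(signals, excluded) if not ex]
    n_excluded = len(signals) - len(usable)
    if not usable:
        raise NoUsableTrialsError(
            f"no usable trials ({len(signals)} provided, {n_excluded} excluded)"
        )
    times = usable[0].times
    for s in usable[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ParameterError("trial traces must share a common time base")
    stack = np.vstack([s.values for s in usable])
    return TrialAverage(
        times=times.copy(),
        values=stack.mean(axis=0),
        n_trials=len(usable),
        n_excluded=n_excluded,
    )
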