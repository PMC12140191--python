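"""Synthetic cohorts emulating the artificial-forelimb illusion experiment.

Everything downstream of video tracking is testable without any recorded
data: this module simulates, at the level of tracked coordinates, cohorts of
head-fixed mice going through the paradigm's timeline (120 s baseline, 120 s
brush pairing, threat at 240 s held 10 s, imaged at 200 Hz).

The trial model, per tracked signal:

* horizontal pupil position = per-mouse baseline offset + stationary
  Ornstein–Uhlenbeck noise + white measurement noise + (after the threat) a
  deterministic biphasic response: a fast excursion toward the threat
  (difference of exponentials) followed by a condition-dependent sustained
  gaze plateau with exponential release.  "Toward threat" is signed per eye.
* pupil diameter (vertical separation of the pupil-top/bottom points) carries
  a slow dilation transient after the threat.
* ear and whisker points receive a post-threat movement burst (extra jitter),
  scaled with the condition's sustained-gaze amplitude.

Brush-stroke trains use inter-onset intervals drawn from an exponential law
truncated to [min_interval, max_interval] (memoryless within bounds);
synchronous pairing duplicates one train onto both brushes, asynchronous
pairing draws the visual and tactile trains independently.

Reproducibility: a single cohort seed deterministically derives per-mouse and
per-trial seeds via ``numpy.random.SeedSequence`` with entropy tuples
``(seed, stream, crc32(mouse_id), session_index, condition_code)``, so trials
are statistically independent but individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter

from .core import (
    CAMERA_SIDES,
    PointTrack,
    TrialTimeline,
    validate_conditions,
)
from .errors import DesignError, ParameterError
from .tracking_io import Manifest, TrackingTable, TrialEntry, write_manifest, write_tracking_table

__all__ = [
    "StrokeSchedule",
    "CohortModel",
    "TrialRecording",
    "sample_stroke_schedule",
    "simulate_trial",
    "simulate_cohort",
    "default_design",
    "BODY_PARTS",
]

# entropy stream tags for seed derivation
_OFFSET_STREAM = 101
_TRIAL_STREAM = 202

#: Tracked body parts per camera side (namespaced by side).  The right camera
#: images the right eye; the left camera additionally sees the ear and one
#: whisker.
BODY_PARTS = {
    "right": ("right_pupil_center", "right_pupil_top", "right_pupil_bottom"),
    "left": (
        "left_pupil_center",
        "left_pupil_top",
        "left_pupil_bottom",
        "left_ear",
        "left_whisker",
    ),
}

#: Nominal image positions (px) on the 1440x1080 camera frames.
_BASE_POSITIONS = {
    "right_pupil_center": (760.0, 520.0),
    "left_pupil_center": (680.0, 520.0),
    "left_ear": (1020.0, 300.0),
    "left_whisker": (420.0, 760.0),
}

_CONDITION_CODES = {
    ("artificial_limb", "synchronous"): 1,
    ("artificial_limb", "asynchronous"): 2,
    ("block", "synchronous"): 3,
    ("block", "asynchronous"): 4,
    ("none", "none"): 5,
}


@dataclass(frozen=True)
class StrokeSchedule:
    """Paired visual/tactile brush-stroke event trains.

    Onset times are in seconds relative to the start of the pairing window.
    Each stroke is a 6 mm back-and-forth sweep lasting 300 ms.
    """

    visual_onsets: np.ndarray
    tactile_onsets: np.ndarray
    stroke_duration: float = 0.3
    sweep_distance: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "visual_onsets", np.asarray(self.visual_onsets, float))
        object.__setattr__(self, "tactile_onsets", np.asarray(self.tactile_onsets, float))

    def validate(self, pairing_duration: float, min_interval: float, max_interval: float) -> None:
        """Assert the schedule invariants for the given interval law."""
        eps = 1e-9
        for name, train in (("visual", self.visual_onsets), ("tactile", self.tactile_onsets)):
            if train.size == 0:
                continue
            if train.min() < -eps or train.max() + self.stroke_duration > pairing_duration + eps:
                raise ParameterError(f"{name} strokes fall outside the pairing window")
            iv = np.diff(train)
            if iv.size and (iv.min() < min_interval - eps or iv.max() > max_interval + eps):
                raise ParameterError(
                    f"{name} inter-onset intervals outside [{min_interval}, {max_interval}]"
                )

    @property
    def synchronous(self) -> bool:
        return (
            self.visual_onsets.shape == self.tactile_onsets.shape
            and np.array_equal(self.visual_onsets, self.tactile_onsets)
        )

    def to_dict(self) -> dict:
        return {
            "visual_onsets": self.visual_onsets.tolist(),
            "tactile_onsets": self.tactile_onsets.tolist(),
            "stroke_duration": self.stroke_duration,
            "sweep_distance": self.sweep_distance,
        }


def _sample_intervals(rng: Generator, n: int, lo: float, hi: float, rate: float) -> np.ndarray:
    """Draw inter-onset intervals from Exp(rate) truncated to [lo, hi]."""
    if lo == hi:
        return np.full(n, lo)
    u = rng.random(n)
    e_lo, e_hi = np.exp(-rate * lo), np.exp(-rate * hi)
    return -np.log(e_lo - u * (e_lo - e_hi)) / rate


def _sample_train(
    rng: Generator, duration: float, lo: float, hi: float, rate: float, stroke_duration: float
) -> np.ndarray:
    onsets: list = []
    t = 0.0
    while True:
        for iv in _sample_intervals(rng, 64, lo, hi, rate):
            t += iv
            if t + stroke_duration > duration:
                return np.asarray(onsets)
            onsets.append(t)


def sample_stroke_schedule(
    pairing_duration: float,
    min_interval: float = 0.6,
    max_interval: float = 2.0,
    mode: str = "synchronous",
    seed=None,
    *,
    rate: float = 1.0,
    stroke_duration: float = 0.3,
    sweep_distance: float = 6.0,
    rng: Generator | None = None,
) -> StrokeSchedule:
    """Sample a brush-stroke schedule for one pairing window.

    Inter-onset intervals follow an exponential law of rate ``rate`` (per
    second; untruncated mean ``1/rate``) truncated to
    ``[min_interval, max_interval]``.  In synchronous mode one train is drawn
    and applied to both brushes; in asynchronous mode the visual and tactile
    trains are drawn independently from the same law.  Only strokes that end
    (onset + stroke_duration) inside the pairing window are kept.
    """
    if not 0 < min_interval <= max_interval:
        raise ParameterError(
            f"require 0 < min_interval <= max_interval, got [{min_interval}, {max_interval}]"
        )
    if pairing_duration <= max_interval:
        raise ParameterError(
            f"pairing_duration ({pairing_duration}) must exceed max_interval ({max_interval})"
        )
    if mode not in ("synchronous", "asynchronous"):
        raise ParameterError(f"unknown mode {mode!r}")
    if rng is None:
        rng = default_rng(seed)
    visual = _sample_train(rng, pairing_duration, min_interval, max_interval, rate, stroke_duration)
    if mode == "synchronous":
        tactile = visual.copy()
    else:
        tactile = _sample_train(
            rng, pairing_duration, min_interval, max_interval, rate, stroke_duration
        )
    return StrokeSchedule(
        visual_onsets=visual,
        tactile_onsets=tactile,
        stroke_duration=stroke_duration,
        sweep_distance=sweep_distance,
    )


def _default_sustained_amplitudes() -> dict:
    # toward-threat sustained gaze (px); ordering
    # limb-sync > limb-async >= block-sync >= block-async > none
    return {
        ("artificial_limb", "synchronous"): 3.0,
        ("artificial_limb", "asynchronous"): 1.2,
        ("block", "synchronous"): 1.0,
        ("block", "asynchronous"): 0.6,
        ("none", "none"): 0.1,
    }


@dataclass
class CohortModel:
    """Parameters of the synthetic cohort generator.

    All position parameters are in pixels, times in seconds.  The defaults
    describe a cohort of 10 mice over 5 sessions with heterogeneous baseline
    gaze positions, slow autocorrelated baseline wander, a strong fast
    excursion toward the threat in all paired conditions, and a sustained
    toward-threat gaze whose amplitude ranks
    limb-sync > limb-async >= block-sync >= block-async > no-pairing.
    """

    n_mice: int = 10
    n_sessions: int = 5

    # baseline structure
    baseline_offset_sd: float = 5.0       # per-mouse gaze offset spread
    baseline_noise_sd: float = 1.0        # OU marginal sd
    baseline_noise_corr_time: float = 0.5  # OU correlation time
    measurement_noise_sd: float = 0.1     # white tracker jitter per coordinate

    # fast threat excursion (shared by all paired conditions)
    fast_amplitude: float = 8.0
    fast_latency: float = 0.1
    fast_rise: float = 0.05
    fast_decay: float = 0.3
    none_fast_scale: float = 0.15         # residual reflex without pairing

    # sustained toward-threat gaze
    sustained_amplitudes: dict = field(default_factory=_default_sustained_amplitudes)
    sustained_onset: float = 1.0          # s after threat onset
    sustained_duration: float = 6.0       # plateau length
    sustained_release: float = 1.5        # exponential release time constant

    # pupil diameter
    pupil_diameter_base: float = 40.0
    dilation_amplitude: float = 6.0
    dilation_rise: float = 1.0
    dilation_decay: float = 5.0
    dilation_condition_scale: dict = field(
        default_factory=lambda: {("artificial_limb", "synchronous"): 0.8}
    )

    # face movement bursts after the threat
    ear_burst_sd: float = 3.0
    whisker_burst_sd: float = 3.0
    burst_duration: float = 3.0

    # sign convention: positive = toward the threat, per camera side
    toward_threat_sign: dict = field(default_factory=lambda: {"right": 1.0, "left": -1.0})

    # stroke-interval law
    min_interval: float = 0.6
    max_interval: float = 2.0
    interval_rate: float = 1.0
    stroke_duration: float = 0.3
    sweep_distance: float = 6.0

    seed: int = 0
    check_amplitude_ordering: bool = True

    def __post_init__(self) -> None:
        if self.n_mice < 0 or self.n_sessions < 0:
            raise ParameterError("n_mice and n_sessions must be >= 0")
        for name in (
            "baseline_offset_sd",
            "baseline_noise_sd",
            "measurement_noise_sd",
            "ear_burst_sd",
            "whisker_burst_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        self.sustained_amplitudes = {
            tuple(k) if not isinstance(k, tuple) else k: float(v)
            for k, v in self.sustained_amplitudes.items()
        }
        for key in self.sustained_amplitudes:
            validate_conditions(*key)
        if self.check_amplitude_ordering:
            a = self.sustained_amplitudes
            order = [
                ("artificial_limb", "synchronous"),
                ("artificial_limb", "asynchronous"),
                ("block", "synchronous"),
                ("block", "asynchronous"),
                ("none", "none"),
            ]
            vals = [a.get(k) for k in order]
            if all(v is not None for v in vals):
                ls, la, bs, ba, no = vals
                strict_ok = (ls > la or ls == la == 0) and (ba > no or ba == no == 0)
                if not (strict_ok and la >= bs >= ba):
                    raise ParameterError(
                        "sustained amplitudes must satisfy limb-sync > limb-async >= "
                        "block-sync >= block-async > none (set "
                        "check_amplitude_ordering=False to override)"
                    )

    def sustained_amplitude(self, object_condition: str, pairing_condition: str) -> float:
        return self.sustained_amplitudes.get((object_condition, pairing_condition), 0.0)

    def mouse_ids(self) -> list:
        return [f"m{i + 1:02d}" for i in range(self.n_mice)]

    def interval_law(self) -> dict:
        return {
            "family": "truncated_exponential",
            "min_interval": self.min_interval,
            "max_interval": self.max_interval,
            "rate": self.interval_rate,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sustained_amplitudes"] = {
            f"{k[0]}/{k[1]}": v for k, v in self.sustained_amplitudes.items()
        }
        d["dilation_condition_scale"] = {
            f"{k[0]}/{k[1]}": v for k, v in self.dilation_condition_scale.items()
        }
        return d


@dataclass
class TrialRecording:
    """All tracked point series plus timeline and condition labels for a trial."""

    mouse_id: str
    session_index: int
    object_condition: str
    pairing_condition: str
    trial_order_within_session: int
    timeline: TrialTimeline
    schedule: StrokeSchedule | None
    tracks: dict  # body-part name -> PointTrack

    def __post_init__(self) -> None:
        validate_conditions(self.object_condition, self.pairing_condition)
        if self.object_condition == "none" and self.schedule is not None:
            raise ParameterError("threat-only trials carry no stroke schedule")
        n = self.timeline.n_frames
        for name, track in self.tracks.items():
            if len(track) != n:
                raise ParameterError(
                    f"track {name!r} has {len(track)} frames, timeline implies {n}"
                )

    def to_tracking_tables(self, scorer: str = "pawshift-synthetic") -> dict:
        """Split tracks into per-camera-side tables."""
        tables = {}
        for side in CAMERA_SIDES:
            points = {name: self.tracks[name] for name in BODY_PARTS[side] if name in self.tracks}
            if points:
                tables[side] = TrackingTable.from_points(scorer, points)
        return tables


def _mouse_rng(model: CohortModel, mouse_id: str) -> Generator:
    return default_rng(SeedSequence((model.seed, _OFFSET_STREAM, zlib.crc32(mouse_id.encode()))))


def _trial_seed_sequence(
    model: CohortModel, mouse_id: str, session_index: int, cond_code: int
) -> SeedSequence:
    return SeedSequence(
        (model.seed, _TRIAL_STREAM, zlib.crc32(mouse_id.encode()), session_index, cond_code)
    )


def mouse_baseline_offset(model: CohortModel, mouse_id: str) -> float:
    """The per-mouse horizontal gaze offset (drawn once per mouse)."""
    return float(_mouse_rng(model, mouse_id).normal(0.0, model.baseline_offset_sd))


def _ou_noise(rng: Generator, n: int, sd: float, tau: float, dt: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck samples (exact discretization)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    if tau <= 0:
        return rng.normal(0.0, sd, n)
    phi = float(np.exp(-dt / tau))
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def _biexponential(s: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized, 0 for s < 0."""
    out = np.zeros_like(s)
    pos = s > 0
    if rise == decay:  # limit case: alpha function
        sp = s[pos] / decay
        out[pos] = sp * np.exp(1.0 - sp)
        return out
    sp = s[pos]
    g = np.exp(-sp / decay) - np.exp(-sp / rise)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out[pos] = g / peak
    return out


def _plateau(s: np.ndarray, onset: float, duration: float, release: float) -> np.ndarray:
    """Unit plateau on [onset, onset + duration], exponential release after."""
    out = np.zeros_like(s)
    hold = (s >= onset) & (s <= onset + duration)
    out[hold] = 1.0
    after = s > onset + duration
    if release > 0:
        out[after] = np.exp(-(s[after] - onset - duration) / release)
    return out


def _dilation(s: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Slow pupil-dilation transient, peak-normalized, 0 for s < 0."""
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos]
    g = (1.0 - np.exp(-sp / rise)) * np.exp(-sp / decay)
    t_peak = rise * np.log(1.0 + decay / rise)
    peak = (1.0 - np.exp(-t_peak / rise)) * np.exp(-t_peak / decay)
    out[pos] = g / peak if peak > 0 else g
    return out


def _meas(rng: Generator, n: int, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


# fixed stream order for per-trial child seed sequences; restricting the
# simulated parts never changes the values of the parts that are computed
_STREAMS = (
    "right_gaze", "right_pupil_center.meas", "right_pupil_top.meas",
    "right_pupil_bottom.meas",
    "left_gaze", "left_pupil_center.meas", "left_pupil_top.meas",
    "left_pupil_bottom.meas",
    "left_ear", "left_whisker", "schedule",
)


def simulate_trial(
    model: CohortModel,
    mouse_id: str,
    session_index: int,
    object_condition: str,
    pairing_condition: str,
    seed=None,
    *,
    timeline: TrialTimeline | None = None,
    trial_order_within_session: int = 1,
    parts: Sequence[str] | None = None,
) -> TrialRecording:
    """Simulate the tracked coordinates of one trial.

    With ``seed=None`` the trial seed is derived deterministically from
    ``model.seed`` and the trial identity, so cohorts are reproducible while
    trials stay independent.  The per-mouse baseline offset depends only on
    ``model.seed`` and ``mouse_id`` and is therefore shared across sessions.

    ``parts`` restricts the simulated tracks to a subset of body-part names
    (an efficiency knob for large simulation studies); every track draws
    from its own child random stream, so the tracks that are computed are
    bit-identical to a full simulation.
    """
    validate_conditions(object_condition, pairing_condition)
    if timeline is None:
        timeline = TrialTimeline()
    cond = (object_condition, pairing_condition)
    if seed is None:
        ss = _trial_seed_sequence(model, mouse_id, session_index, _CONDITION_CODES[cond])
    else:
        ss = SeedSequence(seed)
    streams = dict(zip(_STREAMS, ss.spawn(len(_STREAMS))))
    all_parts = [p for side in CAMERA_SIDES for p in BODY_PARTS[side]]
    wanted = set(all_parts) if parts is None else set(parts)
    unknown = wanted - set(all_parts)
    if unknown:
        raise ParameterError(f"unknown body parts {sorted(unknown)}")

    n = timeline.n_frames
    dt = 1.0 / timeline.frame_rate
    t = timeline.times()
    s = t - timeline.threat_onset  # time relative to threat onset

    offset = mouse_baseline_offset(model, mouse_id)
    tau = model.baseline_noise_corr_time
    sd = model.baseline_noise_sd
    m_sd = model.measurement_noise_sd

    # deterministic threat response templates
    fast_amp = model.fast_amplitude * (
        model.none_fast_scale if object_condition == "none" else 1.0
    )
    fast = fast_amp * _biexponential(s - model.fast_latency, model.fast_rise, model.fast_decay)
    sustained = model.sustained_amplitude(*cond) * _plateau(
        s, model.sustained_onset, model.sustained_duration, model.sustained_release
    )
    gaze_response = fast + sustained
    dil_scale = model.dilation_condition_scale.get(cond, 1.0)
    dilation = dil_scale * model.dilation_amplitude * _dilation(
        s, model.dilation_rise, model.dilation_decay
    )

    burst = (s >= 0) & (s < model.burst_duration)
    amps = list(model.sustained_amplitudes.values())
    max_amp = max(amps) if amps else 0.0
    burst_scale = (
        0.3 + 0.7 * model.sustained_amplitude(*cond) / max_amp if max_amp > 0 else 0.0
    )

    tracks: dict = {}
    for side in CAMERA_SIDES:
        eye_parts = [p for p in BODY_PARTS[side] if "pupil" in p and p in wanted]
        if eye_parts:
            sign = float(model.toward_threat_sign.get(side, 1.0))
            cx, cy = _BASE_POSITIONS[f"{side}_pupil_center"]
            gaze_rng = default_rng(streams[f"{side}_gaze"])
            gaze_x = cx + offset + _ou_noise(gaze_rng, n, sd, tau, dt) + sign * gaze_response
            gaze_y = cy + _ou_noise(gaze_rng, n, sd, tau, dt) + 0.3 * fast
            need_diam = any(p.endswith(("top", "bottom")) for p in eye_parts)
            if need_diam:
                diam = (
                    model.pupil_diameter_base
                    + dilation
                    + _ou_noise(gaze_rng, n, 0.3 * sd, tau, dt)
                )
            for part in eye_parts:
                mrng = default_rng(streams[f"{part}.meas"])
                if part.endswith("center"):
                    px, py = gaze_x, gaze_y
                elif part.endswith("top"):
                    px, py = gaze_x, gaze_y - diam / 2.0
                else:
                    px, py = gaze_x, gaze_y + diam / 2.0
                tracks[part] = PointTrack(
                    px + _meas(mrng, n, m_sd), py + _meas(mrng, n, m_sd), np.ones(n)
                )
        for part, burst_sd in (("left_ear", model.ear_burst_sd),
                               ("left_whisker", model.whisker_burst_sd)):
            if side != "left" or part not in wanted:
                continue
            prng = default_rng(streams[part])
            bx, by = _BASE_POSITIONS[part]
            jitter = burst_sd * burst_scale
            jx = np.where(burst, _meas(prng, n, 1.0), 0.0) * jitter
            jy = np.where(burst, _meas(prng, n, 1.0), 0.0) * jitter
            tracks[part] = PointTrack(
                bx + _ou_noise(prng, n, sd, tau, dt) + jx + _meas(prng, n, m_sd),
                by + _ou_noise(prng, n, sd, tau, dt) + jy + _meas(prng, n, m_sd),
                np.ones(n),
            )

    schedule = None
    if object_condition != "none":
        schedule = sample_stroke_schedule(
            timeline.pairing_duration,
            model.min_interval,
            model.max_interval,
            mode=pairing_condition,
            rate=model.interval_rate,
            stroke_duration=model.stroke_duration,
            sweep_distance=model.sweep_distance,
            rng=default_rng(streams["schedule"]),
        )

    return TrialRecording(
        mouse_id=mouse_id,
        session_index=session_index,
        object_condition=object_condition,
        pairing_condition=pairing_condition,
        trial_order_within_session=trial_order_within_session,
        timeline=timeline,
        schedule=schedule,
        tracks=tracks,
    )


def default_design(
    n_mice: int,
    n_sessions: int = 5,
    object_condition: str = "artificial_limb",
    include_no_pairing: bool = False,
    mouse_ids: Sequence[str] | None = None,
    exclude_mice: Sequence[str] = (),
    exclude_trials: Sequence[tuple] = (),
) -> pd.DataFrame:
    """Build the study's cohort design table.

    Each session holds a synchronous and an asynchronous trial whose order
    alternates across sessions; ``include_no_pairing`` prepends a threat-only
    trial per session (the control experiment's design).  ``exclude_mice``
    removes animals from the design entirely; ``exclude_trials`` is a list of
    ``(mouse_id, session_index)`` pairs flagged excluded in the output (the
    trials stay listed but carry no data downstream).
    """
    if mouse_ids is None:
        mouse_ids = [f"m{i + 1:02d}" for i in range(n_mice)]
    mouse_ids = [m for m in mouse_ids if m not in set(exclude_mice)]
    excluded_set = {(m, s) for m, s in exclude_trials}
    rows = []
    for mouse in mouse_ids:
        for session in range(1, n_sessions + 1):
            order = 1
            if include_no_pairing:
                rows.append((mouse, session, "none", "none", order,
                             (mouse, session) in excluded_set))
                order += 1
            pairings = (
                ("synchronous", "asynchronous")
                if session % 2 == 1
                else ("asynchronous", "synchronous")
            )
            for pairing in pairings:
                rows.append((mouse, session, object_condition, pairing, order,
                             (mouse, session) in excluded_set))
                order += 1
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "session_index",
            "object_condition",
            "pairing_condition",
            "trial_order_within_session",
            "excluded",
        ],
    )


def simulate_cohort(
    model: CohortModel,
    design: pd.DataFrame | None = None,
    output_dir=None,
    *,
    timeline: TrialTimeline | None = None,
    scorer: str = "pawshift-synthetic",
    manifest_name: str = "manifest.yaml",
) -> Manifest:
    """Simulate every (non-excluded) trial of a design and write the cohort.

    Writes one tracking-table CSV per trial per camera side, a manifest
    (YAML) describing the design, and a model-parameters sidecar JSON for
    provenance.  Returns the manifest.  Excluded trials are listed in the
    manifest with ``excluded: true`` and no files (mirroring trials lost to
    equipment failure).
    """
    if design is None:
        design = default_design(model.n_mice, model.n_sessions)
    if output_dir is None:
        raise ParameterError("output_dir is required")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if timeline is None:
        timeline = TrialTimeline()

    required = {"mouse_id", "session_index", "object_condition", "pairing_condition"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns {sorted(missing)}")
    keys = list(
        zip(design["mouse_id"], design["session_index"],
            design["object_condition"], design["pairing_condition"])
    )
    if len(keys) != len(set(keys)):
        dupes = pd.Series(keys)[pd.Series(keys).duplicated()].unique()
        raise DesignError(f"duplicate design rows: {list(dupes)[:5]}")

    trials = []
    for i, row in design.reset_index(drop=True).iterrows():
        mouse = str(row["mouse_id"])
        session = int(row["session_index"])
        obj = str(row["object_condition"])
        pairing = str(row["pairing_condition"])
        order = int(row.get("trial_order_within_session", i + 1))
        excluded = bool(row.get("excluded", False))
        files: dict = {side: None for side in CAMERA_SIDES}
        if not excluded:
            rec = simulate_trial(
                model, mouse, session, obj, pairing,
                timeline=timeline, trial_order_within_session=order,
            )
            for side, table in rec.to_tracking_tables(scorer).items():
                fname = f"{mouse}_s{session}_{obj}_{pairing}_{side}.csv"
                write_tracking_table(table, output_dir / fname)
                files[side] = fname
        trials.append(
            TrialEntry(
                mouse_id=mouse,
                session_index=session,
                object_condition=obj,
                pairing_condition=pairing,
                trial_order_within_session=order,
                excluded=excluded,
                files=files,
            )
        )

    manifest = Manifest(
        timeline=timeline,
        toward_threat_sign=dict(model.toward_threat_sign),
        trials=trials,
        interval_law=model.interval_law(),
        seed=model.seed,
        base_dir=output_dir,
    )
    write_manifest(manifest, output_dir / manifest_name)
    (output_dir / "model_parameters.json").write_text(
        json.dumps(model.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return manifest
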