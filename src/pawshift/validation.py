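"""Statistical validation experiments run entirely on synthetic cohorts.

Two experiments characterize the baseline-segment maximum-statistic
bootstrap as implemented here:

* **Calibration** — on cohorts with zero condition effect (both conditions
  share the same deterministic threat response, so their difference is pure
  autocorrelated noise), the family-wise probability that the observed
  difference trace exceeds the bootstrap threshold anywhere in the 11 s
  analysis window should match the nominal level (5%).
* **Power / recovery** — injecting a sustained toward-threat effect into one
  condition should produce a detected window overlapping the injected
  support and a significant paired signed-rank test, with detection
  frequency increasing in effect amplitude.

Both experiments run the full machinery in memory: trials are simulated by
:func:`pawshift.synthetic.simulate_trial`, signals extracted as in the
pipeline, the null built from the per-mouse baseline differences, and the
threshold applied to the observed window trace.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence

from .core import TrialTimeline
from .errors import ParameterError
from .preprocess import analysis_window, baseline_segment, extract_signal, prethreat_normalize
from .stats import (
    bootstrap_max_null,
    detect_windows,
    paired_difference_traces,
    wilcoxon_signed_rank,
    window_means,
)
from .synthetic import CohortModel, simulate_trial

__all__ = [
    "null_cohort_model",
    "simulate_condition_pair",
    "CalibrationResult",
    "familywise_error_rate",
    "PowerResult",
    "detection_experiment",
]

_COHORT_STREAM = 303


def null_cohort_model(
    n_mice: int = 10,
    baseline_noise_sd: float = 1.0,
    baseline_noise_corr_time: float = 0.5,
    seed: int = 0,
) -> CohortModel:
    """A cohort model with zero condition effect.

    All sustained amplitudes are zero and the fast threat excursion is
    identical across conditions, so every condition difference is pure
    baseline noise.  Measurement white noise is disabled so the marginal
    noise law is exactly the configured Ornstein–Uhlenbeck process.
    """
    return CohortModel(
        n_mice=n_mice,
        n_sessions=1,
        baseline_noise_sd=baseline_noise_sd,
        baseline_noise_corr_time=baseline_noise_corr_time,
        measurement_noise_sd=0.0,
        sustained_amplitudes={k: 0.0 for k in (
            ("artificial_limb", "synchronous"),
            ("artificial_limb", "asynchronous"),
            ("block", "synchronous"),
            ("block", "asynchronous"),
            ("none", "none"),
        )},
        seed=seed,
    )


def simulate_condition_pair(
    model: CohortModel,
    *,
    timeline: TrialTimeline | None = None,
    object_condition: str = "artificial_limb",
    signal: str = "right_pupil_x",
    n_sessions: int | None = None,
) -> tuple:
    """Simulate a cohort's synchronous/asynchronous pair and extract one signal.

    Returns ``(sync, async)`` where each maps mouse id to the session-averaged
    raw signal series (full trial length).  The signed toward-threat
    convention of the model is applied.
    """
    if timeline is None:
        timeline = TrialTimeline()
    if n_sessions is None:
        n_sessions = model.n_sessions
    from .preprocess import SIGNAL_DEFS

    _, sig_parts, _, _ = SIGNAL_DEFS[signal]
    parts = (sig_parts,) if isinstance(sig_parts, str) else tuple(sig_parts)
    sync: dict = {}
    async_: dict = {}
    for mouse in model.mouse_ids():
        per_cond = {"synchronous": [], "asynchronous": []}
        for session in range(1, n_sessions + 1):
            for pairing in ("synchronous", "asynchronous"):
                rec = simulate_trial(
                    model, mouse, session, object_condition, pairing,
                    timeline=timeline, parts=parts,
                )
                per_cond[pairing].append(
                    extract_signal(
                        rec.tracks, signal, timeline,
                        toward_threat_sign=model.toward_threat_sign,
                    )
                )
        sync[mouse] = np.mean(per_cond["synchronous"], axis=0)
        async_[mouse] = np.mean(per_cond["asynchronous"], axis=0)
    return sync, async_


def _cohort_seed(base_seed: int, replicate: int) -> int:
    # deterministic, < 2**31, well-separated per replicate
    return int(SeedSequence((base_seed, _COHORT_STREAM, replicate)).generate_state(1)[0] % (2**31))


@dataclass
class CalibrationResult:
    """Family-wise false-positive rate of the bootstrap threshold under the null."""

    n_cohorts: int
    n_false_positive: int
    n_mice: int
    n_boot: int
    quantile_level: float

    @property
    def rate(self) -> float:
        return self.n_false_positive / self.n_cohorts

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate

    def binomial_ci(self, confidence: float = 0.95) -> tuple:
        """Normal-approximation CI for the false-positive probability."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + confidence / 2.0)
        p = self.rate
        half = z * np.sqrt(p * (1.0 - p) / self.n_cohorts)
        return (max(0.0, p - half), min(1.0, p + half))


def cohort_false_positive(
    model: CohortModel,
    *,
    timeline: TrialTimeline | None = None,
    signal: str = "right_pupil_x",
    object_condition: str = "artificial_limb",
    window: tuple = (-1.0, 10.0),
    segment_length: float = 11.0,
    n_boot: int = 1000,
    quantile_level: float = 0.95,
    boot_seed=None,
) -> bool:
    """Whether one cohort's difference trace exceeds its threshold anywhere."""
    if timeline is None:
        timeline = TrialTimeline()
    sync, async_ = simulate_condition_pair(
        model, timeline=timeline, object_condition=object_condition, signal=signal
    )
    window_a = {m: analysis_window(v, timeline, window)[1] for m, v in sync.items()}
    window_b = {m: analysis_window(v, timeline, window)[1] for m, v in async_.items()}
    times = analysis_window(next(iter(sync.values())), timeline, window)[0]
    trace = paired_difference_traces(window_a, window_b, times)
    baselines = {
        m: baseline_segment(sync[m], timeline) - baseline_segment(async_[m], timeline)
        for m in sync
    }
    null = bootstrap_max_null(
        baselines,
        frame_rate=timeline.frame_rate,
        segment_length=segment_length,
        n_boot=n_boot,
        quantile_level=quantile_level,
        seed=boot_seed,
    )
    return bool((trace.group_mean > null.threshold).any())


def familywise_error_rate(
    n_cohorts: int = 400,
    *,
    n_mice: int = 10,
    baseline_noise_sd: float = 1.0,
    baseline_noise_corr_time: float = 0.5,
    timeline: TrialTimeline | None = None,
    n_boot: int = 1000,
    quantile_level: float = 0.95,
    segment_length: float = 11.0,
    seed: int = 0,
) -> CalibrationResult:
    """Estimate the family-wise false-positive rate over replicate null cohorts.

    Each replicate simulates a fresh zero-effect cohort (seed derived from
    ``seed`` and the replicate index), builds the bootstrap null from its
    baseline differences, and tests whether the observed 11 s window
    difference trace exceeds the threshold anywhere.
    """
    if n_cohorts < 1:
        raise ParameterError("n_cohorts must be >= 1")
    hits = 0
    for r in range(n_cohorts):
        cohort_seed = _cohort_seed(seed, r)
        model = null_cohort_model(
            n_mice=n_mice,
            baseline_noise_sd=baseline_noise_sd,
            baseline_noise_corr_time=baseline_noise_corr_time,
            seed=cohort_seed,
        )
        hits += cohort_false_positive(
            model,
            timeline=timeline,
            n_boot=n_boot,
            quantile_level=quantile_level,
            segment_length=segment_length,
            boot_seed=cohort_seed + 1,
        )
    return CalibrationResult(
        n_cohorts=n_cohorts,
        n_false_positive=hits,
        n_mice=n_mice,
        n_boot=n_boot,
        quantile_level=quantile_level,
    )


@dataclass
class PowerResult:
    """Detection/rejection frequencies for an injected sustained effect."""

    n_replicates: int
    n_detected: int          # a window overlapping the injected support
    n_rejected: int          # detected AND signed-rank p < alpha
    effect_px: float
    injected_support: tuple
    window_midpoints: list   # midpoints of the detected overlapping windows

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_replicates

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_replicates


def detection_experiment(
    effect_px: float,
    n_replicates: int = 100,
    *,
    object_condition: str = "artificial_limb",
    n_mice: int = 10,
    baseline_noise_sd: float = 1.0,
    baseline_noise_corr_time: float = 0.5,
    timeline: TrialTimeline | None = None,
    n_boot: int = 1000,
    quantile_level: float = 0.95,
    alpha: float = 0.05,
    window: tuple = (-1.0, 10.0),
    seed: int = 0,
    signal: str = "right_pupil_x",
) -> PowerResult:
    """Measure detection of a sustained toward-threat effect of ``effect_px``.

    The effect is injected as the synchronous condition's sustained-gaze
    amplitude (the asynchronous amplitude stays zero), supported on the
    model's default plateau (1–7 s post threat).  A replicate counts as
    detected when some supra-threshold window overlaps the injected support,
    and as rejected when additionally the W-window signed-rank test on
    pre-threat-normalized means is significant at ``alpha``.
    """
    if timeline is None:
        timeline = TrialTimeline()
    base_model = null_cohort_model(
        n_mice=n_mice,
        baseline_noise_sd=baseline_noise_sd,
        baseline_noise_corr_time=baseline_noise_corr_time,
    )
    support = (
        base_model.sustained_onset,
        base_model.sustained_onset + base_model.sustained_duration,
    )
    n_detected = n_rejected = 0
    midpoints: list = []
    for r in range(n_replicates):
        cohort_seed = _cohort_seed(seed + 7919, r)
        amps = dict(base_model.sustained_amplitudes)
        amps[(object_condition, "synchronous")] = effect_px
        model = dataclasses.replace(
            base_model,
            sustained_amplitudes=amps,
            seed=cohort_seed,
            check_amplitude_ordering=False,
        )
        sync, async_ = simulate_condition_pair(
            model, timeline=timeline, object_condition=object_condition, signal=signal
        )
        times = analysis_window(next(iter(sync.values())), timeline, window)[0]
        raw_a = {m: analysis_window(v, timeline, window)[1] for m, v in sync.items()}
        raw_b = {m: analysis_window(v, timeline, window)[1] for m, v in async_.items()}
        trace = paired_difference_traces(raw_a, raw_b, times)
        baselines = {
            m: baseline_segment(sync[m], timeline) - baseline_segment(async_[m], timeline)
            for m in sync
        }
        null = bootstrap_max_null(
            baselines,
            frame_rate=timeline.frame_rate,
            n_boot=n_boot,
            quantile_level=quantile_level,
            seed=cohort_seed + 1,
        )
        report = detect_windows(trace, null)
        overlapping = [
            iv for iv in report.intervals if iv[0] < support[1] and iv[1] > support[0]
        ]
        if not overlapping:
            continue
        n_detected += 1
        win = max(overlapping, key=lambda iv: iv[1] - iv[0])
        midpoints.append(0.5 * (win[0] + win[1]))
        norm_a = {
            m: analysis_window(prethreat_normalize(v, timeline).values, timeline, window)[1]
            for m, v in sync.items()
        }
        norm_b = {
            m: analysis_window(prethreat_normalize(v, timeline).values, timeline, window)[1]
            for m, v in async_.items()
        }
        table = window_means(norm_a, norm_b, times, win, labels=("sync", "async"))
        test = wilcoxon_signed_rank(table["sync"].to_numpy(), table["async"].to_numpy())
        if test.p_value < alpha:
            n_rejected += 1
    return PowerResult(
        n_replicates=n_replicates,
        n_detected=n_detected,
        n_rejected=n_rejected,
        effect_px=effect_px,
        injected_support=support,
        window_midpoints=midpoints,
    )
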