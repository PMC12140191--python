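"""Inference core: condition-difference traces, the baseline-segment
maximum-statistic bootstrap, significance-window detection, per-mouse window
means, exact paired signed-rank testing, and the difference-of-differences
contrast.

The family-wise error control works as follows.  The quantity under test is
the across-mice mean of per-mouse condition-difference traces over an 11 s
analysis window around the threat (1 s before to 10 s after onset).  Null
material comes from the 120 s pre-pairing baseline of the very same session
pairs: for each bootstrap iteration, one 11 s segment is drawn at a uniformly
random frame-aligned start per mouse (independently per mouse and iteration),
the segments are averaged across mice, and the maximum of the averaged
segment is recorded.  The empirical 95% quantile of the 10,000 maxima is the
significance threshold; any sample of the observed difference trace exceeding
it is significant with family-wise error ~5% over the whole window.

By default the maximum is taken of the signed averaged series (positive =
toward the threat, a one-sided test); an absolute-value mode is available via
``mode="absolute"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from numpy.random import Generator, default_rng
from scipy import stats as sps

from .errors import DegenerateDataWarning, ParameterError

__all__ = [
    "GroupDifferenceTrace",
    "MaxNullDistribution",
    "SignificanceReport",
    "WilcoxonResult",
    "paired_difference_traces",
    "bootstrap_max_null",
    "detect_windows",
    "window_means",
    "wilcoxon_signed_rank",
    "contrast_of_contrasts",
]

_EPS = 1e-9


@dataclass
class GroupDifferenceTrace:
    """Per-mouse and across-mice condition-difference time series.

    ``times`` are seconds relative to threat onset; ``data`` has one row per
    mouse (condition A minus condition B, toward-threat sign).
    """

    times: np.ndarray
    mice: tuple
    data: np.ndarray  # (n_mice, n_times)
    label: str = ""
    dropped_mice: tuple = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape != (len(self.mice), self.times.size):
            raise ParameterError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.mice)} mice x {self.times.size} time points"
            )

    @property
    def n_mice(self) -> int:
        return len(self.mice)

    @property
    def group_mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.n_mice < 2:
            return np.zeros(self.times.size)
        return self.data.std(axis=0, ddof=1) / math.sqrt(self.n_mice)

    @property
    def window(self) -> tuple:
        dt = float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0
        return (float(self.times[0]), float(self.times[-1]) + dt)

    def per_mouse(self, mouse: str) -> np.ndarray:
        return self.data[self.mice.index(mouse)]


def paired_difference_traces(
    a: Mapping[str, np.ndarray],
    b: Mapping[str, np.ndarray],
    times,
    label: str = "",
) -> GroupDifferenceTrace:
    """Per-mouse pointwise A - B traces with group mean and SEM.

    ``a`` and ``b`` map mouse id to that mouse's condition-averaged trace on
    the common ``times`` base.  Mice missing either condition are excluded
    and recorded in ``dropped_mice``.
    """
    times = np.asarray(times, dtype=float)
    common = sorted(set(a) & set(b))
    dropped = tuple(sorted((set(a) | set(b)) - set(common)))
    if not common:
        raise ParameterError("no mice present in both condition sets")
    rows = []
    for mouse in common:
        xa, xb = np.asarray(a[mouse], float), np.asarray(b[mouse], float)
        if xa.shape != times.shape or xb.shape != times.shape:
            raise ParameterError(f"trace length mismatch for mouse {mouse!r}")
        rows.append(xa - xb)
    return GroupDifferenceTrace(
        times=times, mice=tuple(common), data=np.vstack(rows),
        label=label, dropped_mice=dropped,
    )


@dataclass
class MaxNullDistribution:
    """Bootstrap samples of the across-mice maximum deviation + threshold."""

    samples: np.ndarray
    segment_length: float
    quantile_level: float
    threshold: float
    frame_rate: float
    seed: object = None
    mode: str = "signed"  # signed | absolute
    source: str = ""      # description of the per-mouse baseline material

    @property
    def n_boot(self) -> int:
        return self.samples.size

    def quantile(self, level: float) -> float:
        """Empirical quantile via the ceil(level * n) order statistic."""
        return _order_statistic_quantile(self.samples, level)


def _order_statistic_quantile(samples: np.ndarray, level: float) -> float:
    if not 0.0 < level <= 1.0:
        raise ParameterError(f"quantile level must be in (0, 1], got {level}")
    n = samples.size
    k = max(1, math.ceil(level * n))  # 1-based order statistic (inverse CDF)
    return float(np.sort(samples)[k - 1])


def bootstrap_max_null(
    baselines: Mapping[str, np.ndarray],
    *,
    frame_rate: float,
    segment_length: float = 11.0,
    n_boot: int = 10_000,
    quantile_level: float = 0.95,
    seed=None,
    rng: Generator | None = None,
    mode: str = "signed",
    start_alignment_s: float | None = None,
    source: str = "",
    _chunk: int = 2000,
) -> MaxNullDistribution:
    """Baseline-segment maximum-statistic bootstrap.

    For each of ``n_boot`` iterations, one ``segment_length``-second segment
    of each mouse's baseline difference series is drawn at a uniformly random
    frame-aligned start (with replacement across iterations, independently
    per mouse), the segments are averaged pointwise across mice, and the
    maximum of the averaged series is recorded.  The threshold is the
    ``quantile_level`` empirical quantile of the maxima.

    ``start_alignment_s`` restricts segment starts to multiples of that many
    seconds (e.g. 1.0 for whole-second starts); the default draws from every
    frame-aligned start.  ``mode="absolute"`` takes the maximum of the
    absolute averaged series instead of the signed series.
    """
    if n_boot < 1:
        raise ParameterError(f"n_boot must be >= 1, got {n_boot}")
    if mode not in ("signed", "absolute"):
        raise ParameterError(f"unknown mode {mode!r}")
    if not baselines:
        raise ParameterError("at least one mouse baseline is required")
    seg = int(round(segment_length * frame_rate))
    if seg < 1:
        raise ParameterError("segment_length x frame_rate must be >= 1 frame")
    mice = sorted(baselines)
    windows, n_starts = [], []
    for mouse in mice:
        arr = np.asarray(baselines[mouse], dtype=float)
        if arr.size < seg:
            raise ParameterError(
                f"baseline of mouse {mouse!r} has {arr.size} frames, "
                f"shorter than the {seg}-frame segment"
            )
        if np.isnan(arr).any():
            raise ParameterError(
                f"baseline of mouse {mouse!r} contains NaN; interpolate upstream"
            )
        view = sliding_window_view(arr, seg)
        if start_alignment_s is not None:
            step = int(round(start_alignment_s * frame_rate))
            if step < 1:
                raise ParameterError("start_alignment_s must be >= one frame")
            view = view[::step]
        windows.append(view)
        n_starts.append(view.shape[0])

    if rng is None:
        rng = default_rng(seed)
    n_mice = len(mice)
    samples = np.empty(n_boot)
    done = 0
    while done < n_boot:
        c = min(_chunk, n_boot - done)
        acc = np.zeros((c, seg))
        for view, ns in zip(windows, n_starts):
            starts = rng.integers(0, ns, size=c)
            acc += view[starts]
        acc /= n_mice
        if mode == "absolute":
            np.abs(acc, out=acc)
        samples[done : done + c] = acc.max(axis=1)
        done += c

    return MaxNullDistribution(
        samples=samples,
        segment_length=segment_length,
        quantile_level=quantile_level,
        threshold=_order_statistic_quantile(samples, quantile_level),
        frame_rate=frame_rate,
        seed=seed,
        mode=mode,
        source=source,
    )


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int            # pairs used after dropping zero differences
    method: str       # exact | normal


@dataclass
class SignificanceReport:
    """Supra-threshold intervals, selected windows, quantification and tests."""

    intervals: list            # maximal disjoint [start, end] s, by onset
    w1: tuple | None
    w2: tuple | None
    threshold: float
    analysis_window: tuple
    min_duration: float
    merge_gap: float
    mode: str = "signed"
    contrast_label: str = ""
    window_means: dict = field(default_factory=dict)  # window label -> DataFrame
    tests: dict = field(default_factory=dict)         # window label -> WilcoxonResult


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (start_idx, stop_idx) with stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_windows(
    trace: GroupDifferenceTrace,
    null: MaxNullDistribution,
    min_duration: float = 0.1,
    merge_gap: float = 0.05,
) -> SignificanceReport:
    """Find supra-threshold intervals of the group-mean difference trace.

    Samples where the group mean exceeds the bootstrap threshold are grouped
    into maximal runs; runs separated by gaps of at most ``merge_gap``
    seconds are merged and runs shorter than ``min_duration`` seconds are
    discarded.  The first two surviving intervals (by onset) are labelled W1
    and W2.  An empty result is valid.
    """
    mean = trace.group_mean
    if null.mode == "absolute":
        mean = np.abs(mean)
    supra = mean > null.threshold
    dt = float(trace.times[1] - trace.times[0]) if trace.times.size > 1 else 0.0
    intervals = [
        [float(trace.times[i0]), float(trace.times[i1 - 1]) + dt] for i0, i1 in _runs(supra)
    ]
    merged: list = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= merge_gap + _EPS:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    kept = [tuple(iv) for iv in merged if iv[1] - iv[0] >= min_duration - _EPS]
    return SignificanceReport(
        intervals=kept,
        w1=kept[0] if len(kept) > 0 else None,
        w2=kept[1] if len(kept) > 1 else None,
        threshold=null.threshold,
        analysis_window=trace.window,
        min_duration=min_duration,
        merge_gap=merge_gap,
        mode=null.mode,
        contrast_label=trace.label,
    )


def window_means(
    a: Mapping[str, np.ndarray],
    b: Mapping[str, np.ndarray],
    times,
    window: tuple,
    labels: tuple = ("A", "B"),
) -> pd.DataFrame:
    """Per-mouse time-means of both conditions' traces over a window.

    Returns a DataFrame indexed by mouse with one column per condition.
    The traces should carry the same normalization as the displayed profiles
    (pre-threat normalization in the paradigm's figures).
    """
    times = np.asarray(times, dtype=float)
    start, stop = window
    mask = (times >= start - _EPS) & (times < stop - _EPS)
    if not mask.any() or start < times[0] - _EPS or stop > times[-1] + (
        float(times[1] - times[0]) if times.size > 1 else 0.0
    ) + _EPS:
        raise ParameterError(
            f"window {window} outside the trace range [{times[0]}, {times[-1]}] s"
        )
    common = sorted(set(a) & set(b))
    if not common:
        raise ParameterError("no mice present in both condition sets")
    rows = {
        mouse: {
            labels[0]: float(np.asarray(a[mouse], float)[mask].mean()),
            labels[1]: float(np.asarray(b[mouse], float)[mask].mean()),
        }
        for mouse in common
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(labels)]


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled W+ value (index = 2*W+)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(x, y=None, *, exact_threshold: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking and ties are mid-ranked.
    For n <= ``exact_threshold`` the p-value is exact over all 2^n sign
    assignments (computed by dynamic programming over doubled ranks, which is
    equivalent to full enumeration); larger n uses the normal approximation
    with tie correction.  The two-sided p is ``min(1, 2 * min(P(W+ <= w),
    P(W+ >= w)))``.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 1:
        raise ParameterError("at least one pair is required")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; the signed-rank test is degenerate",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        r2 = np.round(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(r2)
        w2 = int(round(2.0 * w_plus))
        denom = 2.0 ** n
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, p_value=float(p), n=n, method="exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        warnings.warn(
            "zero variance under ties; the signed-rank test is degenerate",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return WilcoxonResult(statistic=w_plus, p_value=1.0, n=n, method="degenerate")
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(statistic=w_plus, p_value=float(min(1.0, p)), n=n, method="normal")


@dataclass
class DifferenceOfDifferences:
    """Second-order contrast between two paired-condition effects."""

    trace: GroupDifferenceTrace
    null: MaxNullDistribution
    report: SignificanceReport


def contrast_of_contrasts(
    limb: GroupDifferenceTrace,
    block: GroupDifferenceTrace,
    limb_baselines: Mapping[str, np.ndarray],
    block_baselines: Mapping[str, np.ndarray],
    *,
    frame_rate: float,
    segment_length: float = 11.0,
    n_boot: int = 10_000,
    quantile_level: float = 0.95,
    seed=None,
    rng: Generator | None = None,
    mode: str = "signed",
    min_duration: float = 0.1,
    merge_gap: float = 0.05,
    label: str = "difference_of_differences",
) -> DifferenceOfDifferences:
    """Difference-of-differences contrast with its own bootstrap null.

    Per common mouse, the second-order trace is (limb A-B) minus (block A-B)
    and the null material is the per-mouse difference of the two experiments'
    baseline-difference series; the same maximum-statistic bootstrap then
    yields the significance threshold.
    """
    common = sorted(set(limb.mice) & set(block.mice)
                    & set(limb_baselines) & set(block_baselines))
    if not common:
        raise ParameterError("no mice common to the two experiments")
    if limb.times.shape != block.times.shape or not np.allclose(limb.times, block.times):
        raise ParameterError("the two contrasts must share a time base")
    rows = [limb.per_mouse(m) - block.per_mouse(m) for m in common]
    trace = GroupDifferenceTrace(
        times=limb.times, mice=tuple(common), data=np.vstack(rows), label=label,
        dropped_mice=tuple(sorted((set(limb.mice) | set(block.mice)) - set(common))),
    )
    second_order = {}
    for m in common:
        la = np.asarray(limb_baselines[m], float)
        bl = np.asarray(block_baselines[m], float)
        if la.shape != bl.shape:
            raise ParameterError(f"baseline length mismatch for mouse {m!r}")
        second_order[m] = la - bl
    null = bootstrap_max_null(
        second_order,
        frame_rate=frame_rate,
        segment_length=segment_length,
        n_boot=n_boot,
        quantile_level=quantile_level,
        seed=seed,
        rng=rng,
        mode=mode,
        source="per-mouse second-order baseline differences",
    )
    report = detect_windows(trace, null, min_duration=min_duration, merge_gap=merge_gap)
    report = replace(report, contrast_label=label)
    return DifferenceOfDifferences(trace=trace, null=null, report=report)
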