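"""Tests of the inference core: difference traces, the baseline-segment
maximum-statistic bootstrap (against exhaustive enumeration), window
detection, window means, the exact signed-rank test (against brute-force
sign-assignment enumeration and scipy), and the difference-of-differences."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pawshift.errors import DegenerateDataWarning, ParameterError
from pawshift.stats import (
    GroupDifferenceTrace,
    MaxNullDistribution,
    bootstrap_max_null,
    contrast_of_contrasts,
    detect_windows,
    paired_difference_traces,
    wilcoxon_signed_rank,
    window_means,
)


class TestPairedDifferenceTraces:
    times = np.linspace(-1.0, 10.0, 111)

    def test_identical_conditions_give_zero(self, rng):
        a = {"m1": rng.normal(size=111), "m2": rng.normal(size=111)}
        trace = paired_difference_traces(a, {k: v.copy() for k, v in a.items()}, self.times)
        np.testing.assert_allclose(trace.group_mean, 0.0)
        np.testing.assert_allclose(trace.sem, 0.0)

    def test_mean_and_sem_arithmetic(self):
        a = {"m1": np.full(111, 2.0), "m2": np.full(111, 4.0)}
        b = {"m1": np.zeros(111), "m2": np.zeros(111)}
        trace = paired_difference_traces(a, b, self.times)
        np.testing.assert_allclose(trace.group_mean, 3.0)
        np.testing.assert_allclose(trace.sem, 1.0)  # sd([2,4])/sqrt(2) = 1
        assert trace.n_mice == 2
        assert trace.window == pytest.approx((-1.0, 10.1))

    def test_unmatched_mice_dropped_and_logged(self):
        a = {"m1": np.zeros(111), "m2": np.zeros(111)}
        b = {"m1": np.zeros(111), "m3": np.zeros(111)}
        trace = paired_difference_traces(a, b, self.times)
        assert trace.mice == ("m1",)
        assert trace.dropped_mice == ("m2", "m3")

    def test_zero_overlap_raises(self):
        with pytest.raises(ParameterError):
            paired_difference_traces({"m1": np.zeros(111)}, {"m2": np.zeros(111)}, self.times)


class TestBootstrapMaxNull:
    def test_all_zero_baselines_give_zero_threshold(self):
        null = bootstrap_max_null(
            {"m1": np.zeros(500), "m2": np.zeros(500)},
            frame_rate=20.0, segment_length=11.0, n_boot=200, seed=0,
        )
        np.testing.assert_array_equal(null.samples, 0.0)
        assert null.threshold == 0.0

    def test_default_sample_count(self):
        null = bootstrap_max_null(
            {"m1": np.arange(30.0)}, frame_rate=1.0, segment_length=5.0, seed=0
        )
        assert null.n_boot == 10_000

    def test_single_mouse_sawtooth_matches_enumeration(self):
        """With one mouse and second-aligned starts, the bootstrap draws from
        exactly the enumerable set of segment maxima, with matching quantiles."""
        rate = 20.0
        t = np.arange(int(120 * rate)) / rate
        baseline = (t % 7.0) - 3.5  # deterministic sawtooth
        seg = int(11 * rate)
        starts = np.arange(0, baseline.size - seg + 1, int(rate))
        assert starts.size == 110
        enumerated = np.array([baseline[s : s + seg].max() for s in starts])

        null = bootstrap_max_null(
            {"m1": baseline}, frame_rate=rate, segment_length=11.0,
            n_boot=5000, seed=42, start_alignment_s=1.0,
        )
        assert set(null.samples).issubset(set(enumerated))
        # empirical distribution ~ uniform over the 110 enumerated values
        ks = max(
            abs(np.mean(null.samples <= v) - np.mean(enumerated <= v)) for v in enumerated
        )
        assert ks < 0.03
        for q in (0.5, 0.95):
            enum_q = np.sort(enumerated)[math.ceil(q * enumerated.size) - 1]
            assert abs(null.quantile(q) - enum_q) <= np.ptp(enumerated) * 0.05

    def test_two_mice_match_pairwise_enumeration(self, rng):
        """Two mice: the bootstrap distribution matches exhaustive enumeration
        over all pairs of second-aligned segment starts."""
        rate = 10.0
        n = int(40 * rate)
        seg = int(4 * rate)
        base = {
            "m1": rng.normal(size=n),
            "m2": rng.normal(size=n),
        }
        step = int(rate)
        starts = np.arange(0, n - seg + 1, step)
        w1 = np.array([base["m1"][s : s + seg] for s in starts])
        w2 = np.array([base["m2"][s : s + seg] for s in starts])
        enumerated = np.array(
            [((a + b) / 2).max() for a in w1 for b in w2]
        )
        null = bootstrap_max_null(
            base, frame_rate=rate, segment_length=4.0,
            n_boot=20000, seed=3, start_alignment_s=1.0,
        )
        assert set(np.round(null.samples, 12)).issubset(set(np.round(enumerated, 12)))
        for q in (0.25, 0.5, 0.9, 0.95):
            enum_q = np.sort(enumerated)[math.ceil(q * enumerated.size) - 1]
            assert abs(null.quantile(q) - enum_q) < 0.1 * np.ptp(enumerated)

    def test_absolute_mode_bounds_signed(self, rng):
        base = {"m1": rng.normal(size=400)}
        signed = bootstrap_max_null(base, frame_rate=10.0, segment_length=4.0,
                                    n_boot=500, seed=5)
        absolute = bootstrap_max_null(base, frame_rate=10.0, segment_length=4.0,
                                      n_boot=500, seed=5, mode="absolute")
        assert (absolute.samples >= signed.samples - 1e-12).all()

    def test_threshold_quantile_monotone(self, rng):
        base = {"m1": rng.normal(size=400)}
        null = bootstrap_max_null(base, frame_rate=10.0, segment_length=4.0,
                                  n_boot=1000, seed=1)
        assert null.quantile(0.99) >= null.quantile(0.95) >= null.quantile(0.5)

    def test_short_baseline_and_nan_rejected(self):
        with pytest.raises(ParameterError, match="shorter"):
            bootstrap_max_null({"m1": np.zeros(10)}, frame_rate=10.0, segment_length=4.0)
        bad = np.zeros(100)
        bad[3] = np.nan
        with pytest.raises(ParameterError, match="NaN"):
            bootstrap_max_null({"m1": bad}, frame_rate=10.0, segment_length=4.0)


def _make_null(threshold: float) -> MaxNullDistribution:
    return MaxNullDistribution(
        samples=np.full(100, threshold), segment_length=11.0, quantile_level=0.95,
        threshold=threshold, frame_rate=20.0,
    )


class TestDetectWindows:
    dt = 0.05
    times = np.arange(-1.0, 10.0, dt)

    def _trace(self, values):
        return GroupDifferenceTrace(times=self.times, mice=("m1",), data=values[None, :])

    def test_below_threshold_everywhere_gives_no_windows(self):
        report = detect_windows(self._trace(np.zeros(self.times.size)), _make_null(1.0))
        assert report.intervals == []
        assert report.w1 is None and report.w2 is None

    def test_two_interval_fixture(self):
        """threshold + 1 on [0.1, 0.4) and [2, 6) -> W1 = [0.1, 0.4], W2 = [2, 6]."""
        thr = 2.0
        vals = np.zeros(self.times.size)
        vals[(self.times >= 0.1 - 1e-9) & (self.times < 0.4 - 1e-9)] = thr + 1.0
        vals[(self.times >= 2.0 - 1e-9) & (self.times < 6.0 - 1e-9)] = thr + 1.0
        report = detect_windows(self._trace(vals), _make_null(thr))
        assert report.w1 == (pytest.approx(0.1), pytest.approx(0.4))
        assert report.w2 == (pytest.approx(2.0), pytest.approx(6.0))
        assert len(report.intervals) == 2

    def test_gap_merging_and_min_duration(self):
        thr = 1.0
        vals = np.zeros(self.times.size)
        # two runs separated by one sub-gap sample -> merged
        vals[(self.times >= 1.0 - 1e-9) & (self.times < 1.2 - 1e-9)] = 2.0
        vals[(self.times >= 1.25 - 1e-9) & (self.times < 1.5 - 1e-9)] = 2.0
        # an isolated single-sample blip -> dropped by min_duration
        vals[np.argmin(np.abs(self.times - 8.0))] = 2.0
        report = detect_windows(self._trace(vals), _make_null(thr),
                                min_duration=0.1, merge_gap=0.05)
        assert len(report.intervals) == 1
        assert report.intervals[0] == (pytest.approx(1.0), pytest.approx(1.5))

    def test_injected_sustained_effect_recovered(self, rng):
        """A sustained-only effect plus small noise yields exactly one window
        covering the injected support."""
        vals = rng.normal(scale=0.05, size=self.times.size)
        support = (self.times >= 1.0) & (self.times < 7.0)
        vals[support] += 3.0
        report = detect_windows(self._trace(vals), _make_null(1.0))
        assert len(report.intervals) == 1
        lo, hi = report.intervals[0]
        assert lo == pytest.approx(1.0, abs=2 * self.dt)
        assert hi == pytest.approx(7.0, abs=2 * self.dt)


class TestWindowMeans:
    times = np.arange(0.0, 10.0, 0.1)

    def test_constant_trace(self):
        a = {"m1": np.full(self.times.size, 5.0)}
        table = window_means(a, a, self.times, (2.0, 4.0))
        assert table.loc["m1", "A"] == pytest.approx(5.0)
        assert table.loc["m1", "B"] == pytest.approx(5.0)

    def test_ramp_symmetric_window_gives_midpoint(self):
        a = {"m1": 3.0 * self.times}
        # include both endpoints' samples symmetrically: [2.0, 4.1) covers
        # samples 2.0 .. 4.0 whose mean time is the midpoint 3.0
        table = window_means(a, a, self.times, (2.0, 4.1))
        assert table.loc["m1", "A"] == pytest.approx(9.0)

    def test_window_outside_trace_rejected(self):
        a = {"m1": np.zeros(self.times.size)}
        with pytest.raises(ParameterError):
            window_means(a, a, self.times, (9.0, 12.0))


def _brute_force_p(d: np.ndarray) -> float:
    """Exhaustive two-sided signed-rank p over all sign assignments."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs)[np.newaxis, :].dot(ranks)[0]
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.p_value == pytest.approx(2 / 2**5)
        assert res.statistic == 15.0
        assert res.method == "exact"

    def test_symmetric_pair_gives_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_n8_fixture_matches_brute_force(self, rng):
        d = rng.normal(size=8)
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(_brute_force_p(d))

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_enumeration_all_small_n(self, n):
        """Exact p equals brute-force enumeration for every n <= 10, with
        ties and zero differences present."""
        rng = np.random.default_rng(n)
        for rep in range(5):
            d = np.round(rng.normal(size=n), 1)  # rounding induces ties/zeros
            if (d == 0).all():
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(_brute_force_p(d)), d

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.normal(size=9)
        assert len(np.unique(np.abs(d))) == 9
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_paired_interface(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(_brute_force_p(x - y))

    def test_degenerate_all_zero(self):
        with pytest.warns(DegenerateDataWarning):
            res = wilcoxon_signed_rank(np.zeros(6))
        assert res.p_value == 1.0
        assert res.n == 0

    def test_normal_approximation_reasonable(self, rng):
        d = rng.normal(loc=0.8, size=40)
        approx = wilcoxon_signed_rank(d)
        assert approx.method == "normal"
        ref = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        assert approx.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestScaleEquivariance:
    def test_scaling_inputs_scales_thresholds_not_inference(self, rng):
        """Multiplying all inputs by k scales thresholds, traces and window
        means by k, and leaves p-values and detected windows unchanged."""
        k = 7.3
        rate, seg = 10.0, 4.0
        times = np.arange(-1.0, 4.0, 1 / rate)
        mice = [f"m{i}" for i in range(6)]
        base = {m: rng.normal(size=400) for m in mice}
        effect = np.where((times >= 1.0) & (times < 3.0), 1.5, 0.0)
        a = {m: effect + rng.normal(scale=0.3, size=times.size) for m in mice}
        b = {m: rng.normal(scale=0.3, size=times.size) for m in mice}

        def run(scale):
            trace = paired_difference_traces(
                {m: v * scale for m, v in a.items()},
                {m: v * scale for m, v in b.items()}, times,
            )
            null = bootstrap_max_null(
                {m: v * scale for m, v in base.items()},
                frame_rate=rate, segment_length=seg, n_boot=500, seed=77,
            )
            report = detect_windows(trace, null)
            means = window_means(
                {m: v * scale for m, v in a.items()},
                {m: v * scale for m, v in b.items()}, times, (1.0, 3.0),
            )
            test = wilcoxon_signed_rank(means["A"].to_numpy(), means["B"].to_numpy())
            return trace, null, report, means, test

        t1, n1, r1, m1, w1 = run(1.0)
        tk, nk, rk, mk, wk = run(k)
        np.testing.assert_allclose(tk.group_mean, k * t1.group_mean, rtol=1e-12)
        np.testing.assert_allclose(nk.threshold, k * n1.threshold, rtol=1e-12)
        np.testing.assert_allclose(mk.to_numpy(), k * m1.to_numpy(), rtol=1e-12)
        assert rk.intervals == r1.intervals
        assert wk.p_value == w1.p_value


class TestContrastOfContrasts:
    times = np.arange(-1.0, 4.0, 0.1)

    def _trace(self, per_mouse):
        mice = tuple(sorted(per_mouse))
        return GroupDifferenceTrace(
            times=self.times, mice=mice, data=np.vstack([per_mouse[m] for m in mice])
        )

    def test_identical_contrasts_give_zero_and_no_windows(self, rng):
        per_mouse = {m: rng.normal(size=self.times.size) for m in ("m1", "m2")}
        limb = self._trace(per_mouse)
        block = self._trace({m: v.copy() for m, v in per_mouse.items()})
        zeros = {m: np.zeros(300) for m in ("m1", "m2")}
        dod = contrast_of_contrasts(
            limb, block, zeros, zeros,
            frame_rate=10.0, segment_length=4.0, n_boot=200, seed=0,
        )
        np.testing.assert_allclose(dod.trace.group_mean, 0.0)
        assert dod.null.threshold == 0.0
        assert dod.report.intervals == []

    def test_limb_only_sustained_effect_detected_late(self, rng):
        mice = ("m1", "m2", "m3", "m4")
        effect = np.where((self.times >= 1.0) & (self.times < 3.0), 2.0, 0.0)
        limb = self._trace(
            {m: effect + rng.normal(scale=0.2, size=self.times.size) for m in mice}
        )
        block = self._trace(
            {m: rng.normal(scale=0.2, size=self.times.size) for m in mice}
        )
        baselines = {m: rng.normal(scale=0.2, size=600) for m in mice}
        dod = contrast_of_contrasts(
            limb, block, baselines,
            {m: rng.normal(scale=0.2, size=600) for m in mice},
            frame_rate=10.0, segment_length=4.0, n_boot=1000, seed=1,
        )
        assert dod.report.intervals, "expected a significant late window"
        overlapping = [iv for iv in dod.report.intervals if iv[0] < 3.0 and iv[1] > 1.0]
        assert overlapping

    def test_no_common_mice_rejected(self, rng):
        a = self._trace({"m1": np.zeros(self.times.size)})
        b = self._trace({"m2": np.zeros(self.times.size)})
        with pytest.raises(ParameterError):
            contrast_of_contrasts(a, b, {"m1": np.zeros(100)}, {"m2": np.zeros(100)},
                                  frame_rate=10.0, segment_length=4.0, n_boot=10)
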