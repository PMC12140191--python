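"""Orchestrate simulate -> preprocess -> stats across signals and contrasts.

:func:`run_full_analysis` consumes a cohort manifest plus an
:class:`AnalysisConfig` and produces, for every signal x contrast, the group
traces with SEM, the condition-difference trace, the bootstrap significance
threshold, supra-threshold intervals with the W1/W2 quantification windows,
per-mouse window means, and paired signed-rank tests.  Raw (unnormalized)
traces feed the significance analysis; pre-threat-normalized traces feed the
displayed profiles and the window quantification.

Per-signal analyses are independent; there is no cross-signal multiplicity
correction beyond the per-signal max-statistic family-wise control.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .core import TrialTimeline
from .errors import ParameterError, PipelineError
from .preprocess import (
    DEFAULT_SIGNALS,
    SIGNAL_DEFS,
    analysis_window,
    baseline_segment,
    extract_signal,
    prethreat_normalize,
)
from .stats import (
    GroupDifferenceTrace,
    bootstrap_max_null,
    contrast_of_contrasts,
    detect_windows,
    paired_difference_traces,
    wilcoxon_signed_rank,
    window_means,
)
from .tracking_io import Manifest, read_manifest, read_tracking_table

logger = logging.getLogger("pawshift")


@dataclass
class Contrast:
    """One condition contrast: paired A-B or a difference of differences."""

    name: str
    kind: str = "paired"  # paired | difference_of_differences
    cond_a: tuple | None = None  # (object_condition, pairing_condition)
    cond_b: tuple | None = None
    base: tuple | None = None    # for dod: names of the two paired contrasts

    def __post_init__(self) -> None:
        if self.kind not in ("paired", "difference_of_differences"):
            raise ParameterError(f"unknown contrast kind {self.kind!r}")
        if self.kind == "paired" and (self.cond_a is None or self.cond_b is None):
            raise ParameterError(f"paired contrast {self.name!r} needs cond_a and cond_b")
        if self.kind == "difference_of_differences" and (
            self.base is None or len(self.base) != 2
        ):
            raise ParameterError(
                f"difference-of-differences contrast {self.name!r} needs two base contrasts"
            )
        if self.cond_a is not None:
            self.cond_a = tuple(self.cond_a)
        if self.cond_b is not None:
            self.cond_b = tuple(self.cond_b)
        if self.base is not None:
            self.base = tuple(self.base)


@dataclass
class AnalysisConfig:
    """Everything the analysis needs beyond the manifest."""

    signals: tuple = DEFAULT_SIGNALS
    contrasts: tuple | None = None  # None -> auto-detect from the manifest
    n_boot: int = 10_000
    segment_length: float = 11.0
    quantile_level: float = 0.95
    max_mode: str = "signed"
    analysis_window: tuple = (-1.0, 10.0)
    min_duration: float = 0.1
    merge_gap: float = 0.05
    confidence_threshold: float = 0.9
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.signals = tuple(self.signals)
        unknown = [s for s in self.signals if s not in SIGNAL_DEFS]
        if unknown:
            raise ParameterError(f"unknown signals {unknown}; known: {sorted(SIGNAL_DEFS)}")
        self.analysis_window = tuple(self.analysis_window)
        if self.contrasts is not None:
            self.contrasts = tuple(
                c if isinstance(c, Contrast) else Contrast(**c) for c in self.contrasts
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.contrasts is not None:
            d["contrasts"] = [asdict(c) for c in self.contrasts]
        d["signals"] = list(self.signals)
        d["analysis_window"] = list(self.analysis_window)
        return d

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def auto_contrasts(conditions: set) -> tuple:
    """Build the paradigm's contrast list from the conditions present."""
    contrasts = []
    paired_by_object = {}
    for obj in ("artificial_limb", "block"):
        if (obj, "synchronous") in conditions and (obj, "asynchronous") in conditions:
            name = f"{obj}_sync_vs_async"
            contrasts.append(
                Contrast(name=name, cond_a=(obj, "synchronous"), cond_b=(obj, "asynchronous"))
            )
            paired_by_object[obj] = name
        if ("none", "none") in conditions:
            for pairing in ("synchronous", "asynchronous"):
                if (obj, pairing) in conditions:
                    contrasts.append(
                        Contrast(
                            name=f"{obj}_{pairing[:4]}_vs_no_pairing",
                            cond_a=(obj, pairing),
                            cond_b=("none", "none"),
                        )
                    )
    if "artificial_limb" in paired_by_object and "block" in paired_by_object:
        contrasts.append(
            Contrast(
                name="limb_vs_block_difference_of_differences",
                kind="difference_of_differences",
                base=(paired_by_object["artificial_limb"], paired_by_object["block"]),
            )
        )
    return tuple(contrasts)


@dataclass
class ContrastResult:
    """Analysis output for one signal x contrast."""

    signal: str
    contrast: Contrast
    trace: GroupDifferenceTrace          # raw differences (significance scale)
    norm_a: dict                         # mouse -> pre-threat-normalized trace
    norm_b: dict
    baselines: dict                      # mouse -> baseline difference series
    threshold: float
    n_boot: int
    report: object                       # SignificanceReport
    window_tables: dict                  # window label -> DataFrame of means
    tests: dict                          # window label -> WilcoxonResult


@dataclass
class ReportBundle:
    """Machine-readable report plus tidy tables; writable to disk."""

    report: dict
    traces: pd.DataFrame
    window_mean_table: pd.DataFrame
    test_table: pd.DataFrame
    results: dict = field(default_factory=dict)  # (signal, contrast) -> ContrastResult
    config: AnalysisConfig | None = None

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(self.report, indent=1, sort_keys=True) + "\n"
        )
        self.traces.to_csv(out_dir / "difference_traces.csv", index=False)
        self.window_mean_table.to_csv(out_dir / "window_means.csv", index=False)
        self.test_table.to_csv(out_dir / "tests.csv", index=False)
        if self.config is not None and self.config.make_plots:
            fig_dir = out_dir / "figures"
            fig_dir.mkdir(exist_ok=True)
            for (signal, cname), res in self.results.items():
                path = fig_dir / f"{signal}__{cname}.svg"
                plot_contrast(res, path)


def plot_contrast(res: ContrastResult, path) -> None:
    """Difference trace + threshold + shaded significance windows (one panel)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    t = res.trace.times
    mean, sem = res.trace.group_mean, res.trace.sem
    ax.fill_between(t, mean - sem, mean + sem, alpha=0.25, lw=0)
    ax.plot(t, mean, lw=1.2, label="difference")
    ax.axhline(res.threshold, ls="--", c="k", lw=0.8, label="threshold")
    for start, end in res.report.intervals:
        ax.axvspan(start, end, color="tab:blue", alpha=0.15)
    for label, win in (("W1", res.report.w1), ("W2", res.report.w2)):
        if win is not None:
            ax.axvspan(win[0], win[1], color="gray", alpha=0.15)
            ax.text(0.5 * (win[0] + win[1]), ax.get_ylim()[1], label, ha="center", va="top")
    ax.axvline(0.0, c="k", lw=0.6)
    ax.set_xlabel("time from threat onset (s)")
    ax.set_ylabel("difference (px)")
    ax.set_title(f"{res.signal}: {res.contrast.name}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _sides_needed(signals: Sequence[str]) -> set:
    return {SIGNAL_DEFS[s][0] for s in signals}


def _load_trial_signals(
    manifest: Manifest, config: AnalysisConfig
) -> dict:
    """Read tracking files and extract raw signals for every active trial.

    Returns ``{(mouse, session, object, pairing): {signal: np.ndarray}}``.
    """
    timeline = manifest.timeline
    sides = _sides_needed(config.signals)
    out: dict = {}
    for entry in manifest.active_trials():
        key = entry.key
        tracks: dict = {}
        for side in sides:
            rel = entry.files.get(side)
            if rel is None:
                raise PipelineError("load", f"trial {key}: no {side}-side file in manifest")
            path = manifest.resolve(rel)
            try:
                table = read_tracking_table(path)
            except Exception as exc:
                raise PipelineError("load", f"trial {key}: {exc}") from exc
            tracks.update(table.points())
        sig_map = {}
        for name in config.signals:
            try:
                sig_map[name] = extract_signal(
                    tracks,
                    name,
                    timeline,
                    toward_threat_sign=manifest.toward_threat_sign,
                    confidence_threshold=config.confidence_threshold,
                )
            except Exception as exc:
                raise PipelineError("extract", f"trial {key}, signal {name}: {exc}") from exc
        out[key] = sig_map
    return out


def _paired_inputs(
    trial_signals: Mapping, signal: str, cond_a: tuple, cond_b: tuple,
    timeline: TrialTimeline, window: tuple,
) -> tuple:
    """Session-paired per-mouse inputs for one paired contrast.

    For each mouse, uses only the sessions holding both conditions and
    averages over them: raw window traces (significance scale), pre-threat
    normalized window traces (display/quantification scale), and the raw
    baseline difference series (null material).
    """
    by_mouse: dict = {}
    for (mouse, session, obj, pairing), sigs in trial_signals.items():
        by_mouse.setdefault(mouse, {}).setdefault(session, {})[(obj, pairing)] = sigs[signal]
    raw_a: dict = {}
    raw_b: dict = {}
    norm_a: dict = {}
    norm_b: dict = {}
    base_diff: dict = {}
    times = None
    for mouse, sessions in sorted(by_mouse.items()):
        ra, rb, na, nb, bd = [], [], [], [], []
        for session, conds in sorted(sessions.items()):
            if cond_a not in conds or cond_b not in conds:
                continue
            sa, sb = conds[cond_a], conds[cond_b]
            ta, wa = analysis_window(sa, timeline, window)
            _, wb = analysis_window(sb, timeline, window)
            ra.append(wa)
            rb.append(wb)
            za = prethreat_normalize(sa, timeline)
            zb = prethreat_normalize(sb, timeline)
            _, zwa = analysis_window(za.values, timeline, window)
            _, zwb = analysis_window(zb.values, timeline, window)
            na.append(zwa)
            nb.append(zwb)
            bd.append(baseline_segment(sa, timeline) - baseline_segment(sb, timeline))
            times = ta
        if ra:
            raw_a[mouse] = np.mean(ra, axis=0)
            raw_b[mouse] = np.mean(rb, axis=0)
            norm_a[mouse] = np.mean(na, axis=0)
            norm_b[mouse] = np.mean(nb, axis=0)
            base_diff[mouse] = np.mean(bd, axis=0)
    if times is None:
        raise PipelineError(
            "contrast", f"no session holds both {cond_a} and {cond_b} for signal {signal}"
        )
    return times, raw_a, raw_b, norm_a, norm_b, base_diff


def _quantify_windows(
    report, norm_a, norm_b, times, labels
) -> tuple[dict, dict]:
    tables: dict = {}
    tests: dict = {}
    for wlabel, win in (("W1", report.w1), ("W2", report.w2)):
        if win is None:
            continue
        table = window_means(norm_a, norm_b, times, win, labels=labels)
        tables[wlabel] = table
        tests[wlabel] = wilcoxon_signed_rank(
            table[labels[0]].to_numpy(), table[labels[1]].to_numpy()
        )
    report.window_means.update(tables)
    report.tests.update(tests)
    return tables, tests


def run_full_analysis(
    manifest, config: AnalysisConfig | None = None, out_dir=None
) -> ReportBundle:
    """Run every signal x contrast analysis over a cohort.

    ``manifest`` is a :class:`~pawshift.tracking_io.Manifest` or a path to
    one.  Writes the report bundle to ``out_dir`` when given, and always
    returns it.
    """
    if config is None:
        config = AnalysisConfig()
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    timeline = manifest.timeline
    trial_signals = _load_trial_signals(manifest, config)
    conditions = {(obj, pairing) for (_, _, obj, pairing) in trial_signals}
    contrasts = config.contrasts if config.contrasts is not None else auto_contrasts(conditions)
    for c in contrasts:
        for cond in (c.cond_a, c.cond_b):
            if cond is not None and cond not in conditions:
                raise ParameterError(
                    f"contrast {c.name!r} references condition {cond} absent from the manifest"
                )

    results: dict = {}
    report_json: dict = {}
    trace_rows: list = []
    mean_rows: list = []
    test_rows: list = []
    excluded = [list(t.key) for t in manifest.trials if t.excluded]

    for i_sig, signal in enumerate(config.signals):
        report_json[signal] = {}
        paired_cache: dict = {}
        for i_con, contrast in enumerate(contrasts):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, i_sig, i_con))
            )
            stage = f"{signal}/{contrast.name}"
            logger.info("analyzing %s", stage)
            if contrast.kind == "paired":
                times, raw_a, raw_b, norm_a, norm_b, base_diff = _paired_inputs(
                    trial_signals, signal, contrast.cond_a, contrast.cond_b,
                    timeline, config.analysis_window,
                )
                trace = paired_difference_traces(raw_a, raw_b, times, label=contrast.name)
                null = bootstrap_max_null(
                    {m: base_diff[m] for m in trace.mice},
                    frame_rate=timeline.frame_rate,
                    segment_length=config.segment_length,
                    n_boot=config.n_boot,
                    quantile_level=config.quantile_level,
                    rng=rng,
                    mode=config.max_mode,
                    source="session-paired baseline differences, averaged per mouse",
                )
                sig_report = detect_windows(
                    trace, null, min_duration=config.min_duration, merge_gap=config.merge_gap
                )
                labels = ("/".join(contrast.cond_a), "/".join(contrast.cond_b))
                tables, tests = _quantify_windows(sig_report, norm_a, norm_b, times, labels)
                norm_diff = {m: norm_a[m] - norm_b[m] for m in trace.mice}
                paired_cache[contrast.name] = (trace, base_diff, norm_diff)
                res = ContrastResult(
                    signal=signal, contrast=contrast, trace=trace,
                    norm_a=norm_a, norm_b=norm_b, baselines=base_diff,
                    threshold=null.threshold, n_boot=null.n_boot,
                    report=sig_report, window_tables=tables, tests=tests,
                )
                # display traces: pre-threat-normalized group means per condition
                for cond_label, norm in ((labels[0], norm_a), (labels[1], norm_b)):
                    arr = np.vstack([norm[m] for m in trace.mice])
                    _append_trace_rows(
                        trace_rows, signal, contrast.name, f"mean[{cond_label}]",
                        times, arr.mean(axis=0),
                    )
            else:  # difference of differences
                missing = [b for b in contrast.base if b not in paired_cache]
                if missing:
                    raise ParameterError(
                        f"contrast {contrast.name!r} needs paired contrasts {missing} "
                        "to run first"
                    )
                (tr_a, base_a, ndiff_a) = paired_cache[contrast.base[0]]
                (tr_b, base_b, ndiff_b) = paired_cache[contrast.base[1]]
                dod = contrast_of_contrasts(
                    tr_a, tr_b, base_a, base_b,
                    frame_rate=timeline.frame_rate,
                    segment_length=config.segment_length,
                    n_boot=config.n_boot,
                    quantile_level=config.quantile_level,
                    rng=rng,
                    mode=config.max_mode,
                    min_duration=config.min_duration,
                    merge_gap=config.merge_gap,
                    label=contrast.name,
                )
                trace, sig_report = dod.trace, dod.report
                times = trace.times
                labels = contrast.base
                norm_a = {m: ndiff_a[m] for m in trace.mice}
                norm_b = {m: ndiff_b[m] for m in trace.mice}
                tables, tests = _quantify_windows(sig_report, norm_a, norm_b, times, labels)
                res = ContrastResult(
                    signal=signal, contrast=contrast, trace=trace,
                    norm_a=norm_a, norm_b=norm_b,
                    baselines={m: base_a[m] - base_b[m] for m in trace.mice},
                    threshold=dod.null.threshold, n_boot=dod.null.n_boot,
                    report=sig_report, window_tables=tables, tests=tests,
                )

            results[(signal, contrast.name)] = res
            _append_trace_rows(
                trace_rows, signal, contrast.name, "difference_mean",
                times, trace.group_mean,
            )
            _append_trace_rows(
                trace_rows, signal, contrast.name, "difference_sem", times, trace.sem
            )
            for mouse in trace.mice:
                _append_trace_rows(
                    trace_rows, signal, contrast.name, f"difference[{mouse}]",
                    times, trace.per_mouse(mouse),
                )
            for wlabel, table in res.window_tables.items():
                for mouse, row in table.iterrows():
                    mean_rows.append(
                        {
                            "signal": signal, "contrast": contrast.name, "window": wlabel,
                            "mouse_id": mouse,
                            "condition_a": table.columns[0], "mean_a": row.iloc[0],
                            "condition_b": table.columns[1], "mean_b": row.iloc[1],
                        }
                    )
            for wlabel, t in res.tests.items():
                win = res.report.w1 if wlabel == "W1" else res.report.w2
                test_rows.append(
                    {
                        "signal": signal, "contrast": contrast.name, "window": wlabel,
                        "start_s": win[0], "end_s": win[1],
                        "statistic": t.statistic, "p_value": t.p_value,
                        "n": t.n, "method": t.method,
                    }
                )
            report_json[signal][contrast.name] = {
                "kind": contrast.kind,
                "n_mice": trace.n_mice,
                "mice": list(trace.mice),
                "dropped_mice": list(trace.dropped_mice),
                "n_boot": res.n_boot,
                "threshold": res.threshold,
                "max_mode": config.max_mode,
                "intervals": [list(iv) for iv in sig_report.intervals],
                "w1": list(sig_report.w1) if sig_report.w1 else None,
                "w2": list(sig_report.w2) if sig_report.w2 else None,
                "tests": {
                    w: {
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "n": t.n,
                        "method": t.method,
                    }
                    for w, t in res.tests.items()
                },
            }

    config_doc = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_doc, sort_keys=True).encode()
    ).hexdigest()
    report = {
        "provenance": {
            "package": "pawshift",
            "version": _version,
            "seed": config.seed,
            "config": config_doc,
            "config_sha256": config_hash,
            "manifest_seed": manifest.seed,
            "n_mice": manifest.n_mice,
            "excluded_trials": excluded,
        },
        "results": report_json,
    }
    bundle = ReportBundle(
        report=report,
        traces=pd.DataFrame(trace_rows),
        window_mean_table=pd.DataFrame(mean_rows),
        test_table=pd.DataFrame(test_rows),
        results=results,
        config=config,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _append_trace_rows(rows, signal, contrast, series, times, values) -> None:
    rows.extend(
        {
            "signal": signal,
            "contrast": contrast,
            "series": series,
            "time_s": float(t),
            "value": float(v),
        }
        for t, v in zip(times, values)
    )
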