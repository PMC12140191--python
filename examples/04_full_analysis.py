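"""End-to-end analysis of a simulated cohort with a real condition effect.

Simulates a cohort whose synchronous artificial-limb condition carries a
sustained toward-threat gaze component, runs the full pipeline (difference
traces, bootstrap threshold, window detection, per-mouse window means,
signed-rank tests) and prints the findings.
"""

import tempfile
from pathlib import Path

from pawshift import AnalysisConfig, CohortModel, TrialTimeline, run_full_analysis, simulate_cohort

out = Path(tempfile.mkdtemp(prefix="pawshift_analysis_"))
timeline = TrialTimeline(frame_rate=50.0)  # reduced rate for a quick example
model = CohortModel(n_mice=6, n_sessions=2, seed=3)
manifest = simulate_cohort(model, output_dir=out / "cohort", timeline=timeline)

config = AnalysisConfig(
    signals=("right_pupil_x", "right_pupil_diameter"),
    n_boot=2000,
    seed=1,
)
bundle = run_full_analysis(manifest, config, out_dir=out / "report")

for signal, contrasts in bundle.report["results"].items():
    for cname, res in contrasts.items():
        print(f"{signal} / {cname}:")
        print(f"  n = {res['n_mice']} mice, threshold = {res['threshold']:.3f} px, "
              f"{len(res['intervals'])} significant window(s)")
        for wlabel, t in res["tests"].items():
            win = res[wlabel.lower()]
            print(f"  {wlabel} [{win[0]:.2f}, {win[1]:.2f}] s: "
                  f"W+ = {t['statistic']:.1f}, p = {t['p_value']:.4f} ({t['method']})")
print()
print(f"full report bundle written to {out / 'report'}")
print("A significant late (W2-style) window in the sync-vs-async pupil-x")
print("contrast is the signature of sustained gaze toward the threatened")
print("artificial limb - the behavioral marker of embodiment.")
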