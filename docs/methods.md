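# Methods

## The paradigm being modeled

A head-fixed mouse is shown a static artificial right forelimb while its own
forelimb is hidden.  Each trial runs 120 s of idle baseline, then 120 s of
brush-stroke pairing (tactile strokes on the hidden limb, visual strokes on
the artifact — simultaneous in the synchronous condition, independently
timed in the asynchronous control), then a sharp object drops next to the
artifact at 240 s and stays for 10 s.  Two cameras image the face at 200 Hz;
pose tracking yields per-frame x/y/likelihood for the pupil centers, two
vertical pupil points per eye (diameter), the left ear and one whisker.  The
behavioral marker of embodiment is gaze: after a fast excursion toward the
threat common to all paired conditions, mice keep looking toward the
threatened artifact for several seconds only after synchronous pairing with
a limb-shaped object.

## Statistical procedure

### Difference traces

Analyses are mouse-level first: trials are averaged per (mouse, condition)
across sessions, never pooled across mice.  For a contrast A−B the per-mouse
difference trace is formed on the window [−1, +10] s around threat onset.
Two scales coexist deliberately:

* the **significance scale** uses raw (unnormalized) traces — so a genuine
  pre-threat offset between conditions is visible to the test;
* the **display/quantification scale** subtracts each trial's mean over the
  1 s preceding the threat (pre-threat normalization), isolating the evoked
  response; whole-trial displays instead subtract the 120 s baseline mean.

Both normalizations are shift-equivariant and idempotent.

### Baseline-segment maximum-statistic bootstrap

Family-wise error over the 11 s window is controlled by resampling null
segments from the same session pairs being contrasted: per mouse, the 120 s
baseline difference series (condition A minus condition B of a session,
averaged over that mouse's paired sessions).  Each of the 10,000 iterations
draws one 11 s segment per mouse at a uniformly random frame-aligned start
(with replacement across iterations, independently per mouse), averages the
segments across mice, and records the maximum of the averaged segment.  The
threshold is the empirical 95% quantile, taken as the ceil(0.95·B)-th order
statistic (inverse-CDF convention) so the threshold is a realized sample
value and convention-stable.

The maximum is taken of the *signed* averaged series — a one-sided test in
the toward-threat direction, which is the direction every hypothesis in the
paradigm concerns.  An absolute-value (two-sided) mode is available via
`mode="absolute"`.

### Window selection and quantification

Samples with group-mean difference above the threshold form maximal runs;
runs separated by gaps ≤ 50 ms are merged, runs shorter than 100 ms are
dropped, and the first two survivors by onset are labelled W1 and W2.  All
three numbers are configuration, surfaced in every report — no published
rule fixes them, and results should be checked for robustness to them.  Per
mouse and condition, the time-mean of the pre-threat-normalized trace over
each window is computed, and the paired difference across mice is tested
with a two-sided Wilcoxon signed-rank test: zero differences dropped, ties
mid-ranked, exact sign-flip distribution for n ≤ 25 (dynamic programming
over doubled ranks — identical to enumerating all 2^n assignments), normal
approximation with tie correction above.

### Difference of differences

To compare the strength of the sync−async effect between two experiments
(artificial limb vs. block), the per-mouse second-order trace
(limbA−limbB) − (blockA−blockB) is tested against a null built from the
per-mouse difference of the two experiments' baseline-difference series,
using the identical bootstrap.  Only mice present in both experiments enter.

## Synthetic cohort generator

The generator emulates the experiment at the level of tracked coordinates
(no video is synthesized).  Per trial:

* **Stroke schedules** — inter-onset intervals follow an exponential law of
  rate 1/s truncated to [0.6, 2.0] s ("Poisson-like" memorylessness within
  the documented bounds; a strictly Poisson train has unbounded intervals,
  so truncation is the modeling choice, recorded in the manifest).  Strokes
  last 300 ms and sweep 6 mm; a stroke must end inside the pairing window.
  Synchronous mode duplicates one train; asynchronous draws two.
* **Baseline noise** — a stationary Ornstein–Uhlenbeck process (default
  sd 1 px, correlation time 0.5 s; exact discretization) plus optional white
  measurement jitter (default 0.1 px).  Autocorrelation matters: a white
  null would make the max-statistic calibration trivially easy.
* **Heterogeneity** — one horizontal gaze offset per mouse (default sd
  5 px), shared across sessions, mirroring the diversity of resting pupil
  positions across animals.
* **Threat response** — deterministic templates added to the pupil x signal
  with a per-eye toward-threat sign (+x on the right camera, −x on the left;
  stored in the manifest so analysis never guesses): a fast
  difference-of-exponentials excursion (default 8 px, latency 0.1 s, rise
  0.05 s, decay 0.3 s; scaled to 15% in threat-only trials, where the onset
  reaction nearly disappears) and a sustained plateau from 1 to 7 s post
  threat with exponential release, whose amplitude ranks
  limb-sync (3 px) > limb-async (1.2) ≥ block-sync (1.0) ≥ block-async (0.6)
  > none (0.1).  The fast excursion is condition-independent among paired
  conditions, so the default cohorts carry their condition effect entirely
  in the sustained phase; early (W1-style) condition differences must be
  injected explicitly if wanted.
* **Diameter, ear, whisker** — a slow dilation transient on the vertical
  pupil-point separation (smaller in limb-sync, matching the paradigm's
  observation), and post-threat jitter bursts on ear/whisker whose amplitude
  scales with the condition's sustained amplitude.

Reproducibility: per-trial seeds derive from the cohort seed via
`SeedSequence((seed, stream, crc32(mouse_id), session, condition_code))`,
and every track draws from its own child stream — simulating a subset of
tracks is bit-identical to the full simulation.

**What the generator does not emulate** (so what passing tests do not show
about real data): blinks and tracking dropouts (confidence is 1 everywhere
unless files are edited), saccadic structure in gaze, slow drift or
habituation across sessions, trial-to-trial amplitude variability of the
threat response, and any coupling between signals beyond the shared gaze
trace.  The calibration result therefore certifies the inference machinery
under a stationary autocorrelated null, not the realism of mouse behavior.

## Numerical choices and degenerate inputs

* Empirical quantiles use the order-statistic convention above; with
  B = 1,000 the expected exceedance probability of the threshold is
  51/1001 ≈ 5.1%, the closest achievable to nominal.
* Interpolation of low-confidence samples (default threshold 0.9) is
  linear with edge-hold; an all-invalid track raises rather than fabricating
  data, and NaNs reaching the bootstrap raise.
* A mouse with zero usable trials for a condition is flagged missing, never
  silently dropped; mice missing one side of a contrast are excluded and
  listed in the trace's `dropped_mice`.
* All-zero inputs propagate cleanly: zero baselines give threshold 0 and no
  windows; an all-zero set of paired differences returns p = 1 with a
  degeneracy warning.
* Point speed uses the 2-D displacement norm times the frame rate with the
  first sample duplicated; the axis treatment is a documented choice.
* Per-session baselines of a mouse are averaged before bootstrapping
  (matching the averaging applied to the window traces, which keeps the
  null and the observed statistic on the same variance scale); no pooling
  across experiments.

## Problem sizes used by tests and the acceptance script

The calibration experiment uses 400 replicate null cohorts of 10 mice with
one session each and 1,000 bootstrap iterations; calibration is invariant to
the session count because window traces and null baselines average over the
same sessions, and one session keeps the experiment comfortably reproducible
on a laptop.  Power experiments use 100 replicates per amplitude.  Pipeline
and I/O tests run on reduced timelines (shorter epochs, 5–50 Hz); every
analysis component is rate- and duration-agnostic, so nothing but wall-clock
changes at 200 Hz.

## Known limitations

* The W1/W2 extraction constants (100 ms minimum duration, 50 ms merge gap)
  are conventions, not estimated quantities.
* The signed (one-sided) maximum is the default; effects away from the
  threat need `mode="absolute"`.
* The exact signed-rank test enumerates up to n = 25; beyond that the normal
  approximation is used without continuity correction.
* Tracking tables are CSV only (the common three-header-row dialect); no
  HDF5 layout is provided.
* No parametric time-series modeling, saccade detection, or cross-signal
  multiplicity correction — per-signal max-statistic control only, by
  design.
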