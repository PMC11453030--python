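# Methods

This note documents the models, numerical choices and known limitations of
the `gcsr` package: what is simulated, how the biomarker is computed, and
what the synthetic validation does and does not establish.

## The stop-signal task model

The task is a two-choice reaction task (left/right arrow, mouse click) in
which one trial of every four-trial set carries an auditory stop signal at a
stop-signal delay (SSD) after the go stimulus.  A session is one practice
block of 30 go-only trials followed by three stop blocks; each stop block
defaults to 15 sets (45 go + 15 stop trials), giving 5 stop trials per SSD
class per block.  The number of sets is configurable; 15 was chosen so the
three SSD classes divide evenly and a full session stays at desk scale.

**Staircases.**  Three SSDs run in parallel, all in integer milliseconds:

* short = 20% and long = 80% of MRT16, the mean reaction time over the 16
  most recent responded go trials, recomputed after every responded go trial;
* medium starts each block at 45% of MRT16 and moves +30 ms after a
  successful stop and −30 ms after a failed one (one-up/one-down, converging
  on the 50%-success SSD, the point of maximum go/stop conflict);
* medium is clamped into `[short + 50, long − 50]` whenever it moves *and*
  whenever short/long move past it, so the separation invariant holds at
  every trial.  Clamping (rather than skipping the update) preserves
  tracking while honouring the constraint.

At each block start the staircases re-initialise from the rolling window
carried over from the previous block.  Stop trials cycle through
short/medium/long in seeded balanced permuted triples; the stop position
within a set is seeded-uniform by default (configurable to a fixed slot).

**Participant.**  An independent horse race: go finishing times G are
normal(μ=450 ms, σ=100 ms by default) truncated below at 150 ms; the stop
process has fixed latency SSRT (200 ms default); the response is withheld
iff `SSD + SSRT ≤ G`.  Go omissions (2%) and choice errors (2%) stand in for
lapses; the real task's RT feedback mechanics are not modelled behaviourally
because the EEG analysis does not depend on them.

**A known property of the clamped staircase.**  Because the medium SSD is
re-clamped whenever go-RT fluctuation moves the long staircase, the clamp
acts as a small downward ratchet that the one-up/one-down walk compensates
with extra successes.  With the default participant the asymptotic
medium-SSD success rate is therefore ≈54%, not exactly 50%, and the bias
grows with go-RT variability (≈51% at σ=10 ms, ≈55% at σ=100 ms).  This is a
property of the task design itself, not of the estimator; the tracking claim
should be read as "near 50%" with a tolerance of a few percentage points.
Individual seeds scatter around that mean with sd ≈1.8 points (final 100 of
≥300 medium trials), so per-seed rates frequently leave [45%, 55%] even
though the seed-averaged rate stays well inside it.

**Trial pairing.**  Spectra are computed for each stop trial and one
adjacent go trial of the same set; the other two go trials are omitted.
"Adjacent" defaults to the immediately preceding go trial, falling back to
the following one when the stop trial opens the set (`policy="following"`
reverses this).  Paired go trials inherit the stop trial's SSD class and a
*virtual* stop time (go onset + paired SSD) for epoch alignment.

## Synthetic EEG

Each recording is synthesised at 512 Hz as the sum of three known parts:

* **Background**: Gaussian noise spectrally shaped to 1/f^α (α=1 default,
  flattened below 0.5 Hz, no DC), RMS-normalised exactly to
  `background_scale_uV` (10 µV default) — so doubling the scale doubles the
  RMS, and the generator is linear by construction.
* **Conflict burst at F8**: a Hanning-enveloped carrier spanning each
  trial's 1 s analysis window, amplitude chosen by that trial's
  (stop/go, SSD-class) condition.  The default carrier is a pure 8 Hz
  sinusoid with random phase (bandwidth 0); setting a bandwidth replaces it
  with band-limited noise of matched power.  By default only (STOP, MEDIUM)
  trials carry a burst, mimicking rhythmicity specific to the
  maximum-conflict condition; other channels carry background only,
  mirroring the F8-specific analysis.
* **Blinks at Fp1**: a fixed biphasic ~400 ms template (one sine cycle under
  a Hanning envelope) at Poisson times, mixed into frontal channels with
  fixed coefficients (F7/F8 get 35% of the Fp1 waveform).  Blink peak times
  are recorded as events, giving the removal stage a recoverable ground
  truth.

The default montage is a compact 8-channel frontal/mastoid set (Fp1, F7, F8,
Fz, Cz, CPz, M1, M2).  Since only F8 carries condition-dependent signal,
additional channels add cost without information; a 32-label cap is provided
as `FULL_MONTAGE_32` for montage-sensitive experiments.

**Effect-size default.**  The default burst amplitude is 8 µV against the
10 µV-RMS background.  It was calibrated, once, so that group differences in
the study-sized 2×2 design (4/4/5/5 subjects) are detectable with roughly
80% power by the full pipeline, while subject-level GCSR stays within a few
tenths of a log10 µV² unit.  The true patient effect size, topography and
bandwidth are unknown; these are free parameters of the generator, not
estimates.

**Cohorts.**  `default_design()` reproduces the study cells — GAD/SAD ×
TR/non-TR at 4/4/5/5 plus 11 TR-MDD and 15 non-TR comorbid GAD+MDD (44
subjects) — with the treatment-resistant GAD cell carrying no burst (the
group that lacked GCSR clinically) and a demographics table sampled around
published group means.  Per-subject seeds derive deterministically from
(master seed, subject id), so any subset reproduces in isolation.

## Preprocessing

Stage order: bandpass → downsample → re-reference → blink removal → epoch →
reject.  Each stage is a pure function of its input plus parameters.

* **Bandpass 1–36 Hz**: linear-phase FIR (Hamming, ~1 Hz transition bands,
  3.3·fs taps) applied once by FFT convolution with the group delay
  compensated — exactly zero phase with the designed magnitude response.
  One pass with delay compensation was preferred over forward–backward
  filtering because the latter squares the magnitude response and doubles
  the cost for no benefit at these band edges.  Edges are reflection-padded.
* **Downsample to 128 Hz**: FIR anti-aliased decimation (integer factors
  only); event indices rescale by floor division.
* **Re-reference**: subtract the samplewise mean of M1 and M2; idempotent,
  and the re-referenced mastoids sum to zero identically.
* **Blink removal**: peaks above 75 µV on a 1–10 Hz-filtered copy of Fp1
  (minimum 0.5 s apart) mark blinks; a per-channel blink-locked average
  template (±250 ms) is least-squares-scaled and subtracted at each
  occurrence.  Fewer than 5 detections passes the recording through with a
  warning.  The threshold and minimum count are explicit because the
  template-fitting procedures used with real clinical data are described
  only in external sources; this implementation honours the same contract
  (≥80% reduction of blink leakage on synthetic ground truth).
* **Epochs**: 1 s (128 samples), placed so the 500 ms stop-signal
  presentation is centred — `[stop_onset − 250 ms, stop_onset + 750 ms)`,
  alignment index 32.  Reading "centred on the 500 ms of the stop signal" as
  centring the *presentation period* is the default; centring on the onset
  itself (`[−500, +500) ms`) is available via `centring="onset"`.  The
  stop-signal duration (500 ms) is configurable.  Sample indexing is 0-based
  with half-open windows.
* **Rejection**: epochs whose analysis channel (F8) exceeds 150 µV
  peak-to-peak are deleted — a conventional screening bound, stated
  explicitly because no number is published.  All-epochs-rejected is a hard
  error; counts are reported per condition.

## The GCSR spectrum

Each epoch is Hanning-tapered and Fourier-transformed; the 1 s window gives
1 Hz bins, of which 1–14 Hz are kept.  Power is one-sided and normalised by
the squared coherent gain of the taper (a unit-amplitude sinusoid at an
exact bin has power ≈1), floored at 10⁻¹² µV² before log10 — the convention
cancels in the contrast, so only the floor matters numerically.  Log10 is
applied per epoch *before* condition averaging (transform, then average);
averaging linear power first is available via `log_domain=False` for
sensitivity analysis.

Per block the six condition means (2 stop/go × 3 SSD classes) are formed and
contrasted: stop-specific power per class (stop minus paired-go), then
medium minus the mean of short and long.  The short/long average cancels
activity tied merely to time-in-trial and any component linear in SSD class;
both cancellations are exact algebraic identities and are tested as such.
Spectra are smoothed with a 3-point running mean across frequency (dropping
the end bins: 1–14 Hz → 2–13 Hz) and averaged over blocks 2–3, where
clinical effects have been clearest.  The depression-style analysis
restricts to 2–10 Hz (9 bins).  F8 is the default channel; any channel is
selectable, and no left-handed F7 flip is applied.

## Trend statistics

For k equally spaced within-subject levels, `orth_poly(k)` builds the k−1
orthonormal polynomial contrasts by Gram–Schmidt on the Vandermonde basis
with one re-orthogonalisation pass (stable to k=12, order 11; verified
against Householder QR to 10⁻¹⁰).  For each order the per-subject trend
score (profile · contrast) enters a between-subjects factorial ANOVA with
sum-to-zero coding and type-III sums of squares — the convention of the
commercial packages used for the clinical analyses, which matters for the
unbalanced 4/4/5/5 cells.  The intercept test is the "frequency (order j)"
effect; each between term tests its interaction with that trend.  With 18
subjects in four cells every denominator df is 14.  Degenerate inputs (zero
trend variance) yield F=0 with an explicit note rather than an exception,
for batch robustness on synthetic nulls; p values are reported without
multiple-comparison correction across orders.

`gg_anova` gives the omnibus multi-df within-subject F: the repeated
measures are projected onto the orthonormal contrasts, sums of squares are
pooled across contrasts, and the Greenhouse–Geisser epsilon is estimated
from the pooled within-cell residual covariance of the projected data
(clamped to [1/(k−1), 1]), deflating both dfs.  Pooling within cells
follows the SPSS-style mixed-ANOVA convention; estimators that use the
grand covariance (e.g. pingouin's) give slightly different epsilons on
grouped data, which is why the cross-check against pingouin compares F
statistics rather than epsilon.

`run_study_analyses` packages the two study designs: (1) GAD/SAD ×
TR/non-TR over 2–13 Hz, orders 1–11; (2) TR-MDD vs non-TR comorbid GAD+MDD
as a single between factor over 2–10 Hz, orders 1–8.

## What the synthetic validation shows — and does not

Passing tests establish that the chain is *internally correct*: the task
model follows its printed rules; the generator's injected contrast is
recovered unbiasedly (null cohorts centre on zero GCSR) and monotonically;
the contrast identities hold exactly; the trend F tests match brute-force
sums of squares and are calibrated under the null; and injected group
structure of plausible magnitude is detected with ~80% power at study sample
sizes.  They do not establish anything about real patients: the generator's
bursts are stationary, narrow-band and confined to F8, its background has no
topography, volume conduction, drift or non-blink artifacts, and the true
clinical effect size and spectrum shape are unknown.  Reported clinical F
values cannot be reproduced because no data were deposited.

## Problem sizes and runtime

Defaults were chosen for desk-scale runs: a session is 210 trials (~7 min
of simulated EEG), one subject processes in well under a second, the
44-subject cohort in about half a minute.  Staircase-convergence estimates
use long sessions (300 sets per block, ≥300 medium stop trials) and 20
seeds; power estimates use 50 seeds of the 18-subject anxiety 2×2
sub-design, the design whose interaction terms are of interest.
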