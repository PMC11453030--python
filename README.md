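# gcsr — goal-conflict-specific rhythmicity from the stop-signal task

`gcsr` is a Python toolkit for the EEG biomarker known as
**goal-conflict-specific rhythmicity (GCSR)**: right-frontal (F8) theta-band
activity that appears specifically when going and stopping are in maximal
conflict during the stop-signal task (SST).  GCSR is of clinical interest as
a candidate biomarker for an anxiety process — and for treatment resistance
in generalised anxiety — but no public EEG accompanies the clinical studies.
This package therefore provides the *whole* measurement chain as tested,
reusable code, with a synthetic-data generator whose conflict signal is known
by construction, so every stage can be validated end to end:

1. **Task model** (`gcsr.task`) — SST simulation: three SSD staircases
   (short/long at 20%/80% of the rolling 16-trial go mean RT, medium starting
   at 45% and moving ±30 ms after each successful/failed stop, never within
   50 ms of the others), an independent horse-race participant
   (truncated-normal go finishing times, fixed SSRT; the response is withheld
   iff `SSD + SSRT ≤ G`), and trial-log generation/validation.
2. **Synthetic EEG** (`gcsr.synth`) — 512 Hz multichannel recordings: 1/f
   background, a Hanning-enveloped 8 Hz burst at F8 whose amplitude depends
   on the (stop/go, SSD-class) condition, stereotyped eyeblinks on Fp1 with
   known frontal mixing, and study-sized cohorts (44 subjects:
   GAD/SAD × TR/non-TR at 4/4/5/5, plus 11 TR-MDD and 15 comorbid GAD+MDD).
3. **Preprocessing** (`gcsr.preprocess`) — 1–36 Hz zero-phase FIR bandpass,
   decimation to 128 Hz, mastoid (M1/M2 mean) re-reference, template-fitting
   blink removal, 1 s stop-locked epochs, peak-to-peak artifact rejection.
4. **Spectral contrast** (`gcsr.spectral`) — per-epoch Hanning/FFT log10
   power (1 Hz bins, 1–14 Hz), the six condition means
   (2 stop/go × 3 short/medium/long SSD) per block, and the GCSR contrast

   ```
   GCSR(f) = [S_M(f) − G_M(f)] − ½·[(S_S(f) − G_S(f)) + (S_L(f) − G_L(f))]
   ```

   (medium-SSD stop-specific power minus the mean of short- and long-SSD
   stop-specific power), 3-point smoothed (→ 2–13 Hz) and averaged over
   blocks 2–3.
5. **Trend statistics** (`gcsr.stats`) — orthogonal-polynomial decomposition
   of the frequency factor inside a between-subjects factorial ANOVA
   (type-III sums of squares, sum-to-zero coding; every single-df trend F is
   reported per order), plus a Greenhouse–Geisser-corrected omnibus mixed
   ANOVA for demographics-style repeated measures.

## Worked example

```bash
python examples/01_simulate_task.py
```

prints (seed 1):

```
simulated 210 trials (30 practice go trials)
block 1: short 85 ms, medium 190 -> 160 ms, long 339 ms
block 2: short 91 ms, medium 205 -> 235 ms, long 364 ms
block 3: short 89 ms, medium 200 -> 230 ms, long 356 ms
medium-SSD stopping success: 53% (the one-up/one-down staircase tracks 50%)
minimum staircase separation: 65 ms (never below 50 ms)
```

The staircase levels are fractions of the participant's running mean go RT
(~450 ms here), the medium staircase wanders in ±30 ms steps towards the SSD
where stopping succeeds half the time, and the 50 ms separation guarantee
holds throughout.  The other examples walk through the remaining stages:

* `02_synthetic_recording.py` — synthesise a recording; verify the blink
  ground truth and that the medium-stop windows carry an 8 Hz burst.
* `03_extract_gcsr.py` — full preprocessing + spectral extraction for one
  subject; prints the smoothed 2–13 Hz GCSR spectrum.
* `04_trend_anova.py` — polynomial-trend ANOVA on an 18-subject 2×2 design
  with a known theta-band group difference, plus the Greenhouse–Geisser
  omnibus test.
* `05_full_cohort.py` — the 44-subject study design end to end (about a
  minute): per-group mean theta GCSR and both study ANOVAs.

A thin CLI wraps the same functions:
`gcsr {simulate-task, simulate-cohort, preprocess-free extract, analyze, run-all}`
with `--config cfg.yaml --seed N --out ...` (see `gcsr --help`).

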