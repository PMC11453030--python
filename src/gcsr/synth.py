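"""Synthetic EEG recordings and cohorts with known goal-conflict rhythmicity.

No public EEG accompanies the clinical GCSR studies, so every downstream
stage is validated against recordings whose conflict signal is known by
construction.  A recording is:

* a 1/f^alpha Gaussian background on every channel (spectrally shaped white
  noise, RMS-calibrated so doubling the scale doubles the RMS exactly);
* at F8, a Hanning-enveloped narrow-band burst inside the 1 s analysis window
  of each trial, with amplitude set per (stop/go, SSD-class) condition —
  by default only (STOP, MEDIUM) carries a burst, mimicking rhythmicity
  specific to the maximum-conflict condition (theta band, peaking near 8 Hz);
* stereotyped biphasic eyeblinks on Fp1, linearly mixed into the other
  frontal channels with fixed known coefficients, giving the blink-removal
  stage a recoverable ground truth.

Cohorts mirror the study design: 44 subjects split 4/4/5/5 over
GAD/SAD x TR/non-TR plus 11 TR-MDD and 15 non-TR comorbid GAD+MDD.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .task import (
    ParticipantModel,
    SessionConfig,
    SsdClass,
    TrialRecord,
    TrialType,
    classify_trials,
    simulate_session,
    write_trial_log,
)

__all__ = [
    "DEFAULT_CHANNELS",
    "FULL_MONTAGE_32",
    "BLINK_MIXING",
    "EegRecording",
    "GcsrEffectSpec",
    "SubjectSpec",
    "SubjectData",
    "theta_boost",
    "generate_recording",
    "default_design",
    "anxiety_design",
    "iter_cohort",
    "generate_cohort",
    "subject_seed",
]

DEFAULT_CHANNELS = ["Fp1", "F7", "F8", "Fz", "Cz", "CPz", "M1", "M2"]

FULL_MONTAGE_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "M1", "T7", "C3", "Cz", "C4", "T8", "M2", "CP5", "CP1", "CPz", "CP2",
    "CP6", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
]

# fixed frontal leakage of the blink generator (fraction of the Fp1 waveform)
BLINK_MIXING = {
    "Fp1": 1.0, "Fp2": 0.9, "F7": 0.35, "F8": 0.35, "Fz": 0.30,
    "F3": 0.30, "F4": 0.30,
}

_ANALYSIS_PRE_S = 0.25  # window = [stop - 250 ms, stop + 750 ms)
_ANALYSIS_LEN_S = 1.0


@dataclass
class EegRecording:
    """Multichannel time series in microvolts with event markers."""

    channel_labels: list[str]
    sample_rate_hz: float
    data: np.ndarray  # channels x samples, uV
    events: list[tuple[int, str]]  # (sample_index, code)
    reference_label: str = "CPz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples matching labels")
        if len(self.channel_labels) < 5:
            raise ValueError("need at least 5 channels")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "EegRecording":
        return EegRecording(list(self.channel_labels), self.sample_rate_hz,
                            self.data.copy(), list(self.events), self.reference_label)


def theta_boost(amplitude_uv: float) -> dict:
    """Condition-amplitude map with a burst only on (STOP, MEDIUM) trials."""
    return {(TrialType.STOP, SsdClass.MEDIUM): float(amplitude_uv)}


@dataclass(frozen=True)
class GcsrEffectSpec:
    """Parameters of the injected conflict signal and background.

    ``amplitude_by_condition`` maps (trial_type, ssd_class) to the peak
    amplitude (uV) of the F8 burst inside that condition's analysis window;
    for GO trials the class is the *paired* stop trial's SSD class.  The
    default boosts only the maximum-conflict (STOP, MEDIUM) cell at 8 Hz with
    8 uV against a 10 uV-RMS 1/f background, calibrated so group differences
    in the study-sized 2x2 design are detectable with ~80% power while
    subject-level GCSR stays within a few tenths of a log10 uV^2 unit.
    """

    centre_freq_hz: float = 8.0
    bandwidth_hz: float = 0.0  # 0 -> pure sinusoid carrier (Hanning-enveloped)
    amplitude_by_condition: dict = field(default_factory=lambda: theta_boost(8.0))
    background_exponent: float = 1.0
    background_scale_uV: float = 10.0
    blink_rate_hz: float = 0.10
    blink_amplitude_uV: float = 120.0

    def __post_init__(self) -> None:
        if self.centre_freq_hz <= 0:
            raise ValueError("centre frequency must be positive")
        if self.bandwidth_hz < 0 or self.background_scale_uV < 0:
            raise ValueError("bandwidth and background scale must be >= 0")
        if self.blink_rate_hz < 0 or self.blink_amplitude_uV < 0:
            raise ValueError("blink parameters must be >= 0")
        for amp in self.amplitude_by_condition.values():
            if amp < 0:
                raise ValueError("condition amplitudes must be >= 0")

    def amplitude_for(self, trial_type: TrialType, ssd_class: SsdClass) -> float:
        return float(self.amplitude_by_condition.get((trial_type, ssd_class), 0.0))


def _background(n: int, fs: float, alpha: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha Gaussian noise with RMS exactly ``scale`` (uV)."""
    white = rng.standard_normal(n)
    if scale == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.maximum(f, 0.5) ** (-alpha / 2.0)  # flatten below 0.5 Hz
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    rms = float(np.sqrt(np.mean(x * x)))
    return x * (scale / rms)


def _blink_template(fs: float) -> np.ndarray:
    """Biphasic ~400 ms blink: one sine cycle under a Hanning envelope,
    normalised to unit peak."""
    n = int(round(0.4 * fs))
    t = np.arange(n) / fs
    tpl = np.hanning(n) * np.sin(2.0 * np.pi * t / 0.4)
    return tpl / np.abs(tpl).max()


def generate_recording(
    trials: Sequence[TrialRecord],
    spec: GcsrEffectSpec,
    seed: int,
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
    sample_rate_hz: float = 512.0,
    pairing_policy: str = "preceding",
    pad_s: float = 2.0,
) -> EegRecording:
    """Synthesise a 512 Hz recording for one session's trial log.

    Burst windows follow the downstream analysis window, [stop_onset - 250 ms,
    stop_onset + 750 ms); for paired GO trials the virtual stop time is
    go_onset + the paired stop trial's SSD.  Reproducible by seed.
    """
    labels = list(channel_labels)
    for required in ("F8", "Fp1", "M1", "M2"):
        if required not in labels:
            raise ValueError(f"channel list must include {required}")
    if spec.centre_freq_hz >= sample_rate_hz / 2:
        raise ValueError("centre frequency at or above Nyquist")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    fs = float(sample_rate_hz)
    t_end_ms = max(
        (t.stop_onset_ms if t.stop_onset_ms is not None else t.go_onset_ms)
        for t in trials
    ) + 2000
    n = int(np.ceil((t_end_ms / 1000.0 + pad_s) * fs))

    rng = np.random.default_rng(seed)
    data = np.empty((len(labels), n))
    for i in range(len(labels)):
        data[i] = _background(n, fs, spec.background_exponent,
                              spec.background_scale_uV, rng)

    # condition-dependent bursts at F8
    win_len = int(round(_ANALYSIS_LEN_S * fs))
    env = np.hanning(win_len)
    f8 = labels.index("F8")
    burst_windows = _burst_windows(trials, spec, pairing_policy, fs)
    overlaps = _count_overlaps(burst_windows, win_len)
    if overlaps:
        warnings.warn(f"{overlaps} overlapping analysis windows in generated bursts")
    for start, amp in burst_windows:
        if amp == 0.0 or start < 0 or start + win_len > n:
            continue
        t = np.arange(win_len) / fs
        if spec.bandwidth_hz == 0:
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.cos(2 * np.pi * spec.centre_freq_hz * t + phase)
        else:
            carrier = _narrowband_noise(win_len, fs, spec.centre_freq_hz,
                                        spec.bandwidth_hz, rng)
        data[f8, start:start + win_len] += amp * env * carrier

    # blinks on Fp1 with fixed frontal mixing
    blink_events: list[tuple[int, str]] = []
    if spec.blink_rate_hz > 0 and spec.blink_amplitude_uV > 0:
        tpl = _blink_template(fs) * spec.blink_amplitude_uV
        peak_off = int(np.argmax(np.abs(tpl)))
        duration_s = n / fs
        n_blinks = rng.poisson(spec.blink_rate_hz * duration_s)
        starts = np.sort(rng.integers(0, n - len(tpl), size=n_blinks))
        for k, s in enumerate(starts):
            for ch, w in BLINK_MIXING.items():
                if ch in labels:
                    data[labels.index(ch), s:s + len(tpl)] += w * tpl
            blink_events.append((int(s) + peak_off, f"blink/{k}"))

    events: list[tuple[int, str]] = list(blink_events)
    for tr in trials:
        events.append((int(round(tr.go_onset_ms / 1000.0 * fs)), f"go/{tr.trial_index}"))
        if tr.stop_onset_ms is not None:
            events.append((int(round(tr.stop_onset_ms / 1000.0 * fs)),
                           f"stop/{tr.trial_index}"))
    return EegRecording(labels, fs, data, events)


def _burst_windows(trials, spec, pairing_policy, fs):
    """(start_sample, amplitude) for every trial with a defined condition."""
    windows = []
    has_go_amps = any(k[0] is TrialType.GO for k in spec.amplitude_by_condition)
    pairs = None
    if has_go_amps:
        pairs, _, _ = classify_trials(trials, policy=pairing_policy)
        paired_class = {p.go.trial_index: p.stop.ssd_class for p in pairs}
    for tr in trials:
        if tr.trial_type is TrialType.STOP:
            amp = spec.amplitude_for(TrialType.STOP, tr.ssd_class)
            centre_ms = tr.stop_onset_ms
        else:
            if not has_go_amps or tr.trial_index not in paired_class:
                continue
            cls = paired_class[tr.trial_index]
            amp = spec.amplitude_for(TrialType.GO, cls)
            # virtual stop at the paired SSD cannot be recovered from the GO
            # record alone; approximate with the paired stop trial's SSD
            centre_ms = tr.go_onset_ms
            for p in pairs:
                if p.go.trial_index == tr.trial_index:
                    centre_ms = tr.go_onset_ms + p.stop.ssd_ms
                    break
        if amp > 0:
            start = int(round((centre_ms / 1000.0 - _ANALYSIS_PRE_S) * fs))
            windows.append((start, amp))
    return windows


def _count_overlaps(windows, win_len) -> int:
    starts = sorted(s for s, _ in windows)
    return sum(1 for a, b in zip(starts, starts[1:]) if b < a + win_len)


def _narrowband_noise(n, fs, centre, bw, rng) -> np.ndarray:
    """Gaussian noise band-limited to centre +/- bw/2, unit RMS * sqrt(2)
    so its power matches a unit-amplitude sinusoid."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= centre - bw / 2.0) & (f <= centre + bw / 2.0)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    rms = float(np.sqrt(np.mean(x * x)))
    if rms == 0:
        return np.zeros(n)
    return x * (1.0 / np.sqrt(2.0) / rms)


# ---------------------------------------------------------------------------
# cohorts

GROUPS = ("GAD_TR", "GAD_NOT", "SAD_TR", "SAD_NOT", "MDD_TR", "GMD_NOT", "CONTROL")

# study cell sizes: 4/4 GAD, 5/5 SAD, 11 TR-MDD, 15 non-TR comorbid GAD+MDD
DESIGN_CELLS = {
    "GAD_TR": 4, "GAD_NOT": 4, "SAD_TR": 5, "SAD_NOT": 5,
    "MDD_TR": 11, "GMD_NOT": 15,
}

# demographic score means (age, neuroticism, trait anxiety, PID-5 anxiety /
# depressiveness) per group, used to give synthetic cohorts a realistic
# demographics table for the matching-style repeated-measures analysis
_DEMOGRAPHIC_MEANS = {
    "GAD_NOT": {"age": 31.75, "EPQN": 15.25, "STAI": 54.50, "PID_Anx": 31.00, "PID_Dep": 27.25},
    "GAD_TR": {"age": 32.25, "EPQN": 20.50, "STAI": 63.75, "PID_Anx": 30.50, "PID_Dep": 39.00},
    "SAD_NOT": {"age": 28.00, "EPQN": 17.00, "STAI": 57.25, "PID_Anx": 30.25, "PID_Dep": 35.50},
    "SAD_TR": {"age": 28.40, "EPQN": 12.20, "STAI": 52.00, "PID_Anx": 24.40, "PID_Dep": 30.00},
    "GMD_NOT": {"age": 29.67, "EPQN": 15.13, "STAI": 56.40, "PID_Anx": 28.47, "PID_Dep": 31.07},
    "MDD_TR": {"age": 28.27, "EPQN": 16.64, "STAI": 61.91, "PID_Anx": 29.64, "PID_Dep": 39.55},
    "CONTROL": {"age": 29.0, "EPQN": 10.0, "STAI": 35.0, "PID_Anx": 12.0, "PID_Dep": 10.0},
}
_DEMOGRAPHIC_SD = {"age": 6.0, "EPQN": 5.0, "STAI": 9.0, "PID_Anx": 6.0, "PID_Dep": 9.0}


@dataclass
class SubjectSpec:
    subject_id: str
    group: str
    effect: GcsrEffectSpec
    participant: ParticipantModel = field(default_factory=ParticipantModel)
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class SubjectData:
    spec: SubjectSpec
    trials: list[TrialRecord]
    recording: EegRecording
    seed: int


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Deterministic per-subject seed derived from (master seed, id)."""
    h = zlib.crc32(subject_id.encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), h]).generate_state(1)[0] % (2**31))


def _make_subjects(cells: dict, boost_uv: float, null_group: str, seed: int,
                   effect_kwargs: dict | None = None) -> list[SubjectSpec]:
    rng = np.random.default_rng(seed)
    effect_kwargs = dict(effect_kwargs or {})
    subjects = []
    for group, size in cells.items():
        for i in range(1, size + 1):
            amp = 0.0 if group == null_group else boost_uv
            eff = GcsrEffectSpec(amplitude_by_condition=theta_boost(amp), **effect_kwargs)
            demo = {
                k: float(np.round(rng.normal(m, _DEMOGRAPHIC_SD[k]), 1))
                for k, m in _DEMOGRAPHIC_MEANS[group].items()
            }
            subjects.append(SubjectSpec(f"{group}_{i:02d}", group, eff, demographics=demo))
    return subjects


def default_design(boost_uv: float = 8.0, null_group: str = "GAD_TR",
                   seed: int = 0, **effect_kwargs) -> list[SubjectSpec]:
    """The 44-subject study design: every group carries the (STOP, MEDIUM)
    theta burst except ``null_group`` (default the treatment-resistant GAD
    cell, the group that lacked GCSR clinically)."""
    return _make_subjects(DESIGN_CELLS, boost_uv, null_group, seed, effect_kwargs)


def anxiety_design(boost_uv: float = 8.0, null_group: str = "GAD_TR",
                   seed: int = 0, **effect_kwargs) -> list[SubjectSpec]:
    """The 18-subject anxiety 2x2 sub-design (GAD/SAD x TR/non-TR)."""
    cells = {g: DESIGN_CELLS[g] for g in ("GAD_TR", "GAD_NOT", "SAD_TR", "SAD_NOT")}
    return _make_subjects(cells, boost_uv, null_group, seed, effect_kwargs)


def iter_cohort(
    design: Sequence[SubjectSpec],
    seed: int,
    session_config: SessionConfig | None = None,
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
) -> Iterator[SubjectData]:
    """Yield one simulated subject at a time (trial log + recording).

    Per-subject seeds derive deterministically from (master seed, subject_id),
    so any subset of the cohort is reproducible in isolation.
    """
    ids = [s.subject_id for s in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    if not design:
        raise ValueError("empty design")
    cfg = session_config or SessionConfig()
    for spec in design:
        sseed = subject_seed(seed, spec.subject_id)
        session = simulate_session(spec.participant, cfg, sseed)
        rec = generate_recording(session.trials, spec.effect, sseed + 1,
                                 channel_labels=channel_labels)
        yield SubjectData(spec, session.trials, rec, sseed)


def generate_cohort(
    design: Sequence[SubjectSpec],
    seed: int,
    out_dir,
    session_config: SessionConfig | None = None,
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
) -> pd.DataFrame:
    """Write one EDF + trial-log CSV per subject plus a manifest CSV.

    Returns the manifest (subject_id, group, file paths, injected effect
    parameters).
    """
    from pathlib import Path

    from .edf import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in iter_cohort(design, seed, session_config, channel_labels):
        sid = sub.spec.subject_id
        edf_path = out / f"{sid}.edf"
        csv_path = out / f"{sid}_trials.csv"
        write_edf(sub.recording, edf_path)
        write_trial_log(sub.trials, csv_path)
        eff = sub.spec.effect
        rows.append({
            "subject_id": sid,
            "group": sub.spec.group,
            "edf": edf_path.name,
            "trials": csv_path.name,
            "seed": sub.seed,
            "centre_freq_hz": eff.centre_freq_hz,
            "boost_uv": eff.amplitude_for(TrialType.STOP, SsdClass.MEDIUM),
            "background_uv": eff.background_scale_uV,
            **{k: v for k, v in sub.spec.demographics.items()},
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
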