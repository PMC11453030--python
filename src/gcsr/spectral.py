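"""GCSR spectral extraction.

Each 1 s epoch (128 samples at 128 Hz) is Hanning-tapered and Fourier
transformed, giving power at 1 Hz resolution; power is log10-transformed to
normalise error variance.  Per participant and block, log-power spectra are
averaged into the six condition cells, 2 (stop, go) x 3 (short, medium, long
SSD).  Goal-conflict-specific rhythmicity (GCSR) is the nominal
linear (stop/go) x quadratic (SSD) orthogonal polynomial contrast of those
cells:

    GCSR(f) = [S_M - G_M] - ((S_S - G_S) + (S_L - G_L)) / 2

i.e. medium-SSD stop-specific power minus the mean of short- and long-SSD
stop-specific power.  The short/long average cancels anything tied merely to
time-in-trial or to monotonic change with SSD, isolating activity specific to
the maximum-conflict (medium SSD) condition.  Spectra are smoothed with a
3-point running mean (1-14 Hz -> 2-13 Hz) and averaged over blocks 2-3.

Power convention: one-sided, normalised by the squared coherent gain of the
taper, so a unit-amplitude sinusoid at an exact bin has peak power 1
(log10 = 0).  Only log-power *differences* enter GCSR, so the convention does
not affect the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .task import SsdClass, TrialType

__all__ = [
    "LOG_POWER_FLOOR",
    "PowerSpectrum",
    "ConditionAverages",
    "GcsrSpectrum",
    "hanning_log_power",
    "hanning_power",
    "average_conditions",
    "gcsr_contrast",
    "smooth3",
    "block_average",
    "restrict_range",
    "subject_gcsr",
    "cohort_table",
    "write_gcsr_tsv",
]

LOG_POWER_FLOOR = 1e-12  # uV^2; avoids -inf on silent synthetic epochs
N_BINS = 14  # retained bins: 1..14 Hz at 1 Hz resolution
_EPOCH_LEN = 128
_FS = 128.0


@dataclass(frozen=True)
class PowerSpectrum:
    """Log10 power at 1..14 Hz for one epoch or one condition average."""

    freqs_hz: np.ndarray
    log_power: np.ndarray
    condition: tuple  # (trial_type, ssd_class, block)
    channel: str
    n_epochs: int = 1

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.log_power):
            raise ValueError("freqs and log_power length mismatch")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def hanning_power(samples: np.ndarray) -> np.ndarray:
    """One-sided tapered power at bins 1..14 Hz (linear uV^2 units)."""
    x = np.asarray(samples, dtype=float)
    if x.shape != (_EPOCH_LEN,):
        raise ValueError(f"epoch must have exactly {_EPOCH_LEN} samples, got {x.shape}")
    w = np.hanning(_EPOCH_LEN)
    spec = np.fft.rfft(x * w)
    # normalise by coherent gain: unit sinusoid at an exact bin -> power 1
    power = (2.0 * np.abs(spec) / w.sum()) ** 2
    return power[1 : N_BINS + 1]


def hanning_log_power(
    samples: np.ndarray,
    condition: tuple = (None, None, None),
    channel: str = "F8",
) -> PowerSpectrum:
    """Hanning-taper, Fourier transform and log10 one 1 s epoch."""
    power = np.maximum(hanning_power(samples), LOG_POWER_FLOOR)
    return PowerSpectrum(
        freqs_hz=np.arange(1, N_BINS + 1, dtype=float),
        log_power=np.log10(power),
        condition=condition,
        channel=channel,
    )


@dataclass
class ConditionAverages:
    """Per block, the six condition-mean spectra (2 stop/go x 3 SSD)."""

    cells: dict  # (block, TrialType, SsdClass) -> PowerSpectrum
    channel: str

    _CLASSES = (SsdClass.SHORT, SsdClass.MEDIUM, SsdClass.LONG)

    def cell(self, block: int, trial_type: TrialType, ssd_class: SsdClass) -> PowerSpectrum:
        key = (block, trial_type, ssd_class)
        if key not in self.cells:
            raise KeyError(f"missing condition cell {key}")
        return self.cells[key]

    def blocks(self) -> list[int]:
        return sorted({k[0] for k in self.cells})

    def validate_block(self, block: int) -> None:
        missing = [
            (block, tt.value, sc.value)
            for tt in (TrialType.STOP, TrialType.GO)
            for sc in self._CLASSES
            if (block, tt, sc) not in self.cells
        ]
        if missing:
            raise ValueError(f"incomplete condition grid, missing cells: {missing}")


def average_conditions(
    spectra: Iterable[PowerSpectrum],
    log_domain: bool = True,
) -> ConditionAverages:
    """Cell-wise mean over epochs for each (block, stop/go, SSD class).

    ``log_domain=True`` (default) averages the per-epoch log spectra
    (transform then average); ``False`` averages linear power then takes
    log10, for sensitivity analysis of the averaging order.
    """
    groups: dict[tuple, list[PowerSpectrum]] = {}
    channel = None
    for s in spectra:
        tt, sc, block = s.condition
        groups.setdefault((block, tt, sc), []).append(s)
        channel = s.channel
    if not groups:
        raise ValueError("no spectra to average")
    cells = {}
    for key, members in groups.items():
        stack = np.vstack([m.log_power for m in members])
        if log_domain:
            mean = stack.mean(axis=0)
        else:
            mean = np.log10(np.maximum((10.0 ** stack).mean(axis=0), LOG_POWER_FLOOR))
        cells[key] = PowerSpectrum(
            freqs_hz=members[0].freqs_hz.copy(),
            log_power=mean,
            condition=(key[1], key[2], key[0]),
            channel=members[0].channel,
            n_epochs=len(members),
        )
    return ConditionAverages(cells=cells, channel=channel)


def gcsr_contrast(cond: ConditionAverages, block: int) -> np.ndarray:
    """Stop/go x SSD-quadratic contrast over bins 1..14 Hz for one block."""
    cond.validate_block(block)

    def sp(tt: TrialType, sc: SsdClass) -> np.ndarray:
        return cond.cell(block, tt, sc).log_power

    stop_specific = {
        sc: sp(TrialType.STOP, sc) - sp(TrialType.GO, sc)
        for sc in (SsdClass.SHORT, SsdClass.MEDIUM, SsdClass.LONG)
    }
    return stop_specific[SsdClass.MEDIUM] - 0.5 * (
        stop_specific[SsdClass.SHORT] + stop_specific[SsdClass.LONG]
    )


def smooth3(values: np.ndarray) -> np.ndarray:
    """3-point running mean across frequency; the two end bins are dropped
    (14 bins at 1-14 Hz -> 12 bins at 2-13 Hz)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1-D vector of at least 3 bins")
    return np.convolve(v, np.ones(3) / 3.0, mode="valid")


@dataclass
class GcsrSpectrum:
    """Per-participant GCSR contrast values per frequency bin (log10 uV^2
    difference units) at one channel."""

    subject_id: str
    channel: str
    freqs_hz: np.ndarray
    gcsr: np.ndarray
    blocks_used: tuple[int, ...]
    smoothed: bool

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.gcsr):
            raise ValueError("freqs and gcsr length mismatch")


def block_average(
    gcsr_by_block: Mapping[int, np.ndarray],
    blocks: Sequence[int] = (2, 3),
) -> np.ndarray:
    """Bin-wise mean of per-block GCSR over the requested blocks."""
    missing = [b for b in blocks if b not in gcsr_by_block]
    if missing:
        raise ValueError(f"missing blocks: {missing}")
    return np.vstack([gcsr_by_block[b] for b in blocks]).mean(axis=0)


def restrict_range(g: GcsrSpectrum, lo_hz: float, hi_hz: float) -> GcsrSpectrum:
    """Keep bins with lo_hz <= f <= hi_hz (e.g. 2-10 Hz for the depression
    analysis)."""
    if lo_hz > hi_hz:
        raise ValueError("lo_hz must not exceed hi_hz")
    mask = (g.freqs_hz >= lo_hz) & (g.freqs_hz <= hi_hz)
    if not mask.any():
        raise ValueError(f"no bins in [{lo_hz}, {hi_hz}] Hz")
    return GcsrSpectrum(
        subject_id=g.subject_id,
        channel=g.channel,
        freqs_hz=g.freqs_hz[mask],
        gcsr=g.gcsr[mask],
        blocks_used=g.blocks_used,
        smoothed=g.smoothed,
    )


def subject_gcsr(
    epochs,
    subject_id: str,
    channel: str = "F8",
    blocks: Sequence[int] = (2, 3),
    smooth: bool = True,
    log_domain: bool = True,
) -> GcsrSpectrum:
    """Full per-subject extraction: epoch spectra -> condition averages ->
    per-block contrast -> smoothing -> block average."""
    spectra = [
        hanning_log_power(ep.channel_data(channel), condition=ep.condition, channel=channel)
        for ep in epochs
    ]
    cond = average_conditions(spectra, log_domain=log_domain)
    per_block = {}
    for b in blocks:
        raw = gcsr_contrast(cond, b)
        per_block[b] = smooth3(raw) if smooth else raw
    values = block_average(per_block, blocks)
    freqs = np.arange(2, 14, dtype=float) if smooth else np.arange(1, 15, dtype=float)
    return GcsrSpectrum(
        subject_id=subject_id,
        channel=channel,
        freqs_hz=freqs,
        gcsr=values,
        blocks_used=tuple(blocks),
        smoothed=smooth,
    )


def cohort_table(spectra: Iterable[GcsrSpectrum]) -> pd.DataFrame:
    """Wide table, one row per subject, one column per frequency bin."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra")
    freqs = spectra[0].freqs_hz
    for s in spectra[1:]:
        if not np.array_equal(s.freqs_hz, freqs):
            raise ValueError("subjects have mismatched frequency grids")
    df = pd.DataFrame(
        [s.gcsr for s in spectra],
        index=pd.Index([s.subject_id for s in spectra], name="subject_id"),
        columns=[f"{int(f)}Hz" for f in freqs],
    )
    return df


def write_gcsr_tsv(spectra: Iterable[GcsrSpectrum], path) -> None:
    """Long-format per-subject GCSR TSV (subject_id, channel, freq_hz, gcsr,
    blocks_used)."""
    rows = []
    for s in spectra:
        for f, v in zip(s.freqs_hz, s.gcsr):
            rows.append({
                "subject_id": s.subject_id,
                "channel": s.channel,
                "freq_hz": int(f),
                "gcsr": v,
                "blocks_used": ",".join(str(b) for b in s.blocks_used),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
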