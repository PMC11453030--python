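"""Stop-signal task (SST) model.

The SST is a two-choice reaction task in which a minority of trials carry an
auditory stop signal at a variable stop-signal delay (SSD) after the go
stimulus.  Behaviour is modelled as an independent horse race between a go
process (finishing-time distribution) and a stop process of fixed latency
(SSRT): the response is withheld iff ``ssd + ssrt <= go_finish_time``.

Three SSD staircases run in parallel.  Short and long SSDs track 20% and 80%
of the mean reaction time over the previous 16 go trials (MRT16); the medium
staircase starts each block at 45% of MRT16 and then moves +/-30 ms after each
successful/failed stop, clamped so it never comes within 50 ms of the short or
long staircase.  A one-up/one-down +/-30 ms rule converges on the SSD at which
stopping succeeds 50% of the time, the point of maximum go/stop conflict.

All times are integer milliseconds.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialType",
    "SsdClass",
    "Side",
    "TrialRecord",
    "StaircaseState",
    "ParticipantModel",
    "SessionConfig",
    "SessionResult",
    "TrialPair",
    "init_staircases",
    "update_medium",
    "update_short_long",
    "draw_go_finish",
    "race_trial",
    "stop_success_probability",
    "simulate_session",
    "classify_trials",
    "trials_to_frame",
    "write_trial_log",
    "read_trial_log",
]


class TrialType(str, enum.Enum):
    GO = "GO"
    STOP = "STOP"


class SsdClass(str, enum.Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    NONE = "NONE"


class Side(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


SHORT_FRACTION = 0.20
MEDIUM_FRACTION = 0.45
LONG_FRACTION = 0.80
STEP_MS = 30
MIN_SEPARATION_MS = 50
WINDOW_LEN = 16


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the stop-signal task."""

    trial_index: int
    block: int
    set_index: int
    position_in_set: int
    trial_type: TrialType
    ssd_class: SsdClass
    ssd_ms: int | None
    arrow: Side
    response: Side | None
    rt_ms: int | None
    correct: bool
    go_onset_ms: int
    stop_onset_ms: int | None

    def __post_init__(self) -> None:
        if self.trial_type is TrialType.STOP:
            if self.ssd_ms is None or self.stop_onset_ms is None:
                raise ValueError("STOP trial requires ssd_ms and stop_onset_ms")
            if self.stop_onset_ms != self.go_onset_ms + self.ssd_ms:
                raise ValueError("stop_onset_ms must equal go_onset_ms + ssd_ms")
        else:
            if self.ssd_class is not SsdClass.NONE:
                raise ValueError("GO trial must have ssd_class NONE")
        if (self.rt_ms is None) != (self.response is None):
            raise ValueError("rt_ms must be present iff a response was made")


@dataclass(frozen=True)
class StaircaseState:
    """The three SSD staircases plus the rolling go-RT window they track."""

    short_ms: int
    medium_ms: int
    long_ms: int
    go_rt_window: tuple[int, ...]
    step_ms: int = STEP_MS
    min_separation_ms: int = MIN_SEPARATION_MS

    def __post_init__(self) -> None:
        if len(self.go_rt_window) != WINDOW_LEN:
            raise ValueError(f"go_rt_window must hold {WINDOW_LEN} reaction times")
        if self.short_ms < 0:
            raise ValueError("SSDs must be non-negative")
        if not (
            self.short_ms + self.min_separation_ms
            <= self.medium_ms
            <= self.long_ms - self.min_separation_ms
        ):
            raise ValueError(
                "staircase separation violated: "
                f"short={self.short_ms} medium={self.medium_ms} long={self.long_ms}"
            )

    @property
    def mrt_ms(self) -> float:
        return float(np.mean(self.go_rt_window))


def _validate_rts(go_rts: Sequence[float]) -> list[int]:
    if len(go_rts) < WINDOW_LEN:
        raise ValueError(
            f"need at least {WINDOW_LEN} go reaction times, got {len(go_rts)}"
        )
    rts = list(go_rts)[-WINDOW_LEN:]
    for rt in rts:
        if not math.isfinite(rt) or rt <= 0:
            raise ValueError(f"invalid go reaction time: {rt!r}")
    return [int(round(rt)) for rt in rts]


def _clamp_medium(medium: int, short: int, long: int, sep: int = MIN_SEPARATION_MS) -> int:
    lo, hi = short + sep, long - sep
    if lo > hi:
        raise ValueError(
            f"no admissible medium SSD: [{lo}, {hi}] is empty "
            f"(short={short}, long={long})"
        )
    return min(max(medium, lo), hi)


def init_staircases(go_rts: Sequence[float]) -> StaircaseState:
    """Initialise the three staircases from the last 16 go reaction times.

    Short/long are 20%/80% of MRT16 and the medium staircase starts at 45%,
    clamped to stay at least 50 ms away from both.
    """
    window = _validate_rts(go_rts)
    mrt = float(np.mean(window))
    short = int(round(SHORT_FRACTION * mrt))
    long = int(round(LONG_FRACTION * mrt))
    medium = _clamp_medium(int(round(MEDIUM_FRACTION * mrt)), short, long)
    return StaircaseState(short, medium, long, tuple(window))


def update_medium(state: StaircaseState, last_stop_success: bool) -> StaircaseState:
    """One-up/one-down +/-30 ms move of the medium staircase, clamped."""
    medium = state.medium_ms + (state.step_ms if last_stop_success else -state.step_ms)
    medium = _clamp_medium(medium, state.short_ms, state.long_ms, state.min_separation_ms)
    return dataclasses.replace(state, medium_ms=medium)


def update_short_long(state: StaircaseState, new_go_rt: float) -> StaircaseState:
    """Roll the go-RT window and recompute the 20%/80% staircases."""
    if not math.isfinite(new_go_rt) or new_go_rt <= 0:
        raise ValueError(f"invalid go reaction time: {new_go_rt!r}")
    window = state.go_rt_window[1:] + (int(round(new_go_rt)),)
    mrt = float(np.mean(window))
    short = int(round(SHORT_FRACTION * mrt))
    long = int(round(LONG_FRACTION * mrt))
    medium = _clamp_medium(state.medium_ms, short, long, state.min_separation_ms)
    return dataclasses.replace(
        state, short_ms=short, medium_ms=medium, long_ms=long, go_rt_window=window
    )


@dataclass(frozen=True)
class ParticipantModel:
    """Horse-race participant.

    Go finishing times are truncated-normal (floor ``rt_floor_ms``); the stop
    process has fixed latency ``ssrt_ms``.  Occasional go omissions and choice
    errors stand in for lapses (and for the speed-feedback mechanics of the
    real task, which are not modelled behaviourally).
    """

    go_rt_mean_ms: float = 450.0
    go_rt_sd_ms: float = 100.0
    ssrt_ms: int = 200
    go_omission_rate: float = 0.02
    choice_error_rate: float = 0.02
    rt_floor_ms: float = 150.0

    def __post_init__(self) -> None:
        if self.go_rt_mean_ms <= 0 or self.ssrt_ms <= 0:
            raise ValueError("go_rt_mean_ms and ssrt_ms must be positive")
        for p in (self.go_omission_rate, self.choice_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")


def draw_go_finish(p: ParticipantModel, rng: np.random.Generator) -> int:
    """Sample a go finishing time (ms) from the floored normal distribution."""
    while True:
        g = rng.normal(p.go_rt_mean_ms, p.go_rt_sd_ms)
        if g >= p.rt_floor_ms:
            return int(round(g))


def race_trial(
    p: ParticipantModel,
    trial_type: TrialType,
    ssd_ms: int | None,
    arrow: Side,
    rng: np.random.Generator,
) -> tuple[Side | None, int | None, bool]:
    """Run the independent horse race for one trial.

    Returns ``(response, rt_ms, correct)``.  On STOP trials the response is
    withheld iff ``ssd + ssrt <= G`` where G is the go finishing time.
    """
    if trial_type is TrialType.STOP:
        if ssd_ms is None:
            raise ValueError("STOP trial requires ssd_ms")
        g = draw_go_finish(p, rng)
        if ssd_ms + p.ssrt_ms <= g:
            return None, None, True  # successful inhibition
        response = arrow if rng.random() >= p.choice_error_rate else _other(arrow)
        return response, g, False
    if rng.random() < p.go_omission_rate:
        return None, None, False
    g = draw_go_finish(p, rng)
    response = arrow if rng.random() >= p.choice_error_rate else _other(arrow)
    return response, g, response is arrow


def _other(side: Side) -> Side:
    return Side.RIGHT if side is Side.LEFT else Side.LEFT


def stop_success_probability(p: ParticipantModel, ssd_ms: float) -> float:
    """Closed-form P(successful stop | SSD) for the truncated-normal race."""
    from scipy.stats import norm

    mu, sd, floor = p.go_rt_mean_ms, p.go_rt_sd_ms, p.rt_floor_ms
    denom = norm.sf((floor - mu) / sd)
    threshold = max(ssd_ms + p.ssrt_ms, floor)
    return float(norm.sf((threshold - mu) / sd) / denom)


@dataclass(frozen=True)
class SessionConfig:
    """Session layout: one practice go-only block then stop blocks of
    four-trial sets (3 go + 1 stop each)."""

    n_block0_go_trials: int = 30
    n_sets_per_block: int = 15
    n_blocks: int = 3
    stop_position_policy: str = "random"  # "random" or "fixed:<pos>"
    trial_period_ms: int = 2000
    start_offset_ms: int = 5000

    def __post_init__(self) -> None:
        if self.n_block0_go_trials < WINDOW_LEN:
            raise ValueError(
                f"n_block0_go_trials must be >= {WINDOW_LEN} to fill the RT window"
            )
        if self.n_sets_per_block < 1 or self.n_blocks < 1:
            raise ValueError("need at least one set and one block")
        if self.trial_period_ms <= 0 or self.start_offset_ms < 0:
            raise ValueError("timing parameters must be positive")
        if self.stop_position_policy != "random":
            if not self.stop_position_policy.startswith("fixed:"):
                raise ValueError(
                    "stop_position_policy must be 'random' or 'fixed:<0..3>'"
                )
            pos = int(self.stop_position_policy.split(":", 1)[1])
            if not 0 <= pos <= 3:
                raise ValueError("fixed stop position must be in 0..3")


@dataclass
class SessionResult:
    trials: list[TrialRecord]
    staircase_trace: pd.DataFrame  # trial_index, block, short_ms, medium_ms, long_ms
    final_state: StaircaseState


def _balanced_classes(n_sets: int, rng: np.random.Generator) -> list[SsdClass]:
    """Seeded balanced ordering of SHORT/MEDIUM/LONG over the sets of a block.

    Full triples are permuted independently; a remainder (when n_sets is not a
    multiple of 3) is drawn without replacement from a final shuffled triple.
    """
    classes: list[SsdClass] = []
    triple = [SsdClass.SHORT, SsdClass.MEDIUM, SsdClass.LONG]
    for _ in range(n_sets // 3):
        order = rng.permutation(3)
        classes.extend(triple[i] for i in order)
    rem = n_sets % 3
    if rem:
        order = rng.permutation(3)
        classes.extend(triple[i] for i in order[:rem])
    return classes


def simulate_session(
    p: ParticipantModel, cfg: SessionConfig, seed: int
) -> SessionResult:
    """Simulate a full session: block 0 (go-only practice) then the stop blocks.

    Staircases re-initialise at each block start from the rolling go-RT window
    carried over from the end of the previous block; within a block the
    short/long staircases update after every responded go trial and the medium
    staircase after every medium-SSD stop trial.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    trace_rows: list[tuple[int, int, int, int, int]] = []
    window: deque[int] = deque(maxlen=WINDOW_LEN)
    t_ms = cfg.start_offset_ms
    idx = 0

    for i in range(cfg.n_block0_go_trials):
        arrow = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        response, rt, correct = race_trial(p, TrialType.GO, None, arrow, rng)
        trials.append(
            TrialRecord(idx, 0, i, 0, TrialType.GO, SsdClass.NONE, None, arrow,
                        response, rt, correct, t_ms, None)
        )
        if rt is not None:
            window.append(rt)
        t_ms += cfg.trial_period_ms
        idx += 1

    if len(window) < WINDOW_LEN:
        raise RuntimeError(
            "fewer than 16 responded go trials in block 0; cannot seed staircases"
        )

    state = init_staircases(list(window))
    for block in range(1, cfg.n_blocks + 1):
        # block-initial SSDs recomputed from the rolling go RT window carried
        # over from the end of the previous block (medium resets to 45%)
        state = init_staircases(list(state.go_rt_window))
        classes = _balanced_classes(cfg.n_sets_per_block, rng)
        for set_idx, ssd_class in enumerate(classes):
            if cfg.stop_position_policy == "random":
                stop_pos = int(rng.integers(0, 4))
            else:
                stop_pos = int(cfg.stop_position_policy.split(":", 1)[1])
            for pos in range(4):
                arrow = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
                trace_rows.append(
                    (idx, block, state.short_ms, state.medium_ms, state.long_ms)
                )
                if pos == stop_pos:
                    ssd = {
                        SsdClass.SHORT: state.short_ms,
                        SsdClass.MEDIUM: state.medium_ms,
                        SsdClass.LONG: state.long_ms,
                    }[ssd_class]
                    response, rt, correct = race_trial(
                        p, TrialType.STOP, ssd, arrow, rng
                    )
                    trials.append(
                        TrialRecord(idx, block, set_idx, pos, TrialType.STOP,
                                    ssd_class, ssd, arrow, response, rt, correct,
                                    t_ms, t_ms + ssd)
                    )
                    if ssd_class is SsdClass.MEDIUM:
                        state = update_medium(state, correct)
                else:
                    response, rt, correct = race_trial(
                        p, TrialType.GO, None, arrow, rng
                    )
                    trials.append(
                        TrialRecord(idx, block, set_idx, pos, TrialType.GO,
                                    SsdClass.NONE, None, arrow, response, rt,
                                    correct, t_ms, None)
                    )
                    if rt is not None:
                        state = update_short_long(state, rt)
                t_ms += cfg.trial_period_ms
                idx += 1

    trace = pd.DataFrame(
        trace_rows, columns=["trial_index", "block", "short_ms", "medium_ms", "long_ms"]
    )
    return SessionResult(trials, trace, state)


@dataclass(frozen=True)
class TrialPair:
    stop: TrialRecord
    go: TrialRecord


def classify_trials(
    trials: Iterable[TrialRecord], policy: str = "preceding"
) -> tuple[list[TrialPair], dict[tuple[int, TrialType, SsdClass], list[TrialRecord]], list[TrialRecord]]:
    """Partition stop-block trials and pair each STOP with its adjacent GO.

    ``policy`` is "preceding" (default; falls back to the following go when the
    stop opens the set) or "following" (symmetric fallback).  Returns
    ``(pairs, partition, omitted_go_trials)``; the partition keys GO trials by
    their *paired* SSD class, and the two unpaired go trials of each set are
    returned in ``omitted_go_trials``.
    """
    if policy not in ("preceding", "following"):
        raise ValueError(f"unknown pairing policy: {policy!r}")
    sets: dict[tuple[int, int], list[TrialRecord]] = {}
    for tr in trials:
        if tr.block == 0:
            continue
        sets.setdefault((tr.block, tr.set_index), []).append(tr)

    bad = [
        key
        for key, members in sets.items()
        if len(members) != 4
        or sum(t.trial_type is TrialType.STOP for t in members) != 1
    ]
    if bad:
        raise ValueError(f"malformed sets (block, set_index): {sorted(bad)}")

    pairs: list[TrialPair] = []
    partition: dict[tuple[int, TrialType, SsdClass], list[TrialRecord]] = {}
    omitted: list[TrialRecord] = []
    for key in sorted(sets):
        members = sorted(sets[key], key=lambda t: t.position_in_set)
        stop = next(t for t in members if t.trial_type is TrialType.STOP)
        gos = [t for t in members if t.trial_type is TrialType.GO]
        p = stop.position_in_set
        preceding = [g for g in gos if g.position_in_set < p]
        following = [g for g in gos if g.position_in_set > p]
        if policy == "preceding":
            paired = preceding[-1] if preceding else following[0]
        else:
            paired = following[0] if following else preceding[-1]
        pairs.append(TrialPair(stop, paired))
        omitted.extend(g for g in gos if g is not paired)
        partition.setdefault((stop.block, TrialType.STOP, stop.ssd_class), []).append(stop)
        partition.setdefault((stop.block, TrialType.GO, stop.ssd_class), []).append(paired)
    return pairs, partition, omitted


# ---------------------------------------------------------------------------
# trial-log CSV round trip

_CSV_COLUMNS = [
    "trial_index", "block", "set_index", "position_in_set", "trial_type",
    "ssd_class", "ssd_ms", "arrow", "response", "rt_ms", "correct",
    "go_onset_ms", "stop_onset_ms",
]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "trial_index": t.trial_index,
            "block": t.block,
            "set_index": t.set_index,
            "position_in_set": t.position_in_set,
            "trial_type": t.trial_type.value,
            "ssd_class": t.ssd_class.value,
            "ssd_ms": "" if t.ssd_ms is None else t.ssd_ms,
            "arrow": t.arrow.value,
            "response": "" if t.response is None else t.response.value,
            "rt_ms": "" if t.rt_ms is None else t.rt_ms,
            "correct": t.correct,
            "go_onset_ms": t.go_onset_ms,
            "stop_onset_ms": "" if t.stop_onset_ms is None else t.stop_onset_ms,
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_trial_log(trials: Iterable[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trial_log(path) -> list[TrialRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")

    def _opt_int(v):
        return None if v == "" else int(float(v))

    out = []
    for _, r in df.iterrows():
        out.append(TrialRecord(
            trial_index=int(r.trial_index),
            block=int(r.block),
            set_index=int(r.set_index),
            position_in_set=int(r.position_in_set),
            trial_type=TrialType(r.trial_type),
            ssd_class=SsdClass(r.ssd_class),
            ssd_ms=_opt_int(r.ssd_ms),
            arrow=Side(r.arrow),
            response=None if r.response == "" else Side(r.response),
            rt_ms=_opt_int(r.rt_ms),
            correct=str(r.correct).lower() in ("true", "1"),
            go_onset_ms=int(r.go_onset_ms),
            stop_onset_ms=_opt_int(r.stop_onset_ms),
        ))
    return out
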