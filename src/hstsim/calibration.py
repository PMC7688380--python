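"""Numeric device-calibration protocol.

Covers the computational half of transducer calibration: converting dB HL
to dB SPL through a table of reference equivalent threshold sound pressure
levels (RETSPL), the ISO 8253-1 style ascending threshold search in 1-dB
steps, the 2-down/1-up adaptive staircase stopped after a fixed number of
reversals, and the pass/fail checks on measured output tables (left/right
channel balance < 1 dB, device-to-device < 1.5 dB).

The 2-down/1-up rule (level decreases only after two consecutive
responses, increases after any non-response) converges to the stimulus
level where the response probability is 1/sqrt(2) ~ 70.7% (Levitt's
transformed up-down method); the test suite verifies that asymptote by
Monte Carlo.  Responders are plain ``level -> bool`` callables.

No transducer constants are shipped: the RETSPL table defaults to identity
(all offsets 0) so pure simulations run in dB HL; real tables load from
CSV (columns ``freq_hz,value_db``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

from .core import CALIBRATION_FREQUENCIES

logger = logging.getLogger(__name__)

Responder = Callable[[float], bool]


@dataclass
class RetsplTable:
    """freq (Hz) -> RETSPL offset (dB): dB SPL = dB HL + offset."""

    offsets: dict[int, float] = field(
        default_factory=lambda: {f: 0.0 for f in CALIBRATION_FREQUENCIES}
    )

    def __post_init__(self) -> None:
        for f, v in self.offsets.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite RETSPL offset at {f} Hz")

    def offset(self, freq: int) -> float:
        try:
            return self.offsets[freq]
        except KeyError:
            raise KeyError(f"no RETSPL entry for {freq} Hz") from None

    @classmethod
    def from_csv(cls, path) -> "RetsplTable":
        frame = pd.read_csv(path)
        return cls({int(r.freq_hz): float(r.value_db) for r in frame.itertuples()})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"freq_hz": sorted(self.offsets), "value_db": [self.offsets[f] for f in sorted(self.offsets)]}
        ).to_csv(path, index=False)


def dbhl_to_dbspl(level_db_hl: float, freq: int, table: RetsplTable) -> float:
    return level_db_hl + table.offset(freq)


def dbspl_to_dbhl(level_db_spl: float, freq: int, table: RetsplTable) -> float:
    return level_db_spl - table.offset(freq)


@dataclass
class StaircaseConfig:
    step_db: float = 1.0
    down_count: int = 2          # consecutive responses required to step down
    stop_reversals: int = 3
    start_offset_db: float = -10.0   # relative to the known threshold
    level_bounds: tuple[float, float] = (-30.0, 130.0)
    discard_reversals: int = 0   # initial reversals excluded from the estimate

    def __post_init__(self) -> None:
        if self.step_db <= 0:
            raise ValueError("step_db must be positive")
        if self.stop_reversals < 1:
            raise ValueError("stop_reversals must be >= 1")
        if not (0 <= self.discard_reversals < self.stop_reversals):
            raise ValueError("discard_reversals must leave at least one reversal")


@dataclass(frozen=True)
class StaircaseResult:
    estimate_db: float
    reversal_levels: tuple[float, ...]
    n_trials: int


def ascending_threshold(
    responder: Responder,
    start_db: float,
    step_db: float = 1.0,
    max_level_db: float = 130.0,
) -> float:
    """Raise the level in fixed steps until the first response.

    A response at the starting level is degenerate (the start was not below
    the threshold region); the start level is returned as-is.
    """
    level = start_db
    while level <= max_level_db:
        if responder(level):
            if level == start_db:
                logger.warning(
                    "ascending search responded at the start level %.1f dB; "
                    "start was not below the threshold region",
                    start_db,
                )
            return level
        level += step_db
    raise RuntimeError(f"no response up to {max_level_db} dB in ascending search")


def staircase_2down1up(
    responder: Responder,
    known_threshold_db: float,
    config: StaircaseConfig | None = None,
) -> StaircaseResult:
    """2-down/1-up staircase; estimate = mean of the kept reversal levels."""
    config = config or StaircaseConfig()
    lo, hi = config.level_bounds
    level = known_threshold_db + config.start_offset_db
    consecutive = 0
    direction = 0  # -1 down, +1 up, 0 before first move
    reversals: list[float] = []
    n = 0
    max_trials = 10000

    while len(reversals) < config.stop_reversals:
        if n >= max_trials:
            raise RuntimeError("staircase failed to accumulate reversals")
        heard = responder(level)
        n += 1
        if heard:
            consecutive += 1
            if consecutive < config.down_count:
                continue  # stay at this level, need another response
            consecutive = 0
            move = -1
        else:
            consecutive = 0
            move = +1
        if direction != 0 and move != direction:
            reversals.append(level)
        direction = move
        level += move * config.step_db
        if not (lo <= level <= hi):
            raise RuntimeError(f"staircase ran away to {level} dB (bounds {lo}..{hi})")

    kept = reversals[config.discard_reversals :]
    return StaircaseResult(
        estimate_db=sum(kept) / len(kept),
        reversal_levels=tuple(reversals),
        n_trials=n,
    )


#: Level at which a logistic psychometric function crosses the 2-down/1-up
#: convergence probability 1/sqrt(2) (guess = lapse = 0).
def levitt_target_level(threshold_db: float, slope_db: float) -> float:
    p = 1.0 / math.sqrt(2.0)
    return threshold_db + slope_db * math.log(p / (1.0 - p))


def channel_balance_check(
    outputs_a: Mapping[int, float],
    outputs_b: Mapping[int, float],
    limit_db: float = 1.0,
) -> tuple[float, bool]:
    """Max per-frequency output difference and pass/fail against a limit.

    Left/right EarPod balance uses the default 1-dB limit; pass
    ``limit_db=1.5`` for the device-to-device comparison.
    """
    if set(outputs_a) != set(outputs_b):
        raise ValueError(
            f"frequency sets differ: {sorted(outputs_a)} vs {sorted(outputs_b)}"
        )
    if not outputs_a:
        raise ValueError("empty output tables")
    max_diff = max(abs(outputs_a[f] - outputs_b[f]) for f in outputs_a)
    return max_diff, max_diff < limit_db
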