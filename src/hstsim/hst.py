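"""The Hearing Scale Test (HST) engine.

The HST finds, per ear, the *minimum audible hearing scale*: the lowest
scale at which the listener responds to all four test tones (1, 2, 4 and
0.5 kHz, in that fixed order).  Testing starts at S5 (25 dB HL).  The level
descends one scale only after an all-correct block; on any miss it ascends
one scale.  The search stops once the boundary is bracketed — an
all-correct block at scale ``k`` with a missed block on record at ``k-1``
(or ``k == 1`` all-correct).  A miss at S20 with no all-correct block on
record anywhere yields NO_RESPONSE.

Each visited scale is re-tested in full (no response caching), and within a
block presentation stops at the first miss — the all-correct requirement is
already violated, so the remaining tones of the block are skipped.

The test is gated on ambient noise below 50 dBA, measured before testing.
Tone duration and inter-stimulus interval are logged metadata only;
simulated time is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import (
    HST_FREQUENCIES,
    NO_RESPONSE,
    SCALE_MAX,
    SCALE_MIN,
    Audiogram,
    EarSide,
    HearingScale,
    InterauralDifference,
    interaural_difference,
    scale_to_db,
)
from .listener import ListenerModel

#: Fixed presentation order of the four test tones (Hz).
DEFAULT_FREQ_ORDER: tuple[int, ...] = (1000, 2000, 4000, 500)

AMBIENT_LIMIT_DBA = 50.0


@dataclass
class HSTConfig:
    start_scale: int = 5
    freq_order: tuple[int, ...] = DEFAULT_FREQ_ORDER
    tone_duration_s: float = 1.5
    inter_stimulus_interval_s: tuple[float, float] = (2.0, 3.0)
    # worst-case complete run (full ascent S1 -> S20, miss on the last tone
    # of every failing block) needs 84 presentations; the cap only trips
    # oscillating stochastic listeners
    max_presentations: int = 120
    ambient_limit_dba: float = AMBIENT_LIMIT_DBA
    confirm_repeats: int = 0
    ear_order: tuple[EarSide, EarSide] = (EarSide.RIGHT, EarSide.LEFT)

    def __post_init__(self) -> None:
        if not (SCALE_MIN <= self.start_scale <= SCALE_MAX):
            raise ValueError(f"start_scale must be in [{SCALE_MIN}, {SCALE_MAX}]")
        if sorted(self.freq_order) != sorted(HST_FREQUENCIES):
            raise ValueError(f"freq_order must be a permutation of {HST_FREQUENCIES}")
        if self.max_presentations < 4:
            raise ValueError("max_presentations must allow at least one full block")
        if self.confirm_repeats < 0:
            raise ValueError("confirm_repeats must be >= 0")


@dataclass(frozen=True)
class Trial:
    scale: int
    freq_hz: int
    level_db_hl: float
    heard: bool


@dataclass
class HSTResult:
    ear: EarSide
    min_audible_scale: HearingScale
    trial_log: list[Trial] = field(default_factory=list)
    valid: bool = True
    abort_reason: str | None = None

    @property
    def n_presentations(self) -> int:
        return len(self.trial_log)

    def to_dict(self) -> dict:
        return {
            "ear": self.ear.value,
            "min_audible_scale": str(self.min_audible_scale),
            "valid": self.valid,
            "abort_reason": self.abort_reason,
            "trials": [
                {"scale": t.scale, "freq_hz": t.freq_hz, "level_db_hl": t.level_db_hl, "heard": t.heard}
                for t in self.trial_log
            ],
        }


def ambient_noise_gate(level_dba: float, limit_dba: float = AMBIENT_LIMIT_DBA) -> bool:
    """Pass iff ambient noise is strictly below the limit (default 50 dBA)."""
    if level_dba < 0:
        raise ValueError(f"ambient noise level cannot be negative, got {level_dba}")
    return level_dba < limit_dba


def deterministic_hst_oracle(audiogram: Audiogram, ear: EarSide) -> HearingScale:
    """Closed-form HST outcome for an ideal step-function listener.

    The lowest all-correct scale is forced by the worst of the four true
    thresholds: clamp(ceil(max_f threshold_f / 5), 1, 20), or NO_RESPONSE
    when the worst threshold exceeds S20's 100 dB HL.  Used as the
    independent oracle against the adaptive search.
    """
    worst = max(audiogram.threshold(ear, f) for f in HST_FREQUENCIES)
    if worst > scale_to_db(SCALE_MAX):
        return NO_RESPONSE
    return HearingScale(min(SCALE_MAX, max(SCALE_MIN, math.ceil(worst / 5.0))))


def _present_block(
    listener: ListenerModel, ear: EarSide, scale: int, config: HSTConfig, log: list[Trial]
) -> bool:
    """Present one scale block; stop at the first miss. True iff all heard."""
    level = scale_to_db(scale)
    for freq in config.freq_order:
        heard = listener.respond(level, freq, ear)
        log.append(Trial(scale=scale, freq_hz=freq, level_db_hl=level, heard=heard))
        if not heard:
            return False
    return True


def run_hst(
    listener: ListenerModel,
    ear: EarSide,
    config: HSTConfig | None = None,
    ambient_dba: float = 30.0,
) -> HSTResult:
    """Adaptive search for the minimum audible hearing scale of one ear."""
    config = config or HSTConfig()
    if not ambient_noise_gate(ambient_dba, config.ambient_limit_dba):
        raise RuntimeError(
            f"ambient noise {ambient_dba} dBA at or above the {config.ambient_limit_dba} dBA limit"
        )
    missing = [f for f in HST_FREQUENCIES if not listener.true_audiogram.has(ear, f)]
    if missing:
        raise ValueError(f"listener lacks thresholds at {missing} Hz for {ear.value} ear")

    log: list[Trial] = []
    last_outcome: dict[int, bool] = {}  # most recent block outcome per scale
    any_pass = False
    current = config.start_scale

    def finish(scale: HearingScale) -> HSTResult | None:
        if config.confirm_repeats and not scale.is_no_response:
            for _ in range(config.confirm_repeats):
                if len(log) >= config.max_presentations:
                    return None
                if not _present_block(listener, ear, scale.index, config, log):
                    last_outcome[scale.index] = False
                    return None  # confirmation failed: resume search
        return HSTResult(ear=ear, min_audible_scale=scale, trial_log=log)

    while True:
        if len(log) >= config.max_presentations:
            passed = [s for s, ok in last_outcome.items() if ok]
            best = HearingScale(min(passed)) if passed else NO_RESPONSE
            return HSTResult(
                ear=ear,
                min_audible_scale=best,
                trial_log=log,
                valid=False,
                abort_reason=f"max_presentations ({config.max_presentations}) exceeded",
            )
        ok = _present_block(listener, ear, current, config, log)
        last_outcome[current] = ok
        any_pass = any_pass or ok
        if ok:
            if current == SCALE_MIN or last_outcome.get(current - 1) is False:
                done = finish(HearingScale(current))
                if done is not None:
                    return done
                current = min(SCALE_MAX, current + 1)
            else:
                current -= 1
        else:
            if current == SCALE_MAX:
                if not any_pass:
                    done = finish(NO_RESPONSE)
                    if done is not None:
                        return done
                # a pass exists below only transiently (stochastic revisit);
                # keep searching from the top scale
                continue
            if last_outcome.get(current + 1) is True:
                done = finish(HearingScale(current + 1))
                if done is not None:
                    return done
                current = min(SCALE_MAX, current + 1)
            else:
                current += 1


def hst_both_ears(
    listener: ListenerModel,
    config: HSTConfig | None = None,
    ambient_dba: float = 30.0,
) -> tuple[dict[EarSide, HSTResult], InterauralDifference]:
    """Run the HST on both ears and report the scale difference.

    The difference is impaired-minus-contralateral with the impaired ear
    taken as the ear with the worse (higher) scale; NO_RESPONSE enters as
    the surrogate index 21, so the scale difference is always >= 0 here.
    """
    config = config or HSTConfig()
    results = {ear: run_hst(listener, ear, config, ambient_dba) for ear in config.ear_order}
    scales = {ear: res.min_audible_scale for ear, res in results.items()}
    worse = max(config.ear_order, key=lambda e: (scales[e].numeric, e is EarSide.RIGHT))
    better = worse.opposite
    diff = interaural_difference((0.0, scales[worse]), (0.0, scales[better]))
    return results, diff
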