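"""Core audiometric domain types and conversions.

The Hearing Scale Test (HST) expresses hearing sensitivity on a stratified
grid of 20 scales 5 dB apart, anchored at scale S5 = 25 dB HL, so scale
``k`` corresponds to ``5 * k`` dB HL (S1 = 5, S17 = 85, S20 = 100).  An ear
that never responds, even at S20, is recorded as :data:`NO_RESPONSE`, which
orders above every numeric scale and enters difference arithmetic as the
surrogate index 21.

The pure-tone average (PTA) is the arithmetic mean of the air-conduction
thresholds at 0.5, 1, 2 and 4 kHz, and is graded for sudden sensorineural
hearing loss (SSNHL) staging with the modified Siegel criteria:

==========  ==================
grade       PTA (dB HL)
==========  ==================
1           <= 25
2           > 25 and <= 45
3           > 45 and <= 75
4           > 75 and <= 90
5           > 90
==========  ==================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Iterable, Mapping

import pandas as pd

#: Frequencies (Hz) used by the HST and entering the four-frequency PTA.
HST_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 4000)

#: Extended frequency set used by the device calibration protocol.
CALIBRATION_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

SCALE_MIN = 1
SCALE_MAX = 20
SCALE_STEP_DB = 5.0

#: Valid audiometric threshold range (dB HL).
THRESHOLD_BOUNDS = (-10.0, 120.0)

#: Numeric surrogate for NO_RESPONSE in scale-difference arithmetic.
NO_RESPONSE_NUMERIC = SCALE_MAX + 1


class EarSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "EarSide":
        return EarSide.LEFT if self is EarSide.RIGHT else EarSide.RIGHT


@total_ordering
@dataclass(frozen=True)
class HearingScale:
    """One HST outcome: scale index 1-20, or no response (``index=None``)."""

    index: int | None

    def __post_init__(self) -> None:
        if self.index is not None and not (SCALE_MIN <= self.index <= SCALE_MAX):
            raise ValueError(f"scale index must be in [{SCALE_MIN}, {SCALE_MAX}], got {self.index}")

    @property
    def is_no_response(self) -> bool:
        return self.index is None

    @property
    def numeric(self) -> int:
        """Index, with NO_RESPONSE mapped to the surrogate 21."""
        return NO_RESPONSE_NUMERIC if self.index is None else self.index

    @property
    def db_hl(self) -> float:
        return scale_to_db(self)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, HearingScale):
            return self.numeric == other.numeric
        return NotImplemented

    def __lt__(self, other: "HearingScale") -> bool:
        if isinstance(other, HearingScale):
            return self.numeric < other.numeric
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.numeric)

    def __str__(self) -> str:
        return "NR" if self.index is None else f"S{self.index}"

    @classmethod
    def parse(cls, text: str | int) -> "HearingScale":
        if isinstance(text, int):
            return cls(text)
        s = str(text).strip().upper()
        if s in {"NR", "NO_RESPONSE", "NONE"}:
            return NO_RESPONSE
        return cls(int(s.lstrip("S")))


NO_RESPONSE = HearingScale(None)


def scale_to_db(scale: HearingScale | int) -> float:
    """dB HL equivalent of a hearing scale (S5 -> 25, S17 -> 85)."""
    if isinstance(scale, HearingScale):
        if scale.is_no_response:
            raise ValueError("NO_RESPONSE has no dB HL equivalent")
        scale = scale.index  # type: ignore[assignment]
    if not (SCALE_MIN <= scale <= SCALE_MAX):
        raise ValueError(f"scale index must be in [{SCALE_MIN}, {SCALE_MAX}], got {scale}")
    return SCALE_STEP_DB * scale


def db_to_scale(level_db_hl: float) -> HearingScale:
    """Smallest scale whose level covers ``level_db_hl``.

    Levels above S20 (100 dB HL) map to NO_RESPONSE; levels at or below
    S1 (5 dB HL) clamp to S1 — the grid has no scale below the screening
    floor.
    """
    if level_db_hl > SCALE_STEP_DB * SCALE_MAX:
        return NO_RESPONSE
    k = math.ceil(level_db_hl / SCALE_STEP_DB)
    return HearingScale(max(SCALE_MIN, k))


@dataclass
class Audiogram:
    """Per-ear air-conduction thresholds, keyed by (ear, frequency Hz)."""

    thresholds: dict[tuple[EarSide, int], float]
    reliable: dict[EarSide, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = THRESHOLD_BOUNDS
        for (ear, freq), thr in self.thresholds.items():
            if not isinstance(ear, EarSide):
                raise TypeError(f"ear key must be EarSide, got {ear!r}")
            if not (lo <= thr <= hi):
                raise ValueError(f"threshold {thr} dB HL at {freq} Hz ({ear.value}) outside [{lo}, {hi}]")

    def threshold(self, ear: EarSide, freq: int) -> float:
        try:
            return self.thresholds[(ear, freq)]
        except KeyError:
            raise KeyError(f"no threshold for {freq} Hz in {ear.value} ear") from None

    def has(self, ear: EarSide, freq: int) -> bool:
        return (ear, freq) in self.thresholds

    def ears(self) -> list[EarSide]:
        return sorted({ear for ear, _ in self.thresholds}, key=lambda e: e.value)

    def frequencies(self, ear: EarSide) -> list[int]:
        return sorted(f for e, f in self.thresholds if e is ear)

    @classmethod
    def from_ear_levels(
        cls,
        right: Iterable[float] | Mapping[int, float] | None = None,
        left: Iterable[float] | Mapping[int, float] | None = None,
        freqs: Iterable[int] = HST_FREQUENCIES,
    ) -> "Audiogram":
        """Build from per-ear threshold sequences ordered like ``freqs``."""
        freqs = tuple(freqs)
        thresholds: dict[tuple[EarSide, int], float] = {}
        for ear, levels in ((EarSide.RIGHT, right), (EarSide.LEFT, left)):
            if levels is None:
                continue
            if isinstance(levels, Mapping):
                items = levels.items()
            else:
                levels = tuple(levels)
                if len(levels) != len(freqs):
                    raise ValueError(f"expected {len(freqs)} levels, got {len(levels)}")
                items = zip(freqs, levels)
            for f, thr in items:
                thresholds[(ear, int(f))] = float(thr)
        return cls(thresholds)


@dataclass(frozen=True)
class InterauralDifference:
    """Impaired-minus-contralateral differences: PTA in dB, scales in steps.

    ``scale_diff`` uses the surrogate index 21 for NO_RESPONSE and carries
    ``involves_no_response`` so downstream reports can flag it.
    """

    pta_diff: float
    scale_diff: int
    involves_no_response: bool = False

    @property
    def scale_diff_db(self) -> float:
        return SCALE_STEP_DB * self.scale_diff


def compute_pta(audiogram: Audiogram, ear: EarSide) -> float:
    """Four-frequency pure-tone average (0.5/1/2/4 kHz) for one ear."""
    missing = [f for f in HST_FREQUENCIES if not audiogram.has(ear, f)]
    if missing:
        raise ValueError(f"missing threshold(s) at {missing} Hz for {ear.value} ear")
    return sum(audiogram.threshold(ear, f) for f in HST_FREQUENCIES) / len(HST_FREQUENCIES)


def siegel_grade(pta_db_hl: float) -> int:
    """Modified Siegel grade (1-5) of a PTA; boundaries are inclusive above."""
    lo, hi = THRESHOLD_BOUNDS
    if not (lo <= pta_db_hl <= hi):
        raise ValueError(f"PTA {pta_db_hl} outside [{lo}, {hi}] dB HL")
    if pta_db_hl <= 25:
        return 1
    if pta_db_hl <= 45:
        return 2
    if pta_db_hl <= 75:
        return 3
    if pta_db_hl <= 90:
        return 4
    return 5


def interaural_difference(
    impaired: tuple[float, HearingScale],
    contralateral: tuple[float, HearingScale],
) -> InterauralDifference:
    """Componentwise (PTA, scale) difference, impaired minus contralateral."""
    pta_i, scale_i = impaired
    pta_c, scale_c = contralateral
    return InterauralDifference(
        pta_diff=float(pta_i) - float(pta_c),
        scale_diff=scale_i.numeric - scale_c.numeric,
        involves_no_response=scale_i.is_no_response or scale_c.is_no_response,
    )


# ---------------------------------------------------------------------------
# serialization (CSV columns: subject_id, ear, freq_hz, threshold_dbhl)

def audiograms_to_frame(audiograms: Mapping[str, Audiogram]) -> pd.DataFrame:
    rows = []
    for subject_id, ag in audiograms.items():
        for (ear, freq), thr in sorted(ag.thresholds.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            rows.append({"subject_id": subject_id, "ear": ear.value, "freq_hz": freq, "threshold_dbhl": thr})
    return pd.DataFrame(rows, columns=["subject_id", "ear", "freq_hz", "threshold_dbhl"])


def audiograms_from_frame(frame: pd.DataFrame) -> dict[str, Audiogram]:
    required = {"subject_id", "ear", "freq_hz", "threshold_dbhl"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"audiogram table missing columns: {sorted(missing)}")
    out: dict[str, Audiogram] = {}
    for subject_id, grp in frame.groupby("subject_id", sort=True):
        thresholds = {
            (EarSide(str(r.ear).lower()), int(r.freq_hz)): float(r.threshold_dbhl)
            for r in grp.itertuples()
        }
        out[str(subject_id)] = Audiogram(thresholds)
    return out
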