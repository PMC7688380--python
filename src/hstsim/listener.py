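"""Virtual listener: a psychometric model answering "heard / not heard".

Real participants press a button when they hear a tone.  The simulator
replaces them with a listener whose probability of responding to a tone at
``level`` dB HL is the classic four-parameter psychometric function

    p(level) = guess + (1 - guess - lapse) * F((level - threshold) / slope)

with ``F`` the standard logistic CDF, ``threshold`` the ear- and
frequency-specific true threshold, ``slope`` the spread in dB, ``guess``
the false-alarm floor and ``lapse`` the inattention ceiling.  In
deterministic mode the listener is an ideal step function: heard iff
``level >= threshold`` (the boundary counts as heard, which makes the
adaptive procedures exactly analyzable).

Each listener owns one random stream, advanced once per presentation, so a
listener's responses are reproducible given its seed and the order of
presentations, independent of any other listener.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import Audiogram, EarSide


@dataclass
class ListenerModel:
    true_audiogram: Audiogram
    slope_db: float = 3.0
    guess_rate: float = 0.02
    lapse_rate: float = 0.02
    deterministic: bool = False
    seed: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.slope_db <= 0:
            raise ValueError("slope_db must be positive")
        for name, rate in (("guess_rate", self.guess_rate), ("lapse_rate", self.lapse_rate)):
            if not (0 <= rate < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {rate}")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be < 1")
        self._rng = np.random.default_rng(self.seed)

    def reset(self, seed: int | None = None) -> None:
        """Restart the response stream (same seed by default)."""
        self._rng = np.random.default_rng(self.seed if seed is None else seed)

    def response_probability(self, level_db_hl: float, freq: int, ear: EarSide) -> float:
        threshold = self.true_audiogram.threshold(ear, freq)
        if self.deterministic:
            return 1.0 if level_db_hl >= threshold else 0.0
        core = expit((level_db_hl - threshold) / self.slope_db)
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core

    def respond(self, level_db_hl: float, freq: int, ear: EarSide) -> bool:
        """One button-press decision for a tone at ``level_db_hl`` dB HL."""
        if self.deterministic:
            return level_db_hl >= self.true_audiogram.threshold(ear, freq)
        return bool(self._rng.random() < self.response_probability(level_db_hl, freq, ear))

    def ear_responder(self, freq: int, ear: EarSide):
        """Single-argument level -> bool callable (for staircase drivers)."""
        return lambda level: self.respond(level, freq, ear)
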