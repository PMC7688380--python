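"""Seeded generator of virtual referral cohorts.

Emulates the statistical structure of a tertiary-referral sample of adults
presenting with possible sudden sensorineural hearing loss: 88 subjects,
half female, age ~ N(46, 14.7) truncated to [18, 90], worst-ear severity
drawn from the modified-Siegel grade mixture (8/9/49/18/16 % for grades
1-5), and about 67/88 gold-standard positives (interaural PTA gap >= 30
dB).  Sex, grade and gold-status counts are stratified (largest-remainder)
so the headline proportions are exact at the default n.

Impaired-ear audiograms are sampled by drawing a grade, a target PTA
uniform within that grade's interval, and per-frequency thresholds =
target + loss-shape offsets + jitter, re-centred so the PTA equals the
target exactly.  Loss shapes mix flat (70%) and down-sloping (30%, +10/+20
dB at 2/4 kHz before re-centring).  Contralateral ears draw per-frequency
thresholds from N(15, 7) truncated to [-10, 60]; when a draw contradicts
the subject's assigned gold status the contralateral ear is re-targeted to
an interaural gap of at least 32 dB (positives) or 10-28 dB (negatives).
Gold positivity is assigned to the subjects with the highest impaired-ear
PTA, since severity and interaural gap are strongly coupled in this
presentation.  The truth label is always recomputed from the final PTAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HST_FREQUENCIES,
    THRESHOLD_BOUNDS,
    Audiogram,
    EarSide,
    compute_pta,
    siegel_grade,
)
from .listener import ListenerModel
from .workflow import gold_standard_ssnhl

#: PTA sampling interval per Siegel grade (dB HL).  Grades 2-4 follow the
#: printed boundaries; the unprinted outer ends use a 5 dB screening floor
#: (grade 1) and a 115 dB profound-loss cap (grade 5).
GRADE_PTA_RANGES: dict[int, tuple[float, float]] = {
    1: (5.0, 25.0),
    2: (25.0, 45.0),
    3: (45.0, 75.0),
    4: (75.0, 90.0),
    5: (90.0, 115.0),
}

FLAT_SHAPE = (0.0, 0.0, 0.0, 0.0)
DOWNSLOPE_SHAPE = (0.0, 0.0, 10.0, 20.0)   # high-frequency tilt at 2/4 kHz


@dataclass
class CohortConfig:
    n: int = 88
    seed: int | None = None
    female_prop: float = 0.5
    age_mean: float = 46.0
    age_sd: float = 14.7
    age_bounds: tuple[float, float] = (18.0, 90.0)
    gold_positive_prop: float = 67.0 / 88.0
    grade_mixture: tuple[float, ...] = (0.08, 0.09, 0.49, 0.18, 0.16)
    contralateral_mean: float = 15.0
    contralateral_sd: float = 7.0
    contralateral_bounds: tuple[float, float] = (-10.0, 60.0)
    jitter_sd: float = 3.0
    downslope_prop: float = 0.3
    positive_min_gap_db: float = 32.0
    negative_gap_range_db: tuple[float, float] = (10.0, 28.0)
    bilateral_prop: float = 0.0
    conductive_prop: float = 0.0
    # virtual-listener behaviour attached to every generated subject
    listener_deterministic: bool = False
    slope_db: float = 3.0
    guess_rate: float = 0.02
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name in ("female_prop", "gold_positive_prop", "downslope_prop",
                     "bilateral_prop", "conductive_prop"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.grade_mixture) != 5:
            raise ValueError("grade_mixture needs 5 proportions")
        if abs(sum(self.grade_mixture) - 1.0) > 1e-9:
            raise ValueError("grade_mixture must sum to 1")
        for g, (lo, hi) in GRADE_PTA_RANGES.items():
            if lo >= hi:
                raise ValueError(f"empty PTA interval for grade {g}")


@dataclass
class GeneratedSubject:
    subject_id: str
    age: float
    sex: str
    impaired_ear: EarSide
    audiogram: Audiogram            # true thresholds, both ears
    impaired_grade: int
    gold_positive: bool
    onset_within_72h: bool = True
    conductive_loss: bool = False
    bilateral_loss: bool = False
    listener_seed: int = 0
    listener_deterministic: bool = False
    slope_db: float = 3.0
    guess_rate: float = 0.02
    lapse_rate: float = 0.02

    def listener(self) -> ListenerModel:
        return ListenerModel(
            true_audiogram=self.audiogram,
            slope_db=self.slope_db,
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
            deterministic=self.listener_deterministic,
            seed=self.listener_seed,
        )

    @property
    def pta(self) -> dict[EarSide, float]:
        return {ear: compute_pta(self.audiogram, ear) for ear in (EarSide.RIGHT, EarSide.LEFT)}


def largest_remainder_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional by largest remainder."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _ear_thresholds(
    rng: np.random.Generator,
    target_pta: float,
    shape: tuple[float, ...],
    jitter_sd: float,
) -> np.ndarray:
    """Per-frequency thresholds with mean exactly ``target_pta``.

    Offsets and jitter are re-centred; clamping to the audiometric range is
    re-balanced iteratively so the mean stays on target whenever the range
    allows it.
    """
    lo, hi = THRESHOLD_BOUNDS
    offs = np.asarray(shape, dtype=float)
    jitter = rng.normal(0.0, jitter_sd, size=len(offs)) if jitter_sd > 0 else np.zeros(len(offs))
    thr = target_pta + (offs - offs.mean()) + (jitter - jitter.mean())
    for _ in range(20):
        thr = np.clip(thr, lo, hi)
        err = target_pta - thr.mean()
        if abs(err) < 1e-9:
            break
        free = (thr < hi - 1e-12) if err > 0 else (thr > lo + 1e-12)
        if not free.any():
            break
        thr[free] += err * len(thr) / free.sum()
    return np.clip(thr, lo, hi)


def generate_cohort(config: CohortConfig | None = None) -> list[GeneratedSubject]:
    """Draw a reproducible virtual cohort under ``config``."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # stratified categorical structure
    n_female = int(largest_remainder_counts(
        np.array([config.female_prop, 1 - config.female_prop]), n)[0])
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    grade_counts = largest_remainder_counts(np.asarray(config.grade_mixture), n)
    grades = np.repeat(np.arange(1, 6), grade_counts)
    rng.shuffle(grades)
    n_pos = int(largest_remainder_counts(
        np.array([config.gold_positive_prop, 1 - config.gold_positive_prop]), n)[0])

    ages = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_bounds, n)
    sides = [EarSide.RIGHT if b else EarSide.LEFT for b in rng.integers(0, 2, size=n)]
    bilateral = rng.random(n) < config.bilateral_prop
    conductive = rng.random(n) < config.conductive_prop

    # impaired-ear PTA target: uniform inside the drawn grade's interval
    # (open lower ends nudged so the sampled PTA grades back to the draw)
    targets = np.empty(n)
    shapes = []
    for i, g in enumerate(grades):
        lo, hi = GRADE_PTA_RANGES[int(g)]
        lo_eff = lo if int(g) == 1 else np.nextafter(lo, hi)
        targets[i] = rng.uniform(lo_eff, hi)
        shapes.append(DOWNSLOPE_SHAPE if rng.random() < config.downslope_prop else FLAT_SHAPE)

    # gold positivity goes to the most severely impaired subjects
    positive = np.zeros(n, dtype=bool)
    positive[np.argsort(-targets, kind="stable")[:n_pos]] = True

    lo_c, hi_c = config.contralateral_bounds
    subjects: list[GeneratedSubject] = []
    for i in range(n):
        impaired = _ear_thresholds(rng, targets[i], shapes[i], config.jitter_sd)
        pta_i = impaired.mean()
        contra = _truncated_normal(
            rng, config.contralateral_mean, config.contralateral_sd,
            config.contralateral_bounds, len(HST_FREQUENCIES),
        )
        gap = pta_i - contra.mean()
        if positive[i] and gap < 30.0:
            target_c = pta_i - rng.uniform(config.positive_min_gap_db,
                                           config.positive_min_gap_db + 15.0)
            if target_c < lo_c:
                raise ValueError(
                    f"infeasible config: impaired PTA {pta_i:.1f} cannot support a "
                    f">=30 dB interaural gap within contralateral bounds"
                )
            contra = _ear_thresholds(rng, target_c, FLAT_SHAPE, config.jitter_sd)
            contra = np.clip(contra, lo_c, hi_c)
        elif not positive[i] and gap >= 30.0:
            g_lo, g_hi = config.negative_gap_range_db
            target_c = pta_i - rng.uniform(g_lo, g_hi)
            if target_c > hi_c:
                raise ValueError(
                    f"infeasible config: impaired PTA {pta_i:.1f} cannot stay below a "
                    f"30 dB interaural gap within contralateral bounds"
                )
            contra = _ear_thresholds(rng, max(target_c, lo_c), FLAT_SHAPE, config.jitter_sd)
            contra = np.clip(contra, lo_c, hi_c)

        side = sides[i]
        audiogram = Audiogram.from_ear_levels(
            right=impaired if side is EarSide.RIGHT else contra,
            left=impaired if side is EarSide.LEFT else contra,
        )
        pta = {ear: compute_pta(audiogram, ear) for ear in (EarSide.RIGHT, EarSide.LEFT)}
        truth = gold_standard_ssnhl(pta[side], pta[side.opposite])
        subjects.append(
            GeneratedSubject(
                subject_id=f"S{i + 1:04d}",
                age=float(ages[i]),
                sex=str(sexes[i]),
                impaired_ear=side,
                audiogram=audiogram,
                impaired_grade=int(grades[i]),
                gold_positive=bool(truth),
                bilateral_loss=bool(bilateral[i]),
                conductive_loss=bool(conductive[i]),
                listener_seed=int(rng.integers(0, 2**31 - 1)),
                listener_deterministic=config.listener_deterministic,
                slope_db=config.slope_db,
                guess_rate=config.guess_rate,
                lapse_rate=config.lapse_rate,
            )
        )
    return subjects


def summarize_cohort(cohort: list[GeneratedSubject]) -> dict:
    """Baseline-characteristics summary in the usual Table-1 layout."""
    if not cohort:
        raise ValueError("empty cohort")
    ages = np.array([s.age for s in cohort])
    impaired_pta = np.array([compute_pta(s.audiogram, s.impaired_ear) for s in cohort])
    contra_pta = np.array(
        [compute_pta(s.audiogram, s.impaired_ear.opposite) for s in cohort]
    )
    grades = np.array([siegel_grade(p) for p in impaired_pta])
    n = len(cohort)
    return {
        "n": n,
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if n > 1 else 0.0,
        "female_n": sum(s.sex == "F" for s in cohort),
        "female_pct": 100.0 * sum(s.sex == "F" for s in cohort) / n,
        "grade_counts": {g: int((grades == g).sum()) for g in range(1, 6)},
        "grade_pct": {g: 100.0 * float((grades == g).mean()) for g in range(1, 6)},
        "worst_ear_pta_mean": float(impaired_pta.mean()),
        "worst_ear_pta_sd": float(impaired_pta.std(ddof=1)) if n > 1 else 0.0,
        "pta_diff_mean": float((impaired_pta - contra_pta).mean()),
        "pta_diff_sd": float((impaired_pta - contra_pta).std(ddof=1)) if n > 1 else 0.0,
        "gold_positive_n": sum(s.gold_positive for s in cohort),
    }


def cohort_frames(cohort: list[GeneratedSubject]) -> dict[str, pd.DataFrame]:
    """Audiogram / demographics / truth-label tables for serialization."""
    from .core import audiograms_to_frame

    audio = audiograms_to_frame({s.subject_id: s.audiogram for s in cohort})
    demo = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "impaired_ear": s.impaired_ear.value,
                "listener_seed": s.listener_seed,
                "listener_deterministic": s.listener_deterministic,
                "slope_db": s.slope_db,
                "guess_rate": s.guess_rate,
                "lapse_rate": s.lapse_rate,
            }
            for s in cohort
        ]
    )
    truth = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "gold_positive": s.gold_positive,
                "impaired_grade": s.impaired_grade,
                "onset_within_72h": s.onset_within_72h,
                "conductive_loss": s.conductive_loss,
                "bilateral_loss": s.bilateral_loss,
            }
            for s in cohort
        ]
    )
    return {"audiograms": audio, "demographics": demo, "truth": truth}
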