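"""Screening triage and decision layer.

Subjects presenting with possible sudden sensorineural hearing loss are
tested with the HST on both ears, grouped by the worse ear's scale
(<=S5, S6-S10, >S10), and referred for comprehensive audiological work-up
when the worse scale exceeds S10 or the interaural scale difference
reaches the referral cutoff (default 5 scales, i.e. 25 dB).  The screening
call is positive when the scale difference reaches the diagnostic cutoff;
the gold standard is an interaural PTA difference >= 30 dB on conventional
audiometry.  Subjects labelled with bilateral loss or conductive loss are
excluded from the analysis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import pandas as pd

from .audiometry import HWConfig, run_pta_exam
from .core import (
    EarSide,
    HearingScale,
    InterauralDifference,
    compute_pta,
    interaural_difference,
    siegel_grade,
)
from .hst import HSTConfig, hst_both_ears

if TYPE_CHECKING:
    from .cohort import GeneratedSubject

logger = logging.getLogger(__name__)

TRIAGE_LOW = "<=S5"
TRIAGE_MID = "S6-S10"
TRIAGE_HIGH = ">S10"


@dataclass
class DecisionConfig:
    scale_cutoff: int = 5            # diagnostic scale-difference cutoff
    gold_cutoff_db: float = 30.0     # interaural PTA difference defining SSNHL
    referral_scale: int = 10         # worse ear above this scale -> refer
    referral_diff: int = 5           # interaural difference at/above this -> refer
    exam_referred_only: bool = False
    exclude_unreliable: bool = False
    ambient_dba: float = 30.0

    def __post_init__(self) -> None:
        if not (1 <= self.scale_cutoff <= 20):
            raise ValueError("scale_cutoff must be in [1, 20]")


def triage(scales: dict[EarSide, HearingScale], config: DecisionConfig | None = None) -> tuple[str, bool]:
    """Triage group from the worse ear and the referral decision."""
    config = config or DecisionConfig()
    if set(scales) != {EarSide.RIGHT, EarSide.LEFT}:
        raise ValueError("triage requires scales for both ears")
    worse = max(s.numeric for s in scales.values())
    diff = abs(scales[EarSide.RIGHT].numeric - scales[EarSide.LEFT].numeric)
    if worse <= 5:
        group = TRIAGE_LOW
    elif worse <= 10:
        group = TRIAGE_MID
    else:
        group = TRIAGE_HIGH
    referred = worse > config.referral_scale or diff >= config.referral_diff
    return group, referred


def classify_ssnhl_by_scale(scale_diff: int, cutoff: int) -> bool:
    """Screen positive iff the interaural scale difference reaches the cutoff."""
    return scale_diff >= cutoff


def gold_standard_ssnhl(
    pta_impaired: float, pta_contralateral: float, cutoff_db: float = 30.0
) -> bool:
    """Gold standard: impaired-minus-contralateral PTA difference >= 30 dB."""
    return (pta_impaired - pta_contralateral) >= cutoff_db


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    hst_scales: dict[EarSide, HearingScale]
    scale_difference: InterauralDifference
    triage_group: str
    referred: bool
    impaired_ear: EarSide
    pta: dict[EarSide, float]
    pta_difference: float
    worst_ear_grade: int
    ssnhl_gold_positive: bool
    screen_positive: dict[int, bool] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None
    hst_valid: bool = True
    exam_reliable: bool = True


def _designate_impaired(
    scales: dict[EarSide, HearingScale], pta: dict[EarSide, float]
) -> EarSide:
    """Worse HST scale; ties broken by higher PTA, then right ear."""
    r, l = scales[EarSide.RIGHT].numeric, scales[EarSide.LEFT].numeric
    if r != l:
        return EarSide.RIGHT if r > l else EarSide.LEFT
    if pta[EarSide.RIGHT] != pta[EarSide.LEFT]:
        return EarSide.RIGHT if pta[EarSide.RIGHT] > pta[EarSide.LEFT] else EarSide.LEFT
    return EarSide.RIGHT


def run_screening(
    cohort: Sequence["GeneratedSubject"],
    hst_config: HSTConfig | None = None,
    hw_config: HWConfig | None = None,
    decision_config: DecisionConfig | None = None,
    cutoffs: Sequence[int] = (5, 6, 7),
) -> list[SubjectRecord]:
    """Run the full screening chain on a simulated cohort.

    Per subject: ambient gate -> HST both ears -> triage/referral ->
    conventional pure-tone exam -> gold-standard call -> screen call at
    each requested cutoff.  By default every subject receives the
    conventional exam so a gold-standard call exists for the whole
    analysis set; with ``exam_referred_only`` non-referred subjects fall
    back to their true audiogram for the gold call.  Bilateral- and
    conductive-loss subjects are excluded (flagged, not dropped).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    hst_config = hst_config or HSTConfig()
    hw_config = hw_config or HWConfig()
    decision = decision_config or DecisionConfig()

    records: list[SubjectRecord] = []
    for subject in cohort:
        listener = subject.listener()
        results, _ = hst_both_ears(listener, hst_config, ambient_dba=decision.ambient_dba)
        scales = {ear: res.min_audible_scale for ear, res in results.items()}
        hst_valid = all(res.valid for res in results.values())
        group, referred = triage(scales, decision)

        if referred or not decision.exam_referred_only:
            exam = run_pta_exam(listener, hw_config)
            pta = exam.pta
            exam_reliable = all(exam.reliable.values())
        else:
            pta = {ear: compute_pta(subject.audiogram, ear) for ear in (EarSide.RIGHT, EarSide.LEFT)}
            exam_reliable = True

        impaired = _designate_impaired(scales, pta)
        contra = impaired.opposite
        diff = interaural_difference(
            (pta[impaired], scales[impaired]), (pta[contra], scales[contra])
        )
        gold = gold_standard_ssnhl(pta[impaired], pta[contra], decision.gold_cutoff_db)
        screen = {c: classify_ssnhl_by_scale(diff.scale_diff, c) for c in cutoffs}

        excluded, reason = False, None
        if subject.conductive_loss:
            excluded, reason = True, "conductive hearing loss"
        elif subject.bilateral_loss:
            excluded, reason = True, "bilateral hearing loss"
        elif decision.exclude_unreliable and not exam_reliable:
            excluded, reason = True, "unreliable audiometry"
        if excluded:
            logger.info("subject %s excluded: %s", subject.subject_id, reason)

        records.append(
            SubjectRecord(
                subject_id=subject.subject_id,
                age=subject.age,
                sex=subject.sex,
                hst_scales=scales,
                scale_difference=diff,
                triage_group=group,
                referred=referred,
                impaired_ear=impaired,
                pta=pta,
                pta_difference=diff.pta_diff,
                worst_ear_grade=siegel_grade(max(pta.values())),
                ssnhl_gold_positive=gold,
                screen_positive=screen,
                excluded=excluded,
                exclusion_reason=reason,
                hst_valid=hst_valid,
                exam_reliable=exam_reliable,
            )
        )
    return records


def analysis_set(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    return [r for r in records if not r.excluded]


def confusion_from_records(records: Sequence[SubjectRecord], cutoff: int):
    """Tabulate screen-vs-gold calls over the (non-excluded) analysis set."""
    from .stats import confusion_from_calls

    usable = analysis_set(records)
    missing = [r.subject_id for r in usable if cutoff not in r.screen_positive]
    if missing:
        raise ValueError(f"records lack a screen call at cutoff {cutoff}: {missing}")
    if not usable:
        raise ValueError("no analysable records")
    return confusion_from_calls(
        [r.screen_positive[cutoff] for r in usable],
        [r.ssnhl_gold_positive for r in usable],
    )


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "scale_right": str(r.hst_scales[EarSide.RIGHT]),
            "scale_left": str(r.hst_scales[EarSide.LEFT]),
            "scale_diff": r.scale_difference.scale_diff,
            "scale_diff_db": r.scale_difference.scale_diff_db,
            "triage_group": r.triage_group,
            "referred": r.referred,
            "impaired_ear": r.impaired_ear.value,
            "pta_right": r.pta[EarSide.RIGHT],
            "pta_left": r.pta[EarSide.LEFT],
            "pta_diff": r.pta_difference,
            "worst_ear_grade": r.worst_ear_grade,
            "gold_positive": r.ssnhl_gold_positive,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
            "hst_valid": r.hst_valid,
            "exam_reliable": r.exam_reliable,
        }
        for c, v in sorted(r.screen_positive.items()):
            row[f"screen_positive_c{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
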