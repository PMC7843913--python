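"""Cohort construction: inclusion rules, windowed worst-value scoring, outcomes.

Turns per-patient observation timelines into the analyzable cohort table used
by the validation analysis: one row per eligible patient carrying the worst
24-h and 72-h scores on all four scales plus the three binary outcomes
(unfavorable 3-month functional outcome, NICU death, 3-month death).

Eligibility reproduces the study rules: coma on the earliest recorded exam
(GCS eye = 1, verbal <= 2, motor <= 4), NICU stay of at least 72 hours, and no
drug-induced coma.  Exclusions are logged per patient with a single primary
reason, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .scales import (
    HIGHER_IS_WORSE,
    PatientObservation,
    Scale,
    ScoreBreakdown,
    score_apache2,
    score_four,
    score_gcs,
    score_incns,
)

WINDOWS = (24, 72)


class OutcomeClass(str, Enum):
    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"


class ExclusionReason(str, Enum):
    NON_COMATOSE = "non_comatose"
    SHORT_STAY = "short_stay"
    DRUG_INDUCED_COMA = "drug_induced_coma"
    LOST_TO_FOLLOWUP = "lost_to_followup"


@dataclass
class PatientTimeline:
    """All observations and outcome data for one NICU admission."""

    patient_id: str
    observations: list[PatientObservation]
    nicu_los_hours: float
    drug_induced_coma: bool
    died_in_nicu: bool
    mrs_3month: int
    died_by_3month: bool
    etiology: Optional[str] = None
    lost_to_followup: bool = False

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"{self.patient_id}: timeline has no observations")
        times = [o.t_hours for o in self.observations]
        if times != sorted(times):
            raise ValueError(f"{self.patient_id}: observations not time-sorted")
        if not 0 <= self.mrs_3month <= 6:
            raise ValueError(f"{self.patient_id}: mRS must lie in [0, 6]")
        if self.died_in_nicu and not self.died_by_3month:
            raise ValueError(f"{self.patient_id}: NICU death implies 3-month death")
        if (self.mrs_3month == 6) != self.died_by_3month:
            raise ValueError(f"{self.patient_id}: mRS 6 must coincide with 3-month death")


@dataclass
class CohortRow:
    """One analyzable patient: eight window scores + three binary outcomes."""

    patient_id: str
    incns_24: int
    incns_72: int
    gcs_24: int
    gcs_72: int
    four_24: int
    four_72: int
    apache2_24: int
    apache2_72: int
    outcome_unfavorable: bool
    outcome_nicu_death: bool
    outcome_3m_death: bool

    def score(self, scale: Scale, window: int) -> int:
        return getattr(self, f"{Scale(scale).value}_{window}")


def is_comatose(gcs_eye: int, gcs_verbal: int, gcs_motor: int) -> bool:
    """Coma inclusion criterion: eye = 1 AND verbal <= 2 AND motor <= 4."""
    breakdown = score_gcs(gcs_eye, gcs_verbal, gcs_motor)  # validates ranges
    del breakdown
    return gcs_eye == 1 and gcs_verbal <= 2 and gcs_motor <= 4


def dichotomize_mrs(mrs: int) -> OutcomeClass:
    """mRS < 3 is favorable; mRS >= 3 (including death, mRS 6) unfavorable."""
    if not isinstance(mrs, int) or isinstance(mrs, bool) or not 0 <= mrs <= 6:
        raise ValueError(f"mRS must be an integer in [0, 6], got {mrs!r}")
    return OutcomeClass.FAVORABLE if mrs < 3 else OutcomeClass.UNFAVORABLE


def _score_observation(obs: PatientObservation, scale: Scale,
                       assume_normal_missing: bool) -> ScoreBreakdown:
    if scale == Scale.INCNS:
        return score_incns(obs, assume_normal_missing=assume_normal_missing)
    if scale == Scale.GCS:
        return score_gcs(obs.exam.gcs_eye, obs.exam.gcs_verbal, obs.exam.gcs_motor,
                         obs.physio.intubated)
    if scale == Scale.FOUR:
        return score_four(obs.exam.four_eye, obs.exam.four_motor,
                          obs.exam.four_brainstem, obs.exam.four_respiration)
    if scale == Scale.APACHE2:
        return score_apache2(obs, assume_normal_missing=assume_normal_missing)
    raise ValueError(f"unknown scale: {scale!r}")


def worst_in_window(timeline: PatientTimeline, scale: Scale, window_hours: float,
                    method: str = "per_item",
                    assume_normal_missing: bool = False) -> ScoreBreakdown:
    """Worst score over the first ``window_hours`` of the NICU stay.

    The default ``per_item`` method takes, for every scored variable
    independently, the most adverse value among the in-window observations and
    scores the resulting composite (worst-case) observation: highest item
    points for INCNS/APACHE II, lowest component values for GCS/FOUR.  Because
    every scale total is the sum of its item points, this equals the per-item
    adverse aggregate of the individual breakdowns.  ``method="worst_total"``
    instead returns the single most adverse whole-observation score
    (sensitivity analysis).
    """
    scale = Scale(scale)
    in_window = [o for o in timeline.observations if 0 <= o.t_hours <= window_hours]
    if not in_window:
        raise ValueError(
            f"{timeline.patient_id}: no observation within the first {window_hours} h")
    breakdowns = [_score_observation(o, scale, assume_normal_missing) for o in in_window]
    if method == "worst_total":
        key = (lambda b: b.total) if HIGHER_IS_WORSE[scale] else (lambda b: -b.total)
        worst = max(breakdowns, key=key)
        return ScoreBreakdown.from_items(
            scale, worst.item_points,
            worst.notes + [f"worst-total over {len(breakdowns)} observations"])
    if method != "per_item":
        raise ValueError(f"unknown worst-value method: {method!r}")
    adverse = max if HIGHER_IS_WORSE[scale] else min
    items = breakdowns[0].item_points.keys()
    worst_points = {item: adverse(b.item_points[item] for b in breakdowns)
                    for item in items}
    notes = sorted({n for b in breakdowns for n in b.notes})
    notes.append(f"worst-per-item over {len(breakdowns)} observations")
    return ScoreBreakdown.from_items(scale, worst_points, notes)


def _exclusion_reason(tl: PatientTimeline) -> Optional[ExclusionReason]:
    # priority order: non-comatose, short stay, drug-induced, lost to follow-up
    first = tl.observations[0].exam
    if not is_comatose(first.gcs_eye, first.gcs_verbal, first.gcs_motor):
        return ExclusionReason.NON_COMATOSE
    if tl.nicu_los_hours < 72:
        return ExclusionReason.SHORT_STAY
    if tl.drug_induced_coma:
        return ExclusionReason.DRUG_INDUCED_COMA
    if tl.lost_to_followup:
        return ExclusionReason.LOST_TO_FOLLOWUP
    return None


def build_cohort(timelines: Sequence[PatientTimeline], method: str = "per_item",
                 assume_normal_missing: bool = False,
                 ) -> tuple[list[CohortRow], list[dict]]:
    """Apply the inclusion rules and fill all window scores and outcomes.

    Returns the included rows and a per-patient exclusion log (one primary
    reason per excluded patient).  The function is a pure function of its
    input: identical timelines give identical rows and log.
    """
    rows: list[CohortRow] = []
    exclusions: list[dict] = []
    for tl in timelines:
        reason = _exclusion_reason(tl)
        if reason is not None:
            exclusions.append({"patient_id": tl.patient_id, "reason": reason.value})
            continue
        scores = {
            f"{scale.value}_{window}": worst_in_window(
                tl, scale, window, method=method,
                assume_normal_missing=assume_normal_missing).total
            for scale in Scale for window in WINDOWS
        }
        rows.append(CohortRow(
            patient_id=tl.patient_id,
            outcome_unfavorable=dichotomize_mrs(tl.mrs_3month) is OutcomeClass.UNFAVORABLE,
            outcome_nicu_death=tl.died_in_nicu,
            outcome_3m_death=tl.died_by_3month,
            **scores,
        ))
    return rows, exclusions


COHORT_COLUMNS = [
    "patient_id", "incns_24", "incns_72", "gcs_24", "gcs_72", "four_24",
    "four_72", "apache2_24", "apache2_72", "outcome_unfavorable",
    "outcome_nicu_death", "outcome_3m_death",
]


def cohort_to_frame(rows: Sequence[CohortRow]) -> pd.DataFrame:
    """Cohort rows as a DataFrame in the canonical column order."""
    if not rows:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    df = pd.DataFrame([vars(r) for r in rows])
    return df[COHORT_COLUMNS]
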