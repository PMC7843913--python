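"""Clinical severity scales for neurocritical-care patients.

Implements the 19-item INCNS score (Inflammation, Nutrition, Consciousness,
Neurological function, Systemic function; 0-44 points, higher = worse) together
with the three comparator instruments used in its validation: the Glasgow Coma
Scale (GCS, 3-15, lower = worse), the Full Outline of UnResponsiveness score
(FOUR, 0-16, lower = worse) and APACHE II (0-71, higher = worse).

Each scorer returns a :class:`ScoreBreakdown` whose item points always sum to
the total, so window-based "worst value per variable" composites can be built
item by item downstream.

Numeric items are scored from closed bands printed at a fixed decimal
resolution.  Inputs are quantised (round half up) to that resolution before
band lookup; a value that still falls in an inter-band gap is assigned to the
nearest band, preferring the higher-point (more severe) band — a conservative
clinical convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional, Union


class Scale(str, Enum):
    """Severity scale identifier."""

    INCNS = "incns"
    GCS = "gcs"
    FOUR = "four"
    APACHE2 = "apache2"


#: Direction in which each scale encodes severity.
HIGHER_IS_WORSE = {
    Scale.INCNS: True,
    Scale.APACHE2: True,
    Scale.GCS: False,
    Scale.FOUR: False,
}


class Arousal(str, Enum):
    SPONTANEOUS_EYE_OPENING = "spontaneous_eye_opening"
    EYE_OPENING_TO_VERBAL = "eye_opening_to_verbal"
    EYE_OPENING_TO_PAIN = "eye_opening_to_pain"
    NONE = "none"


class Awareness(str, Enum):
    CORRECT_RESPONSE = "correct_response"
    CONFUSED_RESPONSE = "confused_response"
    NON_REFLEX_MOVEMENTS = "non_reflex_movements"
    NONE = "none"


class BrainstemReflex(str, Enum):
    """Pupillary light / corneal reflex status (both sides)."""

    BILATERAL_RESPONSIVE = "bilateral_responsive"
    UNILATERAL_IMPAIRED = "unilateral_impaired"
    BILATERAL_IMPAIRED = "bilateral_impaired"


class VerbalResponse(str, Enum):
    ACCURATE = "accurate"
    CONFUSED_OR_INAPPROPRIATE = "confused_or_inappropriate"
    INCOMPREHENSIBLE_OR_NONE = "incomprehensible_or_none"


class PainResponse(str, Enum):
    OBEYING = "obeying"
    LOCALIZING_OR_WITHDRAWAL = "localizing_or_withdrawal"
    FLEXING_OR_EXTENDING = "flexing_or_extending"
    NONE = "none"


class Swallow(str, Enum):
    """Water Swallow Test (Kubota) grade, collapsed to the two scored bands."""

    WST_I_II = "wst_i_ii"
    WST_III_IV_OR_UNASSESSABLE = "wst_iii_iv_or_unassessable"


class VentilatorBreathing(str, Enum):
    NOT_VENTILATED = "not_ventilated"
    ABOVE_VENTILATOR_RATE = "above_ventilator_rate"
    AT_VENTILATOR_RATE_OR_APNEA = "at_ventilator_rate_or_apnea"


class ChronicHealth(str, Enum):
    """APACHE II chronic-health category."""

    NONE = "none"
    ELECTIVE_POSTOP = "elective_postop"
    EMERGENCY_OR_NONOPERATIVE = "emergency_or_nonoperative"


class MissingItemError(ValueError):
    """A required scorer input is absent and no imputation policy was chosen."""


@dataclass
class NeuroExam:
    """Bedside neurological examination snapshot.

    The motor assessment is a tagged union: either Lovett muscle-strength
    grades (0-5) for both limub sides, or a motor response to painful
    stimulus.  Exactly one variant must be present; when both are supplied the
    strength rubric wins and a note is emitted by the scorer.
    """

    arousal: Arousal
    awareness: Awareness
    pupillary_reflex: BrainstemReflex
    corneal_reflex: BrainstemReflex
    verbal: VerbalResponse
    swallow: Swallow
    gcs_eye: int
    gcs_verbal: int
    gcs_motor: int
    four_eye: int
    four_motor: int
    four_brainstem: int
    four_respiration: int
    strength_left: Optional[int] = None
    strength_right: Optional[int] = None
    pain_response: Optional[PainResponse] = None

    def __post_init__(self) -> None:
        _check_range("gcs_eye", self.gcs_eye, 1, 4)
        _check_range("gcs_verbal", self.gcs_verbal, 1, 5)
        _check_range("gcs_motor", self.gcs_motor, 1, 6)
        for name in ("four_eye", "four_motor", "four_brainstem", "four_respiration"):
            _check_range(name, getattr(self, name), 0, 4)
        has_strength = self.strength_left is not None or self.strength_right is not None
        if has_strength:
            if self.strength_left is None or self.strength_right is None:
                raise ValueError("muscle strength requires both left and right grades")
            _check_range("strength_left", self.strength_left, 0, 5)
            _check_range("strength_right", self.strength_right, 0, 5)
        if not has_strength and self.pain_response is None:
            raise ValueError("motor assessment missing: supply Lovett strengths or a pain response")


@dataclass
class PhysioPanel:
    """Vital signs, labs and ventilation status for one observation.

    Fields marked optional are needed only by APACHE II (the INCNS deliberately
    replaces mean arterial pressure with systolic blood pressure and omits
    blood-gas analysis).
    """

    wbc: Optional[float] = None  # 10^9/L
    temp_axillary: Optional[float] = None  # degrees C
    albumin: Optional[float] = None  # g/L
    heart_rate: Optional[float] = None  # bpm
    sbp: Optional[float] = None  # mmHg
    resp_rate: Optional[float] = None  # breaths/min
    glucose: Optional[float] = None  # mmol/L
    sodium: Optional[float] = None  # mmol/L
    potassium: Optional[float] = None  # mmol/L
    creatinine: Optional[float] = None  # umol/L
    bilirubin: Optional[float] = None  # umol/L
    intubated: bool = False
    ventilator_breathing: VentilatorBreathing = VentilatorBreathing.NOT_VENTILATED
    map: Optional[float] = None  # mmHg, APACHE II only
    pao2: Optional[float] = None  # mmHg
    fio2: Optional[float] = None  # fraction
    aado2: Optional[float] = None  # mmHg
    arterial_ph: Optional[float] = None
    hematocrit: Optional[float] = None  # %
    acute_renal_failure: bool = False
    chronic_health: ChronicHealth = ChronicHealth.NONE

    def __post_init__(self) -> None:
        if self.fio2 is not None and not (0.0 <= self.fio2 <= 1.0):
            raise ValueError(f"fio2 must lie in [0, 1], got {self.fio2}")
        for name in ("wbc", "albumin", "heart_rate", "sbp", "resp_rate", "glucose",
                     "sodium", "potassium", "creatinine", "bilirubin", "map",
                     "pao2", "aado2", "hematocrit", "temp_axillary", "arterial_ph"):
            v = getattr(self, name)
            if v is not None:
                if not math.isfinite(v):
                    raise ValueError(f"{name} must be finite, got {v}")
                if v < 0:
                    raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class PatientObservation:
    """One timestamped clinical snapshot of one patient."""

    patient_id: str
    t_hours: float
    age_years: int
    exam: NeuroExam
    physio: PhysioPanel

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_hours) or self.t_hours < 0:
            raise ValueError(f"t_hours must be finite and >= 0, got {self.t_hours}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")


@dataclass
class ScoreBreakdown:
    """Per-item points and total for one scale applied to one observation."""

    scale: Scale
    item_points: dict[str, int]
    total: int
    notes: list[str] = field(default_factory=list)

    @classmethod
    def from_items(cls, scale: Scale, item_points: dict[str, int],
                   notes: Optional[list[str]] = None) -> "ScoreBreakdown":
        return cls(scale=scale, item_points=dict(item_points),
                   total=sum(item_points.values()), notes=list(notes or []))


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


# ---------------------------------------------------------------------------
# Band machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One closed scoring interval; ``None`` endpoints are unbounded."""

    lo: Optional[str]
    hi: Optional[str]
    points: int

    def contains(self, v: Decimal) -> bool:
        if self.lo is not None and v < Decimal(self.lo):
            return False
        if self.hi is not None and v > Decimal(self.hi):
            return False
        return True

    def distance(self, v: Decimal) -> Decimal:
        if self.lo is not None and v < Decimal(self.lo):
            return Decimal(self.lo) - v
        if self.hi is not None and v > Decimal(self.hi):
            return v - Decimal(self.hi)
        return Decimal(0)


@dataclass(frozen=True)
class BandedItem:
    """A numeric item scored from closed bands at a fixed decimal resolution."""

    item_id: str
    resolution: str  # e.g. "0.1" or "1"
    bands: tuple[Band, ...]

    def quantize(self, value: float) -> Decimal:
        if not math.isfinite(value):
            raise ValueError(f"{self.item_id}: value must be finite, got {value}")
        if value < 0:
            raise ValueError(f"{self.item_id}: value must be non-negative, got {value}")
        return Decimal(repr(value)).quantize(Decimal(self.resolution), rounding=ROUND_HALF_UP)

    def points(self, value: float) -> int:
        v = self.quantize(value)
        matches = [b for b in self.bands if b.contains(v)]
        if matches:
            # bands are disjoint by construction; max() guards ties defensively
            return max(b.points for b in matches)
        # inter-band gap: fall to the nearest band, more severe one on ties
        dmin = min(b.distance(v) for b in self.bands)
        return max(b.points for b in self.bands if b.distance(v) == dmin)

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)


# ---------------------------------------------------------------------------
# INCNS band tables (19 items, maximum 44 points)
# ---------------------------------------------------------------------------
# The 2-point WBC band is the complement of the 0/1-point bands (<=2.8 or
# >=25.1): the printed cell for it is an evident transcription error, and the
# complement keeps every WBC value scoreable with an item maximum of 2.
# The creatinine 0-point band is 44-132 umol/L, consistent with the 1-point
# band "<=43".

INCNS_NUMERIC_ITEMS: dict[str, BandedItem] = {
    "wbc": BandedItem("wbc", "0.1", (
        Band(None, "2.8", 2), Band("2.9", "3.9", 1), Band("4", "10", 0),
        Band("10.1", "25.0", 1), Band("25.1", None, 2))),
    "temperature": BandedItem("temperature", "0.1", (
        Band(None, "35.9", 1), Band("36", "38.4", 0),
        Band("38.5", "40", 1), Band("40.1", None, 2))),
    "albumin": BandedItem("albumin", "0.1", (
        Band(None, "24.9", 2), Band("25", "34.9", 1), Band("35", None, 0))),
    "age": BandedItem("age", "1", (
        Band(None, "44", 0), Band("45", "64", 1),
        Band("65", "74", 2), Band("75", None, 3))),
    "heart_rate": BandedItem("heart_rate", "1", (
        Band(None, "39", 2), Band("40", "59", 1), Band("60", "100", 0),
        Band("101", "149", 1), Band("150", None, 2))),
    "sbp": BandedItem("sbp", "1", (
        Band(None, "69", 2), Band("70", "89", 1), Band("90", "140", 0),
        Band("141", "199", 1), Band("200", None, 2))),
    "glucose": BandedItem("glucose", "0.1", (
        Band(None, "2.1", 2), Band("2.2", "3.8", 1), Band("3.9", "11.1", 0),
        Band("11.2", "19.3", 1), Band("19.4", None, 2))),
    "sodium": BandedItem("sodium", "1", (
        Band(None, "119", 2), Band("120", "129", 1), Band("130", "150", 0),
        Band("151", "159", 1), Band("160", None, 2))),
    "potassium": BandedItem("potassium", "0.1", (
        Band(None, "2.4", 2), Band("2.5", "3.4", 1), Band("3.5", "5.5", 0),
        Band("5.6", "6.9", 1), Band("7.0", None, 2))),
    "creatinine": BandedItem("creatinine", "1", (
        Band(None, "43", 1), Band("44", "132", 0),
        Band("133", "171", 1), Band("172", None, 2))),
    "bilirubin": BandedItem("bilirubin", "0.1", (
        Band(None, "34.1", 0), Band("34.2", "102.5", 1), Band("102.6", None, 2))),
}

INCNS_ORDINAL_ITEMS: dict[str, dict] = {
    "arousal": {
        Arousal.SPONTANEOUS_EYE_OPENING: 0, Arousal.EYE_OPENING_TO_VERBAL: 1,
        Arousal.EYE_OPENING_TO_PAIN: 2, Arousal.NONE: 3},
    "awareness": {
        Awareness.CORRECT_RESPONSE: 0, Awareness.CONFUSED_RESPONSE: 1,
        Awareness.NON_REFLEX_MOVEMENTS: 2, Awareness.NONE: 3},
    # the pupillary/corneal rows print no 1-point column: points jump 0 -> 2
    "pupillary_reflex": {
        BrainstemReflex.BILATERAL_RESPONSIVE: 0,
        BrainstemReflex.UNILATERAL_IMPAIRED: 2,
        BrainstemReflex.BILATERAL_IMPAIRED: 3},
    "corneal_reflex": {
        BrainstemReflex.BILATERAL_RESPONSIVE: 0,
        BrainstemReflex.UNILATERAL_IMPAIRED: 2,
        BrainstemReflex.BILATERAL_IMPAIRED: 3},
    "verbal": {
        VerbalResponse.ACCURATE: 0, VerbalResponse.CONFUSED_OR_INAPPROPRIATE: 1,
        VerbalResponse.INCOMPREHENSIBLE_OR_NONE: 2},
    "swallow": {Swallow.WST_I_II: 0, Swallow.WST_III_IV_OR_UNASSESSABLE: 1},
}

PAIN_RESPONSE_POINTS = {
    PainResponse.OBEYING: 0, PainResponse.LOCALIZING_OR_WITHDRAWAL: 1,
    PainResponse.FLEXING_OR_EXTENDING: 2, PainResponse.NONE: 3,
}

#: Canonical item order of the 19-item INCNS sheet.
INCNS_ITEMS: tuple[str, ...] = (
    "wbc", "temperature",                                  # inflammation
    "albumin",                                             # nutrition
    "arousal", "awareness",                                # consciousness
    "pupillary_reflex", "corneal_reflex", "verbal",
    "motor", "swallow", "respiration",                     # neurologic function
    "age", "heart_rate", "sbp", "glucose", "sodium",
    "potassium", "creatinine", "bilirubin",                # systemic condition
)

_MOTOR_MAX = 3
_RESPIRATION_MAX = 3


def motor_strength_points(left: int, right: int) -> int:
    """INCNS motor item from Lovett grades; the worse limb drives the score.

    Unlike GCS/FOUR/APACHE II, the INCNS records the worst motor response from
    any limb: both limbs <=1 scores 3, one limb <=1 scores 2, worse limb 2-3
    scores 1, both limbs >=4 score 0.
    """
    _check_range("strength_left", left, 0, 5)
    _check_range("strength_right", right, 0, 5)
    low = sum(1 for s in (left, right) if s <= 1)
    if low == 2:
        return 3
    if low == 1:
        return 2
    if min(left, right) >= 4:
        return 0
    return 1


def respiration_points(intubated: bool, resp_rate: Optional[float],
                       ventilator_breathing: VentilatorBreathing) -> int:
    """INCNS respiration item."""
    if intubated:
        if ventilator_breathing == VentilatorBreathing.ABOVE_VENTILATOR_RATE:
            return 2
        if ventilator_breathing == VentilatorBreathing.AT_VENTILATOR_RATE_OR_APNEA:
            return 3
        raise ValueError("intubated patient needs a ventilator breathing pattern")
    if resp_rate is None:
        raise MissingItemError("respiration: resp_rate required when not intubated")
    rr = BandedItem("resp_rate", "1", (
        Band(None, "11", 1), Band("12", "24", 0), Band("25", None, 1)))
    return rr.points(resp_rate)


def incns_item_points(item_id: str, value) -> int:
    """Score a single INCNS item from a raw measurement or enum value.

    For the composite items, ``motor`` accepts a ``(left, right)`` Lovett pair
    or a :class:`PainResponse`, and ``respiration`` accepts a tuple
    ``(intubated, resp_rate, ventilator_breathing)``.
    """
    if item_id in INCNS_NUMERIC_ITEMS:
        return INCNS_NUMERIC_ITEMS[item_id].points(float(value))
    if item_id in INCNS_ORDINAL_ITEMS:
        table = INCNS_ORDINAL_ITEMS[item_id]
        try:
            return table[value]
        except KeyError:
            raise ValueError(f"{item_id}: {value!r} is not in the item's domain") from None
    if item_id == "motor":
        if isinstance(value, PainResponse):
            return PAIN_RESPONSE_POINTS[value]
        if isinstance(value, tuple) and len(value) == 2:
            return motor_strength_points(*value)
        raise ValueError("motor: expected (left, right) strengths or a PainResponse")
    if item_id == "respiration":
        if isinstance(value, tuple) and len(value) == 3:
            return respiration_points(*value)
        raise ValueError("respiration: expected (intubated, resp_rate, ventilator_breathing)")
    raise ValueError(f"unknown INCNS item: {item_id!r}")


_INCNS_PHYSIO_FIELD = {
    "wbc": "wbc", "temperature": "temp_axillary", "albumin": "albumin",
    "heart_rate": "heart_rate", "sbp": "sbp", "glucose": "glucose",
    "sodium": "sodium", "potassium": "potassium", "creatinine": "creatinine",
    "bilirubin": "bilirubin",
}


def score_incns(obs: PatientObservation, assume_normal_missing: bool = False) -> ScoreBreakdown:
    """Score the 19-item INCNS sheet for one observation.

    Missing numeric inputs raise :class:`MissingItemError` unless
    ``assume_normal_missing`` is set, in which case the 0-point band is imputed
    and the imputation is recorded in the breakdown notes.
    """
    exam, physio = obs.exam, obs.physio
    points: dict[str, int] = {}
    notes: list[str] = []

    for item, fld in _INCNS_PHYSIO_FIELD.items():
        value = getattr(physio, fld)
        if value is None:
            if not assume_normal_missing:
                raise MissingItemError(f"INCNS item {item!r} missing ({fld})")
            points[item] = 0
            notes.append(f"{item}: missing, imputed 0-point band")
        else:
            points[item] = INCNS_NUMERIC_ITEMS[item].points(value)
    points["age"] = INCNS_NUMERIC_ITEMS["age"].points(obs.age_years)

    for item in ("arousal", "awareness", "pupillary_reflex", "corneal_reflex",
                 "verbal", "swallow"):
        points[item] = INCNS_ORDINAL_ITEMS[item][getattr(exam, item)]

    if exam.strength_left is not None and exam.strength_right is not None:
        points["motor"] = motor_strength_points(exam.strength_left, exam.strength_right)
        notes.append("motor: muscle-strength rubric (worst limb)")
        if exam.pain_response is not None:
            notes.append("motor: pain-response rubric also supplied; strength rubric wins")
    elif exam.pain_response is not None:
        points["motor"] = PAIN_RESPONSE_POINTS[exam.pain_response]
        notes.append("motor: pain-response rubric")
    else:  # pragma: no cover - NeuroExam validation prevents this
        raise MissingItemError("INCNS motor assessment missing")

    points["respiration"] = respiration_points(
        physio.intubated, physio.resp_rate, physio.ventilator_breathing)

    ordered = {item: points[item] for item in INCNS_ITEMS}
    return ScoreBreakdown.from_items(Scale.INCNS, ordered, notes)


# ---------------------------------------------------------------------------
# GCS and FOUR
# ---------------------------------------------------------------------------

GCS_COMPONENT_RANGES = {"eye": (1, 4), "verbal": (1, 5), "motor": (1, 6)}
FOUR_COMPONENT_RANGES = {"eye": (0, 4), "motor": (0, 4),
                         "brainstem": (0, 4), "respiration": (0, 4)}


def score_gcs(eye: int, verbal: int, motor: int, intubated: bool = False) -> ScoreBreakdown:
    """Glasgow Coma Scale; an intubated patient's verbal score is forced to 1."""
    _check_range("eye", eye, *GCS_COMPONENT_RANGES["eye"])
    _check_range("verbal", verbal, *GCS_COMPONENT_RANGES["verbal"])
    _check_range("motor", motor, *GCS_COMPONENT_RANGES["motor"])
    notes = []
    if intubated and verbal != 1:
        notes.append(f"verbal coerced {verbal} -> 1 (intubated)")
        verbal = 1
    return ScoreBreakdown.from_items(
        Scale.GCS, {"eye": eye, "verbal": verbal, "motor": motor}, notes)


def score_four(eye: int, motor: int, brainstem: int, respiration: int) -> ScoreBreakdown:
    """Full Outline of UnResponsiveness score (four components, 0-4 each)."""
    comps = {"eye": eye, "motor": motor, "brainstem": brainstem, "respiration": respiration}
    for name, v in comps.items():
        _check_range(name, v, *FOUR_COMPONENT_RANGES[name])
    return ScoreBreakdown.from_items(Scale.FOUR, comps)


# ---------------------------------------------------------------------------
# APACHE II
# ---------------------------------------------------------------------------
# Acute Physiology Score bands per the original instrument (12 variables,
# 0-4 points each; creatinine in umol/L with points doubled under acute renal
# failure; the GCS item contributes 15 - GCS), plus age and chronic-health
# points.  Oxygenation uses the A-a gradient when FiO2 >= 0.5, PaO2 otherwise.

APACHE_NUMERIC_ITEMS: dict[str, BandedItem] = {
    "temperature": BandedItem("temperature", "0.1", (
        Band(None, "29.9", 4), Band("30", "31.9", 3), Band("32", "33.9", 2),
        Band("34", "35.9", 1), Band("36", "38.4", 0), Band("38.5", "38.9", 1),
        Band("39", "40.9", 3), Band("41", None, 4))),
    "map": BandedItem("map", "1", (
        Band(None, "49", 4), Band("50", "69", 2), Band("70", "109", 0),
        Band("110", "129", 2), Band("130", "159", 3), Band("160", None, 4))),
    "heart_rate": BandedItem("heart_rate", "1", (
        Band(None, "39", 4), Band("40", "54", 3), Band("55", "69", 2),
        Band("70", "109", 0), Band("110", "139", 2), Band("140", "179", 3),
        Band("180", None, 4))),
    "resp_rate": BandedItem("resp_rate", "1", (
        Band(None, "5", 4), Band("6", "9", 2), Band("10", "11", 1),
        Band("12", "24", 0), Band("25", "34", 1), Band("35", "49", 3),
        Band("50", None, 4))),
    "arterial_ph": BandedItem("arterial_ph", "0.01", (
        Band(None, "7.14", 4), Band("7.15", "7.24", 3), Band("7.25", "7.32", 2),
        Band("7.33", "7.49", 0), Band("7.50", "7.59", 1), Band("7.60", "7.69", 3),
        Band("7.70", None, 4))),
    "sodium": BandedItem("sodium", "1", (
        Band(None, "110", 4), Band("111", "119", 3), Band("120", "129", 2),
        Band("130", "149", 0), Band("150", "154", 1), Band("155", "159", 2),
        Band("160", "179", 3), Band("180", None, 4))),
    "potassium": BandedItem("potassium", "0.1", (
        Band(None, "2.4", 4), Band("2.5", "2.9", 2), Band("3.0", "3.4", 1),
        Band("3.5", "5.4", 0), Band("5.5", "5.9", 1), Band("6.0", "6.9", 3),
        Band("7.0", None, 4))),
    # umol/L (original bands in mg/dL x 88.4)
    "creatinine": BandedItem("creatinine", "1", (
        Band(None, "52", 2), Band("53", "132", 0), Band("133", "176", 2),
        Band("177", "309", 3), Band("310", None, 4))),
    "hematocrit": BandedItem("hematocrit", "0.1", (
        Band(None, "19.9", 4), Band("20", "29.9", 2), Band("30", "45.9", 0),
        Band("46", "49.9", 1), Band("50", "59.9", 2), Band("60", None, 4))),
    "wbc": BandedItem("wbc", "0.1", (
        Band(None, "0.9", 4), Band("1", "2.9", 2), Band("3", "14.9", 0),
        Band("15", "19.9", 1), Band("20", "39.9", 2), Band("40", None, 4))),
}

APACHE_AADO2 = BandedItem("aado2", "1", (
    Band(None, "199", 0), Band("200", "349", 2), Band("350", "499", 3),
    Band("500", None, 4)))
APACHE_PAO2 = BandedItem("pao2", "1", (
    Band(None, "54", 4), Band("55", "60", 3), Band("61", "70", 1),
    Band("71", None, 0)))
APACHE_AGE = BandedItem("age", "1", (
    Band(None, "44", 0), Band("45", "54", 2), Band("55", "64", 3),
    Band("65", "74", 5), Band("75", None, 6)))
APACHE_CHRONIC_POINTS = {
    ChronicHealth.NONE: 0, ChronicHealth.ELECTIVE_POSTOP: 2,
    ChronicHealth.EMERGENCY_OR_NONOPERATIVE: 5,
}

_APACHE_PHYSIO_FIELD = {
    "temperature": "temp_axillary", "map": "map", "heart_rate": "heart_rate",
    "resp_rate": "resp_rate", "arterial_ph": "arterial_ph", "sodium": "sodium",
    "potassium": "potassium", "creatinine": "creatinine",
    "hematocrit": "hematocrit", "wbc": "wbc",
}


def _apache_oxygenation(physio: PhysioPanel, notes: list[str],
                        assume_normal_missing: bool) -> int:
    fio2 = physio.fio2
    if fio2 is not None and fio2 >= 0.5:
        if physio.aado2 is None:
            if assume_normal_missing:
                notes.append("oxygenation: A-aDO2 missing, imputed 0-point band")
                return 0
            raise MissingItemError("APACHE II oxygenation: A-aDO2 required when FiO2 >= 0.5")
        notes.append("oxygenation: A-aDO2 bands (FiO2 >= 0.5)")
        return APACHE_AADO2.points(physio.aado2)
    if physio.pao2 is None:
        if assume_normal_missing:
            notes.append("oxygenation: PaO2 missing, imputed 0-point band")
            return 0
        raise MissingItemError("APACHE II oxygenation: PaO2 required when FiO2 < 0.5")
    notes.append("oxygenation: PaO2 bands (FiO2 < 0.5)")
    return APACHE_PAO2.points(physio.pao2)


def score_apache2(obs: PatientObservation, gcs_total: Optional[int] = None,
                  assume_normal_missing: bool = False) -> ScoreBreakdown:
    """APACHE II total = acute physiology + age + chronic health points.

    ``gcs_total`` defaults to the GCS computed from the observation's exam
    (with the intubation convention applied).
    """
    physio = obs.physio
    notes: list[str] = []
    points: dict[str, int] = {}

    for item, fld in _APACHE_PHYSIO_FIELD.items():
        value = getattr(physio, fld)
        if value is None:
            if not assume_normal_missing:
                raise MissingItemError(f"APACHE II variable {item!r} missing ({fld})")
            points[item] = 0
            notes.append(f"{item}: missing, imputed 0-point band")
            continue
        pts = APACHE_NUMERIC_ITEMS[item].points(value)
        if item == "creatinine" and physio.acute_renal_failure:
            pts *= 2
            notes.append("creatinine points doubled (acute renal failure)")
        points[item] = pts

    points["oxygenation"] = _apache_oxygenation(physio, notes, assume_normal_missing)

    if gcs_total is None:
        gcs_total = score_gcs(obs.exam.gcs_eye, obs.exam.gcs_verbal,
                              obs.exam.gcs_motor, physio.intubated).total
    _check_range("gcs_total", gcs_total, 3, 15)
    points["gcs"] = 15 - gcs_total
    points["age"] = APACHE_AGE.points(obs.age_years)
    points["chronic_health"] = APACHE_CHRONIC_POINTS[physio.chronic_health]
    return ScoreBreakdown.from_items(Scale.APACHE2, points, notes)


# ---------------------------------------------------------------------------
# Scale maxima (computed from the implemented tables, not hard-coded)
# ---------------------------------------------------------------------------

def max_score(scale: Scale) -> int:
    """Maximum achievable total of a scale, derived from its item tables."""
    scale = Scale(scale)
    if scale == Scale.INCNS:
        total = sum(item.max_points for item in INCNS_NUMERIC_ITEMS.values())
        total += sum(max(t.values()) for t in INCNS_ORDINAL_ITEMS.values())
        return total + _MOTOR_MAX + _RESPIRATION_MAX
    if scale == Scale.GCS:
        return sum(hi for _, hi in GCS_COMPONENT_RANGES.values())
    if scale == Scale.FOUR:
        return sum(hi for _, hi in FOUR_COMPONENT_RANGES.values())
    if scale == Scale.APACHE2:
        gcs_min = sum(lo for lo, _ in GCS_COMPONENT_RANGES.values())
        aps = sum(item.max_points for item in APACHE_NUMERIC_ITEMS.values())
        aps += APACHE_NUMERIC_ITEMS["creatinine"].max_points  # ARF doubling
        aps += max(APACHE_AADO2.max_points, APACHE_PAO2.max_points)
        aps += 15 - gcs_min
        return aps + APACHE_AGE.max_points + max(APACHE_CHRONIC_POINTS.values())
    raise ValueError(f"unknown scale: {scale!r}")


def incns_domain_maxima() -> dict[str, int]:
    """Per-domain INCNS maxima (inflammation, nutrition, consciousness,
    neurologic function, systemic condition), computed from the item tables."""
    num = {k: v.max_points for k, v in INCNS_NUMERIC_ITEMS.items()}
    ordmax = {k: max(v.values()) for k, v in INCNS_ORDINAL_ITEMS.items()}
    return {
        "inflammation": num["wbc"] + num["temperature"],
        "nutrition": num["albumin"],
        "consciousness": ordmax["arousal"] + ordmax["awareness"],
        "neurologic": (ordmax["pupillary_reflex"] + ordmax["corneal_reflex"]
                       + ordmax["verbal"] + _MOTOR_MAX + ordmax["swallow"]
                       + _RESPIRATION_MAX),
        "systemic": (num["age"] + num["heart_rate"] + num["sbp"] + num["glucose"]
                     + num["sodium"] + num["potassium"] + num["creatinine"]
                     + num["bilirubin"]),
    }
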