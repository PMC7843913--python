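"""Builders for hand-scored observations used across the test suite."""

from __future__ import annotations

from incns import (
    Arousal,
    Awareness,
    BrainstemReflex,
    ChronicHealth,
    NeuroExam,
    PainResponse,
    PatientObservation,
    PhysioPanel,
    Swallow,
    VentilatorBreathing,
    VerbalResponse,
)

_EXAM_FIELDS = {
    "arousal", "awareness", "pupillary_reflex", "corneal_reflex", "verbal",
    "swallow", "gcs_eye", "gcs_verbal", "gcs_motor", "four_eye", "four_motor",
    "four_brainstem", "four_respiration", "strength_left", "strength_right",
    "pain_response",
}
_TOP_FIELDS = {"patient_id", "t_hours", "age_years"}


def make_obs(**overrides) -> PatientObservation:
    """An all-normal adult; every INCNS and APACHE II item in its 0 band.

    Keyword overrides address exam, physio or top-level fields by name.
    """
    exam = dict(
        arousal=Arousal.SPONTANEOUS_EYE_OPENING,
        awareness=Awareness.CORRECT_RESPONSE,
        pupillary_reflex=BrainstemReflex.BILATERAL_RESPONSIVE,
        corneal_reflex=BrainstemReflex.BILATERAL_RESPONSIVE,
        verbal=VerbalResponse.ACCURATE,
        swallow=Swallow.WST_I_II,
        strength_left=5, strength_right=5, pain_response=None,
        gcs_eye=4, gcs_verbal=5, gcs_motor=6,
        four_eye=4, four_motor=4, four_brainstem=4, four_respiration=4,
    )
    physio = dict(
        wbc=7.0, temp_axillary=36.8, albumin=40.0, heart_rate=75.0, sbp=120.0,
        resp_rate=16.0, glucose=5.0, sodium=140.0, potassium=4.0,
        creatinine=80.0, bilirubin=10.0, intubated=False,
        ventilator_breathing=VentilatorBreathing.NOT_VENTILATED,
        map=90.0, pao2=90.0, fio2=0.21, aado2=None, arterial_ph=7.4,
        hematocrit=40.0, acute_renal_failure=False,
        chronic_health=ChronicHealth.NONE,
    )
    top = dict(patient_id="T0", t_hours=2.0, age_years=30)
    for key, value in overrides.items():
        if key in _EXAM_FIELDS:
            exam[key] = value
        elif key in physio:
            physio[key] = value
        elif key in _TOP_FIELDS:
            top[key] = value
        else:
            raise KeyError(key)
    return PatientObservation(exam=NeuroExam(**exam), physio=PhysioPanel(**physio), **top)


def make_worst_incns_obs(**overrides) -> PatientObservation:
    """Every INCNS item in its highest-point band (total 44)."""
    return make_obs(
        age_years=80, wbc=30.0, temp_axillary=40.5, albumin=20.0,
        arousal=Arousal.NONE, awareness=Awareness.NONE,
        pupillary_reflex=BrainstemReflex.BILATERAL_IMPAIRED,
        corneal_reflex=BrainstemReflex.BILATERAL_IMPAIRED,
        verbal=VerbalResponse.INCOMPREHENSIBLE_OR_NONE,
        strength_left=0, strength_right=0,
        swallow=Swallow.WST_III_IV_OR_UNASSESSABLE,
        intubated=True,
        ventilator_breathing=VentilatorBreathing.AT_VENTILATOR_RATE_OR_APNEA,
        heart_rate=160.0, sbp=210.0, glucose=25.0, sodium=165.0,
        potassium=7.5, creatinine=200.0, bilirubin=120.0,
        gcs_eye=1, gcs_verbal=1, gcs_motor=1,
        four_eye=0, four_motor=0, four_brainstem=0, four_respiration=0,
        **overrides,
    )


def make_worst_apache_obs(**overrides) -> PatientObservation:
    """Every APACHE II item in its worst band (total 71)."""
    return make_obs(
        age_years=80, temp_axillary=41.5, map=170.0, heart_rate=185.0,
        resp_rate=55.0, fio2=0.6, aado2=550.0, pao2=None, arterial_ph=7.05,
        sodium=185.0, potassium=7.5, creatinine=350.0, acute_renal_failure=True,
        hematocrit=62.0, wbc=45.0,
        chronic_health=ChronicHealth.EMERGENCY_OR_NONOPERATIVE,
        gcs_eye=1, gcs_verbal=1, gcs_motor=1,
        **overrides,
    )


def make_mixed_incns_obs() -> PatientObservation:
    """A hand-summed mixed severity case; INCNS total 27."""
    return make_obs(
        age_years=70,                                   # 2
        wbc=12.0,                                       # 1
        temp_axillary=39.0,                             # 1
        albumin=30.0,                                   # 1
        arousal=Arousal.EYE_OPENING_TO_PAIN,            # 2
        awareness=Awareness.NONE,                       # 3
        pupillary_reflex=BrainstemReflex.UNILATERAL_IMPAIRED,  # 2
        corneal_reflex=BrainstemReflex.BILATERAL_RESPONSIVE,   # 0
        verbal=VerbalResponse.INCOMPREHENSIBLE_OR_NONE,        # 2
        strength_left=1, strength_right=1,              # 3 (bilateral <= 1)
        swallow=Swallow.WST_III_IV_OR_UNASSESSABLE,     # 1
        intubated=True,
        ventilator_breathing=VentilatorBreathing.ABOVE_VENTILATOR_RATE,  # 2
        heart_rate=110.0,                               # 1
        sbp=150.0,                                      # 1
        glucose=15.0,                                   # 1
        sodium=155.0,                                   # 1
        potassium=3.0,                                  # 1
        creatinine=150.0,                               # 1
        bilirubin=50.0,                                 # 1
    )
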