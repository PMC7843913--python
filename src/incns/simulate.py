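"""Synthetic comatose-cohort generator.

Emulates a NICU cohort of comatose patients with the statistical structure the
validation analysis assumes: a single latent severity factor ``z`` per patient
drives three properly nested binary outcomes (unfavorable 3-month functional
outcome ⊇ 3-month death ⊇ NICU death) and, through monotone noisy links,
every input of the four severity scorers at each scheduled observation time.

Outcome model
-------------
The unfavorable outcome is drawn first with the configured prevalence and the
latent severity is ``z | y ~ N(latent_effect * y, 1)``.  This is equivalent to
logistic thresholding of ``z`` (the posterior is expit-linear in ``z``) and
makes the binormal calibration exact: ``latent_effect =
calibrate_effect_for_auc(a)`` yields a latent-score AUC of exactly ``a`` for
the unfavorable outcome in expectation.  The nested mortality outcomes are
then selected within the unfavorable class with probability
``expit(b * (z - m))`` where ``b = mortality_steepness * latent_effect`` (so a
null generator with zero effect carries no score-outcome association at all)
and the offsets ``m`` are solved by Gauss-Hermite quadrature so the marginal
prevalences match the configuration in expectation.

Observations map ``s(t) = z + deterioration_drift * t`` plus per-item Gaussian
noise monotonically into scorer inputs: labs drift into higher-point bands and
GCS/FOUR components fall as severity rises.  A configured fraction of
timelines violates each inclusion rule so the cohort pipeline has work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from .cohort import PatientTimeline
from .scales import (
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


def closed_form_auc(mu0: float, mu1: float, sd0: float, sd1: float) -> float:
    """Binormal AUC: Phi((mu1 - mu0) / sqrt(sd0^2 + sd1^2)), higher positive."""
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(ndtr((mu1 - mu0) / math.hypot(sd0, sd1)))


def calibrate_effect_for_auc(target_auc: float) -> float:
    """Class separation (unit SDs) giving a binormal AUC of ``target_auc``."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target AUC must lie strictly between 0.5 and 1")
    return float(math.sqrt(2) * ndtri(target_auc))


DEFAULT_FRACTION_EXCLUDED = {
    "non_comatose": 0.03,
    "short_stay": 0.04,
    "drug_induced": 0.02,
}

DEFAULT_ETIOLOGY_PROBS = {
    "cerebral_infarction": 0.325,
    "cns_infection": 0.232,
    "cerebral_hemorrhage": 0.18,
    "other": 0.263,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the validation cohort: 271 analyzable patients, outcome
    prevalences 83% unfavorable / 45% 3-month death / 9.6% NICU death,
    repeated observations over the first 72 h, and a latent effect calibrated
    for an unfavorable-outcome AUC of 0.80 (mid severity-score range).
    """

    n_patients: int = 271
    seed: int = 0
    prevalence_unfavorable: float = 0.83
    prevalence_3m_death: float = 0.45
    prevalence_nicu_death: float = 0.096
    latent_effect: Optional[float] = None  # default: calibrated for AUC 0.80
    mortality_steepness: float = 1.2
    obs_schedule: tuple[float, ...] = (2.0, 12.0, 24.0, 48.0, 72.0)
    deterioration_drift: float = 0.005  # latent SD units per hour
    item_noise_sd: float = 0.5
    fraction_excluded: dict = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_EXCLUDED))
    fraction_lost_followup: float = 0.0
    etiology_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_ETIOLOGY_PROBS))

    def __post_init__(self) -> None:
        if self.latent_effect is None:
            self.latent_effect = calibrate_effect_for_auc(0.80)
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        p_u, p_3, p_n = (self.prevalence_unfavorable, self.prevalence_3m_death,
                         self.prevalence_nicu_death)
        if not (0 < p_n < p_3 < p_u < 1):
            raise ValueError(
                "prevalences must nest: 0 < nicu_death < 3m_death < unfavorable < 1")
        if self.latent_effect < 0 or self.item_noise_sd < 0:
            raise ValueError("latent_effect and item_noise_sd must be >= 0")
        if not self.obs_schedule:
            raise ValueError("observation schedule must be non-empty")
        sched = tuple(float(t) for t in self.obs_schedule)
        if any(t <= 0 or t > 72 for t in sched) or list(sched) != sorted(sched):
            raise ValueError("obs_schedule must be sorted times in (0, 72]")
        self.obs_schedule = sched
        if sum(self.fraction_excluded.values()) + self.fraction_lost_followup >= 1:
            raise ValueError("exclusion fractions must sum to < 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "obs_schedule" in raw:
            raw["obs_schedule"] = tuple(raw["obs_schedule"])
        return cls(**raw)


# monotone linear links u -> measurement; (base, slope, lo, hi, decimals).
# Severity perturbs each variable in ONE clinical direction only, and the
# healthy-side clip sits at the edge of the zero-point band, so every scored
# item is monotone non-decreasing in the latent severity (two-sided bands
# would otherwise score low-severity excursions, e.g. bradycardia).
_NUMERIC_LINKS = {
    "wbc": (7.0, 4.0, 4.0, 60.0, 1),
    "temp_axillary": (37.0, 0.6, 36.0, 42.5, 1),
    "albumin": (40.0, -4.0, 10.0, 55.0, 1),
    "heart_rate": (82.0, 20.0, 60.0, 220.0, 0),
    "sbp": (125.0, 22.0, 90.0, 260.0, 0),
    "glucose": (6.5, 3.2, 3.9, 40.0, 1),
    "sodium": (140.0, 5.5, 130.0, 185.0, 0),
    "potassium": (4.2, 0.7, 3.5, 9.0, 1),
    "creatinine": (90.0, 35.0, 53.0, 600.0, 0),
    "bilirubin": (14.0, 16.0, 2.0, 400.0, 1),
    "map": (92.0, 11.0, 70.0, 200.0, 0),
    "arterial_ph": (7.40, -0.035, 6.80, 7.49, 2),
    "hematocrit": (40.0, -2.5, 12.0, 45.9, 1),
}

# ordinal cutpoints on the per-item latent u (ascending severity)
_CUTS = {
    "eye": (-0.3, 0.4, 1.1),          # arousal level / GCS eye / shared
    "awareness": (-0.4, 0.2, 0.9),
    "gcs_verbal": (-0.8, -0.2, 0.5, 1.2),
    "gcs_motor": (-0.6, 0.0, 0.7, 1.4, 2.1),
    "four_eye": (-0.3, 0.3, 0.9, 1.6),
    "four_motor": (-0.2, 0.6, 1.3, 2.1),
    "four_brainstem": (0.7, 1.5, 2.2, 2.9),
    "pupillary": (1.7, 2.5),
    "corneal": (1.5, 2.3),
    "speech": (-0.5, 0.3),
    "strength": (-0.6, 0.1, 0.8, 1.5, 2.2),
    "pain": (0.0, 0.9, 1.8),
}

_AROUSAL_LEVELS = (Arousal.SPONTANEOUS_EYE_OPENING, Arousal.EYE_OPENING_TO_VERBAL,
                   Arousal.EYE_OPENING_TO_PAIN, Arousal.NONE)
_AWARENESS_LEVELS = (Awareness.CORRECT_RESPONSE, Awareness.CONFUSED_RESPONSE,
                     Awareness.NON_REFLEX_MOVEMENTS, Awareness.NONE)
_REFLEX_LEVELS = (BrainstemReflex.BILATERAL_RESPONSIVE,
                  BrainstemReflex.UNILATERAL_IMPAIRED,
                  BrainstemReflex.BILATERAL_IMPAIRED)
_SPEECH_LEVELS = (VerbalResponse.ACCURATE, VerbalResponse.CONFUSED_OR_INAPPROPRIATE,
                  VerbalResponse.INCOMPREHENSIBLE_OR_NONE)
_PAIN_LEVELS = (PainResponse.OBEYING, PainResponse.LOCALIZING_OR_WITHDRAWAL,
                PainResponse.FLEXING_OR_EXTENDING, PainResponse.NONE)


def _level(cuts: tuple, u: float) -> int:
    return int(np.searchsorted(cuts, u))


def _solve_selection_offsets(cfg: SimulationConfig) -> tuple[float, float]:
    """Logistic-selection offsets matching the nested mortality prevalences."""
    delta = cfg.latent_effect
    b = cfg.mortality_steepness * delta
    if b == 0:
        raise ValueError("selection offsets are undefined for a null severity link")
    p_3m_in_unf = cfg.prevalence_3m_death / cfg.prevalence_unfavorable
    p_nicu_in_3m = cfg.prevalence_nicu_death / cfg.prevalence_3m_death
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    weights = weights / weights.sum()
    zs = nodes + delta  # z | unfavorable ~ N(delta, 1)

    def frac_3m(m):
        return float(np.sum(weights * expit(b * (zs - m)))) - p_3m_in_unf

    m1 = brentq(frac_3m, -60, 60, xtol=1e-12)
    sel = weights * expit(b * (zs - m1))  # density weights of z | 3m death
    sel = sel / sel.sum()

    def frac_nicu(m):
        return float(np.sum(sel * expit(b * (zs - m)))) - p_nicu_in_3m

    m2 = brentq(frac_nicu, -60, 60, xtol=1e-12)
    return float(m1), float(m2)


def _draw_exam_physio(rng: np.random.Generator, s: float, noise: float,
                      age: int, use_strength: bool, asym: float,
                      chronic: ChronicHealth, coma_clamp: bool,
                      force_awake: bool) -> tuple[NeuroExam, PhysioPanel]:
    u = {k: s + noise * rng.standard_normal() for k in
         ("eye", "awareness", "verbal", "motor", "pupil", "cornea", "speech",
          "swallow", "resp", "labs_extra")}

    eye_idx = _level(_CUTS["eye"], u["eye"])
    gcs_eye = 4 - eye_idx
    awareness_idx = _level(_CUTS["awareness"], u["awareness"])
    gcs_verbal = 5 - _level(_CUTS["gcs_verbal"], u["verbal"])
    gcs_motor = 6 - _level(_CUTS["gcs_motor"], u["motor"])
    four_eye = 4 - _level(_CUTS["four_eye"], u["eye"])
    four_motor = 4 - _level(_CUTS["four_motor"], u["motor"])
    four_brainstem = 4 - _level(_CUTS["four_brainstem"], u["pupil"])
    pupil_idx = _level(_CUTS["pupillary"], u["pupil"])
    cornea_idx = _level(_CUTS["corneal"], u["cornea"])
    speech_idx = _level(_CUTS["speech"], u["speech"])
    pain_idx = _level(_CUTS["pain"], u["motor"])
    strength_right = 5 - _level(_CUTS["strength"], u["motor"])
    strength_left = 5 - _level(_CUTS["strength"], u["motor"] + asym)

    if coma_clamp:
        gcs_eye, eye_idx, four_eye = 1, 3, min(four_eye, 1)
        gcs_verbal = min(gcs_verbal, 2)
        gcs_motor = min(gcs_motor, 4)
        speech_idx = 2
        awareness_idx = max(awareness_idx, 2)
        pain_idx = max(pain_idx, 1)
        strength_left = min(strength_left, 3)
        strength_right = min(strength_right, 3)
    elif force_awake:
        gcs_eye = max(gcs_eye, 2)
        eye_idx = 4 - gcs_eye
        four_eye = max(four_eye, 2)

    # respiration / ventilation
    intubated = rng.random() < expit(1.3 * (u["resp"] - 1.6))
    if intubated:
        vent = (VentilatorBreathing.ABOVE_VENTILATOR_RATE if u["resp"] < 2.6
                else VentilatorBreathing.AT_VENTILATOR_RATE_OR_APNEA)
        resp_rate = 14.0
        four_resp = 1 if vent is VentilatorBreathing.ABOVE_VENTILATOR_RATE else 0
    else:
        vent = VentilatorBreathing.NOT_VENTILATED
        resp_rate = float(np.clip(round(17 + 4 * u["resp"]), 12, 60))
        four_resp = 4 if u["resp"] < 1.5 else (3 if u["resp"] < 2.2 else 2)

    values = {}
    for fld, (base, slope, lo, hi, dec) in _NUMERIC_LINKS.items():
        uu = s + noise * rng.standard_normal()
        values[fld] = float(np.clip(round(base + slope * uu, dec), lo, hi))

    u_ox = s + noise * rng.standard_normal()
    fio2 = float(np.clip(round(0.21 + 0.07 * u_ox, 2), 0.21, 1.0))
    if fio2 >= 0.5:
        aado2 = float(np.clip(round(120 + 80 * u_ox), 50, 700))
        pao2 = None
    else:
        aado2 = None
        pao2 = float(np.clip(round(92 - 8 * u_ox), 35, 150))

    exam = NeuroExam(
        arousal=_AROUSAL_LEVELS[eye_idx],
        awareness=_AWARENESS_LEVELS[awareness_idx],
        pupillary_reflex=_REFLEX_LEVELS[pupil_idx],
        corneal_reflex=_REFLEX_LEVELS[cornea_idx],
        verbal=_SPEECH_LEVELS[speech_idx],
        swallow=(Swallow.WST_I_II if u["swallow"] < 1.1
                 else Swallow.WST_III_IV_OR_UNASSESSABLE),
        strength_left=int(np.clip(strength_left, 0, 5)) if use_strength else None,
        strength_right=int(np.clip(strength_right, 0, 5)) if use_strength else None,
        pain_response=None if use_strength else _PAIN_LEVELS[pain_idx],
        gcs_eye=gcs_eye, gcs_verbal=gcs_verbal, gcs_motor=gcs_motor,
        four_eye=four_eye, four_motor=four_motor,
        four_brainstem=four_brainstem, four_respiration=four_resp,
    )
    physio = PhysioPanel(
        wbc=values["wbc"], temp_axillary=values["temp_axillary"],
        albumin=values["albumin"], heart_rate=values["heart_rate"],
        sbp=values["sbp"], resp_rate=resp_rate, glucose=values["glucose"],
        sodium=values["sodium"], potassium=values["potassium"],
        creatinine=values["creatinine"], bilirubin=values["bilirubin"],
        intubated=bool(intubated), ventilator_breathing=vent,
        map=values["map"], pao2=pao2, fio2=fio2, aado2=aado2,
        arterial_ph=values["arterial_ph"], hematocrit=values["hematocrit"],
        acute_renal_failure=bool(rng.random() < expit(1.5 * (u["labs_extra"] - 2.8))),
        chronic_health=chronic,
    )
    return exam, physio


_ARMS = ("included", "non_comatose", "short_stay", "drug_induced", "lost_followup")


def generate_cohort(config: SimulationConfig, return_latent: bool = False):
    """Generate synthetic patient timelines (optionally with the latent table).

    Identical configurations (including the seed) produce identical output.
    With ``return_latent=True`` also returns a DataFrame with each patient's
    latent severity and outcome indicators, for calibration diagnostics.
    """
    import pandas as pd

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    delta = cfg.latent_effect
    b = cfg.mortality_steepness * delta
    if b > 0:
        m1, m2 = _solve_selection_offsets(cfg)
    else:
        m1 = m2 = 0.0
    p_3m_in_unf = cfg.prevalence_3m_death / cfg.prevalence_unfavorable
    p_nicu_in_3m = cfg.prevalence_nicu_death / cfg.prevalence_3m_death

    arm_probs = [
        1 - sum(cfg.fraction_excluded.values()) - cfg.fraction_lost_followup,
        cfg.fraction_excluded.get("non_comatose", 0.0),
        cfg.fraction_excluded.get("short_stay", 0.0),
        cfg.fraction_excluded.get("drug_induced", 0.0),
        cfg.fraction_lost_followup,
    ]
    etio_names = list(cfg.etiology_probs)
    etio_probs = np.asarray([cfg.etiology_probs[k] for k in etio_names], float)
    etio_probs = etio_probs / etio_probs.sum()

    timelines: list[PatientTimeline] = []
    latent_rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        arm = _ARMS[rng.choice(len(_ARMS), p=arm_probs)]

        y_unf = bool(rng.random() < cfg.prevalence_unfavorable)
        z = float(delta * y_unf + rng.standard_normal())
        if y_unf:
            p3 = expit(b * (z - m1)) if b > 0 else p_3m_in_unf
            d3 = bool(rng.random() < p3)
        else:
            d3 = False
        if d3:
            pn = expit(b * (z - m2)) if b > 0 else p_nicu_in_3m
            dn = bool(rng.random() < pn)
        else:
            dn = False

        if not y_unf:
            mrs = int(rng.integers(0, 3))
        elif not d3:
            mrs = int(rng.integers(3, 6))
        else:
            mrs = 6

        age = int(np.clip(round(rng.normal(55, 17)), 16, 94))
        etiology = etio_names[rng.choice(len(etio_names), p=etio_probs)]
        use_strength = bool(rng.random() < 0.7)
        asym = 0.8 if rng.random() < 0.4 else 0.0
        chronic = ChronicHealth(rng.choice(
            [c.value for c in ChronicHealth], p=[0.85, 0.05, 0.10]))

        if arm == "short_stay":
            los = float(rng.uniform(24, 71))
        else:
            los = float(72 + rng.exponential(240))

        times = [t for t in cfg.obs_schedule if t <= los]
        observations = []
        for j, t in enumerate(times):
            s = z + cfg.deterioration_drift * t
            exam, physio = _draw_exam_physio(
                rng, s, cfg.item_noise_sd, age, use_strength, asym, chronic,
                coma_clamp=(j == 0 and arm != "non_comatose"),
                force_awake=(j == 0 and arm == "non_comatose"))
            observations.append(PatientObservation(
                patient_id=pid, t_hours=t, age_years=age,
                exam=exam, physio=physio))

        timelines.append(PatientTimeline(
            patient_id=pid, observations=observations, nicu_los_hours=los,
            drug_induced_coma=(arm == "drug_induced"), died_in_nicu=dn,
            mrs_3month=mrs, died_by_3month=d3, etiology=etiology,
            lost_to_followup=(arm == "lost_followup")))
        latent_rows.append({"patient_id": pid, "arm": arm, "z": z,
                            "unfavorable": y_unf, "death_3m": d3,
                            "death_nicu": dn})

    if return_latent:
        return timelines, pd.DataFrame(latent_rows)
    return timelines
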