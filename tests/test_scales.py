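"""Unit and property tests for the four severity scorers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from incns import (
    MissingItemError,
    PainResponse,
    Scale,
    incns_item_points,
    max_score,
    score_apache2,
    score_four,
    score_gcs,
    score_incns,
)
from incns.scales import (
    APACHE_NUMERIC_ITEMS,
    INCNS_ITEMS,
    INCNS_NUMERIC_ITEMS,
    incns_domain_maxima,
    motor_strength_points,
)
from helpers import (
    make_mixed_incns_obs,
    make_obs,
    make_worst_apache_obs,
    make_worst_incns_obs,
)


class TestIncnsItems:
    @pytest.mark.parametrize("item,value,expected", [
        ("temperature", 39.0, 1),
        ("albumin", 40.0, 0),
        ("glucose", 19.35, 2),   # rounds to 19.4 at band resolution
        ("wbc", 10.05, 1),       # rounds into the 10.1-25.0 band
        ("wbc", 3.95, 0),        # rounds to 4.0
        ("wbc", 2.0, 2),         # reconstructed severe leukopenia band
        ("wbc", 30.0, 2),
        ("creatinine", 40.0, 1),  # below the 44-132 normal band
        ("creatinine", 100.0, 0),
    ])
    def test_item_examples(self, item, value, expected):
        assert incns_item_points(item, value) == expected

    def test_unknown_item_and_bad_values(self):
        with pytest.raises(ValueError):
            incns_item_points("bogus", 1.0)
        with pytest.raises(ValueError):
            incns_item_points("wbc", -1.0)
        with pytest.raises(ValueError):
            incns_item_points("wbc", float("nan"))
        with pytest.raises(ValueError):
            incns_item_points("arousal", "not_an_enum_member")

    def test_band_tables_exhaustive_grid(self):
        """Brute-force scan: every grid point maps to exactly one band and the
        assignment is reproduced by an independent interval lookup."""
        from decimal import Decimal

        for item_id, item in INCNS_NUMERIC_ITEMS.items():
            res = float(item.resolution)
            hi_probe = 1.5 * max(float(b.lo) for b in item.bands if b.lo)
            grid = np.arange(0.0, hi_probe, res / 2)
            for v in grid:
                got = item.points(float(v))
                q = Decimal(repr(float(v))).quantize(Decimal(item.resolution),
                                                     rounding="ROUND_HALF_UP")
                oracle = [b.points for b in item.bands
                          if (b.lo is None or q >= Decimal(b.lo))
                          and (b.hi is None or q <= Decimal(b.hi))]
                assert oracle, f"{item_id}: {v} falls in a gap after quantising"
                assert got == oracle[0], f"{item_id} at {v}"

    def test_item_maxima_sum_to_44_by_domain(self):
        domains = incns_domain_maxima()
        assert domains == {"inflammation": 4, "nutrition": 2, "consciousness": 6,
                           "neurologic": 15, "systemic": 17}
        assert sum(domains.values()) == 44

    @pytest.mark.parametrize("left,right,expected", [
        (5, 5, 0), (4, 4, 0), (5, 4, 0),
        (3, 5, 1), (2, 2, 1), (3, 2, 1),
        (1, 4, 2), (0, 5, 2), (5, 1, 2),
        (1, 1, 3), (0, 0, 3), (0, 1, 3),
    ])
    def test_motor_worst_limb(self, left, right, expected):
        assert motor_strength_points(left, right) == expected

    def test_motor_pain_rubric(self):
        assert incns_item_points("motor", PainResponse.OBEYING) == 0
        assert incns_item_points("motor", PainResponse.NONE) == 3


class TestScoreIncns:
    def test_all_normal_adult_scores_zero(self):
        bd = score_incns(make_obs())
        assert bd.total == 0
        assert len(bd.item_points) == 19
        assert set(bd.item_points) == set(INCNS_ITEMS)
        assert all(v == 0 for v in bd.item_points.values())

    def test_worst_case_reaches_the_maximum(self):
        bd = score_incns(make_worst_incns_obs())
        assert bd.total == 44 == max_score(Scale.INCNS)

    def test_mixed_case_hand_sum(self):
        bd = score_incns(make_mixed_incns_obs())
        assert bd.total == 27
        expected = {"age": 2, "wbc": 1, "temperature": 1, "albumin": 1,
                    "arousal": 2, "awareness": 3, "pupillary_reflex": 2,
                    "corneal_reflex": 0, "verbal": 2, "motor": 3, "swallow": 1,
                    "respiration": 2, "heart_rate": 1, "sbp": 1, "glucose": 1,
                    "sodium": 1, "potassium": 1, "creatinine": 1, "bilirubin": 1}
        assert bd.item_points == {k: expected[k] for k in bd.item_points}

    def test_missing_item_errors_unless_imputed(self):
        obs = make_obs(albumin=None)
        with pytest.raises(MissingItemError):
            score_incns(obs)
        bd = score_incns(obs, assume_normal_missing=True)
        assert bd.item_points["albumin"] == 0
        assert any("albumin" in n and "imputed" in n for n in bd.notes)

    def test_strength_rubric_wins_when_both_supplied(self):
        obs = make_obs(strength_left=5, strength_right=5,
                       pain_response=PainResponse.NONE)
        bd = score_incns(obs)
        assert bd.item_points["motor"] == 0
        assert any("strength rubric wins" in n for n in bd.notes)

    def test_single_item_monotonicity(self):
        """Moving any one numeric input into a higher-point band never lowers
        the total."""
        base = make_obs()
        probes = {
            "wbc": [7.0, 11.0, 30.0], "temp_axillary": [37.0, 39.0, 40.5],
            "albumin": [40.0, 30.0, 20.0], "heart_rate": [80.0, 120.0, 160.0],
            "sbp": [120.0, 150.0, 210.0], "glucose": [5.0, 15.0, 25.0],
            "sodium": [140.0, 155.0, 165.0], "potassium": [4.0, 3.0, 2.0],
            "creatinine": [100.0, 150.0, 200.0], "bilirubin": [10.0, 50.0, 120.0],
        }
        for fld, seq in probes.items():
            totals = [score_incns(make_obs(**{fld: v})).total for v in seq]
            assert totals == sorted(totals), fld


class TestComparators:
    @pytest.mark.parametrize("e,v,m,intub,total", [
        (4, 5, 6, False, 15), (1, 1, 1, False, 3), (3, 4, 6, True, 10),
    ])
    def test_gcs(self, e, v, m, intub, total):
        bd = score_gcs(e, v, m, intub)
        assert bd.total == total
        if intub and v != 1:
            assert bd.item_points["verbal"] == 1
            assert any("coerced" in n for n in bd.notes)

    def test_gcs_out_of_range(self):
        with pytest.raises(ValueError):
            score_gcs(0, 5, 6)

    @pytest.mark.parametrize("args,total", [
        ((4, 4, 4, 4), 16), ((0, 0, 0, 0), 0), ((2, 3, 1, 0), 6),
    ])
    def test_four(self, args, total):
        assert score_four(*args).total == total

    def test_apache_all_normal_is_zero(self):
        obs = make_obs(age_years=40)
        assert score_apache2(obs).total == 0

    def test_apache_worst_case_is_71(self):
        bd = score_apache2(make_worst_apache_obs())
        assert bd.total == 71 == max_score(Scale.APACHE2)
        assert any("doubled" in n for n in bd.notes)

    def test_apache_arf_doubling_plus_age(self):
        # creatinine in a 3-point band, doubled under ARF; age 45-54 adds 2
        obs = make_obs(age_years=50, creatinine=200.0, acute_renal_failure=True)
        bd = score_apache2(obs)
        assert bd.item_points["creatinine"] == 6
        assert bd.item_points["age"] == 2
        assert bd.total == 8

    def test_apache_oxygenation_switches_on_fio2(self):
        high = score_apache2(make_obs(fio2=0.6, aado2=400.0, pao2=None))
        assert high.item_points["oxygenation"] == 3
        low = score_apache2(make_obs(fio2=0.21, pao2=58.0))
        assert low.item_points["oxygenation"] == 3
        with pytest.raises(MissingItemError):
            score_apache2(make_obs(fio2=0.6, aado2=None, pao2=90.0))

    def test_apache_explicit_gcs_total(self):
        bd = score_apache2(make_obs(), gcs_total=3)
        assert bd.item_points["gcs"] == 12


class TestMaxScores:
    def test_maxima_from_tables(self):
        assert max_score(Scale.INCNS) == 44
        assert max_score(Scale.APACHE2) == 71
        assert max_score(Scale.GCS) == 15
        assert max_score(Scale.FOUR) == 16
        with pytest.raises(ValueError):
            max_score("saps2")


@st.composite
def random_observation(draw):
    from incns import (Arousal, Awareness, BrainstemReflex, ChronicHealth,
                       PainResponse, Swallow, VentilatorBreathing, VerbalResponse)

    fin = dict(allow_nan=False, allow_infinity=False)
    kwargs = dict(
        age_years=draw(st.integers(16, 99)),
        wbc=draw(st.floats(0.1, 60, **fin)),
        temp_axillary=draw(st.floats(28, 43, **fin)),
        albumin=draw(st.floats(5, 60, **fin)),
        heart_rate=draw(st.floats(10, 250, **fin)),
        sbp=draw(st.floats(30, 280, **fin)),
        glucose=draw(st.floats(0.5, 45, **fin)),
        sodium=draw(st.floats(100, 200, **fin)),
        potassium=draw(st.floats(1, 10, **fin)),
        creatinine=draw(st.floats(5, 900, **fin)),
        bilirubin=draw(st.floats(1, 500, **fin)),
        map=draw(st.floats(20, 220, **fin)),
        arterial_ph=draw(st.floats(6.6, 7.9, **fin)),
        hematocrit=draw(st.floats(10, 70, **fin)),
        resp_rate=draw(st.floats(0, 70, **fin)),
        arousal=draw(st.sampled_from(Arousal)),
        awareness=draw(st.sampled_from(Awareness)),
        pupillary_reflex=draw(st.sampled_from(BrainstemReflex)),
        corneal_reflex=draw(st.sampled_from(BrainstemReflex)),
        verbal=draw(st.sampled_from(VerbalResponse)),
        swallow=draw(st.sampled_from(Swallow)),
        chronic_health=draw(st.sampled_from(ChronicHealth)),
        acute_renal_failure=draw(st.booleans()),
        gcs_eye=draw(st.integers(1, 4)),
        gcs_verbal=draw(st.integers(1, 5)),
        gcs_motor=draw(st.integers(1, 6)),
        four_eye=draw(st.integers(0, 4)),
        four_motor=draw(st.integers(0, 4)),
        four_brainstem=draw(st.integers(0, 4)),
        four_respiration=draw(st.integers(0, 4)),
    )
    if draw(st.booleans()):
        kwargs.update(strength_left=draw(st.integers(0, 5)),
                      strength_right=draw(st.integers(0, 5)), pain_response=None)
    else:
        kwargs.update(strength_left=None, strength_right=None,
                      pain_response=draw(st.sampled_from(PainResponse)))
    if draw(st.booleans()):
        kwargs.update(intubated=True, ventilator_breathing=draw(st.sampled_from([
            VentilatorBreathing.ABOVE_VENTILATOR_RATE,
            VentilatorBreathing.AT_VENTILATOR_RATE_OR_APNEA])))
    fio2 = draw(st.floats(0.21, 1.0, **fin))
    kwargs.update(fio2=fio2,
                  aado2=draw(st.floats(0, 700, **fin)) if fio2 >= 0.5 else None,
                  pao2=draw(st.floats(20, 600, **fin)) if fio2 < 0.5 else None)
    return make_obs(**kwargs)


class TestScoreProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(random_observation())
    def test_totals_sum_and_stay_in_range(self, obs):
        """Sum and range invariants for all four scorers on random valid data."""
        incns = score_incns(obs)
        assert incns.total == sum(incns.item_points.values())
        assert 0 <= incns.total <= 44
        assert len(incns.item_points) == 19

        gcs = score_gcs(obs.exam.gcs_eye, obs.exam.gcs_verbal, obs.exam.gcs_motor,
                        obs.physio.intubated)
        assert gcs.total == sum(gcs.item_points.values())
        assert 3 <= gcs.total <= 15

        four = score_four(obs.exam.four_eye, obs.exam.four_motor,
                          obs.exam.four_brainstem, obs.exam.four_respiration)
        assert four.total == sum(four.item_points.values())
        assert 0 <= four.total <= 16

        apache = score_apache2(obs)
        assert apache.total == sum(apache.item_points.values())
        assert 0 <= apache.total <= 71

    def test_apache_band_tables_cover_every_grid_point(self):
        for item_id, item in APACHE_NUMERIC_ITEMS.items():
            res = float(item.resolution)
            hi_probe = 1.4 * max(float(b.lo) for b in item.bands if b.lo)
            grid = np.arange(0.0, hi_probe, res)
            for v in grid:
                q = item.quantize(float(v))
                assert any(b.contains(q) for b in item.bands), (item_id, v)
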