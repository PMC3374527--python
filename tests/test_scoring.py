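import math

import pytest
from hypothesis import given, settings, strategies as st

from activeq.questionnaire import QuestionnaireResponse, ResponseItem
from activeq.scoring import (
    EnergyProfile,
    activity_ee,
    adjust_to_24h,
    met_hours,
    score_response,
)

REL = 1e-9


def _resp(items, occupation_hours=0.0, rank=1):
    return QuestionnaireResponse(
        participant_id="P1",
        administration="I",
        occupation_effort_rank=rank,
        occupation_hours=occupation_hours,
        items=tuple(items),
    )


class TestActivityEE:
    def test_unit_case(self):
        assert activity_ee(1.0, 1.0, 1.0) == 4.184

    def test_zero_duration(self):
        assert activity_ee(8.0, 70.0, 0.0) == 0.0

    def test_hand_evaluation(self):
        # direct evaluation oracle: MET x weight x hours x 4.184
        assert activity_ee(8.0, 70.0, 0.5) == pytest.approx(
            8.0 * 70.0 * 0.5 * 4.184, rel=1e-12
        )
        assert activity_ee(8.0, 70.0, 0.5) == pytest.approx(1171.52, rel=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="daily_hours"):
            activity_ee(3.0, 60.0, -1.0)

    def test_non_positive_met_rejected(self):
        with pytest.raises(ValueError, match="met"):
            activity_ee(0.0, 60.0, 1.0)

    @given(
        met=st.floats(0.5, 12.0),
        hours=st.floats(0.0, 16.0),
        w1=st.floats(40.0, 120.0),
        scale=st.floats(0.5, 2.0),
    )
    def test_linear_in_weight(self, met, hours, w1, scale):
        assert activity_ee(met, w1 * scale, hours) == pytest.approx(
            scale * activity_ee(met, w1, hours), rel=REL
        )


class TestScoreResponse:
    def test_empty_response(self, catalog, category_map, profile):
        ep = score_response(_resp([]), profile, catalog, category_map)
        assert ep.crude_total_kj == 0.0
        assert ep.crude_hours == 0.0

    def test_single_leisure_item(self, catalog, category_map, profile):
        # 1 h/d of household chores (MET 3.0) at 60 kg
        items = [ResponseItem("household_chores", "7 times/week", "1 h")]
        ep = score_response(_resp(items), profile, catalog, category_map)
        assert ep.crude_total_kj == pytest.approx(
            activity_ee(3.0, 60.0, 1.0), rel=REL
        )
        assert ep.per_domain_kj["leisure"] == ep.crude_total_kj

    def test_occupation_uses_rank_met(self, catalog, category_map, profile):
        ep = score_response(
            _resp([], occupation_hours=8.0, rank=3), profile, catalog, category_map
        )
        assert ep.crude_total_kj == pytest.approx(
            activity_ee(3.0, 60.0, 8.0), rel=REL
        )
        assert ep.per_domain_kj["occupation"] == ep.crude_total_kj

    def test_multi_domain_sums(self, catalog, category_map, profile):
        items = [
            ResponseItem("walking_transportation", "7 times/week", "0.5 h"),
            ResponseItem("watching_tv", "7 times/week", "2 h"),
            ResponseItem("jogging_running", "3-4 times/week", "1 h"),
        ]
        ep = score_response(
            _resp(items, occupation_hours=8.0, rank=2),
            profile, catalog, category_map,
        )
        assert sum(ep.per_domain_kj.values()) == pytest.approx(
            ep.crude_total_kj, rel=REL
        )
        assert sum(ep.per_activity_kj.values()) == pytest.approx(
            ep.crude_total_kj, rel=REL
        )
        # summation oracle, term by term
        expected = (
            activity_ee(2.3, 60.0, 8.0)
            + activity_ee(4.0, 60.0, 0.5)
            + activity_ee(1.0, 60.0, 2.0)
            + activity_ee(8.0, 60.0, 3.5 * 1.0 / 7.0)
        )
        assert ep.crude_total_kj == pytest.approx(expected, rel=REL)

    def test_overfull_day_rejected(self, catalog, category_map, profile):
        with pytest.raises(ValueError, match="24"):
            score_response(
                _resp([], occupation_hours=25.0), profile, catalog, category_map
            )

    def test_unknown_activity_lookup_error(self, catalog, category_map, profile):
        from activeq.activity_catalog import CatalogError

        items = [ResponseItem("zorbing", "7 times/week", "1 h")]
        with pytest.raises(CatalogError, match="zorbing"):
            score_response(_resp(items), profile, catalog, category_map)


def _profile_with(crude_total, crude_hours):
    return EnergyProfile(
        participant_id="P1",
        administration="I",
        per_activity_kj={},
        per_domain_kj={},
        crude_total_kj=crude_total,
        crude_hours=crude_hours,
    )


class TestAdjustTo24h:
    def test_exact_24h_day(self):
        ep = adjust_to_24h(_profile_with(5000.0, 16.0), weight_kg=60.0)
        assert ep.filler_hours == 0.0
        assert ep.adjusted_total_kj == pytest.approx(
            5000.0 + activity_ee(0.9, 60.0, 8.0), rel=REL
        )

    def test_cohort_mean_day(self):
        # 11 h 24 min reported -> 4.6 h of filler at MET 2.0
        ep = adjust_to_24h(_profile_with(7008.0, 11.4), weight_kg=60.0)
        assert ep.filler_hours == pytest.approx(4.6, rel=REL)
        expected = 7008.0 + 0.9 * 8 * 60.0 * 4.184 + 2.0 * 4.6 * 60.0 * 4.184
        assert ep.adjusted_total_kj == pytest.approx(expected, rel=REL)

    def test_negative_filler_subtracts(self):
        ep = adjust_to_24h(_profile_with(9000.0, 18.0), weight_kg=70.0)
        assert ep.filler_hours == pytest.approx(-2.0, rel=REL)
        expected = 9000.0 + 0.9 * 8 * 70.0 * 4.184 - 2.0 * 70.0 * 2.0 * 4.184
        assert ep.adjusted_total_kj == pytest.approx(expected, rel=REL)

    @given(
        crude=st.floats(0.0, 30000.0),
        hours=st.floats(0.0, 24.0),
        weight=st.floats(40.0, 120.0),
    )
    def test_time_budget_conserved(self, crude, hours, weight):
        ep = adjust_to_24h(_profile_with(crude, hours), weight_kg=weight)
        assert ep.crude_hours + ep.sleep_hours + ep.filler_hours == pytest.approx(
            24.0, abs=1e-12
        )


ITEM_POOL = [
    ("walking_transportation", 4.0),
    ("car_taxi", 1.0),
    ("watching_tv", 1.0),
    ("household_chores", 3.0),
    ("walking_leisure", 3.4),
    ("jogging_running", 8.0),
    ("spinning", 8.5),
    ("other_sport", 2.5),
]


@st.composite
def random_responses(draw):
    n_items = draw(st.integers(0, len(ITEM_POOL)))
    picks = draw(
        st.lists(
            st.sampled_from(range(len(ITEM_POOL))),
            min_size=n_items, max_size=n_items, unique=True,
        )
    )
    items = []
    durations = ["0.25 h", "0.5 h", "1 h", "1.5 h", "2 h"]
    for i in picks:
        items.append(
            ResponseItem(
                ITEM_POOL[i][0],
                "7 times/week",
                draw(st.sampled_from(durations)),
            )
        )
    occupation_hours = draw(st.floats(0.0, 10.0))
    rank = draw(st.integers(1, 5))
    return _resp(items, occupation_hours=occupation_hours, rank=rank)


class TestScoringProperties:
    @given(resp=random_responses())
    @settings(max_examples=60)
    def test_conservation(self, resp, catalog, category_map, profile):
        ep = score_response(resp, profile, catalog, category_map)
        assert ep.crude_total_kj == pytest.approx(
            sum(ep.per_activity_kj.values()), rel=REL, abs=1e-12
        )
        assert ep.crude_total_kj == pytest.approx(
            sum(ep.per_domain_kj.values()), rel=REL, abs=1e-12
        )

    @given(resp=random_responses(), extra=st.sampled_from(["0.5 h", "1 h", "2 h"]))
    @settings(max_examples=60)
    def test_met2_neutrality(self, resp, extra, catalog, category_map, profile):
        """Adding MET-2.0 time never moves the adjusted total: the filler
        absorbs it exactly."""
        base = adjust_to_24h(
            score_response(resp, profile, catalog, category_map), profile.weight_kg
        )
        with_met2 = QuestionnaireResponse(
            participant_id=resp.participant_id,
            administration=resp.administration,
            occupation_effort_rank=resp.occupation_effort_rank,
            occupation_hours=resp.occupation_hours,
            items=resp.items
            + (
                ResponseItem(
                    "musical_instrument_active_games", "7 times/week", extra
                ),
            ),
        )
        if "musical_instrument_active_games" in {i.activity_id for i in resp.items}:
            return
        aug = adjust_to_24h(
            score_response(with_met2, profile, catalog, category_map),
            profile.weight_kg,
        )
        assert aug.adjusted_total_kj == pytest.approx(
            base.adjusted_total_kj, rel=REL
        )

    @pytest.mark.parametrize(
        "activity_id,met", [("jogging_running", 8.0), ("watching_tv", 1.0)]
    )
    def test_monotone_in_duration(self, catalog, category_map, profile, activity_id, met):
        def adjusted(duration):
            resp = _resp(
                [ResponseItem(activity_id, "7 times/week", duration)],
                occupation_hours=2.0,
            )
            ep = score_response(resp, profile, catalog, category_map)
            return adjust_to_24h(ep, profile.weight_kg).adjusted_total_kj

        lo, hi = adjusted("1 h"), adjusted("2 h")
        if met > 2.0:
            assert hi > lo
        else:
            assert hi < lo

    @given(scale=st.floats(0.5, 2.5))
    @settings(max_examples=25)
    def test_ee_scales_with_weight(self, scale, catalog, category_map, profile):
        import dataclasses

        resp = _resp(
            [ResponseItem("jogging_running", "7 times/week", "1 h")],
            occupation_hours=6.0, rank=3,
        )
        heavy = dataclasses.replace(profile, weight_kg=profile.weight_kg * scale)
        ep1 = score_response(resp, profile, catalog, category_map)
        ep2 = score_response(resp, heavy, catalog, category_map)
        assert ep2.crude_total_kj == pytest.approx(scale * ep1.crude_total_kj, rel=REL)
        a1 = adjust_to_24h(ep1, profile.weight_kg).adjusted_total_kj
        a2 = adjust_to_24h(ep2, heavy.weight_kg).adjusted_total_kj
        assert a2 == pytest.approx(scale * a1, rel=REL)


class TestMetHours:
    def test_inverse_of_ee(self, catalog, category_map, profile):
        resp = _resp([ResponseItem("jogging_running", "7 times/week", "1 h")])
        ep = score_response(resp, profile, catalog, category_map)
        assert met_hours(ep, profile.weight_kg) == pytest.approx(8.0, rel=REL)
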