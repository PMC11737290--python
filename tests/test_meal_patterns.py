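"""Hourly aggregation, EDO classification, bolus scoring and redistribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mealtrace.config import Thresholds
from mealtrace.meal_patterns import (
    FLAG_LARGE,
    FLAG_NONE,
    FLAG_SMALL,
    bolus_cross_association,
    bolus_table,
    classify_edos,
    day_profiles,
    edo_summary,
    hour_slot,
    hourly_aggregate,
    meal_protein_summary,
    redistribute_surplus,
)

from conftest import make_entries


class TestHourlyWindow:
    def test_half_hour_slots_roll_into_following_hour(self):
        # 6:30, 6:45, 7:00, 7:15 all count as intake at 7 o'clock
        entries = make_entries(
            [{"time_min": t, "energy_kj": 100.0, "protein_g": 1.0}
             for t in (390, 405, 420, 435)]
        )
        profile = hourly_aggregate(entries)
        assert profile.hourly_energy[7] == pytest.approx(400.0)
        assert profile.hourly_energy.sum() == pytest.approx(400.0)

    def test_item_at_half_past_belongs_to_next_hour(self):
        profile = hourly_aggregate(make_entries([{"time_min": 450}]))  # 7:30
        assert profile.hourly_energy[8] > 0 and profile.hourly_energy[7] == 0

    def test_late_evening_wraps_to_slot_zero_same_day(self):
        profile = hourly_aggregate(make_entries([{"time_min": 1410}]))  # 23:30
        assert profile.hourly_energy[0] > 0

    def test_empty_day_is_all_zero(self):
        profile = hourly_aggregate(make_entries([]))
        assert profile.hourly_energy.sum() == 0
        assert profile.hourly_protein.sum() == 0

    def test_off_grid_time_raises(self):
        with pytest.raises(ValueError, match="grid"):
            hour_slot(440)

    @given(st.integers(min_value=0, max_value=95))
    def test_slot_matches_literal_window_definition(self, slot15):
        t = slot15 * 15
        h = hour_slot(t)
        window = {((h - 1) * 60 + 30) % 1440, ((h - 1) * 60 + 45) % 1440,
                  (h * 60) % 1440, (h * 60 + 15) % 1440}
        assert t in window

    def test_conservation_sum_hourly_equals_daily(self, small_cohort):
        entries = small_cohort.entries
        profiles = day_profiles(entries)
        daily = entries.groupby(["participant_id", "day"])[["energy_kj", "protein_g"]].sum()
        for p in profiles[:50]:
            row = daily.loc[(p.participant_id, p.day)]
            assert p.daily_energy == pytest.approx(row["energy_kj"], abs=1e-9)
            assert p.daily_protein == pytest.approx(row["protein_g"], abs=1e-9)


class TestEDOClassification:
    def _profile(self, hours_kj: dict[int, float]):
        energy = np.zeros(24)
        for h, kj in hours_kj.items():
            energy[h] = kj
        from mealtrace.meal_patterns import DayProfile

        return DayProfile("P1", 1, energy, np.zeros(24))

    def test_strict_energy_threshold(self):
        p = classify_edos(self._profile({8: 210.0, 12: 211.0, 18: 1579.0}))
        assert p.edo_flags[8] == FLAG_NONE  # exactly 210 kJ is not an EDO
        assert p.edo_flags[12] == FLAG_SMALL  # 211/2000 = 10.55%
        assert p.edo_flags[18] == FLAG_LARGE

    def test_large_boundary_inclusive_at_15_pct(self):
        p = classify_edos(self._profile({12: 300.0, 18: 1700.0}))
        assert p.edo_flags[12] == FLAG_LARGE  # exactly 15% of 2000 kJ

    def test_zero_energy_day_has_no_edos(self):
        p = classify_edos(self._profile({}))
        assert all(f == FLAG_NONE for f in p.edo_flags)

    def test_edo_summary_mean_over_days(self):
        # days with 4, 5, 5, 5 total EDOs -> 4.75/day
        profiles = []
        for day, n_edo in enumerate((4, 5, 5, 5), start=1):
            hours = {6 + i: 500.0 for i in range(n_edo)}
            p = self._profile(hours)
            p.day = day
            profiles.append(classify_edos(p))
        out = edo_summary(profiles)
        assert out.loc[0, "total_edo"] == pytest.approx(4.75)
        assert out.loc[0, "total_edo"] == pytest.approx(
            out.loc[0, "large_edo"] + out.loc[0, "small_edo"]
        )


class TestMealProteinSummary:
    def test_across_day_means(self):
        rows = []
        for day, grams in enumerate((10.0, 20.0, 15.0, 15.0), start=1):
            rows.append({"day": day, "meal": "breakfast", "protein_g": grams})
            rows.append({"day": day, "meal": "dinner", "protein_g": 30.0})
        summaries = meal_protein_summary(make_entries(rows))
        assert summaries.loc[0, "protein_breakfast"] == pytest.approx(15.0)
        assert summaries.loc[0, "protein_lunch"] == 0.0  # never reported
        assert bool(summaries.loc[0, "bolus_dinner"])  # mean exactly 30 g meets

    def test_cv_hand_example_with_sample_sd(self):
        # meal means (10, 20, 30): sample SD 10, mean 20 -> CV 0.5
        rows = [
            {"meal": "breakfast", "protein_g": 10.0},
            {"meal": "lunch", "protein_g": 20.0},
            {"meal": "dinner", "protein_g": 30.0},
        ]
        summaries = meal_protein_summary(make_entries(rows))
        assert summaries.loc[0, "cv"] == pytest.approx(0.5)

    def test_cv_zero_iff_equal_means(self):
        rows = [{"meal": m, "protein_g": 20.0} for m in ("breakfast", "lunch", "dinner")]
        assert meal_protein_summary(make_entries(rows)).loc[0, "cv"] == 0.0

    def test_meal_partition_of_daily_protein(self, small_cohort):
        entries = small_cohort.entries
        summaries = meal_protein_summary(entries)
        n_days = entries.groupby("participant_id")["day"].nunique()
        daily = entries.groupby("participant_id")["protein_g"].sum() / n_days
        total = summaries.set_index("participant_id")[
            ["protein_breakfast", "protein_lunch", "protein_dinner", "protein_other"]
        ].sum(axis=1)
        assert np.allclose(total, daily.loc[total.index], atol=1e-9)


class TestBolusTable:
    def test_full_attainment_and_surplus(self):
        summaries = pd.DataFrame(
            {
                "participant_id": ["A", "B"],
                "protein_breakfast": [10.0, 12.0],
                "protein_lunch": [20.0, 25.0],
                "protein_dinner": [45.0, 45.0],
                "protein_other": [5.0, 5.0],
            }
        )
        table = bolus_table(summaries).set_index("meal")
        assert table.loc["dinner", "pct_attain"] == 100.0
        assert table.loc["dinner", "mean_surplus_g"] == pytest.approx(15.0)

    def test_no_attainers_gives_absent_cells(self):
        summaries = pd.DataFrame(
            {
                "participant_id": ["A"],
                "protein_breakfast": [5.0],
                "protein_lunch": [10.0],
                "protein_dinner": [15.0],
                "protein_other": [2.0],
            }
        )
        table = bolus_table(summaries).set_index("meal")
        assert table.loc["dinner", "pct_attain"] == 0.0
        assert np.isnan(table.loc["dinner", "mean_surplus_g"])
        assert np.isnan(table.loc["dinner", "surplus_nearest_g"])

    def test_pct_below_and_attain_sum_to_100(self, small_cohort):
        from mealtrace.records import apply_exclusions, filter_entries

        retained, _ = apply_exclusions(small_cohort.participants, small_cohort.entries)
        entries = filter_entries(small_cohort.entries, retained)
        table = bolus_table(meal_protein_summary(entries), retained)
        assert np.allclose(table["pct_below"] + table["pct_attain"], 100.0)


class TestRedistribution:
    def _summaries(self, lunch, dinner):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(lunch))],
                "protein_lunch": lunch,
                "protein_dinner": dinner,
            }
        )

    def test_rule_application(self):
        res = redistribute_surplus(self._summaries([17.0], [44.0]))
        row = res.per_participant.iloc[0]
        assert row["protein_lunch_after"] == pytest.approx(31.0)
        assert row["protein_dinner_after"] == pytest.approx(30.0)
        assert res.lunch_attain_before == 0.0 and res.lunch_attain_after == 1.0

    def test_no_transfer_below_bolus(self):
        res = redistribute_surplus(self._summaries([17.0], [25.0]))
        row = res.per_participant.iloc[0]
        assert row["protein_lunch_after"] == 17.0
        assert row["protein_dinner_after"] == 25.0

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=120),
                st.floats(min_value=0, max_value=120),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_conservation_monotonicity_idempotence(self, pairs):
        lunch = [a for a, _ in pairs]
        dinner = [b for _, b in pairs]
        res = redistribute_surplus(self._summaries(lunch, dinner))
        per = res.per_participant
        np.testing.assert_allclose(
            per["protein_lunch_after"] + per["protein_dinner_after"],
            per["protein_lunch"] + per["protein_dinner"],
            atol=1e-9,
        )
        assert res.lunch_attain_after >= res.lunch_attain_before
        twice = redistribute_surplus(
            per[["participant_id", "protein_lunch_after", "protein_dinner_after"]]
            .rename(
                columns={
                    "protein_lunch_after": "protein_lunch",
                    "protein_dinner_after": "protein_dinner",
                }
            )
        )
        np.testing.assert_allclose(
            twice.per_participant["protein_lunch_after"],
            per["protein_lunch_after"],
            atol=1e-12,
        )


class TestBolusCrossAssociation:
    def test_chi2_matches_hand_formula(self):
        # table [[30, 20], [10, 40]] via the raw sum((O-E)^2 / E)
        flags = pd.DataFrame(
            {
                "bolus_lunch": [False] * 50 + [True] * 50,
                "bolus_dinner": [False] * 30 + [True] * 20 + [False] * 10 + [True] * 40,
            }
        )
        res = bolus_cross_association(flags)
        observed = res["table"]
        total = observed.sum()
        expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
        by_hand = ((observed - expected) ** 2 / expected).sum()
        assert res["chi2"] == pytest.approx(by_hand, rel=1e-12)

    def test_identical_rows_give_zero(self):
        flags = pd.DataFrame(
            {
                "bolus_lunch": [False] * 20 + [True] * 20,
                "bolus_dinner": ([False] * 10 + [True] * 10) * 2,
            }
        )
        assert bolus_cross_association(flags)["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_flagged_not_raised(self):
        flags = pd.DataFrame(
            {"bolus_lunch": [True, True, True], "bolus_dinner": [True, False, True]}
        )
        res = bolus_cross_association(flags)
        assert not res["valid"] and np.isnan(res["chi2"])

    def test_planted_dependence_detected(self, rng):
        n = 2000
        lunch = rng.random(n) < 0.4
        dinner = np.where(lunch, rng.random(n) < 0.25, rng.random(n) < 0.55)
        res = bolus_cross_association(
            pd.DataFrame({"bolus_lunch": lunch, "bolus_dinner": dinner})
        )
        assert res["p_value"] < 1e-6
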