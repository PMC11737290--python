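"""Hourly intake profiles, eating/drinking occasions and protein-bolus scoring.

The diary timestamps sit on a 15-minute grid. Hourly intake assigns the four
grid slots :30, :45, :00, :15 to the *following* clock hour — food reported at
6:30, 6:45, 7:00 and 7:15 all counts as intake "at 7 o'clock". Entries at
23:30/23:45 wrap to hour 0 of the same recorded day, keeping each day
self-contained (recorded days are independent units).

An hour is an eating/drinking occasion (EDO) when its energy is strictly above
210 kJ (~50 kcal); an EDO holding at least 15% of the day's energy is "large",
otherwise "small". Hours are never merged: each clock hour is its own unit.

Protein is also summed by the participant's self-indicated meals (breakfast,
lunch, dinner, everything else pooled as "other"); a participant "attains the
bolus" at a meal when their across-day mean protein at that meal is at least
30 g. The within-day skew of protein is summarised by the coefficient of
variation over the three main-meal means (sample SD / mean).

The redistribution experiment transfers each participant's dinner protein
above 30 g onto lunch and re-evaluates lunch bolus attainment — a
counterfactual that conserves total protein exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .records import MAIN_MEALS, MEALS, TIME_GRID_MIN

FLAG_NONE = "none"
FLAG_SMALL = "small"
FLAG_LARGE = "large"


@dataclass
class DayProfile:
    """One participant-day as 24 hourly energy/protein slots with EDO flags."""

    participant_id: str
    day: int
    hourly_energy: np.ndarray  # kJ, shape (24,)
    hourly_protein: np.ndarray  # g, shape (24,)
    edo_flags: np.ndarray | None = None  # dtype object: none/small/large

    @property
    def daily_energy(self) -> float:
        return float(self.hourly_energy.sum())

    @property
    def daily_protein(self) -> float:
        return float(self.hourly_protein.sum())


def hour_slot(time_min: int) -> int:
    """Clock-hour slot for a grid time: :30/:45 roll forward, 23:30+ wraps to 0."""
    if time_min % TIME_GRID_MIN != 0 or not 0 <= time_min < 1440:
        raise ValueError(f"time {time_min} min is off the 15-min grid")
    return ((time_min + 30) // 60) % 24


def hourly_aggregate(entries: pd.DataFrame) -> DayProfile:
    """Aggregate one participant-day of entries into a :class:`DayProfile`."""
    pids = entries["participant_id"].unique()
    days = entries["day"].unique()
    if len(pids) > 1 or len(days) > 1:
        raise ValueError("hourly_aggregate expects a single participant-day")
    energy = np.zeros(24)
    protein = np.zeros(24)
    for row in entries.itertuples(index=False):
        slot = hour_slot(int(row.time_min))
        energy[slot] += row.energy_kj
        protein[slot] += row.protein_g
    pid = pids[0] if len(pids) else ""
    day = int(days[0]) if len(days) else 0
    return DayProfile(pid, day, energy, protein)


def classify_edos(profile: DayProfile, thresholds: Thresholds = Thresholds()) -> DayProfile:
    """Attach EDO flags to a day profile (strict >210 kJ; large iff >=15% of day)."""
    flags = np.full(24, FLAG_NONE, dtype=object)
    total = profile.daily_energy
    if total > 0:
        is_edo = profile.hourly_energy > thresholds.edo_kj
        large = profile.hourly_energy >= thresholds.large_edo_fraction * total
        flags[is_edo & large] = FLAG_LARGE
        flags[is_edo & ~large] = FLAG_SMALL
    profile.edo_flags = flags
    return profile


def day_profiles(
    entries: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> list[DayProfile]:
    """Classified day profiles for every recorded participant-day."""
    return [
        classify_edos(hourly_aggregate(group), thresholds)
        for _, group in entries.groupby(["participant_id", "day"], sort=True)
    ]


def profiles_to_frame(profiles: list[DayProfile]) -> pd.DataFrame:
    """Long-format export: participant, day, hour, energy, protein, flag."""
    recs = []
    for p in profiles:
        flags = p.edo_flags if p.edo_flags is not None else np.full(24, FLAG_NONE)
        for h in range(24):
            recs.append(
                (p.participant_id, p.day, h, p.hourly_energy[h], p.hourly_protein[h], flags[h])
            )
    return pd.DataFrame(
        recs, columns=["participant_id", "day", "hour", "energy_kj", "protein_g", "edo_flag"]
    )


def edo_summary(profiles: list[DayProfile]) -> pd.DataFrame:
    """Mean EDO counts per day, per participant (total = large + small)."""
    recs = []
    for p in profiles:
        if p.edo_flags is None:
            raise ValueError("profiles must be classified before summarising")
        recs.append(
            {
                "participant_id": p.participant_id,
                "day": p.day,
                "large": int(np.sum(p.edo_flags == FLAG_LARGE)),
                "small": int(np.sum(p.edo_flags == FLAG_SMALL)),
            }
        )
    per_day = pd.DataFrame(recs)
    out = per_day.groupby("participant_id")[["large", "small"]].mean()
    out.columns = ["large_edo", "small_edo"]
    out["total_edo"] = out["large_edo"] + out["small_edo"]
    return out.reset_index()


def meal_protein_summary(
    entries: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-participant mean protein by self-indicated meal, bolus flags and CV.

    Day-level protein is summed per meal, then averaged over the participant's
    recorded days (a meal never reported on a recorded day contributes 0 g for
    that day). The bolus flag tests the across-day mean against 30 g; the CV is
    the sample SD (ddof=1) over the breakfast/lunch/dinner means divided by
    their mean (NaN when that mean is zero).
    """
    day_meal = (
        entries.groupby(["participant_id", "day", "meal"])["protein_g"].sum().reset_index()
    )
    n_days = entries.groupby("participant_id")["day"].nunique()
    rows = []
    for pid, grp in day_meal.groupby("participant_id"):
        nd = n_days[pid]
        means = {m: grp.loc[grp["meal"] == m, "protein_g"].sum() / nd for m in MEALS}
        main = np.array([means[m] for m in MAIN_MEALS])
        mean_main = main.mean()
        cv = np.nan if mean_main == 0 else main.std(ddof=1) / mean_main
        row = {"participant_id": pid, "n_days": int(nd), "cv": cv}
        for m in MEALS:
            row[f"protein_{m}"] = means[m]
            row[f"bolus_{m}"] = means[m] >= thresholds.bolus_g
        rows.append(row)
    return pd.DataFrame(rows)


def bolus_table(
    summaries: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Attainment of the 30 g per-meal protein bolus, optionally by sex.

    For each meal (and sex stratum when ``participants`` is given): the overall
    mean (SD) protein, percentage and count below/at-or-above the bolus, the
    subgroup means (SD), and among attainers the mean *surplus* over the bolus
    (subgroup mean - 30 g) plus its nearest-gram rounding. Empty strata yield
    NaN cells, never zeros.
    """
    df = summaries
    if participants is not None:
        df = df.merge(participants[["participant_id", "sex"]], on="participant_id")
        strata = [(sex, g) for sex, g in df.groupby("sex")]
    else:
        strata = [("all", df)]
    rows = []
    for sex, g in strata:
        for meal in MEALS:
            x = g[f"protein_{meal}"].to_numpy(dtype=float)
            attain = x >= thresholds.bolus_g
            below, above = x[~attain], x[attain]
            surplus = above.mean() - thresholds.bolus_g if above.size else np.nan
            rows.append(
                {
                    "sex": sex,
                    "meal": meal,
                    "n": x.size,
                    "mean_g": x.mean() if x.size else np.nan,
                    "sd_g": x.std(ddof=1) if x.size > 1 else np.nan,
                    "n_below": int(below.size),
                    "pct_below": 100.0 * below.size / x.size if x.size else np.nan,
                    "mean_below_g": below.mean() if below.size else np.nan,
                    "sd_below_g": below.std(ddof=1) if below.size > 1 else np.nan,
                    "n_attain": int(above.size),
                    "pct_attain": 100.0 * above.size / x.size if x.size else np.nan,
                    "mean_attain_g": above.mean() if above.size else np.nan,
                    "sd_attain_g": above.std(ddof=1) if above.size > 1 else np.nan,
                    "mean_surplus_g": surplus,
                    "surplus_nearest_g": float(np.rint(surplus)) if above.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RedistributionResult:
    """Outcome of the dinner-to-lunch surplus-transfer counterfactual."""

    per_participant: pd.DataFrame  # lunch/dinner before and after, g
    lunch_attain_before: float  # proportion in [0, 1]
    lunch_attain_after: float
    total_protein_delta: float  # conservation check, g


def redistribute_surplus(
    summaries: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> RedistributionResult:
    """Move each participant's dinner protein above 30 g onto lunch.

    dinner' = min(dinner, 30) when dinner exceeds the bolus, else unchanged;
    lunch' = lunch + transferred surplus. Total protein is conserved exactly
    and the operation is idempotent. Lunch attainment can only rise.
    """
    bolus = thresholds.bolus_g
    lunch = summaries["protein_lunch"].to_numpy(dtype=float)
    dinner = summaries["protein_dinner"].to_numpy(dtype=float)
    surplus = np.maximum(0.0, dinner - bolus)
    lunch_after = lunch + surplus
    dinner_after = dinner - surplus
    per = pd.DataFrame(
        {
            "participant_id": summaries["participant_id"],
            "protein_lunch": lunch,
            "protein_dinner": dinner,
            "protein_lunch_after": lunch_after,
            "protein_dinner_after": dinner_after,
        }
    )
    n = len(per)
    before = float(np.mean(lunch >= bolus)) if n else np.nan
    after = float(np.mean(lunch_after >= bolus)) if n else np.nan
    delta = float((lunch_after + dinner_after - lunch - dinner).sum())
    return RedistributionResult(per, before, after, delta)


def bolus_cross_association(
    summaries: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> dict:
    """Pearson chi-squared test of lunch-bolus x dinner-bolus attainment.

    Returns the 2x2 table, statistic and two-sided p-value (no continuity
    correction). A zero margin makes the test undefined; it is then flagged
    and statistic/p are NaN rather than raised.
    """
    lunch = summaries["bolus_lunch"].to_numpy(dtype=bool)
    dinner = summaries["bolus_dinner"].to_numpy(dtype=bool)
    table = np.array(
        [
            [np.sum(~lunch & ~dinner), np.sum(~lunch & dinner)],
            [np.sum(lunch & ~dinner), np.sum(lunch & dinner)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"table": table, "chi2": np.nan, "p_value": np.nan, "valid": False}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p_value": float(p), "valid": True}
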