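"""Diary data model, CSV I/O and the cohort exclusion filters.

Two tables carry the whole analysis:

``entries`` — one row per consumed item:
    participant_id, day (1..n_days), time_min (minutes from midnight, on the
    15-minute recording grid), meal (breakfast/lunch/dinner or free text,
    normalised to "other"), food_group (codebook code), weight_g, energy_kj,
    protein_g.

``participants`` — one row per participant:
    participant_id, sex ("male"/"female"), age_yr, height_m, weight_kg
    (height/weight may be missing), education (primary/secondary/university).

Exclusion filters drop participants with missing self-reported height or
weight, with no recorded intake, or with an implausible mean daily energy
intake (outside 800-4000 kcal/day for men, 500-3500 for women, strict
inequalities; kcal converted at 4.184 kJ/kcal). Each excluded participant gets
exactly one primary reason in the exclusion log.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK, FoodGroupCodebook
from .config import KCAL_TO_KJ, Thresholds

TIME_GRID_MIN = 15
MAIN_MEALS = ("breakfast", "lunch", "dinner")
MEALS = MAIN_MEALS + ("other",)
SEXES = ("male", "female")
EDUCATION_LEVELS = ("primary", "secondary", "university")

ENTRY_COLUMNS = [
    "participant_id",
    "day",
    "time_min",
    "meal",
    "food_group",
    "weight_g",
    "energy_kj",
    "protein_g",
]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "age_yr",
    "height_m",
    "weight_kg",
    "education",
]

# Exclusion reasons, in precedence order (one primary reason per participant).
REASON_MISSING_ANTHRO = "missing height or weight"
REASON_NO_INTAKE = "no intake data"
REASON_ENERGY_LOW = "mean daily energy below plausible band"
REASON_ENERGY_HIGH = "mean daily energy above plausible band"


class DiaryParseError(ValueError):
    """Raised when diary rows violate the schema; message lists row numbers."""


def normalize_meal_label(label: str) -> str:
    """Map a self-indicated meal label onto breakfast/lunch/dinner/other.

    Anything that is not one of the three main meals (after case folding and
    stripping) is pooled into "other".
    """
    norm = str(label).strip().lower()
    return norm if norm in MAIN_MEALS else "other"


def parse_time(value) -> int:
    """Parse 'HH:MM' or integer minutes-from-midnight. Returns minutes."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        return int(hh) * 60 + int(mm)
    return int(value)


def _row_errors(entries: pd.DataFrame, codebook: FoodGroupCodebook) -> list[str]:
    errors = []
    known = set(codebook.groups)
    for i, row in enumerate(entries.itertuples(index=False)):
        rownum = i + 2  # 1-based + header line
        if row.time_min % TIME_GRID_MIN != 0 or not 0 <= row.time_min < 1440:
            errors.append(f"row {rownum}: time {row.time_min} min off the 15-min grid")
        if row.food_group not in known:
            errors.append(f"row {rownum}: unknown food group {row.food_group!r}")
        for col in ("weight_g", "energy_kj", "protein_g"):
            v = getattr(row, col)
            if not np.isfinite(v) or v < 0:
                errors.append(f"row {rownum}: {col} must be finite and >= 0, got {v}")
        if not 1 <= row.day:
            errors.append(f"row {rownum}: day must be >= 1, got {row.day}")
    return errors


def validate_entries(
    entries: pd.DataFrame, codebook: FoodGroupCodebook = DEFAULT_CODEBOOK
) -> pd.DataFrame:
    """Type, normalise and validate an entries table.

    Returns a clean copy with ``meal`` normalised; raises
    :class:`DiaryParseError` listing every offending row.
    """
    missing = set(ENTRY_COLUMNS) - set(entries.columns)
    if missing:
        raise DiaryParseError(f"entries table missing columns: {sorted(missing)}")
    out = entries.loc[:, ENTRY_COLUMNS].copy()
    out["time_min"] = [parse_time(v) for v in out["time_min"]]
    out["day"] = out["day"].astype(int)
    for col in ("weight_g", "energy_kj", "protein_g"):
        out[col] = out[col].astype(float)
    errors = _row_errors(out, codebook)
    if errors:
        raise DiaryParseError("invalid diary rows:\n" + "\n".join(errors))
    out["meal"] = [normalize_meal_label(m) for m in out["meal"]]
    return out


def validate_participants(participants: pd.DataFrame) -> pd.DataFrame:
    missing = set(PARTICIPANT_COLUMNS) - set(participants.columns)
    if missing:
        raise DiaryParseError(f"participant table missing columns: {sorted(missing)}")
    out = participants.loc[:, PARTICIPANT_COLUMNS].copy()
    errors = []
    for i, row in enumerate(out.itertuples(index=False)):
        rownum = i + 2
        if row.sex not in SEXES:
            errors.append(f"row {rownum}: sex must be male/female, got {row.sex!r}")
        if row.age_yr < 0:
            errors.append(f"row {rownum}: negative age {row.age_yr}")
        if pd.notna(row.height_m) and not 0.5 < row.height_m < 2.5:
            errors.append(f"row {rownum}: height {row.height_m} m outside (0.5, 2.5)")
        if pd.notna(row.weight_kg) and row.weight_kg <= 0:
            errors.append(f"row {rownum}: nonpositive weight {row.weight_kg}")
        if pd.notna(row.education) and row.education not in EDUCATION_LEVELS:
            errors.append(f"row {rownum}: unknown education {row.education!r}")
    if out["participant_id"].duplicated().any():
        errors.append("duplicated participant ids")
    if errors:
        raise DiaryParseError("invalid participant rows:\n" + "\n".join(errors))
    return out


def read_diary(
    diary_path,
    participants_path,
    codebook: FoodGroupCodebook = DEFAULT_CODEBOOK,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the participant and diary CSVs.

    Returns ``(participants, entries)`` with meal labels normalised. Entries
    referencing unknown participants are a parse error.
    """
    participants = validate_participants(pd.read_csv(participants_path))
    entries = validate_entries(pd.read_csv(diary_path), codebook)
    orphan = set(entries["participant_id"]) - set(participants["participant_id"])
    if orphan:
        raise DiaryParseError(f"entries reference unknown participants: {sorted(orphan)}")
    return participants, entries


def write_diary(participants: pd.DataFrame, entries: pd.DataFrame,
                diary_path, participants_path) -> None:
    """Write both tables as UTF-8 CSV with '.' decimals."""
    entries.loc[:, ENTRY_COLUMNS].to_csv(diary_path, index=False)
    participants.loc[:, PARTICIPANT_COLUMNS].to_csv(participants_path, index=False)


def mean_daily_energy_kj(entries: pd.DataFrame) -> pd.Series:
    """Mean daily energy per participant over recorded days (kJ/day).

    A day counts as recorded when it holds at least one entry; a single
    feast/fast day therefore cannot dominate a 4-day record.
    """
    daily = entries.groupby(["participant_id", "day"])["energy_kj"].sum()
    return daily.groupby("participant_id").mean()


def apply_exclusions(
    participants: pd.DataFrame,
    entries: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion filters.

    Returns ``(retained_participants, exclusion_log)`` where the log has one
    row per excluded participant with columns ``participant_id``, ``reason``
    and ``mean_daily_kcal`` (NaN when intake was never computable). Precedence
    of reasons: missing anthropometry, then no intake data, then extreme
    energy. Idempotent: re-applying to the retained set excludes nobody.
    """
    energy = mean_daily_energy_kj(entries)
    reasons: dict[str, str] = {}
    kcal_log: dict[str, float] = {}
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        kcal = energy.get(pid, np.nan) / KCAL_TO_KJ
        kcal_log[pid] = kcal
        if pd.isna(row.height_m) or pd.isna(row.weight_kg):
            reasons[pid] = REASON_MISSING_ANTHRO
        elif pd.isna(kcal):
            reasons[pid] = REASON_NO_INTAKE
        else:
            lo, hi = thresholds.energy_band_kcal(row.sex)
            if kcal < lo:
                reasons[pid] = REASON_ENERGY_LOW
            elif kcal > hi:
                reasons[pid] = REASON_ENERGY_HIGH
    excluded = sorted(reasons)
    log = pd.DataFrame(
        {
            "participant_id": excluded,
            "reason": [reasons[p] for p in excluded],
            "mean_daily_kcal": [kcal_log[p] for p in excluded],
        }
    )
    retained = participants[~participants["participant_id"].isin(reasons)].reset_index(
        drop=True
    )
    return retained, log


def filter_entries(entries: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Keep only entries belonging to the given (retained) participants."""
    keep = entries["participant_id"].isin(set(participants["participant_id"]))
    return entries[keep].reset_index(drop=True)
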