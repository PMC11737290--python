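"""Adjusted body weight, basal metabolic rate and protein adequacy.

For participants with BMI above 25 kg/m², protein requirements are normalised
to an *adjusted* body weight rather than measured weight, so that adipose
excess does not inflate the denominator:

    adjusted = w25 + 0.25 * (weight - w25),   w25 = 25 * height²

i.e. the weight at BMI 25 plus a quarter of the excess above it. At or below
BMI 25 the measured weight is used unchanged, and the formula is continuous at
the boundary.

BMR (MJ/day) uses the Henry weight-and-height regression equations, sex- and
age-band specific, on the (adjusted) body weight. The coefficient table is
shipped as an editable CSV (``data/henry_coefficients.csv``, three adult bands
per sex from the Oxford database analysis, Henry 2005, Public Health Nutrition
8:1133-1152) and is an implementation input: swap in another table to use a
different BMR model. A weight-only Henry variant can be emulated by zeroing
the height coefficients in a custom table.

Daily protein adequacy is protein (g/day, mean over recorded days) divided by
adjusted weight, classed against an inclusive 1.1 g/kg cutoff.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .config import PROTEIN_KJ_PER_G, Thresholds


class AnthropometryError(ValueError):
    pass


def adjusted_body_weight(
    weight: float, height: float, thresholds: Thresholds = Thresholds()
):
    """Adjusted body weight (kg) for protein normalisation.

    Identity below the BMI threshold; above it, the weight at the threshold
    BMI plus ``excess_weight_factor`` (default 0.25) of the excess. Accepts
    scalars or numpy arrays.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise AnthropometryError("weight and height must be positive")
    w_at_threshold = thresholds.bmi_adjust_threshold * height**2
    adjusted = w_at_threshold + thresholds.excess_weight_factor * (weight - w_at_threshold)
    out = np.where(weight > w_at_threshold, adjusted, weight)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=1)
def default_henry_table() -> pd.DataFrame:
    with resources.files("mealtrace.data").joinpath("henry_coefficients.csv").open() as fh:
        return pd.read_csv(fh)


def bmr_henry(
    sex: str, age: float, weight: float, height: float, table: pd.DataFrame | None = None
) -> float:
    """Basal metabolic rate, MJ/day, from the Henry weight+height equations.

    ``weight`` should be the adjusted body weight for BMI > 25 participants.
    Age bands are half-open ``[age_min, age_max)``; ages outside every band
    raise an error naming the supported bands.
    """
    if table is None:
        table = default_henry_table()
    rows = table[
        (table["sex"] == sex) & (table["age_min"] <= age) & (age < table["age_max"])
    ]
    if rows.empty:
        bands = ", ".join(
            f"{r.sex} {r.age_min}-{r.age_max}" for r in table.itertuples(index=False)
        )
        raise AnthropometryError(
            f"no BMR band for sex={sex!r}, age={age}; supported bands: {bands}"
        )
    row = rows.iloc[0]
    return float(row["weight_coef"] * weight + row["height_coef"] * height + row["intercept"])


def protein_adequacy(
    daily_protein: float,
    adjusted_weight: float,
    cutoff: float = Thresholds().cutoff_g_per_kg,
) -> tuple[float, bool]:
    """Protein intake per kg adjusted body weight and the adequacy flag.

    The cutoff is inclusive: exactly ``cutoff`` g/kg meets the target.
    """
    if adjusted_weight <= 0:
        raise AnthropometryError("adjusted weight must be positive")
    ratio = daily_protein / adjusted_weight
    return ratio, ratio >= cutoff


def compute_anthropometry(
    participants: pd.DataFrame,
    daily_energy_kj: pd.Series,
    daily_protein_g: pd.Series,
    thresholds: Thresholds = Thresholds(),
    henry_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-participant anthropometry-derived summary.

    Parameters
    ----------
    participants
        Retained participant table (height/weight present).
    daily_energy_kj, daily_protein_g
        Mean daily intakes indexed by participant_id.

    Returns a frame with bmi, weight_at_bmi25, adjusted_weight, bmr_mj,
    pal (energy intake / BMR, descriptive only), protein_g_per_kg and
    meets_cutoff.
    """
    rows = []
    for p in participants.itertuples(index=False):
        bmi = p.weight_kg / p.height_m**2
        w25 = thresholds.bmi_adjust_threshold * p.height_m**2
        adj = adjusted_body_weight(p.weight_kg, p.height_m, thresholds)
        bmr = bmr_henry(p.sex, p.age_yr, adj, p.height_m, henry_table)
        energy = daily_energy_kj.get(p.participant_id, np.nan)
        protein = daily_protein_g.get(p.participant_id, np.nan)
        ratio, meets = protein_adequacy(protein, adj, thresholds.cutoff_g_per_kg)
        rows.append(
            {
                "participant_id": p.participant_id,
                "sex": p.sex,
                "bmi": bmi,
                "weight_at_bmi25": w25,
                "adjusted_weight_kg": adj,
                "bmr_mj": bmr,
                "pal": energy / 1000.0 / bmr,
                "energy_kj_day": energy,
                "protein_g_day": protein,
                "protein_e_pct": protein * PROTEIN_KJ_PER_G / energy * 100.0,
                "protein_g_per_kg": ratio,
                "meets_cutoff": meets,
            }
        )
    return pd.DataFrame(rows)
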