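"""Correlation and regression analyses of protein intake and meal patterns.

Two analyses, both stratified by sex:

* Spearman rank-correlation matrices over the protein-related variables
  (daily energy and protein, protein E% and g/kg, meal-specific protein, CV,
  EDO counts, dietary-pattern scores), with average ranks for ties and
  pairwise-complete observations.

* A binary logistic-regression suite for meeting the >=1.1 g protein/kg
  adjusted body-weight target. Three blocks mirror the study design:

  - daily block: protein (per 5 g), energy (per MJ) and total EDO frequency,
    each individually adjusted for age + education only, and all three
    mutually adjusted in a single model;
  - meal block: protein at each self-indicated meal (per 5 g), four individual
    models and one additive model with all four meals, every model adjusted
    for age, education, energy and total EDO;
  - dietary-pattern block: each retained pattern score (per score SD),
    individually and jointly, with the same adjustment set.

  ORs are per reporting unit with Wald 95% CIs; the adjustment set is printed
  next to every estimate. No multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PROTEIN_KJ_PER_G, ModelOptions

EDUCATION_REFERENCE = "primary"

#: Default variable set of the correlation matrix, in presentation order.
CORRELATION_VARIABLES = [
    "energy_mj_day",
    "protein_g_day",
    "protein_e_pct",
    "protein_g_per_kg",
    "protein_breakfast",
    "protein_lunch",
    "protein_dinner",
    "protein_other",
    "cv",
    "total_edo",
    "large_edo",
    "small_edo",
]


class ModelError(RuntimeError):
    pass


def build_analysis_frame(
    participants: pd.DataFrame,
    anthro: pd.DataFrame,
    meal_summaries: pd.DataFrame,
    edo_summaries: pd.DataFrame,
    dp_scores: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One row per retained participant with every modelled variable.

    ``dp_scores`` maps stratum (sex) to a participant-indexed score frame;
    scores are merged within stratum so sexes never share pattern scales.
    Maintains the identity protein_e_pct == protein_g_day * 17 / energy_kj * 100.
    """
    frame = participants.merge(
        anthro.drop(columns=["sex"]), on="participant_id", how="left"
    )
    frame = frame.merge(meal_summaries, on="participant_id", how="left")
    frame = frame.merge(edo_summaries, on="participant_id", how="left")
    frame["energy_mj_day"] = frame["energy_kj_day"] / 1000.0
    if dp_scores:
        parts = []
        for sex, scores in dp_scores.items():
            sub = scores.copy()
            sub.columns = [f"{c}_score" for c in sub.columns]
            parts.append(sub.reset_index())
        frame = frame.merge(pd.concat(parts, axis=0), on="participant_id", how="left")
    return frame


def spearman_matrix(
    frame: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation and two-sided p-value matrices.

    Average ranks for ties, pairwise-complete observations per cell. Constant
    variables (or cells with fewer than 3 complete pairs) give NaN.
    """
    variables = variables or [v for v in CORRELATION_VARIABLES if v in frame.columns]
    k = len(variables)
    corr = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    cols = [frame[v].to_numpy(dtype=float) for v in variables]
    for i in range(k):
        corr[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            x, y = cols[i], cols[j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(corr, index=variables, columns=variables),
        pd.DataFrame(pval, index=variables, columns=variables),
    )


def _design(frame: pd.DataFrame, terms: list[str], options: ModelOptions) -> pd.DataFrame:
    """Design matrix with scaled exposures and education dummies."""
    X = pd.DataFrame(index=frame.index)
    for term in terms:
        if term == "age":
            X["age"] = frame["age_yr"].astype(float)
        elif term == "education":
            for level in ("secondary", "university"):
                X[f"education_{level}"] = (frame["education"] == level).astype(float)
        elif term == "energy_mj":
            X["energy_mj"] = frame["energy_kj_day"] / options.energy_unit_kj
        elif term == "total_edo":
            X["total_edo"] = frame["total_edo"].astype(float)
        elif term == "protein_5g":
            X["protein_5g"] = frame["protein_g_day"] / options.protein_unit_g
        elif term.startswith("protein_") and term.endswith("_5g"):
            meal = term[: -len("_5g")]
            X[term] = frame[meal] / options.protein_unit_g
        elif term.endswith("_score_sd"):
            col = term[: -len("_sd")]
            sd = frame[col].std(ddof=1)
            X[term] = frame[col] / sd
        else:
            raise ModelError(f"unknown model term {term!r}")
    return X


def _fit_one(
    frame: pd.DataFrame,
    model_id: str,
    exposures: list[str],
    adjusters: list[str],
    options: ModelOptions,
) -> list[dict]:
    terms = exposures + adjusters
    X = _design(frame, terms, options)
    y = frame["meets_cutoff"].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    X, y = X[ok], y[ok]
    if y.nunique() < 2:
        raise ModelError(f"{model_id}: outcome is constant; model not identifiable")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=options.max_iter)
    except Exception as exc:  # perfect separation, singular design
        return [
            {
                "model": model_id,
                "term": e,
                "or": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "n": int(ok.sum()),
                "adjustment": "+".join(adjusters),
                "note": f"fit failed: {exc}",
            }
            for e in exposures
        ]
    if not fit.mle_retvals.get("converged", True):
        raise ModelError(f"{model_id}: logistic fit did not converge\n{fit.summary()}")
    z = stats.norm.ppf(0.5 + options.ci_level / 2)
    rows = []
    for exposure in exposures:
        cols = (
            [exposure]
            if exposure != "education"
            else ["education_secondary", "education_university"]
        )
        for col in cols:
            beta = fit.params[col]
            se = fit.bse[col]
            rows.append(
                {
                    "model": model_id,
                    "term": col,
                    "or": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * se)),
                    "ci_high": float(np.exp(beta + z * se)),
                    "p_value": float(fit.pvalues[col]),
                    "n": int(fit.nobs),
                    "adjustment": "+".join(adjusters),
                    "note": "",
                }
            )
    return rows


def fit_logistic_suite(
    frame: pd.DataFrame,
    options: ModelOptions | None = None,
    dp_terms: list[str] | None = None,
) -> pd.DataFrame:
    """Fit the full model suite on one (already sex-stratified) frame.

    ``dp_terms`` names the pattern-score columns (e.g. ``["DP1_score", ...]``);
    they are scaled per score SD inside the models. Returns a tidy frame:
    model, term, or, ci_low, ci_high, p_value, n, adjustment, note.
    """
    options = options or ModelOptions()
    base = ["age", "education"]
    full = base + ["energy_mj", "total_edo"]
    rows: list[dict] = []
    # daily block: individually adjusted = age + education only
    rows += _fit_one(frame, "daily_protein_individual", ["protein_5g"], base, options)
    rows += _fit_one(frame, "daily_energy_individual", ["energy_mj"], base, options)
    rows += _fit_one(frame, "daily_edo_individual", ["total_edo"], base, options)
    rows += _fit_one(
        frame, "daily_mutual", ["protein_5g", "energy_mj", "total_edo"], base, options
    )
    # meal block: every model carries energy and EDO in the adjustment set
    meals = ["protein_breakfast_5g", "protein_lunch_5g", "protein_dinner_5g", "protein_other_5g"]
    for term in meals:
        rows += _fit_one(frame, f"meal_{term.split('_')[1]}_individual", [term], full, options)
    rows += _fit_one(frame, "meal_additive", meals, full, options)
    # dietary-pattern block
    dp_terms = dp_terms or []
    sd_terms = [f"{t}_sd" for t in dp_terms if frame[t].notna().any()]
    for term in sd_terms:
        rows += _fit_one(frame, f"dp_{term.split('_')[0].lower()}_individual", [term], full, options)
    if len(sd_terms) > 1:
        rows += _fit_one(frame, "dp_mutual", sd_terms, full, options)
    return pd.DataFrame(rows)


def protein_e_pct(protein_g: float, energy_kj: float) -> float:
    """Percent of energy from protein at 17 kJ/g."""
    return protein_g * PROTEIN_KJ_PER_G / energy_kj * 100.0
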