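"""End-to-end pipeline: generate/ingest -> filter -> anthropometry ->
meal patterns -> dietary patterns -> associations -> report.

``run_pipeline`` executes every stage on a synthetic cohort (or on diary CSVs
passed in), writes table analogues of the study's four result tables plus all
intermediate frames as CSV, a loading heatmap figure, and a run manifest
recording the seed, thresholds (with any overrides), package versions and
exclusion counts. Outputs are deterministic given (config, seed): no
timestamps enter any written table.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .anthropometry import compute_anthropometry
from .associations import (
    build_analysis_frame,
    fit_logistic_suite,
    spearman_matrix,
)
from .codebook import DEFAULT_CODEBOOK, FoodGroupCodebook
from .config import PipelineConfig, Thresholds
from .dietary_patterns import build_foodgroup_matrix, log_transform, pca_varimax
from .meal_patterns import (
    bolus_cross_association,
    bolus_table,
    day_profiles,
    edo_summary,
    meal_protein_summary,
    profiles_to_frame,
    redistribute_surplus,
)
from .records import apply_exclusions, filter_entries
from .synthetic import cohort_config_from_overrides, generate_cohort


class PipelineError(RuntimeError):
    """A stage failure, naming the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def table1_analogue(frame: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Cohort characteristics by sex and protein-adequacy category."""
    rows = []
    for sex, g in frame.groupby("sex"):
        for label, sub in (
            ("below_cutoff", g[~g["meets_cutoff"]]),
            ("meets_cutoff", g[g["meets_cutoff"]]),
            ("all", g),
        ):
            if not len(sub):
                continue
            rows.append(
                {
                    "sex": sex,
                    "group": label,
                    "n": len(sub),
                    "age_mean": sub["age_yr"].mean(),
                    "bmi_mean": sub["bmi"].mean(),
                    "pct_overweight": 100.0 * (sub["bmi"] > thresholds.bmi_adjust_threshold).mean(),
                    "energy_mj_mean": sub["energy_mj_day"].mean(),
                    "protein_g_mean": sub["protein_g_day"].mean(),
                    "protein_e_pct_mean": sub["protein_e_pct"].mean(),
                    "protein_g_per_kg_mean": sub["protein_g_per_kg"].mean(),
                    "bmr_mj_mean": sub["bmr_mj"].mean(),
                    "pal_mean": sub["pal"].mean(),
                    "total_edo_mean": sub["total_edo"].mean(),
                }
            )
    return pd.DataFrame(rows)


@_stage("generate")
def _generate(config: PipelineConfig):
    cohort_cfg = cohort_config_from_overrides(
        seed=config.seed, n_participants=config.n_participants, **config.cohort_overrides
    )
    return generate_cohort(cohort_cfg)


def run_pipeline(
    config: PipelineConfig,
    participants: pd.DataFrame | None = None,
    entries: pd.DataFrame | None = None,
    codebook: FoodGroupCodebook = DEFAULT_CODEBOOK,
    write: bool = True,
) -> dict:
    """Run every stage; return a dict of all result objects.

    With no ``participants``/``entries`` a synthetic cohort is generated from
    ``config.seed`` (mandatory in that case). When ``write`` is true, tables,
    figure and manifest land under ``config.out_dir``.
    """
    if participants is None or entries is None:
        cohort = _generate(config)
        participants, entries = cohort.participants, cohort.entries
        truth = cohort.truth
    else:
        truth = None

    thresholds = config.thresholds
    n_input = len(participants)

    # filter
    try:
        retained, exclusion_log = apply_exclusions(participants, entries, thresholds)
        entries_r = filter_entries(entries, retained)
    except Exception as exc:
        raise PipelineError(f"stage 'filter' failed: {exc}") from exc

    # meal patterns
    try:
        profiles = day_profiles(entries_r, thresholds)
        profile_frame = profiles_to_frame(profiles)
        edos = edo_summary(profiles)
        meals = meal_protein_summary(entries_r, thresholds)
        table2 = bolus_table(meals, retained, thresholds)
        merged = meals.merge(retained[["participant_id", "sex"]], on="participant_id")
        redistribution = {
            sex: redistribute_surplus(g, thresholds) for sex, g in merged.groupby("sex")
        }
        cross = {
            sex: bolus_cross_association(g, thresholds) for sex, g in merged.groupby("sex")
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'meal_patterns' failed: {exc}") from exc

    # anthropometry
    try:
        daily = entries_r.groupby(["participant_id", "day"])[["energy_kj", "protein_g"]].sum()
        per_part = daily.groupby("participant_id").mean()
        anthro = compute_anthropometry(
            retained, per_part["energy_kj"], per_part["protein_g"], thresholds
        )
    except Exception as exc:
        raise PipelineError(f"stage 'anthropometry' failed: {exc}") from exc

    # dietary patterns
    try:
        matrix = build_foodgroup_matrix(entries_r, retained, codebook)
        logm = log_transform(matrix, config.pca.log_offset)
        patterns = pca_varimax(logm, retained, config.pca)
    except Exception as exc:
        raise PipelineError(f"stage 'dietary_patterns' failed: {exc}") from exc

    # associations
    try:
        frame = build_analysis_frame(
            retained,
            anthro,
            meals,
            edos,
            {sex: res.scores for sex, res in patterns.items()},
        )
        correlations = {}
        models = {}
        for sex, g in frame.groupby("sex"):
            corr, pvals = spearman_matrix(g)
            correlations[sex] = {"corr": corr, "p": pvals}
            dp_terms = [
                f"{c}_score"
                for c in patterns[sex].analysis_components
                if f"{c}_score" in g.columns
            ]
            models[sex] = fit_logistic_suite(g, config.models, dp_terms)
        table4 = pd.concat(
            [m.assign(sex=sex) for sex, m in models.items()], ignore_index=True
        )
    except Exception as exc:
        raise PipelineError(f"stage 'associations' failed: {exc}") from exc

    table1 = table1_analogue(frame, thresholds)
    table3 = {sex: correlations[sex]["corr"] for sex in correlations}

    results = {
        "participants": participants,
        "retained": retained,
        "entries": entries_r,
        "exclusion_log": exclusion_log,
        "profiles": profile_frame,
        "edo_summary": edos,
        "meal_summaries": meals,
        "redistribution": redistribution,
        "bolus_cross": cross,
        "anthropometry": anthro,
        "foodgroup_matrix": matrix,
        "patterns": patterns,
        "frame": frame,
        "correlations": correlations,
        "models": models,
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table4": table4,
        "truth": truth,
    }
    if write:
        results["out_dir"] = write_run(results, config)
    return results


def _loading_heatmap(patterns: dict, path: Path) -> None:
    fig, axes = plt.subplots(
        1, len(patterns), figsize=(4.5 * len(patterns), 8), squeeze=False
    )
    for ax, (sex, res) in zip(axes[0], patterns.items()):
        L = res.loadings
        im = ax.imshow(L.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(L.shape[1]))
        ax.set_xticklabels(
            [
                f"{c} ({v:.0f}%)"
                for c, v in zip(L.columns, res.pct_variance[: L.shape[1]])
            ],
            rotation=90,
        )
        ax.set_yticks(range(L.shape[0]))
        ax.set_yticklabels(L.index, fontsize=7)
        ax.set_title(f"Dietary patterns ({sex})")
    fig.colorbar(im, ax=axes[0], shrink=0.6, label="loading")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_run(results: dict, config: PipelineConfig) -> Path:
    """Write tables, figure and manifest to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results["exclusion_log"].to_csv(out / "exclusions.csv", index=False)
    results["retained"].to_csv(out / "participants_retained.csv", index=False)
    results["profiles"].to_csv(out / "hourly_profiles.csv", index=False)
    results["edo_summary"].to_csv(out / "edo_summary.csv", index=False)
    results["meal_summaries"].to_csv(out / "meal_protein_summaries.csv", index=False)
    results["anthropometry"].to_csv(out / "anthropometry.csv", index=False)
    results["frame"].to_csv(out / "analysis_frame.csv", index=False)
    results["table1"].to_csv(out / "table1_characteristics.csv", index=False)
    results["table2"].to_csv(out / "table2_bolus_attainment.csv", index=False)
    for sex, corr in results["table3"].items():
        corr.to_csv(out / f"table3_correlations_{sex}.csv")
        results["correlations"][sex]["p"].to_csv(out / f"table3_pvalues_{sex}.csv")
    results["table4"].to_csv(out / "table4_logistic_models.csv", index=False)
    for sex, res in results["patterns"].items():
        res.loadings.to_csv(out / f"pattern_loadings_{sex}.csv")
        res.scores.to_csv(out / f"pattern_scores_{sex}.csv")
        pd.DataFrame(
            {
                "eigenvalue": res.eigenvalues,
            }
        ).to_csv(out / f"pattern_eigenvalues_{sex}.csv", index=False)
        if not res.tertiles.empty:
            res.tertiles.to_csv(out / f"pattern_tertiles_{sex}.csv")
    redist_rows = []
    for sex, r in results["redistribution"].items():
        r.per_participant.assign(sex=sex).to_csv(
            out / f"redistribution_{sex}.csv", index=False
        )
        redist_rows.append(
            {
                "sex": sex,
                "lunch_attain_before_pct": 100.0 * r.lunch_attain_before,
                "lunch_attain_after_pct": 100.0 * r.lunch_attain_after,
                "total_protein_delta_g": r.total_protein_delta,
            }
        )
    pd.DataFrame(redist_rows).to_csv(out / "redistribution_summary.csv", index=False)

    _loading_heatmap(results["patterns"], out / "pattern_loadings.png")

    thresholds = config.thresholds
    manifest = {
        "package": "mealtrace",
        "version": __version__,
        "seed": config.seed,
        "n_participants_input": len(results["participants"]),
        "n_retained": len(results["retained"]),
        "n_excluded": len(results["exclusion_log"]),
        "exclusion_reasons": results["exclusion_log"]["reason"]
        .value_counts()
        .to_dict(),
        "thresholds": dataclasses.asdict(thresholds),
        "threshold_overrides": thresholds.overrides(),
        "pca": dataclasses.asdict(config.pca),
        "models": dataclasses.asdict(config.models),
        "versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
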