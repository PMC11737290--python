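"""Seeded synthetic cohorts of 4-day time-stamped food diaries.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without survey microdata:

* three daily energy peaks (breakfast ~07:30, lunch ~12:30, dinner ~18:30)
  plus Poisson-distributed snacks, all timestamps on the 15-minute grid;
* per-meal protein drawn from a lognormal re-parameterised to the configured
  mean/SD (intakes are skewed and nonnegative) — defaults at the scale
  observed in older Swedish adults (dinner 33.4 g SD 15.0 for men,
  27.4 g SD 11.3 for women, and so on per meal);
* meal energy derived from protein through a per-meal protein-E% target with
  multiplicative noise, so the 210 kJ eating-occasion threshold and the kcal
  exclusion bands are exercised realistically (mean total EDO/day ~4.7);
* each meal decomposed into food-group items drawn from per-meal categorical
  mixtures over the 27-group codebook, with item gram weights carrying a
  planted low-rank factor structure (participant-level latent factors acting
  on log habitual grams) that the dietary-pattern PCA can recover;
* anthropometry (age, height, BMI by sex) at the scale of the study
  population, with optional missing height/weight to exercise the exclusion
  filters.

Everything is deterministic given (config, seed); the generator refuses to run
without an explicit seed. The planted truth (meal-protein parameters, factor
loadings) is returned alongside the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import DEFAULT_CODEBOOK, FoodGroupCodebook
from .config import PROTEIN_KJ_PER_G, ConfigError
from .records import MAIN_MEALS, TIME_GRID_MIN

# ---------------------------------------------------------------------------
# Default calibration (study-population scale; editable via CohortConfig)
# ---------------------------------------------------------------------------

#: Per-meal protein mean/SD (g) by sex. Main meals are day-level totals;
#: "other" is per snack occasion.
DEFAULT_MEAL_PROTEIN = {
    "male": {
        "breakfast": (17.3, 7.5),
        "lunch": (23.2, 12.4),
        "dinner": (33.4, 15.0),
        "other": (5.5, 4.5),
    },
    "female": {
        "breakfast": (14.0, 6.4),
        "lunch": (20.0, 11.5),
        "dinner": (27.4, 11.3),
        "other": (4.8, 4.2),
    },
}

#: Mean clock hour and SD per meal.
DEFAULT_MEAL_TIMES = {
    "breakfast": (7.5, 0.9),
    "lunch": (12.5, 0.9),
    "dinner": (18.5, 1.1),
}

#: Protein E% target per meal (fraction of meal energy from protein).
DEFAULT_PROTEIN_E_FRACTION = {
    "breakfast": 0.15,
    "lunch": 0.18,
    "dinner": 0.20,
    "other": 0.12,
}

#: Anthropometry (mean, SD) by sex.
DEFAULT_ANTHROPOMETRY = {
    "male": {"age_yr": (68.0, 6.0), "height_m": (1.78, 0.065), "bmi": (26.5, 3.3)},
    "female": {"age_yr": (68.0, 5.0), "height_m": (1.65, 0.060), "bmi": (25.5, 4.1)},
}

DEFAULT_EDUCATION_PROBS = {"primary": 0.21, "secondary": 0.44, "university": 0.35}

#: Items drawn per occasion.
DEFAULT_ITEMS_PER_MEAL = {"breakfast": 4, "lunch": 5, "dinner": 5, "other": 2}


def _mixture(pairs: dict[str, float]) -> dict[str, float]:
    total = sum(pairs.values())
    return {k: v / total for k, v in pairs.items()}


#: Per-meal categorical food-group mixtures (probability vectors over the
#: codebook; zero for unlisted groups). Breakfast is dairy/bread/cereal-heavy,
#: lunch and dinner are meat/fish/vegetable-heavy, snacks are coffee/fruit/
#: cake-heavy — the hourly protein-by-food-group structure seen in the survey.
DEFAULT_FOODGROUP_MIXTURES = {
    "breakfast": _mixture(
        {
            "milk_yoghurt": 0.18, "bread": 0.15, "cheese": 0.09,
            "porridge_cereals": 0.17, "coffee": 0.12, "sugar_jam": 0.10,
            "fat_oil": 0.05, "egg": 0.04, "fruit": 0.05, "juice": 0.02,
            "tea": 0.02, "supplements": 0.01,
        }
    ),
    "lunch": _mixture(
        {
            "meat": 0.16, "fish": 0.08, "potatoes": 0.10, "pasta_rice": 0.09,
            "vegetables": 0.15, "bread": 0.06, "sauce": 0.06, "fat_oil": 0.05,
            "milk_yoghurt": 0.05, "soup": 0.05, "beverages": 0.04,
            "water": 0.05, "legume": 0.02, "egg": 0.02, "other": 0.02,
        }
    ),
    "dinner": _mixture(
        {
            "meat": 0.18, "fish": 0.10, "potatoes": 0.12, "pasta_rice": 0.08,
            "vegetables": 0.15, "sauce": 0.08, "fat_oil": 0.05, "bread": 0.04,
            "milk_yoghurt": 0.04, "beverages": 0.06, "water": 0.05,
            "soup": 0.02, "legume": 0.02, "other": 0.01,
        }
    ),
    "other": _mixture(
        {
            "coffee": 0.22, "tea": 0.06, "fruit": 0.14, "cake_dessert": 0.14,
            "sweets": 0.08, "bread": 0.06, "milk_yoghurt": 0.06, "cheese": 0.04,
            "snacks": 0.05, "juice": 0.05, "beverages": 0.05,
            "nuts_seeds": 0.03, "other": 0.02,
        }
    ),
}

#: Log of habitual daily grams per group (population base level).
DEFAULT_LOG_GRAMS = {
    "meat": 4.6, "fish": 3.7, "egg": 3.2, "milk_yoghurt": 5.3, "cheese": 3.0,
    "bread": 4.4, "porridge_cereals": 4.0, "pasta_rice": 4.3, "potatoes": 4.6,
    "vegetables": 5.0, "fruit": 5.0, "legume": 2.0, "nuts_seeds": 1.6,
    "fat_oil": 2.8, "sugar_jam": 2.6, "cake_dessert": 3.7, "sweets": 2.8,
    "snacks": 2.5, "soup": 3.5, "sauce": 3.6, "beverages": 5.0, "juice": 4.6,
    "coffee": 6.0, "tea": 4.5, "water": 5.9, "other": 2.0, "supplements": 1.0,
}

#: Approximate protein density (g protein / g food), used only to apportion a
#: meal's protein over its items.
DEFAULT_PROTEIN_DENSITY = {
    "meat": 0.20, "fish": 0.19, "egg": 0.12, "milk_yoghurt": 0.035,
    "cheese": 0.25, "bread": 0.09, "porridge_cereals": 0.05, "pasta_rice": 0.05,
    "potatoes": 0.02, "vegetables": 0.015, "fruit": 0.005, "legume": 0.08,
    "nuts_seeds": 0.20, "fat_oil": 0.001, "sugar_jam": 0.001,
    "cake_dessert": 0.05, "sweets": 0.04, "snacks": 0.06, "soup": 0.03,
    "sauce": 0.02, "beverages": 0.005, "juice": 0.005, "coffee": 0.002,
    "tea": 0.0, "water": 0.0, "other": 0.02, "supplements": 0.2,
}


def _default_pattern_loadings() -> pd.DataFrame:
    """Planted 3-factor loading matrix on log habitual grams (25 PCA groups).

    Factor 1: bread/potatoes/cheese; factor 2: porridge/milk/sugar-jam;
    factor 3: vegetables/fruit — echoing the kinds of patterns seen in older
    Swedish adults. Loadings are in log-gram units.
    """
    groups = DEFAULT_CODEBOOK.pca_groups
    L = pd.DataFrame(0.0, index=list(groups), columns=["F1", "F2", "F3"])
    L.loc["bread", "F1"] = 0.9
    L.loc["potatoes", "F1"] = 0.8
    L.loc["cheese", "F1"] = 0.8
    L.loc["meat", "F1"] = 0.5
    L.loc["sauce", "F1"] = 0.5
    L.loc["fat_oil", "F1"] = 0.4
    L.loc["porridge_cereals", "F2"] = 0.9
    L.loc["milk_yoghurt", "F2"] = 0.9
    L.loc["sugar_jam", "F2"] = 0.7
    L.loc["cake_dessert", "F2"] = 0.5
    L.loc["coffee", "F2"] = 0.4
    L.loc["vegetables", "F3"] = 0.9
    L.loc["fruit", "F3"] = 0.9
    L.loc["fish", "F3"] = 0.5
    L.loc["tea", "F3"] = 0.4
    L.loc["legume", "F3"] = 0.3
    L.loc["nuts_seeds", "F3"] = 0.3
    return L


@dataclass
class CohortConfig:
    """Configuration of a synthetic diary cohort. ``seed`` is mandatory."""

    n_participants: int = 500
    sex_ratio: float = 237 / 505  # fraction male
    n_days: int = 4
    seed: int | None = None
    anthropometry: dict = field(default_factory=lambda: DEFAULT_ANTHROPOMETRY)
    meal_times: dict = field(default_factory=lambda: DEFAULT_MEAL_TIMES)
    meal_protein: dict = field(default_factory=lambda: DEFAULT_MEAL_PROTEIN)
    protein_e_fraction: dict = field(default_factory=lambda: DEFAULT_PROTEIN_E_FRACTION)
    snack_rate: float = 2.4  # expected snacks/day; with hour collisions and
    # sub-210 kJ snacks this yields ~4.7 EDOs/day
    items_per_meal: dict = field(default_factory=lambda: DEFAULT_ITEMS_PER_MEAL)
    foodgroup_mixtures: dict = field(default_factory=lambda: DEFAULT_FOODGROUP_MIXTURES)
    education_probs: dict = field(default_factory=lambda: DEFAULT_EDUCATION_PROBS)
    log_grams: dict = field(default_factory=lambda: DEFAULT_LOG_GRAMS)
    protein_density: dict = field(default_factory=lambda: DEFAULT_PROTEIN_DENSITY)
    pattern_loadings: pd.DataFrame = field(default_factory=_default_pattern_loadings)
    pattern_noise_sd: float = 0.45  # idiosyncratic SD on log habitual grams
    item_weight_noise_sd: float = 0.25  # lognormal sigma on item grams
    energy_noise_sd: float = 0.15  # lognormal sigma on meal energy
    day_correlation: float = 0.0  # within-person day-to-day correlation of meal protein
    missingness_rate: float = 0.03  # fraction with missing height or weight
    age_range: tuple[float, float] = (60.0, 80.0)

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("CohortConfig.seed is required (no silent nondeterminism)")
        if self.n_participants < 1 or self.n_days < 1:
            raise ConfigError("n_participants and n_days must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if not 0.0 <= self.day_correlation < 1.0:
            raise ConfigError("day_correlation must be in [0, 1)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ConfigError("missingness_rate must be in [0, 1)")
        for name in ("pattern_noise_sd", "item_weight_noise_sd", "energy_noise_sd",
                     "snack_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for meal, mix in self.foodgroup_mixtures.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigError(f"mixture for {meal!r} sums to {s}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"mixture for {meal!r} has negative probabilities")
        for sex, meals in self.meal_protein.items():
            for meal, (mean, sd) in meals.items():
                if mean <= 0 or sd < 0:
                    raise ConfigError(f"meal_protein[{sex}][{meal}] needs mean>0, sd>=0")


@dataclass
class SyntheticCohort:
    """A generated cohort with its planted ground truth."""

    participants: pd.DataFrame
    entries: pd.DataFrame
    truth: dict


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _snap_to_grid(hours: float) -> int:
    """Clock hours -> minutes snapped to the 15-min grid, clipped to the day."""
    minutes = int(round(hours * 60.0 / TIME_GRID_MIN)) * TIME_GRID_MIN
    return int(np.clip(minutes, 0, 1440 - TIME_GRID_MIN))


def generate_cohort(
    config: CohortConfig, codebook: FoodGroupCodebook = DEFAULT_CODEBOOK
) -> SyntheticCohort:
    """Generate a cohort of participants and diary entries (see module docs)."""
    config.validate()
    codebook.validate_codes(config.log_grams)
    for mix in config.foodgroup_mixtures.values():
        codebook.validate_codes(mix)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_male = int(round(n * config.sex_ratio))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)

    groups = list(codebook.groups)
    loadings = config.pattern_loadings.reindex(
        index=groups, columns=config.pattern_loadings.columns, fill_value=0.0
    )
    L = loadings.to_numpy()
    k = L.shape[1]
    mu_log = np.array([config.log_grams[g] for g in groups])
    density = np.array([config.protein_density[g] for g in groups])
    gidx = {g: i for i, g in enumerate(groups)}
    mix_arrays = {
        meal: np.array([mix.get(g, 0.0) for g in groups])
        for meal, mix in config.foodgroup_mixtures.items()
    }
    # expected items of each group per day (meals + expected snacks), used to
    # scale item grams so day totals track the habitual level
    expected_items = sum(
        config.items_per_meal[m] * mix_arrays[m] for m in MAIN_MEALS
    ) + config.snack_rate * config.items_per_meal["other"] * mix_arrays["other"]
    expected_items = np.maximum(expected_items, 1e-3)

    edu_levels = list(config.education_probs)
    edu_p = np.array([config.education_probs[e] for e in edu_levels])
    edu_p = edu_p / edu_p.sum()

    participants = []
    entry_rows: list[tuple] = []
    rho = config.day_correlation

    for i in range(n):
        pid = f"P{i + 1:05d}"
        sex = sexes[i]
        anth = config.anthropometry[sex]
        lo_age, hi_age = config.age_range
        age = float(np.clip(rng.normal(*anth["age_yr"]), lo_age, hi_age))
        height = float(np.clip(rng.normal(*anth["height_m"]), 1.4, 2.1))
        bmi = float(np.clip(rng.normal(*anth["bmi"]), 16.0, 45.0))
        weight = bmi * height**2
        education = edu_levels[rng.choice(len(edu_levels), p=edu_p)]
        height_out, weight_out = height, weight
        if config.missingness_rate and rng.random() < config.missingness_rate:
            if rng.random() < 0.5:
                height_out = np.nan
            else:
                weight_out = np.nan
        participants.append(
            {
                "participant_id": pid,
                "sex": sex,
                "age_yr": age,
                "height_m": height_out,
                "weight_kg": weight_out,
                "education": education,
            }
        )

        z = rng.standard_normal(k)
        log_habitual = (
            mu_log + L @ z + rng.normal(0.0, config.pattern_noise_sd, len(groups))
        )
        habitual_grams = np.exp(log_habitual)
        item_scale = habitual_grams / expected_items

        # participant-level component of log meal protein (day-to-day correlation)
        protein_params = {
            meal: _lognormal_params(*config.meal_protein[sex][meal])
            for meal in config.meal_protein[sex]
        }
        person_shift = {
            meal: rng.normal(0.0, np.sqrt(rho) * sig)
            for meal, (_, sig) in protein_params.items()
        }

        for day in range(1, config.n_days + 1):
            occasions: list[tuple[str, str, int]] = []  # (meal label, kind, time)
            for meal in MAIN_MEALS:
                t = _snap_to_grid(rng.normal(*config.meal_times[meal]))
                occasions.append((meal, meal, t))
            for _ in range(rng.poisson(config.snack_rate)):
                t = _snap_to_grid(rng.uniform(9.0, 21.75))
                occasions.append(("other", "other", t))
            for meal_label, kind, t in occasions:
                mu_p, sig_p = protein_params[kind]
                noise = rng.normal(0.0, np.sqrt(max(1.0 - rho, 0.0)) * sig_p)
                protein = float(np.exp(mu_p + person_shift[kind] + noise))
                n_items = config.items_per_meal[kind]
                picks = rng.choice(len(groups), size=n_items, p=mix_arrays[kind])
                weights = item_scale[picks] * np.exp(
                    rng.normal(0.0, config.item_weight_noise_sd, n_items)
                )
                raw = density[picks] * weights
                shares = raw / raw.sum() if raw.sum() > 0 else np.full(n_items, 1.0 / n_items)
                e_frac = config.protein_e_fraction[kind]
                energy = (
                    protein * PROTEIN_KJ_PER_G / e_frac
                    * float(np.exp(rng.normal(0.0, config.energy_noise_sd)))
                )
                e_shares = weights / weights.sum()
                for j in range(n_items):
                    entry_rows.append(
                        (
                            pid,
                            day,
                            t,
                            meal_label,
                            groups[picks[j]],
                            round(float(weights[j]), 2),
                            round(float(energy * e_shares[j]), 2),
                            round(float(protein * shares[j]), 3),
                        )
                    )

    participants_df = pd.DataFrame(participants)
    entries_df = pd.DataFrame(
        entry_rows,
        columns=[
            "participant_id", "day", "time_min", "meal",
            "food_group", "weight_g", "energy_kj", "protein_g",
        ],
    )
    truth = {
        "meal_protein": config.meal_protein,
        "pattern_loadings": loadings.loc[list(codebook.pca_groups)],
        "protein_e_fraction": config.protein_e_fraction,
        "snack_rate": config.snack_rate,
        "logistic_coefficients": None,  # adequacy emerges from intakes here;
        # planted coefficients exist only in generate_logistic_fixture
    }
    return SyntheticCohort(participants_df, entries_df, truth)


def generate_logistic_fixture(
    n: int, coefficients: np.ndarray, seed: int, intercept: float = 0.0
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Design matrix and Bernoulli outcomes from a known logistic model.

    Covariates are iid standard normal; outcomes are drawn
    ``Bernoulli(logit^-1(intercept + X @ coefficients))``. Returns
    ``(X, y, truth)`` with the planted coefficients in ``truth``.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if seed is None:
        raise ConfigError("seed is required")
    beta = np.asarray(coefficients, dtype=float)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, beta.size))
    eta = intercept + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    Xdf = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(beta.size)])
    return Xdf, y, {"intercept": intercept, "coefficients": beta}


def cohort_config_from_yaml(path, seed: int | None = None) -> CohortConfig:
    """Load a cohort calibration file (key-value YAML) into a CohortConfig.

    Tuple-valued parameters (mean/SD pairs, bands) may be written as YAML
    lists. The file never carries a seed; pass one explicitly.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def tuplify(obj):
        if isinstance(obj, list):
            return tuple(tuplify(v) for v in obj)
        if isinstance(obj, dict):
            return {k: tuplify(v) for k, v in obj.items()}
        return obj

    raw = {k: tuplify(v) for k, v in raw.items()}
    raw.pop("seed", None)
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown cohort config fields: {sorted(unknown)}")
    return CohortConfig(seed=seed, **raw)


def cohort_config_from_overrides(seed: int, n_participants: int, **overrides) -> CohortConfig:
    """Build a CohortConfig from keyword overrides (unknown keys rejected)."""
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(f"unknown cohort config fields: {sorted(unknown)}")
    return CohortConfig(seed=seed, n_participants=n_participants, **overrides)
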