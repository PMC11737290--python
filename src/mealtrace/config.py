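"""Analysis thresholds and pipeline configuration.

Every threshold carries the study default (210 kJ eating-occasion cutoff, 15%
large-occasion fraction, 30 g protein bolus, 1.1 g/kg adequacy cutoff, the
sex-specific kcal exclusion bands). Overrides are legal but are always echoed
in the run log — thresholds never change silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Thermochemical kilocalorie.
KCAL_TO_KJ = 4.184
#: Metabolisable energy of protein, kJ per gram (Atwater, kJ form). Used to
#: express protein as a percentage of energy intake (E%).
PROTEIN_KJ_PER_G = 17.0


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class Thresholds:
    """Analysis cutoffs, all at their study defaults."""

    #: An hour is an eating/drinking occasion (EDO) when its energy is
    #: strictly above this (kJ); 210 kJ ~ 50 kcal.
    edo_kj: float = 210.0
    #: An EDO is "large" when it holds at least this fraction of the day's energy.
    large_edo_fraction: float = 0.15
    #: Per-meal protein bolus threshold (g), the upper end of the 25-30 g range
    #: suggested to stimulate muscle protein synthesis in older adults.
    bolus_g: float = 30.0
    #: Daily protein adequacy cutoff (g per kg adjusted body weight, inclusive).
    cutoff_g_per_kg: float = 1.1
    #: Plausible mean daily energy band for men, kcal (strict inequalities).
    energy_band_kcal_men: tuple[float, float] = (800.0, 4000.0)
    #: Plausible mean daily energy band for women, kcal (strict inequalities).
    energy_band_kcal_women: tuple[float, float] = (500.0, 3500.0)
    #: BMI above which the adjusted body weight replaces measured weight.
    bmi_adjust_threshold: float = 25.0
    #: Weighting of excess weight above BMI-25 weight in the adjustment.
    excess_weight_factor: float = 0.25

    def energy_band_kcal(self, sex: str) -> tuple[float, float]:
        if sex == "male":
            return self.energy_band_kcal_men
        if sex == "female":
            return self.energy_band_kcal_women
        raise ConfigError(f"unknown sex {sex!r}; expected 'male' or 'female'")

    def overrides(self) -> dict[str, Any]:
        """Fields differing from the study defaults (echoed in run logs)."""
        default = Thresholds()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }


@dataclass
class PCAOptions:
    """Dietary-pattern extraction options."""

    graphical_eigenvalue: float = 1.0   # retained for plotting/rotation
    analysis_eigenvalue: float = 1.5    # retained for downstream models
    standardize: bool = True            # correlation-matrix PCA
    log_offset: float = 1.0             # log(x + offset) gram transform
    kaiser_normalize: bool = True
    varimax_tol: float = 1e-8
    varimax_max_iter: int = 1000


@dataclass
class ModelOptions:
    """Logistic-regression reporting options."""

    protein_unit_g: float = 5.0   # ORs per 5 g protein
    energy_unit_kj: float = 1000.0  # ORs per MJ
    ci_level: float = 0.95
    max_iter: int = 200


@dataclass
class PipelineConfig:
    """Full configuration for an end-to-end run on a synthetic cohort."""

    seed: int | None = None
    n_participants: int = 500
    out_dir: str = "mealtrace_run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    pca: PCAOptions = field(default_factory=PCAOptions)
    models: ModelOptions = field(default_factory=ModelOptions)
    # overrides forwarded to synthetic.CohortConfig
    cohort_overrides: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in ("seed", "n_participants", "out_dir", "cohort_overrides"):
            if key in raw:
                kwargs[key] = raw[key]
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw["thresholds"].items()
                }
            )
        if "pca" in raw:
            kwargs["pca"] = PCAOptions(**raw["pca"])
        if "models" in raw:
            kwargs["models"] = ModelOptions(**raw["models"])
        return cls(**kwargs)
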