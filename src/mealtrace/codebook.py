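"""Food-group codebook.

The analysis works on 27 food groups rather than individual food items.
Grouping follows culinary use (pea soup counts as soup, not legume; cheese is
kept apart from other dairy because of its protein density). Two groups —
``other`` (mixed culinary ingredients) and ``supplements`` (few consumers) —
are flagged as excluded from the dietary-pattern PCA, leaving 25 analysis
columns.

Only part of the 27-group list is fixed by the analysis itself; the remaining
codes are survey-style placeholders and can be replaced by loading a custom
codebook CSV (columns ``group``, ``pca_excluded``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

N_GROUPS = 27

#: Default 27 food-group codes. Order is fixed and defines column order in the
#: food-group intake matrix.
DEFAULT_GROUPS: tuple[str, ...] = (
    "meat",
    "fish",
    "egg",
    "milk_yoghurt",
    "cheese",
    "bread",
    "porridge_cereals",
    "pasta_rice",
    "potatoes",
    "vegetables",
    "fruit",
    "legume",
    "nuts_seeds",
    "fat_oil",
    "sugar_jam",
    "cake_dessert",
    "sweets",
    "snacks",
    "soup",
    "sauce",
    "beverages",
    "juice",
    "coffee",
    "tea",
    "water",
    "other",
    "supplements",
)

#: Groups never entered into the dietary-pattern PCA.
PCA_EXCLUDED: frozenset[str] = frozenset({"other", "supplements"})


class CodebookError(ValueError):
    """Raised for malformed codebooks or unknown group codes."""


@dataclass(frozen=True)
class FoodGroupCodebook:
    """Mapping of food-group codes with PCA-exclusion flags.

    Parameters
    ----------
    groups
        Exactly 27 unique group codes.
    pca_excluded
        Subset of ``groups`` excluded from pattern analysis; must contain
        ``other`` and ``supplements``.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    pca_excluded: frozenset[str] = field(default=PCA_EXCLUDED)

    def __post_init__(self) -> None:
        if len(self.groups) != N_GROUPS:
            raise CodebookError(
                f"codebook must define exactly {N_GROUPS} food groups, "
                f"got {len(self.groups)}"
            )
        if len(set(self.groups)) != len(self.groups):
            raise CodebookError("food-group codes must be unique")
        missing = self.pca_excluded - set(self.groups)
        if missing:
            raise CodebookError(f"pca_excluded codes not in codebook: {sorted(missing)}")
        if not {"other", "supplements"} <= self.pca_excluded:
            raise CodebookError("'other' and 'supplements' must be flagged PCA-excluded")

    @property
    def pca_groups(self) -> tuple[str, ...]:
        """The 25 groups entering the dietary-pattern matrix, in codebook order."""
        return tuple(g for g in self.groups if g not in self.pca_excluded)

    def validate_codes(self, codes) -> None:
        """Raise :class:`CodebookError` listing any codes outside the codebook."""
        unknown = sorted(set(codes) - set(self.groups))
        if unknown:
            raise CodebookError(f"unknown food-group codes: {unknown}")

    @classmethod
    def from_csv(cls, path) -> "FoodGroupCodebook":
        df = pd.read_csv(path)
        if not {"group", "pca_excluded"} <= set(df.columns):
            raise CodebookError("codebook CSV needs columns: group, pca_excluded")
        excluded = frozenset(df.loc[df["pca_excluded"].astype(bool), "group"])
        return cls(groups=tuple(df["group"]), pca_excluded=excluded)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "group": self.groups,
                "pca_excluded": [g in self.pca_excluded for g in self.groups],
            }
        ).to_csv(path, index=False)


DEFAULT_CODEBOOK = FoodGroupCodebook()
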