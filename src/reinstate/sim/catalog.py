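"""Stimulus catalog: themed scene/object pairs grouped into categories."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from reinstate.errors import ConfigurationError

#: Default 7-category scheme used when no explicit label list is given.
DEFAULT_CATEGORIES = (
    "field",
    "water",
    "housing",
    "forest",
    "infrastructure",
    "indoor",
    "farming",
)


@dataclass(frozen=True)
class StimulusCatalog:
    """Themed stimulus inventory.

    Each theme belongs to exactly one category and contributes
    ``exemplars_per_theme`` scene/object pairs.
    """

    themes: tuple
    theme_category: dict
    scenes: pd.DataFrame  # columns: scene_id, theme, category
    objects: pd.DataFrame  # columns: object_id, theme
    exemplars_per_theme: int
    categories: tuple = field(default=DEFAULT_CATEGORIES)

    @property
    def n_scenes(self) -> int:
        return len(self.scenes)

    def category_theme_counts(self) -> dict:
        counts = {c: 0 for c in self.categories}
        for cat in self.theme_category.values():
            counts[cat] += 1
        return counts


def build_catalog(
    n_themes: int = 60,
    exemplars_per_theme: int = 4,
    categories=DEFAULT_CATEGORIES,
) -> StimulusCatalog:
    """Build a stimulus catalog with round-robin category assignment.

    Theme *i* is assigned ``categories[i % len(categories)]`` so category
    sizes (in themes) differ by at most one.
    """
    categories = tuple(categories)
    if not categories:
        raise ConfigurationError("category list must be non-empty")
    if n_themes < 1:
        raise ConfigurationError("n_themes must be >= 1")
    if exemplars_per_theme < 1:
        raise ConfigurationError("exemplars_per_theme must be >= 1")

    themes = tuple(f"theme{i:03d}" for i in range(n_themes))
    theme_category = {t: categories[i % len(categories)] for i, t in enumerate(themes)}

    scene_rows = []
    object_rows = []
    for theme in themes:
        for e in range(exemplars_per_theme):
            scene_rows.append(
                {
                    "scene_id": f"{theme}_s{e}",
                    "theme": theme,
                    "category": theme_category[theme],
                }
            )
            object_rows.append({"object_id": f"{theme}_o{e}", "theme": theme})

    scenes = pd.DataFrame(scene_rows)
    objects = pd.DataFrame(object_rows)
    if scenes["scene_id"].duplicated().any():  # pragma: no cover - invariant
        raise AssertionError("scene ids must be unique")
    return StimulusCatalog(
        themes=themes,
        theme_category=theme_category,
        scenes=scenes,
        objects=objects,
        exemplars_per_theme=exemplars_per_theme,
        categories=categories,
    )
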