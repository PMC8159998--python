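"""Percent benthic cover from photo-quadrat point counts.

Each quadrat photograph is annotated at a fixed number of random points
(five per photo in the standard protocol); per-transect percent cover is
the share of points falling in each category, and site-level cover is the
mean over transects.  Category labels are validated against a controlled
vocabulary so typos fail loudly instead of silently splitting a category.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["DEFAULT_VOCABULARY", "POINTS_PER_PHOTO", "percent_cover"]

POINTS_PER_PHOTO = 5

#: benthic categories of the survey protocol; hard corals are annotated to
#: genus/family and may be analysed at either level.
DEFAULT_VOCABULARY = (
    "acropora", "anacropora", "montipora", "porites_branching",
    "porites_massive", "porites_rus", "pachyseris", "merulinidae",
    "dipsastraea", "goniastrea", "hydnophora", "lobophyllia",
    "soft_coral", "turf_algae", "macroalgae", "cca",
    "other_invertebrate", "non_living",
)

#: categories counted as scleractinian hard coral when aggregating
HARD_CORAL = frozenset(DEFAULT_VOCABULARY[:12])


class PointCountError(ValueError):
    """Annotation table violates the point-count protocol."""


def percent_cover(
    points: pd.DataFrame,
    *,
    level: str = "category",
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    points_per_photo: int = POINTS_PER_PHOTO,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate point annotations to percent cover.

    Parameters
    ----------
    points : long-format DataFrame with columns site_id, transect_id,
        photo_id, point_index, category.
    level : 'category' keeps the vocabulary as-is; 'group' pools all hard
        coral categories into 'hard_coral'.
    vocabulary : allowed category labels; unknown labels raise.
    points_per_photo : protocol point count per photograph; photos with a
        different count raise, listing the offending photo IDs.

    Returns
    -------
    (transect_cover, site_cover) : tidy frames with a percent column.
    Per-transect percentages sum to 100; site cover is the unweighted mean
    over transects, invariant to transect order.
    """
    required = {"site_id", "transect_id", "photo_id", "point_index", "category"}
    missing = required - set(points.columns)
    if missing:
        raise PointCountError(f"annotation table missing columns: {sorted(missing)}")

    unknown = set(points["category"]) - set(vocabulary)
    if unknown:
        raise PointCountError(f"unknown benthic categories: {sorted(unknown)}")

    photo_counts = points.groupby(["site_id", "transect_id", "photo_id"]).size()
    bad = photo_counts[photo_counts != points_per_photo]
    if len(bad):
        raise PointCountError(
            f"photos without exactly {points_per_photo} points: "
            f"{sorted(str(i[2]) for i in bad.index)}"
        )

    df = points.copy()
    if level == "group":
        df["category"] = [
            "hard_coral" if c in HARD_CORAL else c for c in df["category"]
        ]
        cats = ["hard_coral"] + [c for c in vocabulary if c not in HARD_CORAL]
    elif level == "category":
        cats = list(vocabulary)
    else:
        raise ValueError("level must be 'category' or 'group'")

    counts = (
        df.groupby(["site_id", "transect_id", "category"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cats, fill_value=0)
    )
    transect = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    site = transect.groupby("site_id").mean()

    transect_tidy = (
        transect.reset_index()
        .melt(id_vars=["site_id", "transect_id"], var_name="category",
              value_name="percent")
        .sort_values(["site_id", "transect_id", "category"], ignore_index=True)
    )
    site_tidy = (
        site.reset_index()
        .melt(id_vars=["site_id"], var_name="category", value_name="percent")
        .sort_values(["site_id", "category"], ignore_index=True)
    )
    return transect_tidy, site_tidy
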