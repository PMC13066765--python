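"""Species endemism scoring and community-weighted means.

Five endemism categories map onto fixed integer scores; the community value
is the abundance-weighted mean of its members' scores, and the landscape
value is the plain average of its communities' values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ClassificationError, DesignError, DomainError

log = logging.getLogger(__name__)

#: category -> integer score; order matters (it is the endemism_mix order).
CATEGORY_SCORES: dict[str, int] = {
    "exotic": -1,
    "not_endemic_pantropical_neotropical": 0,
    "not_endemic_south_american": 1,
    "regional_endemic": 2,
    "local_endemic": 3,
}

CATEGORIES: tuple[str, ...] = tuple(CATEGORY_SCORES)


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    category: str
    score: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_SCORES:
            raise ClassificationError(f"unknown endemism category: {self.category!r}")
        if self.score != CATEGORY_SCORES[self.category]:
            raise ClassificationError(
                f"score {self.score} does not match category {self.category!r}"
            )


def score_species(category: str) -> int:
    """Map an endemism category to its integer score in {-1, 0, 1, 2, 3}."""
    try:
        return CATEGORY_SCORES[category]
    except KeyError:
        raise ClassificationError(f"unknown endemism category: {category!r}") from None


def community_cwm(
    abundances: Mapping[str, float] | pd.Series,
    scores: Mapping[str, int] | pd.Series,
    strict: bool = True,
) -> float:
    """Abundance-weighted mean endemism score of one community.

    In strict mode a species with positive abundance but no score raises; in
    lenient mode it is excluded from numerator and denominator (logged).
    """
    ab = pd.Series(abundances, dtype=float)
    ab = ab[ab > 0]
    if ab.empty or ab.sum() <= 0:
        raise DomainError("community has zero total abundance")
    sc = pd.Series(scores, dtype=float)
    missing = ab.index.difference(sc.index)
    if len(missing) > 0:
        if strict:
            raise ClassificationError(
                f"species without endemism score: {sorted(missing)[:5]}"
            )
        log.warning("excluding %d unscored species from CWM", len(missing))
        ab = ab.drop(missing)
        if ab.empty:
            raise DomainError("no scored species with positive abundance")
    s = sc.reindex(ab.index)
    return float((ab * s).sum() / ab.sum())


def landscape_endemism(community_cwms: Iterable[float]) -> float:
    """Unweighted arithmetic mean of member-community CWM values."""
    values = np.asarray(list(community_cwms), dtype=float)
    if values.size == 0:
        raise DesignError("landscape has no community CWM values")
    return float(values.mean())


def species_scores(species: pd.DataFrame) -> pd.Series:
    """Extract a species_id -> score series from a species table.

    The table must have ``species_id`` and either ``score`` or ``category``.
    """
    df = species.set_index("species_id") if "species_id" in species.columns else species
    if "score" in df.columns:
        return df["score"].astype(int)
    if "category" in df.columns:
        return df["category"].map(score_species).astype(int)
    raise ClassificationError("species table lacks 'score' and 'category' columns")


def endemism_tables(
    abundances: pd.DataFrame,
    species: pd.DataFrame,
    membership: pd.DataFrame,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community and per-landscape endemism tables.

    ``abundances``: wide matrix (rows = inventory id, columns = species id).
    ``membership``: columns inventory_id, landscape_id.
    """
    scores = species_scores(species)
    rows = []
    for inv_id, row in abundances.iterrows():
        rows.append({"inventory_id": inv_id, "cwm": community_cwm(row, scores, strict)})
    per_community = pd.DataFrame(rows)
    merged = per_community.merge(membership, on="inventory_id")
    per_landscape = (
        merged.groupby("landscape_id")["cwm"]
        .mean()
        .rename("endemism")
        .reset_index()
    )
    return per_community, per_landscape
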