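"""Geographical and ecological population densities from point counts.

Geographical density is individuals per hectare of *surveyed* area:
total abundance divided by (number of points x point area).  Ecological
density is individuals per hectare of *suitable* habitat: total abundance
divided by the summed area of habitat suitable for the species at the
points where it was recorded (default), or at all points
(``mode="all_points"``).  Under either denominator, ecological density is
at least the geographical density for every species.

Abundance per point is the maximum of the two seasonal visits: the two
visits bracket early and late breeders, and the per-visit maximum is the
best available proxy of the local breeding population; summing visits
would double-count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .habitats import POINT_AREA_HA

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["point", "visit", "species", "count"]


def collapse_visits(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-point abundance as the maximum count over the two visits.

    Parameters
    ----------
    counts : DataFrame
        Long table with columns ``point, visit, species, count`` (a
        ``transect`` column is allowed and ignored).  Missing
        (species, point, visit) combinations count as 0.

    Returns
    -------
    DataFrame
        species x point abundance matrix (non-negative integers).
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")
    bad = set(counts["visit"].unique()) - {1, 2}
    if bad:
        raise ValueError(f"visit index must be 1 or 2, found {sorted(bad)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    observed_visits = set(counts["visit"].unique())
    if observed_visits and observed_visits != {1, 2}:
        logger.warning(
            "only visit(s) %s present; missing visits treated as zero counts",
            sorted(observed_visits),
        )
    per_visit = counts.pivot_table(
        index="species", columns=["point", "visit"], values="count",
        aggfunc="sum", fill_value=0,
    )
    abundance = per_visit.T.groupby(level="point").max().T
    return abundance


def aggregate_habitats(
    composition: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Collapse a point x raw-class composition onto aggregated classes.

    Each aggregated class receives the summed proportions of its member
    classes; rows still sum to 1.
    """
    unknown = [c for c in composition.columns if c not in mapping]
    if unknown:
        raise ValueError(f"unknown habitat class label(s): {unknown}")
    sums = composition.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = composition.index[~np.isclose(sums, 1.0, atol=1e-6)].tolist()
        raise ValueError(f"compositions do not sum to 1 at points {bad[:5]}")
    agg = composition.T.groupby(composition.columns.map(mapping)).sum().T
    # keep a stable class order: first appearance in the mapping
    order = [c for c in dict.fromkeys(mapping.values()) if c in agg.columns]
    return agg[order]


def suitability_matrix(
    prefs: pd.DataFrame,
    aggregation_map: dict[str, str],
    aggregated_classes: list[str],
) -> pd.DataFrame:
    """Species x aggregated-class binary suitability.

    A species finds an aggregated class suitable if it prefers at least one
    source class mapping to it.
    """
    if not prefs.isin([0, 1]).all().all():
        raise ValueError("preference entries must be 0 or 1")
    if (prefs.sum(axis=1) < 1).any():
        empty = prefs.index[prefs.sum(axis=1) < 1].tolist()
        raise ValueError(f"species with no preferred class: {empty}")
    unknown = [c for c in prefs.columns if c not in aggregation_map]
    if unknown:
        raise ValueError(f"preference class(es) not in aggregation map: {unknown}")
    grouped = prefs.T.groupby(prefs.columns.map(aggregation_map)).max().T
    suit = pd.DataFrame(
        0, index=prefs.index, columns=aggregated_classes, dtype=int
    )
    suit[grouped.columns] = grouped.astype(int)
    return suit


def suitable_area_matrix(
    composition: pd.DataFrame,
    prefs: pd.DataFrame,
    aggregation_map: dict[str, str],
    point_area_ha: float = POINT_AREA_HA,
) -> pd.DataFrame:
    """Suitable habitat area (ha) for every (point, species) pair.

    ``composition`` is point x aggregated-class proportions; the suitable
    area at a point is the point area times the summed proportion of
    classes the species finds suitable.
    """
    suit = suitability_matrix(prefs, aggregation_map, list(composition.columns))
    area = composition.to_numpy() @ suit.to_numpy().T * point_area_ha
    return pd.DataFrame(area, index=composition.index, columns=prefs.index)


def suitable_area(
    composition: pd.Series,
    species_prefs: pd.Series,
    aggregation_map: dict[str, str],
    point_area_ha: float = POINT_AREA_HA,
) -> float:
    """Suitable area (ha) at a single point for a single species."""
    comp = composition.to_frame().T
    prefs = species_prefs.to_frame().T
    return float(
        suitable_area_matrix(comp, prefs, aggregation_map, point_area_ha).iloc[0, 0]
    )


def geographical_density(
    abundance: pd.DataFrame, n_points: int | None = None,
    point_area_ha: float = POINT_AREA_HA,
) -> pd.Series:
    """Individuals per hectare of total surveyed area, per species."""
    if n_points is None:
        n_points = abundance.shape[1]
    if n_points < 1:
        raise ValueError("at least one census point is required")
    return abundance.sum(axis=1) / (n_points * point_area_ha)


def ecological_density(
    abundance: pd.DataFrame,
    suitable: pd.DataFrame,
    mode: str = "presence",
    point_area_ha: float = POINT_AREA_HA,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Individuals per hectare of suitable habitat, per species.

    Parameters
    ----------
    abundance : DataFrame
        species x point abundance (visits already collapsed).
    suitable : DataFrame
        point x species suitable area in hectares.
    mode : {"presence", "all_points"}
        Denominator: suitable area summed over points where the species was
        recorded (default) or over every surveyed point.

    Returns
    -------
    (density, suitable_area_total, flags)
        Per-species density (ind/ha), the denominator used (ha), and a
        per-species flag frame.  A presence point with zero suitable
        habitat contributes its full area to the denominator (presence is
        itself evidence of suitability) and is flagged.  Species never
        recorded are dropped with a warning — their ecological density is
        undefined.

    Notes
    -----
    Both denominators are bounded by the total surveyed area, so
    ecological density >= geographical density always holds.
    """
    if mode not in ("presence", "all_points"):
        raise ValueError(f"unknown mode {mode!r}")
    suit = suitable.reindex(index=abundance.columns, columns=abundance.index)
    if suit.isna().any().any():
        raise ValueError("suitable-area matrix does not cover all points/species")

    totals = abundance.sum(axis=1)
    absent = totals.index[totals == 0]
    if len(absent):
        logger.warning(
            "%d species with zero total abundance dropped (ecological density "
            "undefined): %s", len(absent), list(absent[:5]),
        )
    kept = totals.index[totals > 0]

    ab = abundance.loc[kept].to_numpy()            # species x points
    sa = suit.to_numpy().T[[abundance.index.get_loc(s) for s in kept]]
    presence = ab > 0
    zero_suit_presence = presence & (sa <= 0)
    # presence where nothing is mapped as suitable: count the full point area
    sa_eff = np.where(zero_suit_presence, point_area_ha, sa)

    if mode == "presence":
        denom = (sa_eff * presence).sum(axis=1)
    else:
        denom = sa_eff.sum(axis=1)
    density = totals.loc[kept].to_numpy() / denom

    flags = pd.DataFrame(
        {
            "n_zero_suitable_presence": zero_suit_presence.sum(axis=1),
        },
        index=kept,
    )
    n_flagged = int((flags["n_zero_suitable_presence"] > 0).sum())
    if n_flagged:
        logger.warning(
            "%d species recorded at points with zero mapped suitable habitat; "
            "full point area used there", n_flagged,
        )
    return (
        pd.Series(density, index=kept, name="eco_density"),
        pd.Series(denom, index=kept, name="suitable_area_total"),
        flags,
    )


def density_table(
    counts: pd.DataFrame,
    composition: pd.DataFrame,
    prefs: pd.DataFrame,
    aggregation_map: dict[str, str],
    mode: str = "presence",
    point_area_ha: float = POINT_AREA_HA,
) -> pd.DataFrame:
    """End-to-end per-species density table from raw inputs.

    Returns a frame with ``total_count, n_presence_points,
    suitable_area_total, geo_density, eco_density, flags`` indexed by
    species (species never recorded are excluded).
    """
    abundance = collapse_visits(counts)
    abundance = abundance.reindex(columns=composition.index, fill_value=0)
    suitable = suitable_area_matrix(
        composition, prefs, aggregation_map, point_area_ha
    )
    geo = geographical_density(abundance, point_area_ha=point_area_ha)
    eco, denom, flags = ecological_density(
        abundance, suitable, mode=mode, point_area_ha=point_area_ha
    )
    out = pd.DataFrame(
        {
            "total_count": abundance.sum(axis=1).loc[eco.index].astype(int),
            "n_presence_points": (abundance > 0).sum(axis=1).loc[eco.index],
            "suitable_area_total": denom,
            "geo_density": geo.loc[eco.index],
            "eco_density": eco,
        }
    )
    out["flags"] = [
        f"zero_suitable_presence:{int(k)}" if k > 0 else ""
        for k in flags["n_zero_suitable_presence"]
    ]
    out.index.name = "species"
    return out
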