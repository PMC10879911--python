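"""Core data model for elevational-gradient occurrence analyses.

Occurrence records, site profiles and vegetation plots are carried as
:class:`pandas.DataFrame` objects with fixed column schemas (see the
``*_COLUMNS`` constants).  This module owns the elevation-band convention
(100-m half-open bands keyed by their lower bound), the effective-taxon
counting rule used for species richness, and the aggregation of vegetation
plot measurements into per-site covariates.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BAND_WIDTH",
    "OCCURRENCE_COLUMNS",
    "SITE_COLUMNS",
    "PLOT_COLUMNS",
    "SEASONS",
    "METHODS",
    "RANKS",
    "SUBORDERS",
    "STUDY_AREAS",
    "SchemaError",
    "assign_band",
    "read_occurrences",
    "read_sites",
    "read_vegetation_plots",
    "effective_taxa",
    "richness_per_site",
    "richness_per_band",
    "aggregate_vegetation",
    "build_richness_table",
    "circular_mean_deg",
]

BAND_WIDTH = 100

SEASONS = frozenset({"summer", "autumn", "spring"})
METHODS = frozenset({"net", "hand"})
RANKS = frozenset({"species", "higher"})
SUBORDERS = frozenset({"Caelifera", "Ensifera"})
STUDY_AREAS = frozenset({"TOR", "MOL", "TAV", "VFE"})

OCCURRENCE_COLUMNS = [
    "site_id",
    "visit_id",
    "season",
    "method",
    "taxon_id",
    "rank",
    "parent_taxon",
    "suborder",
    "life_stage",
    "count",
    "distinct_flag",
]

SITE_COLUMNS = [
    "site_id",
    "study_area",
    "elevation_band_lower",
    "veg_cover",
    "veg_max_height",
    "veg_height75",
    "veg_density",
    "slope",
    "aspect",
]

PLOT_COLUMNS = [
    "site_id",
    "visit_season",
    "max_height",
    "height75",
    "touch1",
    "touch2",
    "touch3",
    "touch4",
    "touch5",
    "cover_vegetation",
    "cover_rock",
    "cover_bare",
]

#: Tolerance for eye-estimated cover percentages summing over 100.
COVER_SUM_TOLERANCE = 5.0


class SchemaError(ValueError):
    """Raised when an input table violates its column schema or invariants."""


def assign_band(elevation: float) -> int:
    """Return the lower bound of the 100-m elevation band containing ``elevation``.

    Bands are half-open ``[lower, lower + 100)``: a site at 1650 m lies in
    the 1600–1700 m band and is keyed 1600; the lower edge is inclusive.

    Raises
    ------
    ValueError
        If ``elevation`` is negative or not finite.
    """
    if not math.isfinite(elevation):
        raise ValueError(f"elevation must be finite, got {elevation!r}")
    if elevation < 0:
        raise ValueError(f"elevation must be non-negative, got {elevation!r}")
    return int(math.floor(elevation / BAND_WIDTH) * BAND_WIDTH)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an occurrence table against the record invariants.

    Returns the validated frame (dtypes normalised).  Stored records must
    have ``count >= 1``; species-rank records must name a parent taxon.
    """
    _require_columns(df, OCCURRENCE_COLUMNS, "occurrence")
    df = df.copy()
    df["count"] = df["count"].astype(int)
    df["distinct_flag"] = df["distinct_flag"].astype(bool)
    df["parent_taxon"] = df["parent_taxon"].fillna("").astype(str)
    if (df["count"] < 1).any():
        bad = df.loc[df["count"] < 1, "taxon_id"].tolist()
        raise SchemaError(f"records with count < 1: {bad}")
    bad_method = set(df["method"]) - METHODS
    if bad_method:
        raise SchemaError(f"unknown survey methods: {sorted(bad_method)}")
    bad_rank = set(df["rank"]) - RANKS
    if bad_rank:
        raise SchemaError(f"unknown taxonomic ranks: {sorted(bad_rank)}")
    orphan = df[(df["rank"] == "species") & (df["parent_taxon"] == "")]
    if not orphan.empty:
        raise SchemaError(
            "species-rank records lacking parent_taxon: "
            f"{sorted(orphan['taxon_id'].unique())}"
        )
    return df


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a site table: 100-m band keys and percentage bounds."""
    _require_columns(df, ["site_id", "study_area", "elevation_band_lower"], "site")
    df = df.copy()
    df["elevation_band_lower"] = df["elevation_band_lower"].astype(int)
    if (df["elevation_band_lower"] % BAND_WIDTH != 0).any():
        bad = df.loc[df["elevation_band_lower"] % BAND_WIDTH != 0, "site_id"]
        raise SchemaError(
            f"elevation_band_lower not a multiple of {BAND_WIDTH}: {sorted(bad)}"
        )
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"]
        raise SchemaError(f"duplicate site_id rows: {sorted(dup)}")
    if "veg_cover" in df.columns:
        cover = df["veg_cover"].dropna()
        if ((cover < 0) | (cover > 100)).any():
            raise SchemaError("veg_cover outside [0, 100]")
    return df


def validate_vegetation_plots(df: pd.DataFrame) -> pd.DataFrame:
    """Validate vegetation plots: five rod counts present, covers plausible."""
    _require_columns(df, PLOT_COLUMNS, "vegetation plot")
    df = df.copy()
    touch_cols = [f"touch{i}" for i in range(1, 6)]
    if df[touch_cols].isna().any().any():
        bad = df.loc[df[touch_cols].isna().any(axis=1), "site_id"]
        raise SchemaError(f"missing rod counts for sites: {sorted(set(bad))}")
    if (df[touch_cols] < 0).any().any():
        raise SchemaError("negative rod touch counts")
    cover_sum = df[["cover_vegetation", "cover_rock", "cover_bare"]].sum(axis=1)
    over = cover_sum > 100 + COVER_SUM_TOLERANCE
    if over.any():
        raise SchemaError(
            "cover percentages exceed 100 beyond tolerance for sites: "
            f"{sorted(set(df.loc[over, 'site_id']))}"
        )
    return df


def read_occurrences(path) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(path, keep_default_na=False, na_values=[]))


def read_sites(path) -> pd.DataFrame:
    return validate_sites(pd.read_csv(path))


def read_vegetation_plots(path) -> pd.DataFrame:
    return validate_vegetation_plots(pd.read_csv(path))


def effective_taxa(records: pd.DataFrame) -> set[str]:
    """Taxa counted as species for richness, within one scope (site or band).

    All species-rank taxa count.  A higher-rank taxon counts as well when
    either no species-rank record in the scope belongs to it, or the record
    was flagged by the curator as clearly distinct from the species present.
    Records should already be pooled across all visits in the scope.
    """
    if records.empty:
        return set()
    species_mask = records["rank"] == "species"
    species = set(records.loc[species_mask, "taxon_id"])
    parents_with_species = set(records.loc[species_mask, "parent_taxon"])
    higher = records.loc[~species_mask]
    kept_higher = {
        row.taxon_id
        for row in higher.itertuples()
        if row.taxon_id not in parents_with_species or row.distinct_flag
    }
    return species | kept_higher


def richness_per_site(records: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """One row per site with its effective-taxon richness.

    Sites without records get richness 0.  Records referencing a site_id not
    present in ``sites`` are rejected.
    """
    known = set(sites["site_id"])
    orphans = set(records["site_id"]) - known
    if orphans:
        raise SchemaError(f"occurrence records reference unknown sites: {sorted(orphans)}")
    richness = {
        site: len(effective_taxa(group))
        for site, group in records.groupby("site_id", sort=False)
    }
    out = sites[["site_id"]].copy()
    out["richness"] = out["site_id"].map(richness).fillna(0).astype(int)
    return out


def richness_per_band(records: pd.DataFrame, sites: pd.DataFrame) -> pd.Series:
    """Effective-taxon count per elevation band (records pooled across the band)."""
    known = set(sites["site_id"])
    orphans = set(records["site_id"]) - known
    if orphans:
        raise SchemaError(f"occurrence records reference unknown sites: {sorted(orphans)}")
    band_of = sites.set_index("site_id")["elevation_band_lower"]
    tagged = records.assign(_band=records["site_id"].map(band_of))
    counts = {
        int(band): len(effective_taxa(group))
        for band, group in tagged.groupby("_band", sort=True)
    }
    return pd.Series(counts, name="richness", dtype=int).rename_axis("elevation_band_lower")


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, in [0, 360)."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    mean = math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
    deg = float(np.rad2deg(mean) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def aggregate_vegetation(plots: pd.DataFrame) -> pd.DataFrame:
    """Collapse vegetation plots to one covariate row per site.

    Per plot, density is the mean of the five rod touch counts; per site,
    each parameter is the arithmetic mean over all plots from all seasons.
    The covariates are kept separate (no combined structure index).
    """
    plots = validate_vegetation_plots(plots)
    touch_cols = [f"touch{i}" for i in range(1, 6)]
    work = plots.assign(density=plots[touch_cols].mean(axis=1))
    agg = (
        work.groupby("site_id", sort=True)
        .agg(
            veg_cover=("cover_vegetation", "mean"),
            veg_max_height=("max_height", "mean"),
            veg_height75=("height75", "mean"),
            veg_density=("density", "mean"),
        )
        .reset_index()
    )
    return agg


def build_richness_table(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    effort: pd.DataFrame | None = None,
    dropna: bool = True,
) -> pd.DataFrame:
    """Assemble the per-site modelling table: richness, covariates and effort.

    ``effort`` is an optional per-site table carrying ``se_value`` (see
    :mod:`elevgrad.effort`).  Rows with missing covariates are dropped with a
    warning rather than imputed (set ``dropna=False`` to keep them).
    """
    sites = validate_sites(sites)
    table = richness_per_site(records, sites).merge(sites, on="site_id", how="left")
    if effort is not None:
        table = table.merge(effort[["site_id", "se_value"]], on="site_id", how="left")
    if dropna:
        incomplete = table.isna().any(axis=1)
        if incomplete.any():
            dropped = sorted(table.loc[incomplete, "site_id"])
            warnings.warn(
                f"dropping {len(dropped)} site(s) with missing covariates: {dropped}",
                stacklevel=2,
            )
            table = table.loc[~incomplete].reset_index(drop=True)
    return table
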