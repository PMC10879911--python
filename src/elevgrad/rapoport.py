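"""Range–midpoint analysis of elevational ranges (Rapoport-effect test).

Each species' elevational range spans from the lower bound of its lowest
occupied 100-m band to the upper bound of its highest, so a single-band
species has a 100-m range; the midpoint is halfway along that span.  Range
is regressed on midpoint with ordinary-least-squares polynomials up to a
configurable order, compared by Gaussian AIC, adjusted R² and nested
F-tests.  Band-wise (Stevens) and upper-extreme (Pagel) estimators are
provided as comparators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_data import BAND_WIDTH
from .richness_model import DevianceTest

__all__ = [
    "PolyFit",
    "filter_species_level",
    "remove_singletons",
    "species_elevational_range",
    "fit_polynomials",
    "select_model",
    "stevens_estimate",
    "pagel_estimate",
]


def filter_species_level(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only records identified to species rank."""
    return records.loc[records["rank"] == "species"].reset_index(drop=True)


def remove_singletons(records: pd.DataFrame) -> pd.DataFrame:
    """Drop every record of species represented by a single individual in total."""
    totals = records.groupby("taxon_id")["count"].sum()
    singletons = set(totals.index[totals == 1])
    return records.loc[~records["taxon_id"].isin(singletons)].reset_index(drop=True)


def species_elevational_range(
    records: pd.DataFrame, sites: pd.DataFrame
) -> pd.DataFrame:
    """Per-species band extent, elevational range (m) and range midpoint (m).

    range_m = (highest occupied band + 100) − lowest occupied band, so a
    species confined to one band gets 100 m; midpoint_m is halfway between
    the extremes of that span.  The surveyed elevation window is attached as
    frame ``attrs`` so boundary-touching species can be flagged downstream.
    """
    band_of = sites.set_index("site_id")["elevation_band_lower"]
    unknown = set(records["site_id"]) - set(band_of.index)
    if unknown:
        raise ValueError(f"records reference unknown sites: {sorted(unknown)}")
    work = records.assign(_band=records["site_id"].map(band_of))
    rows = []
    for taxon, group in work.groupby("taxon_id", sort=True):
        lo = int(group["_band"].min())
        hi = int(group["_band"].max())
        range_m = hi + BAND_WIDTH - lo
        rows.append(
            {
                "species_id": taxon,
                "n_records": int(group["count"].sum()),
                "min_band": lo,
                "max_band": hi,
                "range_m": range_m,
                "midpoint_m": (lo + hi + BAND_WIDTH) / 2.0,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["species_id", "n_records", "min_band", "max_band", "range_m", "midpoint_m"],
    )
    out.attrs["surveyed_window"] = (
        (int(sites["elevation_band_lower"].min()), int(sites["elevation_band_lower"].max()) + BAND_WIDTH)
        if len(sites)
        else None
    )
    return out


@dataclass(frozen=True)
class PolyFit:
    """One ordinary-least-squares polynomial fit of range on midpoint.

    ``coefficients`` are on the original predictor scale in ascending order
    (intercept first).  AIC uses the Gaussian likelihood with the error
    variance counted as a fitted parameter:
    AIC = n·ln(RSS/n) + n·ln(2π) + n + 2·(order + 2).
    """

    order: int
    coefficients: tuple[float, ...]
    rss: float
    aic: float
    adj_r2: float
    n: int
    residual_df: int

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": list(self.coefficients),
            "rss": self.rss,
            "aic": self.aic,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "residual_df": self.residual_df,
        }


def gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """AIC of an OLS fit under Gaussian errors, sigma counted as a parameter."""
    return n * np.log(rss / n) + n * np.log(2 * np.pi) + n + 2 * (n_coef + 1)


def _fit_one(x: np.ndarray, y: np.ndarray, order: int) -> PolyFit:
    n = x.size
    # fit in the mapped [-1, 1] domain for conditioning; report raw-scale coefficients
    if np.unique(x).size < order + 1:
        raise np.linalg.LinAlgError(f"rank-deficient design for polynomial order {order}")
    series = np.polynomial.Polynomial.fit(x, y, deg=order)
    coefs = tuple(float(c) for c in series.convert().coef)
    resid = y - series(x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - order - 1)
    return PolyFit(
        order=order,
        coefficients=coefs,
        rss=rss,
        aic=float(gaussian_aic(rss, n, order + 1)),
        adj_r2=float(adj),
        n=n,
        residual_df=n - (order + 1),
    )


def fit_polynomials(
    midpoints, ranges, max_order: int = 4
) -> list[PolyFit]:
    """OLS polynomial fits of range on midpoint for orders 1..max_order."""
    x = np.asarray(midpoints, dtype=float)
    y = np.asarray(ranges, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("midpoints and ranges must be equal-length 1-d vectors")
    if x.size <= max_order + 1:
        raise ValueError(f"need more than {max_order + 1} points for order {max_order}")
    return [_fit_one(x, y, order) for order in range(1, max_order + 1)]


def select_model(fits: list[PolyFit]) -> tuple[PolyFit, list[DevianceTest]]:
    """Pick the minimum-AIC fit and compare consecutive orders by nested F-tests.

    Adjusted R² is used as corroboration; a disagreement between the two
    criteria is logged as a warning (AIC wins).
    """
    fits = sorted(fits, key=lambda f: f.order)
    best = min(fits, key=lambda f: f.aic)
    best_adj = max(fits, key=lambda f: f.adj_r2)
    if best_adj.order != best.order:
        warnings.warn(
            f"AIC prefers order {best.order} but adjusted R2 prefers order "
            f"{best_adj.order}; selecting by AIC",
            stacklevel=2,
        )
    comparisons = []
    for low, high in zip(fits, fits[1:]):
        dp = high.order - low.order
        f = ((low.rss - high.rss) / dp) / (high.rss / high.residual_df)
        f = max(f, 0.0)
        p = float(scipy.stats.f.sf(f, dp, high.residual_df))
        comparisons.append(
            DevianceTest(
                term_tested=f"order{high.order}_vs_order{low.order}",
                f_value=float(f),
                df_num=dp,
                df_den=high.residual_df,
                p_value=p,
            )
        )
    return best, comparisons


def stevens_estimate(ranges: pd.DataFrame) -> pd.Series:
    """Mean range of the species present in each band (band-wise comparator).

    A species is present in every band its [min_band, max_band] extent
    covers.  Bands with no species are absent from the result.
    """
    if ranges.empty:
        return pd.Series(dtype=float, name="mean_range_m").rename_axis("elevation_band_lower")
    lo = int(ranges["min_band"].min())
    hi = int(ranges["max_band"].max())
    out = {}
    for band in range(lo, hi + BAND_WIDTH, BAND_WIDTH):
        present = ranges[(ranges["min_band"] <= band) & (ranges["max_band"] >= band)]
        if len(present):
            out[band] = float(present["range_m"].mean())
    return pd.Series(out, name="mean_range_m").rename_axis("elevation_band_lower")


def pagel_estimate(ranges: pd.DataFrame) -> dict:
    """OLS regression of range on the upper extreme of each species' range.

    Returns slope, intercept, and p-value for the slope.  Requires at least
    three species and a non-degenerate predictor.
    """
    if len(ranges) < 3:
        raise ValueError("need at least 3 species")
    x = (ranges["max_band"] + BAND_WIDTH).to_numpy(dtype=float)
    y = ranges["range_m"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all species share the same maximum elevation; no predictor variance")
    res = scipy.stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
        "r_value": float(res.rvalue),
        "n": int(len(ranges)),
    }
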