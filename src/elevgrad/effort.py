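"""Sampling-effort standardisation for mixed net/hand transect surveys.

The effort index expresses a site's total sampling in equivalent net-survey
units: SE = surveys_net + total_obs_hand / mean_obs_net.  The second term
converts hand-caught specimens into the number of net surveys that would
have caught as many.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_data import validate_occurrences

__all__ = ["EffortIndex", "UndefinedEffortError", "sampling_effort", "effort_from_records"]


class UndefinedEffortError(ValueError):
    """Effort index undefined (no net surveys, or hand captures with zero net catch)."""


@dataclass(frozen=True)
class EffortIndex:
    """Per-site effort components and the standardised effort value."""

    site_id: str
    surveys_net: int
    total_obs_hand: int
    mean_obs_net: float
    se_value: float


def sampling_effort(
    surveys_net: int,
    total_obs_hand: int,
    mean_obs_net: float,
    site_id: str = "<unknown>",
) -> float:
    """SE = surveys_net + total_obs_hand / mean_obs_net.

    With no hand captures the index equals the net survey count regardless
    of ``mean_obs_net``.  Hand captures at a site whose net surveys caught
    nothing leave the conversion undefined.
    """
    if surveys_net < 1:
        raise UndefinedEffortError(
            f"site {site_id}: effort undefined without at least one net survey"
        )
    if total_obs_hand < 0 or mean_obs_net < 0:
        raise ValueError(f"site {site_id}: negative effort components")
    if total_obs_hand == 0:
        return float(surveys_net)
    if mean_obs_net == 0:
        raise UndefinedEffortError(
            f"site {site_id}: hand captures present but mean net catch is zero"
        )
    return float(surveys_net + total_obs_hand / mean_obs_net)


def effort_from_records(
    records: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    visits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the per-site effort index from occurrence records.

    A survey is one distinct (site_id, visit_id, method) pass.  Surveys are
    inferred from the records unless a ``visits`` registry (columns site_id,
    visit_id, method) is supplied, in which case zero-capture net surveys
    are counted too.  If ``sites`` is given, every site must end up with at
    least one net survey.

    Returns a frame with columns site_id, surveys_net, total_obs_hand,
    mean_obs_net, se_value.
    """
    records = validate_occurrences(records)
    if visits is not None:
        surveys = visits[["site_id", "visit_id", "method"]].drop_duplicates()
        logged = set(map(tuple, surveys.to_numpy()))
        seen = set(
            map(tuple, records[["site_id", "visit_id", "method"]].drop_duplicates().to_numpy())
        )
        unlogged = seen - logged
        if unlogged:
            raise ValueError(f"records from surveys missing in the visit registry: {sorted(unlogged)}")
    else:
        surveys = records[["site_id", "visit_id", "method"]].drop_duplicates()

    site_ids = (
        sorted(sites["site_id"]) if sites is not None else sorted(surveys["site_id"].unique())
    )
    net_surveys = (
        surveys[surveys["method"] == "net"].groupby("site_id")["visit_id"].nunique()
    )
    catch = records.groupby(["site_id", "method"])["count"].sum()

    rows = []
    for site in site_ids:
        n_net = int(net_surveys.get(site, 0))
        if n_net == 0:
            raise UndefinedEffortError(f"site {site}: no net surveys, effort undefined")
        total_net = int(catch.get((site, "net"), 0))
        total_hand = int(catch.get((site, "hand"), 0))
        mean_net = total_net / n_net
        rows.append(
            EffortIndex(
                site_id=site,
                surveys_net=n_net,
                total_obs_hand=total_hand,
                mean_obs_net=mean_net,
                se_value=sampling_effort(n_net, total_hand, mean_net, site_id=site),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
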