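import pandas as pd
import pytest

from elevgrad.synthetic import ScenarioConfig, generate_community


def occ_row(
    site_id,
    taxon_id,
    rank="species",
    parent_taxon="G1",
    count=1,
    visit_id="v1",
    method="net",
    season="summer",
    suborder="Caelifera",
    life_stage="adult",
    distinct_flag=False,
):
    return {
        "site_id": site_id,
        "visit_id": visit_id,
        "season": season,
        "method": method,
        "taxon_id": taxon_id,
        "rank": rank,
        "parent_taxon": parent_taxon if rank == "species" else "",
        "suborder": suborder,
        "life_stage": life_stage,
        "count": count,
        "distinct_flag": distinct_flag,
    }


def occ_frame(rows):
    return pd.DataFrame([occ_row(**r) if isinstance(r, dict) else r for r in rows])


def site_row(site_id, band, study_area="TOR", **kw):
    row = {
        "site_id": site_id,
        "study_area": study_area,
        "elevation_band_lower": band,
        "veg_cover": 80.0,
        "veg_max_height": 40.0,
        "veg_height75": 28.0,
        "veg_density": 4.0,
        "slope": 20.0,
        "aspect": 180.0,
    }
    row.update(kw)
    return row


def sites_frame(pairs):
    """pairs: iterable of (site_id, band) or dicts."""
    rows = [site_row(*p) if not isinstance(p, dict) else site_row(**p) for p in pairs]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_community():
    """One default-scenario community shared across tests (seed fixed)."""
    config = ScenarioConfig()
    occ, sites, visits, truth = generate_community(config, seed=7)
    return {"config": config, "occurrences": occ, "sites": sites,
            "visits": visits, "truth": truth}
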