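"""Synthetic occurrence, site, visit and vegetation-plot generation.

Communities are simulated with the statistical structure the downstream
analyses assume: species occupy hard elevational intervals whose breadth is
a configurable function of the range midpoint (linear, quadratic hump, or
constant), detected counts are negative-binomially overdispersed, survey
effort increases with elevation, and vegetation covariates decline with
elevation.  Ground truth (true midpoints, breadths, occupied bands and the
generating coefficients) is returned alongside so parameter recovery can be
verified end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core_data import BAND_WIDTH

__all__ = ["ScenarioConfig", "GroundTruth", "generate_community", "generate_vegetation_plots"]

#: Default site layout mirroring a 28-site, 3-main-area stratified design:
#: (study_area, elevation_band_lower) pairs.
DEFAULT_SITE_LAYOUT: tuple[tuple[str, int], ...] = (
    tuple(("TOR", b) for b in range(1200, 2200, 100))        # 10 sites
    + tuple(("MOL", b) for b in range(1800, 2600, 100))      # 8 sites
    + tuple(("TAV", b) for b in range(1500, 2200, 100))      # 7 sites
    + (("VFE", 1100), ("VFE", 1200), ("VFE", 1200))          # 3 valley sites
)


def _default_hump_coefficients() -> tuple[float, float, float]:
    # breadth peaking at 1800 m (900 m) and falling to ~200 m at the window edges
    c2 = -700.0 / 490_000.0
    c1 = -2 * 1800.0 * c2
    c0 = 900.0 + c2 * 1800.0**2
    return (c0, c1, c2)


@dataclass
class ScenarioConfig:
    """Parameters of a simulated survey campaign.

    ``range_model`` controls the true breadth-vs-midpoint relationship used
    to place species: ``rapoport_linear`` (breadth = c0 + c1·midpoint),
    ``hump_quadratic`` (c0 + c1·m + c2·m²) or ``constant`` (c0).
    """

    bands: tuple[int, ...] = tuple(range(1100, 2600, 100))
    site_layout: tuple[tuple[str, int], ...] = DEFAULT_SITE_LAYOUT
    n_species: int = 37
    n_genera: int = 12
    range_model: str = "hump_quadratic"
    range_coefficients: tuple[float, ...] = field(default_factory=_default_hump_coefficients)
    range_noise_sd: float = 150.0
    abundance_meanlog: float = -1.4
    abundance_sdlog: float = 2.1
    detection_rate: float = 0.9
    hand_rate_factor: float = 0.35
    nb_dispersion_k: float = 2.0
    site_abundance_decline: float = 0.18   # per 100 m of elevation above the lowest band
    net_surveys_base: float = 3.0
    net_surveys_elev_slope: float = 0.3    # extra net surveys per 100 m
    net_surveys_range: tuple[int, int] = (3, 8)
    hand_surveys_range: tuple[int, int] = (2, 3)
    higher_taxon_fraction: float = 0.6
    distinct_flag_prob: float = 0.1
    singleton_fraction: float = 7 / 37     # calibration target, not enforced per draw
    soft_occupancy: bool = False
    soft_occupancy_sd: float = 250.0
    veg_cover_intercept: float = 95.0
    veg_cover_slope: float = -4.0          # per 100 m
    veg_height_intercept: float = 70.0
    veg_height_slope: float = -3.5         # per 100 m
    covariate_noise_sd: float = 6.0
    plot_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if any(b % BAND_WIDTH for b in self.bands):
            raise ValueError("bands must be multiples of 100")
        if list(self.bands) != sorted(self.bands):
            raise ValueError("bands must be sorted ascending")
        if self.range_model not in {"rapoport_linear", "hump_quadratic", "constant"}:
            raise ValueError(f"unknown range_model {self.range_model!r}")
        for name in ("detection_rate", "nb_dispersion_k", "higher_taxon_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("bands", "range_coefficients", "net_surveys_range", "hand_surveys_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "site_layout" in raw:
            raw["site_layout"] = tuple((str(a), int(b)) for a, b in raw["site_layout"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """The generating process behind one simulated community."""

    species_midpoint: dict[str, float]
    species_breadth: dict[str, float]
    species_bands: dict[str, tuple[int, ...]]
    site_taxa: dict[str, tuple[str, ...]]
    range_model: str
    range_coefficients: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "species_midpoint": self.species_midpoint,
            "species_breadth": self.species_breadth,
            "species_bands": {k: list(v) for k, v in self.species_bands.items()},
            "site_taxa": {k: list(v) for k, v in self.site_taxa.items()},
            "range_model": self.range_model,
            "range_coefficients": list(self.range_coefficients),
        }


def true_breadth(config: ScenarioConfig, midpoint: float) -> float:
    """Noise-free breadth implied by the configured range model."""
    c = config.range_coefficients
    if config.range_model == "constant":
        return float(c[0])
    if config.range_model == "rapoport_linear":
        return float(c[0] + c[1] * midpoint)
    return float(c[0] + c[1] * midpoint + c[2] * midpoint**2)


def _nb_draw(rng: np.random.Generator, mean: float, k: float) -> int:
    """Negative binomial with mean ``mean`` and shape ``k`` (Poisson-gamma)."""
    if mean <= 0:
        return 0
    return int(rng.negative_binomial(k, k / (k + mean)))


def _sample_species(config: ScenarioConfig, rng: np.random.Generator):
    lo = config.bands[0]
    hi = config.bands[-1] + BAND_WIDTH
    species = []
    for i in range(config.n_species):
        sp = f"sp{i + 1:02d}"
        for _ in range(200):
            mid = float(rng.uniform(lo, hi))
            breadth = true_breadth(config, mid) + float(rng.normal(0, config.range_noise_sd))
            if breadth > 0:
                break
        else:
            breadth = float(BAND_WIDTH)
        occupied = tuple(
            b for b in config.bands
            if b + BAND_WIDTH > mid - breadth / 2 and b < mid + breadth / 2
        )
        if not occupied:  # interval fell between band edges; occupy nearest band
            nearest = min(config.bands, key=lambda b: abs(b + BAND_WIDTH / 2 - mid))
            occupied = (nearest,)
        abundance = float(rng.lognormal(config.abundance_meanlog, config.abundance_sdlog))
        species.append((sp, mid, breadth, occupied, abundance))
    return species


def generate_community(
    config: ScenarioConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one survey campaign.

    Returns (occurrences, sites, visits, ground_truth).  Identical
    seed + config give identical frames.
    """
    rng = np.random.default_rng(seed)
    lo_band = config.bands[0]

    # --- sites and covariates -------------------------------------------
    site_rows = []
    counters: dict[tuple[str, int], int] = {}
    for area, band in config.site_layout:
        counters[(area, band)] = counters.get((area, band), 0) + 1
        suffix = chr(ord("a") + counters[(area, band)] - 1)
        site_id = f"{area}_{band}{suffix}"
        steps = (band - lo_band) / BAND_WIDTH
        cover = np.clip(
            config.veg_cover_intercept
            + config.veg_cover_slope * steps
            + rng.normal(0, config.covariate_noise_sd),
            0, 100,
        )
        max_h = max(
            config.veg_height_intercept
            + config.veg_height_slope * steps
            + rng.normal(0, config.covariate_noise_sd),
            2.0,
        )
        site_rows.append(
            {
                "site_id": site_id,
                "study_area": area,
                "elevation_band_lower": band,
                "veg_cover": round(float(cover), 2),
                "veg_max_height": round(float(max_h), 2),
                "veg_height75": round(float(max_h) * 0.7 + float(rng.normal(0, 2)), 2),
                "veg_density": round(max(float(max_h) * 0.12 + float(rng.normal(0, 0.8)), 0.0), 2),
                "slope": round(float(np.clip(rng.normal(20 + steps, 6), 0, 60)), 2),
                "aspect": round(float(rng.uniform(0, 360)), 1),
            }
        )
    sites = pd.DataFrame(site_rows)

    # --- species pool ----------------------------------------------------
    species = _sample_species(config, rng)
    genus_of = {
        sp: f"Genus{int(rng.integers(config.n_genera)) + 1:02d}" for sp, *_ in species
    }
    genera = sorted(set(genus_of.values()))
    suborder_of_genus = {
        g: ("Caelifera" if rng.random() < 0.75 else "Ensifera") for g in genera
    }

    # --- surveys ---------------------------------------------------------
    visit_rows = []
    for row in site_rows:
        steps = (row["elevation_band_lower"] - lo_band) / BAND_WIDTH
        n_net = int(np.clip(
            round(config.net_surveys_base + config.net_surveys_elev_slope * steps
                  + rng.normal(0, 0.7)),
            *config.net_surveys_range,
        ))
        n_hand = int(rng.integers(config.hand_surveys_range[0], config.hand_surveys_range[1] + 1))
        for k in range(n_net):
            visit_rows.append({
                "site_id": row["site_id"],
                "visit_id": f"{row['site_id']}_n{k + 1}",
                "season": "summer" if k % 2 == 0 else "autumn",
                "method": "net",
            })
        for k in range(n_hand):
            visit_rows.append({
                "site_id": row["site_id"],
                "visit_id": f"{row['site_id']}_h{k + 1}",
                "season": "summer" if k % 2 == 0 else "autumn",
                "method": "hand",
            })
    visits = pd.DataFrame(visit_rows)

    # --- detections ------------------------------------------------------
    occ_rows = []
    site_taxa: dict[str, list[str]] = {row["site_id"]: [] for row in site_rows}
    for row in site_rows:
        band = row["elevation_band_lower"]
        steps = (band - lo_band) / BAND_WIDTH
        site_factor = float(np.exp(-config.site_abundance_decline * steps))
        elev_mid = band + BAND_WIDTH / 2
        site_visits = [v for v in visit_rows if v["site_id"] == row["site_id"]]
        for sp, mid, breadth, occupied, abundance in species:
            if config.soft_occupancy:
                suitability = float(
                    np.exp(-((elev_mid - mid) ** 2) / (2 * config.soft_occupancy_sd**2))
                )
            else:
                suitability = 1.0 if band in occupied else 0.0
            if suitability <= 0:
                continue
            site_taxa[row["site_id"]].append(sp)
            for visit in site_visits:
                rate = config.detection_rate * (
                    config.hand_rate_factor if visit["method"] == "hand" else 1.0
                )
                mean = abundance * rate * site_factor * suitability
                caught = _nb_draw(rng, mean, config.nb_dispersion_k)
                if caught == 0:
                    continue
                n_higher = int(rng.binomial(caught, config.higher_taxon_fraction))
                n_species_level = caught - n_higher
                genus = genus_of[sp]
                suborder = suborder_of_genus[genus]
                stage = "adult" if rng.random() < 0.4 else "nymph"
                if n_species_level:
                    occ_rows.append({
                        "site_id": row["site_id"], "visit_id": visit["visit_id"],
                        "season": visit["season"], "method": visit["method"],
                        "taxon_id": sp, "rank": "species", "parent_taxon": genus,
                        "suborder": suborder, "life_stage": stage,
                        "count": n_species_level, "distinct_flag": False,
                    })
                if n_higher:
                    occ_rows.append({
                        "site_id": row["site_id"], "visit_id": visit["visit_id"],
                        "season": visit["season"], "method": visit["method"],
                        "taxon_id": genus, "rank": "higher", "parent_taxon": "",
                        "suborder": suborder, "life_stage": stage,
                        "count": n_higher,
                        "distinct_flag": bool(rng.random() < config.distinct_flag_prob),
                    })
    occurrences = pd.DataFrame(
        occ_rows,
        columns=[
            "site_id", "visit_id", "season", "method", "taxon_id", "rank",
            "parent_taxon", "suborder", "life_stage", "count", "distinct_flag",
        ],
    )
    truth = GroundTruth(
        species_midpoint={sp: mid for sp, mid, *_ in species},
        species_breadth={sp: breadth for sp, _, breadth, *_ in species},
        species_bands={sp: occupied for sp, _, _, occupied, _ in species},
        site_taxa={k: tuple(v) for k, v in site_taxa.items()},
        range_model=config.range_model,
        range_coefficients=tuple(config.range_coefficients),
    )
    return occurrences, sites, visits, truth


def generate_vegetation_plots(
    config: ScenarioConfig, sites: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Six plot rows per site (three per season) around the site's latent values.

    With ``plot_noise_sd = 0`` aggregation recovers the site covariates
    exactly (rod touch counts are then emitted as the latent density rather
    than integer draws).
    """
    rng = np.random.default_rng(seed)
    sd = config.plot_noise_sd
    rows = []
    for site in sites.itertuples():
        for season in ("summer", "autumn"):
            for _ in range(3):
                max_h = max(site.veg_max_height + rng.normal(0, sd), 0.5)
                h75 = max(site.veg_height75 + rng.normal(0, sd), 0.5)
                if sd == 0:
                    max_h, h75 = site.veg_max_height, site.veg_height75
                    touches = [site.veg_density] * 5
                else:
                    touches = [int(rng.poisson(max(site.veg_density, 0.0))) for _ in range(5)]
                cover_veg = float(np.clip(site.veg_cover + rng.normal(0, sd), 0, 100))
                if sd == 0:
                    cover_veg = site.veg_cover
                rock = float(rng.uniform(0, 100 - cover_veg))
                bare = max(100 - cover_veg - rock, 0.0)
                rows.append({
                    "site_id": site.site_id,
                    "visit_season": season,
                    "max_height": round(max_h, 2),
                    "height75": round(h75, 2),
                    **{f"touch{i + 1}": t for i, t in enumerate(touches)},
                    "cover_vegetation": round(cover_veg, 2),
                    "cover_rock": round(rock, 2),
                    "cover_bare": round(bare, 2),
                })
    return pd.DataFrame(rows)
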