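import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from elevgrad.rapoport import (
    fit_polynomials,
    filter_species_level,
    gaussian_aic,
    pagel_estimate,
    remove_singletons,
    select_model,
    species_elevational_range,
    stevens_estimate,
)

from conftest import occ_frame, sites_frame


def bands_to_records(band_sets):
    """Build records + sites where species k occupies exactly band_sets[k]."""
    occ_rows, site_rows, seen = [], [], set()
    for sp, bands in band_sets.items():
        for band in bands:
            site = f"s{band}"
            if site not in seen:
                seen.add(site)
                site_rows.append((site, band))
            occ_rows.append(dict(site_id=site, taxon_id=sp, parent_taxon="G"))
    return occ_frame(occ_rows), sites_frame(site_rows)


def brute_force_ranges(records, sites):
    """Independent oracle: enumerate occupied bands per species with plain loops."""
    band_of = dict(zip(sites["site_id"], sites["elevation_band_lower"]))
    occupied: dict[str, set] = {}
    counts: dict[str, int] = {}
    for row in records.to_dict(orient="records"):
        occupied.setdefault(row["taxon_id"], set()).add(band_of[row["site_id"]])
        counts[row["taxon_id"]] = counts.get(row["taxon_id"], 0) + row["count"]
    out = {}
    for sp, bands in occupied.items():
        lo, hi = min(bands), max(bands)
        out[sp] = {
            "range_m": hi + 100 - lo,
            "midpoint_m": (lo + (hi + 100)) / 2,
            "n_records": counts[sp],
        }
    return out


class TestFilters:
    def test_higher_rank_dropped(self):
        records = occ_frame([
            dict(site_id="s1", taxon_id="spA"),
            dict(site_id="s1", taxon_id="G", rank="higher"),
        ])
        out = filter_species_level(records)
        assert list(out["taxon_id"]) == ["spA"]

    def test_all_species_identity(self):
        records = occ_frame([dict(site_id="s1", taxon_id=f"sp{i}") for i in range(5)])
        pd.testing.assert_frame_equal(filter_species_level(records), records)

    def test_singletons_removed(self):
        records = occ_frame(
            [dict(site_id="s1", taxon_id="common", count=3),
             dict(site_id="s1", taxon_id="rare", count=1)]
        )
        out = remove_singletons(records)
        assert set(out["taxon_id"]) == {"common"}

    def test_split_counts_not_singleton(self):
        # two records of one individual each: total 2, kept
        records = occ_frame([
            dict(site_id="s1", taxon_id="spA", visit_id="v1", count=1),
            dict(site_id="s2", taxon_id="spA", visit_id="v2", count=1),
        ])
        assert len(remove_singletons(records)) == 2

    def test_no_singletons_identity(self):
        records = occ_frame([dict(site_id="s1", taxon_id="spA", count=2)])
        pd.testing.assert_frame_equal(remove_singletons(records), records)

    def test_all_singletons_empty(self):
        records = occ_frame([dict(site_id="s1", taxon_id=f"sp{i}", count=1)
                             for i in range(4)])
        assert remove_singletons(records).empty


class TestSpeciesRange:
    def test_single_band(self):
        occ, sites = bands_to_records({"spA": [1400]})
        out = species_elevational_range(occ, sites).iloc[0]
        assert out["range_m"] == 100
        assert out["midpoint_m"] == 1450.0

    def test_full_span(self):
        occ, sites = bands_to_records({"spA": list(range(1100, 2600, 100))})
        out = species_elevational_range(occ, sites).iloc[0]
        assert out["range_m"] == 1500

    def test_two_band_gap(self):
        occ, sites = bands_to_records({"spA": [1600, 2000]})
        out = species_elevational_range(occ, sites).iloc[0]
        assert out["range_m"] == 500
        assert out["midpoint_m"] == 1850.0

    def test_surveyed_window_metadata(self):
        occ, sites = bands_to_records({"spA": [1400, 1800]})
        out = species_elevational_range(occ, sites)
        assert out.attrs["surveyed_window"] == (1400, 1900)

    def test_unknown_site_rejected(self):
        occ = occ_frame([dict(site_id="ghost", taxon_id="spA")])
        with pytest.raises(ValueError, match="ghost"):
            species_elevational_range(occ, sites_frame([("s1", 1200)]))

    def test_brute_force_oracle_random_communities(self):
        rng = np.random.default_rng(21)
        bands = list(range(1100, 2600, 100))
        for _ in range(200):
            band_sets = {
                f"sp{i}": sorted(rng.choice(bands, size=rng.integers(1, 6), replace=False))
                for i in range(rng.integers(1, 8))
            }
            occ, sites = bands_to_records(band_sets)
            got = species_elevational_range(occ, sites).set_index("species_id")
            want = brute_force_ranges(occ, sites)
            for sp, expect in want.items():
                assert got.loc[sp, "range_m"] == expect["range_m"]
                assert got.loc[sp, "midpoint_m"] == expect["midpoint_m"]
                assert got.loc[sp, "n_records"] == expect["n_records"]

    def test_algebraic_identities(self):
        rng = np.random.default_rng(22)
        bands = list(range(1100, 2600, 100))
        band_sets = {
            f"sp{i}": sorted(rng.choice(bands, size=rng.integers(1, 10), replace=False))
            for i in range(12)
        }
        occ, sites = bands_to_records(band_sets)
        out = species_elevational_range(occ, sites)
        assert (out["range_m"] >= 100).all()
        assert (out["range_m"] % 100 == 0).all()
        assert (out["midpoint_m"] - out["min_band"] == out["range_m"] / 2).all()
        assert (out["midpoint_m"] - 50 >= out["min_band"]).all()
        assert (out["midpoint_m"] + 50 <= out["max_band"] + 100).all()

    def test_removing_records_never_grows_range(self):
        occ, sites = bands_to_records({"spA": [1200, 1500, 2100]})
        full = species_elevational_range(occ, sites).iloc[0]["range_m"]
        for idx in occ.index:
            sub = species_elevational_range(occ.drop(index=idx), sites).iloc[0]
            assert sub["range_m"] <= full


class TestPolynomials:
    def test_linear_truth_selects_order_one(self):
        rng = np.random.default_rng(30)
        x = rng.uniform(0, 10, 50)
        y = 2 * x + 1 + rng.normal(0, 1, 50)
        fits = fit_polynomials(x, y)
        best = min(fits, key=lambda f: f.aic)
        assert best.order == 1
        # independent OLS oracle for the linear coefficients
        slope, intercept = np.polyfit(x, y, 1)
        assert fits[0].coefficients[1] == pytest.approx(slope, rel=1e-8)
        assert fits[0].coefficients[0] == pytest.approx(intercept, rel=1e-8)

    def test_quadratic_truth_selects_order_two(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(1100, 2600, 40)
        y = 900 - 0.0014 * (x - 1800) ** 2 + rng.normal(0, 50, 40)
        fits = fit_polynomials(x, y)
        best = min(fits, key=lambda f: f.aic)
        assert best.order == 2
        assert max(fits, key=lambda f: f.adj_r2).order == 2

    def test_rss_nested_monotone(self):
        rng = np.random.default_rng(32)
        x = rng.uniform(0, 1, 25)
        y = rng.normal(size=25)
        fits = fit_polynomials(x, y)
        for low, high in zip(fits, fits[1:]):
            assert high.rss <= low.rss + 1e-9

    def test_aic_and_adj_r2_closed_form(self):
        rng = np.random.default_rng(33)
        x = rng.uniform(0, 5, 30)
        y = x + rng.normal(0, 0.5, 30)
        for fit in fit_polynomials(x, y):
            resid = y - np.polynomial.polynomial.polyval(x, fit.coefficients)
            rss = float(resid @ resid)
            n, k = 30, fit.order + 1
            assert fit.rss == pytest.approx(rss, rel=1e-8)
            assert fit.aic == pytest.approx(
                n * np.log(rss / n) + n * np.log(2 * np.pi) + n + 2 * (k + 1), rel=1e-10
            )
            r2 = 1 - rss / np.sum((y - y.mean()) ** 2)
            assert fit.adj_r2 == pytest.approx(
                1 - (1 - r2) * (n - 1) / (n - fit.order - 1), rel=1e-10
            )
            assert fit.residual_df == n - k

    def test_aic_matches_gaussian_loglik(self):
        # AIC = 2k - 2 logLik with sigma^2 = RSS/n counted as a parameter
        rss, n, k = 123.4, 30, 3
        loglik = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
        assert gaussian_aic(rss, n, k) == pytest.approx(2 * (k + 1) - 2 * loglik)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            fit_polynomials([1, 2, 3], [1, 2, 3], max_order=4)

    def test_rank_deficient_rejected(self):
        x = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])  # 4 distinct values cannot fit order 4
        y = np.arange(8, dtype=float)
        with pytest.raises(np.linalg.LinAlgError, match="order 4"):
            fit_polynomials(x, y, max_order=4)


class TestSelectModel:
    def test_argmin_aic(self):
        rng = np.random.default_rng(34)
        x = rng.uniform(0, 10, 40)
        y = 3 * x + rng.normal(0, 1, 40)
        fits = fit_polynomials(x, y)
        best, comparisons = select_model(fits)
        assert best.aic == min(f.aic for f in fits)
        assert len(comparisons) == 3

    def test_nested_f_formula(self):
        rng = np.random.default_rng(35)
        x = rng.uniform(0, 10, 40)
        y = x**2 + rng.normal(0, 3, 40)
        fits = fit_polynomials(x, y)
        _, comparisons = select_model(fits)
        lin, quad = fits[0], fits[1]
        f_manual = ((lin.rss - quad.rss) / 1) / (quad.rss / quad.residual_df)
        assert comparisons[0].f_value == pytest.approx(f_manual, rel=1e-10)
        assert comparisons[0].p_value == pytest.approx(
            scipy.stats.f.sf(f_manual, 1, quad.residual_df), rel=1e-8
        )

    def test_recovery_simulation_scaled(self):
        # scaled-down recovery (full 200-rep version lives in acceptance)
        rng = np.random.default_rng(36)
        hump_wins = lin_wins = 0
        reps = 40
        for _ in range(reps):
            mid = rng.uniform(1150, 2550, 30)
            hump = 900 - 0.0014 * (mid - 1800) ** 2 + rng.normal(0, 300, 30)
            line = 0.4 * mid - 200 + rng.normal(0, 300, 30)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                b_h, _ = select_model(fit_polynomials(mid, hump))
                b_l, _ = select_model(fit_polynomials(mid, line))
            hump_wins += b_h.order == 2
            lin_wins += b_l.order == 1
        assert hump_wins > reps / 2
        assert lin_wins > reps / 2


class TestComparators:
    def test_stevens_constant_ranges(self):
        occ, sites = bands_to_records({
            "spA": [1200, 1400], "spB": [1500, 1700], "spC": [1800, 2000],
        })
        ranges = species_elevational_range(occ, sites)
        est = stevens_estimate(ranges)
        assert (est == 300.0).all()

    def test_stevens_overlap_mean(self):
        occ, sites = bands_to_records({"spA": [1500], "spB": [1300, 1700]})
        ranges = species_elevational_range(occ, sites)
        est = stevens_estimate(ranges)
        assert est[1500] == pytest.approx((100 + 500) / 2)

    def test_stevens_positive_under_rapoport_community(self):
        rng = np.random.default_rng(37)
        band_sets = {}
        for i in range(25):
            lo = int(rng.choice(range(1100, 2400, 100)))
            width = max(int((lo - 1000) / 400), 1)  # higher species, wider ranges
            band_sets[f"sp{i}"] = list(range(lo, min(lo + width * 100, 2600), 100))
        occ, sites = bands_to_records(band_sets)
        est = stevens_estimate(species_elevational_range(occ, sites))
        rho, _ = scipy.stats.spearmanr(est.index, est.values)
        assert rho > 0

    def test_pagel_degenerate_predictor(self):
        occ, sites = bands_to_records({"spA": [2000], "spB": [2000], "spC": [2000]})
        ranges = species_elevational_range(occ, sites)
        with pytest.raises(ValueError, match="variance"):
            pagel_estimate(ranges)

    def test_pagel_toy_closed_form(self):
        ranges = pd.DataFrame({
            "species_id": list("abcde"),
            "min_band": [1100, 1200, 1400, 1600, 1800],
            "max_band": [1200, 1500, 1800, 2000, 2400],
            "range_m": [200, 400, 500, 500, 700],
            "midpoint_m": [0, 0, 0, 0, 0],
            "n_records": [2, 2, 2, 2, 2],
        })
        x = ranges["max_band"].to_numpy() + 100.0
        y = ranges["range_m"].to_numpy(dtype=float)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        out = pagel_estimate(ranges)
        assert out["slope"] == pytest.approx(slope, rel=1e-10)
        assert out["intercept"] == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_pagel_slope_recovery(self):
        rng = np.random.default_rng(38)
        maxes = rng.choice(range(1500, 2600, 100), 40)
        ranges = pd.DataFrame({
            "species_id": [f"sp{i}" for i in range(40)],
            "min_band": 1100,
            "max_band": maxes,
            "range_m": 0.5 * (maxes + 100) - 600 + rng.normal(0, 40, 40),
            "midpoint_m": 0.0,
            "n_records": 2,
        })
        out = pagel_estimate(ranges)
        assert out["slope"] == pytest.approx(0.5, abs=0.1)
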