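"""Tests of the synthetic landscape / disease / selection generator."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm
from hurdlemap.synthetic import (
    CATEGORY_PROBS,
    STRATA_PROPS,
    export_geojson,
    read_tracts_csv,
    validate_tracts,
    write_tracts_csv,
)

from conftest import make_tracts


class TestLandscape:
    def test_deterministic_under_fixed_seed(self):
        a = hm.generate_landscape(100, seed=1)
        b = hm.generate_landscape(100, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = hm.generate_landscape(20, seed=1)
        b = hm.generate_landscape(20, seed=2)
        assert not a["x"].equals(b["x"])

    def test_strata_sum_to_total(self):
        t = hm.generate_landscape(100, seed=1)
        strata = t[[f"pop_{s}" for s in STRATA_PROPS]].sum(axis=1)
        assert (strata == t["pop_total"]).all()
        adult = (
            t["pop_men_16to64"]
            + t["pop_men_65plus"]
            + t["pop_women_16to64"]
            + t["pop_women_65plus"]
        )
        assert (adult == t["pop_over16"]).all()

    def test_median_population_near_census_norm(self):
        t = hm.generate_landscape(2000, seed=7)
        med = t["pop_total"].median()
        assert abs(med - 1400.0) / 1400.0 < 0.20

    def test_two_disjoint_regions(self):
        t = hm.generate_landscape(50, seed=3)
        xa = t.loc[t.region == "A", "x"]
        xb = t.loc[t.region == "B", "x"]
        assert xa.max() < xb.min()
        assert set(t.region) == {"A", "B"}

    def test_too_few_tracts_rejected(self):
        for bad in (0, -5, 3):
            with pytest.raises(ValueError):
                hm.generate_landscape(bad, seed=1)

    def test_coordinates_finite_and_quintiles_valid(self):
        t = hm.generate_landscape(40, seed=9)
        assert np.isfinite(t[["x", "y"]].to_numpy()).all()
        assert t["deprivation_q"].between(1, 5).all()


class TestMaternField:
    def test_single_point_marginal_variance(self):
        p = hm.MaternParams(sigma2=1.0, kappa=1.0, nu=1.0)
        draws = hm.sample_matern_field([[0.0, 0.0]], p, seed=11, n_draws=10_000)
        assert 0.95 <= draws.var() <= 1.05

    def test_coincident_points_identical_values(self):
        p = hm.MaternParams(sigma2=2.0, kappa=0.5, nu=1.0)
        field = hm.sample_matern_field(
            [[1.0, 1.0], [1.0, 1.0]], p, seed=4, jitter=1e-12
        )
        assert field[0] == pytest.approx(field[1], abs=1e-4)

    def test_empirical_covariance_matches_closed_form(self):
        # MC oracle: empirical covariance of 5,000 draws vs the closed form,
        # entrywise within 3 MC standard errors for >= 98.5% of entries
        # (about 0.3% are expected to exceed 3 SE by chance) and within 5 SE
        # everywhere.
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 8, size=(50, 2))
        p = hm.MaternParams(sigma2=1.5, kappa=0.9, nu=1.0)
        n_draws = 5000
        draws = hm.sample_matern_field(coords, p, seed=21, n_draws=n_draws)
        emp = (draws.T @ draws) / n_draws
        cov = hm.matern_covariance_matrix(coords, p)
        se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n_draws)
        zscores = np.abs(emp - cov) / se
        assert (zscores <= 3.0).mean() >= 0.985
        assert zscores.max() <= 5.0

    def test_deterministic(self):
        p = hm.MaternParams(1.0, 1.0)
        coords = [[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]]
        a = hm.sample_matern_field(coords, p, seed=5)
        b = hm.sample_matern_field(coords, p, seed=5)
        assert np.array_equal(a, b)

    def test_failure_advises_jitter(self):
        coords = [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            hm.sample_matern_field(coords, hm.MaternParams(1.0, 1.0), seed=1, jitter=0.0)


class TestIndicators:
    def test_loading_indicators_track_latent(self):
        from scipy.stats import spearmanr

        tracts = pd.DataFrame(index=range(1000))
        ind = hm.generate_indicators(tracts, 6, 4, seed=8)
        for name in ind.loading_names:
            rho = spearmanr(ind.values[name], ind.latent).statistic
            assert rho > 0.5

    def test_all_signal_case(self):
        from scipy.stats import spearmanr

        tracts = pd.DataFrame(index=range(500))
        ind = hm.generate_indicators(tracts, 10, 0, seed=8)
        assert len(ind.values.columns) == 10
        for name in ind.values.columns:
            assert spearmanr(ind.values[name], ind.latent).statistic > 0.5

    def test_deterministic(self):
        tracts = pd.DataFrame(index=range(50))
        a = hm.generate_indicators(tracts, 6, 4, seed=1)
        b = hm.generate_indicators(tracts, 6, 4, seed=1)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_counts_must_sum_to_ten(self):
        with pytest.raises(ValueError):
            hm.generate_indicators(pd.DataFrame(index=range(10)), 6, 3, seed=1)


class TestSimulateDisease:
    def test_poisson_total_oracle(self):
        # 2e6 at-risk persons x 5 years = 1e7 person-years at rate 2/100,000
        # -> expected 200 cases; observed within 4 sqrt(200)
        tracts = make_tracts(n=100, pop_over16=20_000)
        truth = hm.TruthParams(base_rate=2.0, matern=None, rw1_sd=0.0)
        sim = hm.simulate_disease(tracts, truth, range(2011, 2016), seed=13)
        total = hm.case_totals(sim.tracts, "MND").sum()
        assert abs(total - 200) <= 4 * math.sqrt(200)
        assert sim.expected_counts.sum() == pytest.approx(200.0)

    def test_zero_rate_limit(self):
        tracts = make_tracts(n=20, pop_over16=10_000)
        truth = hm.TruthParams(base_rate=1e-9, matern=None)
        sim = hm.simulate_disease(tracts, truth, range(2011, 2016), seed=1)
        assert hm.case_totals(sim.tracts, "MND").sum() == 0

    def test_log_rates_exactly_linear_without_latent_noise(self):
        tracts = hm.generate_landscape(30, seed=5)
        beta = {"dep_q5": 0.4, "male_frac": 1.2}
        truth = hm.TruthParams(base_rate=10.0, beta=beta, matern=None, rw1_sd=0.0)
        years = [2015, 2016]
        sim = hm.simulate_disease(tracts, truth, years, seed=6)
        cov = hm.build_covariates(tracts)
        expected = np.exp(
            math.log(10.0 / 1e5)
            + 0.4 * cov["dep_q5"].to_numpy()
            + 1.2 * cov["male_frac"].to_numpy()
            + np.log(tracts["pop_over16"].to_numpy(float))
        )
        assert np.allclose(sim.expected_counts, expected[:, None])

    def test_category_conservation(self, default_simulation):
        _, sim = default_simulation
        validate_tracts(sim.tracts)  # raises if MND != ALS + PMA + PLS
        for yr in range(2013, 2019):
            parts = sum(
                sim.tracts[f"cases_{c}_{yr}"] for c in ("ALS", "PMA", "PLS")
            )
            assert (parts == sim.tracts[f"cases_MND_{yr}"]).all()

    def test_patient_marginals(self):
        tracts = make_tracts(n=50, pop_over16=200_000)
        truth = hm.TruthParams(base_rate=50.0, matern=None)
        sim = hm.simulate_disease(tracts, truth, range(2011, 2019), seed=3)
        pats = sim.patients
        assert len(pats) > 2000
        assert abs(pats["sex"].eq("male").mean() - 0.55) < 0.03
        assert abs(pats["age_at_diagnosis"].mean() - 63.0) < 1.0
        share = pats["category"].value_counts(normalize=True)
        for cat, p in CATEGORY_PROBS.items():
            assert abs(share.get(cat, 0.0) - p) < 0.03
        assert pats["age_q"].between(1, 5).all()
        assert pats["year"].between(2011, 2018).all()

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError):
            hm.simulate_disease(make_tracts(5), hm.TruthParams(), [], seed=1)

    def test_deterministic(self):
        tracts = hm.generate_landscape(10, seed=2)
        truth = hm.default_truth()
        a = hm.simulate_disease(tracts, truth, [2015, 2016], seed=9)
        b = hm.simulate_disease(tracts, truth, [2015, 2016], seed=9)
        pd.testing.assert_frame_equal(a.tracts, b.tracts)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        assert np.array_equal(a.spatial_field, b.spatial_field)


@pytest.fixture(scope="module")
def simulated():
    tracts = hm.generate_landscape(100, seed=31)
    truth = hm.TruthParams(
        base_rate=40.0,
        matern=hm.MaternParams(0.25, math.sqrt(8.0) / 10.0, 1.0),
    )
    sim = hm.simulate_disease(tracts, truth, range(2013, 2019), seed=32)
    return truth, sim


class TestSelection:
    def test_huge_intercept_observes_everyone(self, simulated):
        _, sim = simulated
        sel = hm.SelectionParams(intercept=20.0)
        pats = hm.apply_selection(sim.patients, sim.tracts, sel, sim.spatial_field, 1)
        assert pats["observed"].all()

    def test_fair_coin_selection_fraction(self, simulated):
        _, sim = simulated
        pats0 = sim.patients
        # replicate patients to reach >= 10,000 for a tight binomial band
        reps = int(np.ceil(10_000 / len(pats0)))
        pats = pd.concat([pats0] * reps, ignore_index=True).iloc[:10_000]
        sel = hm.SelectionParams(intercept=0.0, dist_coeff=0.0, frailty_coeff=0.0)
        out = hm.apply_selection(pats, sim.tracts, sel, sim.spatial_field, 7)
        assert 0.49 <= out["observed"].mean() <= 0.51

    def test_endogenous_selection_skews_observed_tracts(self, simulated):
        _, sim = simulated
        sel = hm.SelectionParams(intercept=0.0, dist_coeff=0.0, frailty_coeff=1.5)
        out = hm.apply_selection(sim.patients, sim.tracts, sel, sim.spatial_field, 3)
        rate = sim.expected_counts.sum(axis=1) / sim.tracts["pop_over16"].to_numpy(float)
        pos = {tid: i for i, tid in enumerate(sim.tracts["tract_id"])}
        obs_idx = [pos[t] for t in out.loc[out["observed"], "tract_id"]]
        pop_mean_rate = np.average(rate, weights=sim.tracts["pop_over16"])
        assert rate[obs_idx].mean() > pop_mean_rate

    def test_exogenous_limit_recovers_rate_by_mean_probability(self, simulated):
        truth, sim = simulated
        sel = hm.SelectionParams(intercept=0.4, dist_coeff=-0.03, frailty_coeff=0.0)
        out = hm.apply_selection(sim.patients, sim.tracts, sel, sim.spatial_field, 5)
        true_cases = len(out)
        observed = int(out["observed"].sum())
        mean_p = out["p_observed"].mean()
        corrected = observed / mean_p
        assert abs(corrected - true_cases) <= 4 * math.sqrt(true_cases)

    def test_misaligned_frailty_rejected(self, simulated):
        _, sim = simulated
        with pytest.raises(ValueError):
            hm.apply_selection(
                sim.patients, sim.tracts, hm.SelectionParams(), np.zeros(3), 1
            )

    def test_deterministic(self, simulated):
        _, sim = simulated
        sel = hm.SelectionParams(intercept=0.5, dist_coeff=-0.02, frailty_coeff=0.5)
        a = hm.apply_selection(sim.patients, sim.tracts, sel, sim.spatial_field, 17)
        b = hm.apply_selection(sim.patients, sim.tracts, sel, sim.spatial_field, 17)
        pd.testing.assert_frame_equal(a, b)


class TestObservedCounts:
    def test_observed_counts_match_patient_flags(self, default_simulation):
        truth, sim = default_simulation
        pats = hm.apply_selection(
            sim.patients, sim.tracts, truth.selection, sim.spatial_field, 23
        )
        obs = hm.tracts_with_observed_counts(sim.tracts, pats)
        assert hm.case_totals(obs, "MND").sum() == int(pats["observed"].sum())
        assert (
            hm.case_totals(obs, "MND") <= hm.case_totals(sim.tracts, "MND")
        ).all()
        validate_tracts(obs)


class TestCalibration:
    def test_default_landscape_zero_fraction_in_band(self):
        # structural realism: ~90% of tracts should show zero observed cases
        truth = hm.default_truth()
        land = hm.generate_landscape(250, seed=101)
        sim = hm.simulate_disease(land, truth, range(2013, 2019), seed=102)
        pats = hm.apply_selection(
            sim.patients, sim.tracts, truth.selection, sim.spatial_field, 103
        )
        obs = hm.tracts_with_observed_counts(sim.tracts, pats)
        frac = hm.zero_fraction(obs, "MND")
        assert 85.0 <= frac <= 97.0


class TestIO:
    def test_tracts_csv_roundtrip(self, tmp_path, default_simulation):
        _, sim = default_simulation
        path = tmp_path / "tracts.csv"
        write_tracts_csv(sim.tracts, path)
        back = read_tracts_csv(path)
        assert len(back) == len(sim.tracts)
        assert (back["tract_id"] == sim.tracts["tract_id"]).all()
        assert np.allclose(back["x"], sim.tracts["x"])

    def test_geojson_export(self, tmp_path, small_landscape):
        path = tmp_path / "tracts.geojson"
        export_geojson(small_landscape, path)
        gj = json.loads(path.read_text())
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == len(small_landscape)
        ring = gj["features"][0]["geometry"]["coordinates"][0]
        assert len(ring) == 5 and ring[0] == ring[-1]
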