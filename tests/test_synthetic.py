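"""Synthetic study-system generator: determinism, structure, forward models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from rootdepth.forcing import DAYS_PER_YEAR
from rootdepth.hydraulics import predict_B
from rootdepth.inverse import interval_factors
from rootdepth.synthetic import (
    SyntheticConfig,
    gen_forcing,
    gen_growth,
    gen_isotopes,
    gen_mortality,
    gen_species,
    generate_world,
)


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_years=0)
        with pytest.raises(ValueError):
            SyntheticConfig(drought_year_prob=1.5)

    def test_interval_count(self):
        assert SyntheticConfig(n_years=25, census_interval_years=5).n_intervals == 5


class TestForcing:
    def test_series_length_no_leap(self):
        f = gen_forcing(SyntheticConfig(n_years=25))
        assert f.n_days == 25 * DAYS_PER_YEAR == 9125

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=9)
        f1, f2 = gen_forcing(cfg), gen_forcing(cfg)
        assert np.array_equal(f1.precip, f2.precip)
        assert np.array_equal(f1.vpd, f2.vpd)
        assert f1.drought_years == f2.drought_years

    def test_vpd_peaks_in_dry_season(self):
        f = gen_forcing(SyntheticConfig(seed=3))
        dry = f.dry_season_mask
        assert f.vpd[dry].mean() > f.vpd[~dry].mean()

    def test_rain_peaks_in_wet_season(self):
        f = gen_forcing(SyntheticConfig(seed=3))
        dry = f.dry_season_mask
        assert f.precip[~dry].mean() > f.precip[dry].mean()

    def test_annual_total_near_target(self):
        cfg = SyntheticConfig(seed=5, n_years=40, drought_year_prob=0.0,
                              annual_precip_cv=0.0)
        f = gen_forcing(cfg)
        assert f.precip.sum() / 40 == pytest.approx(2627, rel=0.1)

    def test_drought_years_drier(self):
        cfg = SyntheticConfig(seed=1, n_years=30)
        f = gen_forcing(cfg)
        assert len(f.drought_years) >= 1
        yearly = f.precip.reshape(30, DAYS_PER_YEAR).sum(axis=1)
        dr = np.array(f.drought_years)
        non = np.setdiff1d(np.arange(30), dr)
        assert yearly[dr].mean() < yearly[non].mean()

    def test_every_interval_has_a_drought_year(self):
        f = gen_forcing(SyntheticConfig(seed=2, n_years=25))
        years = np.array(f.drought_years)
        for block in range(5):
            assert np.any((years >= 5 * block) & (years < 5 * (block + 1)))


class TestSpecies:
    def test_table_structure(self):
        sp = gen_species(SyntheticConfig(n_species=12, seed=0))
        assert len(sp) == 12
        assert sp["true_layer"].nunique() >= 4
        assert np.all(sp["B"] > 0) and np.all(sp["A"] > 0)
        assert set(sp["leaf_habit"]) == {"evergreen", "deciduous"}

    def test_b_follows_trait_proxy_at_zero_noise(self):
        cfg = SyntheticConfig(n_species=8, seed=1, b_noise_sd=0.0, a_noise_sd=0.0)
        sp = gen_species(cfg)
        assert np.allclose(sp["B"], predict_B(sp["wsg"].to_numpy(), sp["lma"].to_numpy()))

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=4)
        assert gen_species(cfg).equals(gen_species(cfg))


class TestGrowth:
    def make_inputs(self, noise_sd, beta0=0.1, beta1=0.4, n_species=2):
        cfg = SyntheticConfig(
            n_species=n_species, n_years=25, seed=0, growth_noise_sd=noise_sd,
            n_trees_per_species=3, tree_noise_sd=0.0,
        )
        sp = gen_species(cfg).assign(beta0=beta0, beta1=beta1)
        return cfg, sp

    def test_noiseless_linear_evaluation(self):
        cfg, sp = self.make_inputs(0.0)
        factors = {
            s: np.full((13, 5, 1), 0.5) for s in sp["species"]
        }
        growth, _ = gen_growth(sp, factors, cfg)
        assert np.allclose(growth["growth_index"], 0.1 + 0.4 * 0.5)
        assert np.allclose(growth["growth_index"], growth["growth_true"])

    def test_distinct_layers_give_distinct_series(self, rng):
        cfg, sp = self.make_inputs(0.0)
        assert sp["true_layer"].nunique() == 2  # same betas, different layers
        factors = {s: rng.random((13, 5, 1)) for s in sp["species"]}
        shared = rng.random((13, 5, 1))
        factors = {s: shared for s in sp["species"]}
        growth, _ = gen_growth(sp, factors, cfg)
        g = growth.pivot(index="species", columns="interval", values="growth_index")
        assert not np.allclose(g.iloc[0], g.iloc[1])

    def test_missing_factor_at_true_layer_rejected(self):
        cfg, sp = self.make_inputs(0.0)
        factors = {s: np.full((13, 5, 1), np.nan) for s in sp["species"]}
        with pytest.raises(ValueError):
            gen_growth(sp, factors, cfg)

    def test_census_trees_consistent_with_species_means(self):
        cfg, sp = self.make_inputs(0.0)
        factors = {s: np.full((13, 5, 1), 0.5) for s in sp["species"]}
        growth, census = gen_growth(sp, factors, cfg)
        one = census[census.tree_id == census.tree_id.iloc[0]].sort_values("date")
        increments = np.diff(one["dbh_cm"].to_numpy()) / 5.0
        assert np.allclose(increments, 0.3)


class TestMortality:
    def make_exposure(self, n_rows, exposure=0.0):
        return pd.DataFrame(
            {
                "species": [f"sp{i:02d}" for i in range(n_rows)],
                "interval": 0,
                "exposure_pct": exposure,
            }
        )

    def test_binomial_expectation_oracle(self):
        # slope 0, annual p = 0.02 over 5 years, N = 1000:
        # E[D] = 1000 * (1 - 0.98^5) = 96.08
        cfg = SyntheticConfig(
            n_species=50, seed=0, mortality_baseline=0.02,
            exposure_slope_evergreen=0.0, exposure_slope_deciduous=0.0,
            n_trees_mortality=1000,
        )
        sp = gen_species(cfg)
        mort = gen_mortality(sp, self.make_exposure(50), cfg)
        expected = 1000 * (1 - 0.98**5)
        assert mort["d"].mean() == pytest.approx(expected, abs=5.0)
        assert np.allclose(mort["p_annual_true"], 0.02)

    def test_deterministic(self):
        cfg = SyntheticConfig(n_species=5, seed=3)
        sp = gen_species(cfg)
        exp = self.make_exposure(5, exposure=10.0)
        assert gen_mortality(sp, exp, cfg).equals(gen_mortality(sp, exp, cfg))

    def test_exposure_out_of_range_rejected(self):
        cfg = SyntheticConfig(n_species=2, seed=0)
        sp = gen_species(cfg)
        with pytest.raises(ValueError):
            gen_mortality(sp, self.make_exposure(2, exposure=150.0), cfg)

    def test_logit_link(self):
        cfg = SyntheticConfig(
            n_species=2, seed=0, mortality_baseline=0.01,
            exposure_slope_evergreen=0.05, exposure_slope_deciduous=0.05,
        )
        sp = gen_species(cfg)
        mort = gen_mortality(sp, self.make_exposure(2, exposure=20.0), cfg)
        from scipy.special import expit

        assert np.allclose(mort["p_annual_true"], expit(logit(0.01) + 0.05 * 20))


class TestIsotopes:
    def species_at(self, depths):
        return pd.DataFrame(
            {"species": [f"s{i}" for i in range(len(depths))],
             "true_erd_m": depths}
        )

    def test_boundary_and_asymptote(self):
        cfg = SyntheticConfig(d2h_noise_sd=0.0)
        iso = gen_isotopes(self.species_at([0.0, 1e6]), cfg)
        assert iso["d2h_permil"].iloc[0] == pytest.approx(-20.0)
        assert iso["d2h_permil"].iloc[1] == pytest.approx(-55.0)

    def test_hand_value_at_two_meters(self):
        cfg = SyntheticConfig(d2h_noise_sd=0.0)
        iso = gen_isotopes(self.species_at([2.0]), cfg)
        assert iso["d2h_permil"].iloc[0] == pytest.approx(
            -55 + 35 * np.exp(-1), abs=1e-6
        )

    def test_monotone_toward_surface(self):
        cfg = SyntheticConfig(d2h_noise_sd=0.0)
        iso = gen_isotopes(self.species_at(np.linspace(0, 10, 20)), cfg)
        assert np.all(np.diff(iso["d2h_permil"]) < 0)


class TestWorld:
    def test_deterministic_end_to_end(self):
        cfg = SyntheticConfig(
            n_species=3, n_years=10, n_realizations=2, seed=11,
            true_layer_indices=(5, 7, 9),
        )
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert np.array_equal(w1.psi_ensemble, w2.psi_ensemble)
        assert w1.growth.equals(w2.growth)
        assert w1.mortality.equals(w2.mortality)
        assert w1.isotopes.equals(w2.isotopes)

    def test_forward_inverse_consistency_at_zero_noise(self, small_world):
        # the stored true parameters reproduce the noiseless growth exactly
        w = small_world
        for row in w.species.itertuples():
            fac = interval_factors(
                w.curves[row.species], w.mean_psi, w.vpd_hat_star, w.intervals
            )[row.true_layer, :, 0]
            expected = row.beta0 + row.beta1 * fac
            got = w.growth[w.growth.species == row.species].sort_values("interval")
            assert np.allclose(got["growth_true"], expected, atol=1e-12)

    def test_exposure_bounds(self, small_world):
        e = small_world.exposure["exposure_pct"]
        assert e.between(0, 100).all()
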