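"""Seeded synthetic inputs implementing the forward version of every model
the pipeline inverts.

The generator emulates a seasonal tropical-forest setting: wet-season-peaked
daily rainfall (annual mean about 2627 mm) with a pronounced mid-December
to April dry season, dry-season-peaked VPD, episodic drought years (rainfall
deficit plus VPD inflation), a community of canopy species with covarying
traits (WSG and LMA drive the vulnerability-curve parameters through the
trait proxies), a jittered-parameter ensemble of soil-column realizations, a
census growth table generated from the forward growth model at each species'
true rooting-depth layer, binomial mortality linked logistically to
water-stress exposure, and a monotone depth-to-deuterium map evaluated at
the true rooting depth.  Every output is a deterministic function of the
configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .demography import exposure_table
from .forcing import DAYS_PER_YEAR, ClimateForcing, census_intervals
from .hydraulics import VulnerabilityCurve, predict_A, predict_B
from .inverse import gpp_vpd_proxy, interval_factors
from .soil import SoilGrid, SoilParams, run_column

__all__ = [
    "SyntheticConfig",
    "gen_forcing",
    "gen_species",
    "gen_psi_ensemble",
    "gen_growth",
    "gen_mortality",
    "gen_isotopes",
    "SyntheticWorld",
    "generate_world",
]

# drought-year types: day-of-year windows of the rainfall deficit
# (prolonged/intense dry season, delayed wet-season onset, mid-wet-season
# failure) — distinct seasonal drought signatures reach different depths
DROUGHT_WINDOWS = {
    "dry-season": (335, 150),   # wraps the year boundary
    "onset-delay": (120, 230),
    "wet-season": (210, 330),
}

# substreams: one independent child seed per generator component
_STREAMS = {"forcing": 1, "species": 2, "ensemble": 3, "growth": 4,
            "mortality": 5, "isotopes": 6}


def _rng(config, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for the synthetic community.

    Defaults are the standard conditions exercised throughout the test
    suite: 12 canopy species, 25 years of daily forcing in 5-year census
    intervals, a 20-member hydrological ensemble, and species growth noise
    at 25% of each species' noiseless growth-signal SD.
    """

    n_species: int = 12
    n_years: int = 25
    census_interval_years: int = 5
    n_realizations: int = 20
    growth_noise_sd: float | None = None   # absolute SD, growth units
    growth_noise_frac: float = 0.25        # fraction of noiseless signal SD
    drought_year_prob: float = 0.2
    seed: int = 0

    # climate
    mean_annual_precip_mm: float = 2627.0
    annual_precip_cv: float = 0.2   # interannual SD of yearly totals (~516/2627)
    dry_season_precip_mm_day: float = 2.0
    vpd_wet_kpa: float = 0.5
    vpd_seasonal_amplitude_kpa: float = 0.8
    vpd_noise_sd_kpa: float = 0.12
    drought_rain_factor: float = 0.6
    drought_vpd_factor: float = 1.2

    # species traits
    wsg_range: tuple = (0.3, 0.8)
    lma_range: tuple = (50.0, 200.0)
    b_noise_sd: float = 0.3
    a_noise_sd: float = 2.0
    beta0_range: tuple = (0.1, 0.3)
    beta1_range: tuple = (0.5, 1.5)
    true_layer_indices: tuple = (5, 6, 7, 8, 9, 10, 11)

    # hydrological ensemble
    ensemble_jitter: float = 0.05          # surface-flux parameters
    ensemble_jitter_profile: float = 0.30  # depth-profile parameters
    warmup_years: int = 3

    # census tables
    n_trees_per_species: int = 12
    tree_noise_sd: float = 0.1
    start_year: float = 1990.0

    # mortality link (logit-scale)
    mortality_baseline: float = 0.015      # annual probability at zero exposure
    exposure_slope_evergreen: float = 0.04
    exposure_slope_deciduous: float = 0.0
    n_trees_mortality: int = 200

    # isotope map
    d2h_surface: float = -20.0
    d2h_deep: float = -55.0
    d2h_scale_m: float = 2.0
    d2h_noise_sd: float = 1.5

    def __post_init__(self):
        for name in ("n_species", "n_years", "census_interval_years",
                     "n_realizations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.drought_year_prob <= 1:
            raise ValueError("drought_year_prob must be in [0, 1]")
        if self.growth_noise_sd is not None and self.growth_noise_sd < 0:
            raise ValueError("growth_noise_sd must be non-negative")
        if self.growth_noise_frac < 0:
            raise ValueError("growth_noise_frac must be non-negative")

    @property
    def n_intervals(self) -> int:
        return self.n_years // self.census_interval_years


def gen_forcing(config: SyntheticConfig) -> ClimateForcing:
    """Seasonal daily precipitation and VPD with episodic drought years.

    Rainfall follows a raised-cosine seasonal mean (trough in the dry
    season, March; crest in the late wet season) with gamma-distributed
    daily amounts; VPD mirrors the cycle with its peak in the dry season.
    Drought years scale rainfall by ``drought_rain_factor`` and VPD by
    ``drought_vpd_factor``.
    """
    rng = _rng(config, "forcing")
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), config.n_years)
    # seasonal weight: 0 at DOY 60 (dry-season trough), 1 half a year later
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (doy - 60) / DAYS_PER_YEAR))
    base_dry = config.dry_season_precip_mm_day
    wet_scale = (config.mean_annual_precip_mm - base_dry * DAYS_PER_YEAR) / (
        0.5 * DAYS_PER_YEAR
    )
    mean_precip = base_dry + wet_scale * w
    # interannual variability of yearly totals (wet vs dry years)
    year_factor = np.clip(
        rng.normal(1.0, config.annual_precip_cv, config.n_years), 0.3, None
    )
    yf = np.repeat(year_factor, DAYS_PER_YEAR)
    mean_precip = mean_precip * yf
    # intermittent rainfall: seasonal occurrence probability times
    # gamma-distributed wet-day amounts (dry spells matter for the surface)
    wet_prob = np.clip((0.2 + 0.7 * w) * np.sqrt(yf), 0.02, 0.95)
    wet_day = rng.random(doy.size) < wet_prob
    shape = 0.7  # right-skewed wet-day rainfall
    amounts = rng.gamma(shape, (mean_precip / wet_prob) / shape)
    precip = np.where(wet_day, amounts, 0.0)
    vpd = (
        config.vpd_wet_kpa
        + config.vpd_seasonal_amplitude_kpa * (1.0 - w)
        + rng.normal(0.0, config.vpd_noise_sd_kpa, doy.size)
    )
    vpd = np.clip(vpd, 0.05, None)

    # drought years come in distinct seasonal types (prolonged dry season,
    # delayed wet-season onset, or mid-wet-season failure), so different
    # depths carry different drought signatures
    # stratified drought occurrence: at least one drought year per census
    # interval (as observed at the study site), extras Bernoulli so the
    # marginal rate matches drought_year_prob
    drought = np.zeros(config.n_years, dtype=bool)
    block = config.census_interval_years
    expected = config.drought_year_prob * block
    p_extra = max(0.0, (expected - 1.0) / max(block - 1, 1))
    for start in range(0, config.n_years, block):
        years = np.arange(start, min(start + block, config.n_years))
        drought[rng.choice(years)] = True
        extras = years[rng.random(years.size) < p_extra]
        drought[extras] = True
    dtype = rng.integers(0, len(DROUGHT_WINDOWS), config.n_years)
    year = np.repeat(np.arange(config.n_years), DAYS_PER_YEAR)
    windows = list(DROUGHT_WINDOWS.values())
    for y in np.flatnonzero(drought):
        ymask = year == y
        lo, hi = windows[dtype[y]]
        if lo <= hi:
            in_win = ymask & (doy >= lo) & (doy < hi)
        else:  # wraps the year boundary
            in_win = ymask & ((doy >= lo) | (doy < hi))
        out_win = ymask & ~in_win
        precip[in_win] *= config.drought_rain_factor * 0.5
        precip[out_win] *= min(config.drought_rain_factor + 0.3, 1.0)
        vpd[in_win] *= config.drought_vpd_factor
    # parametric community leaf-area seasonality: full canopy through the
    # wet season, partial shedding late in the dry season
    lai = 0.55 + 0.45 * w
    return ClimateForcing(
        precip=precip, vpd=vpd, drought_years=tuple(np.flatnonzero(drought)),
        lai=lai,
    )


def gen_species(config: SyntheticConfig, grid: SoilGrid | None = None) -> pd.DataFrame:
    """Ground-truth species table: traits, curve parameters, true ERD layers.

    WSG and LMA are uniform draws; B follows the trait proxy polynomial plus
    noise and A the chained proxy plus noise, so trait covariation matches
    the prediction pipeline.  True rooting-depth layers cycle through
    ``true_layer_indices`` (spanning the grid); leaf habits alternate
    evergreen/deciduous.
    """
    rng = _rng(config, "species")
    grid = grid or SoilGrid()
    s = config.n_species
    wsg = rng.uniform(*config.wsg_range, s)
    lma = rng.uniform(*config.lma_range, s)
    # additive noise on the proxy predictions, rejection-resampled where a
    # draw would violate the positivity invariant of the curve parameters
    b = predict_B(wsg, lma) + rng.normal(0.0, config.b_noise_sd, s)
    a = predict_A(np.maximum(b, 1e-6), lma) + rng.normal(0.0, config.a_noise_sd, s)
    for _ in range(100):
        bad = (b <= 0) | (a <= 0)
        if not bad.any():
            break
        n_bad = int(bad.sum())
        b[bad] = predict_B(wsg[bad], lma[bad]) + rng.normal(0.0, config.b_noise_sd, n_bad)
        a[bad] = predict_A(np.maximum(b[bad], 1e-6), lma[bad]) + rng.normal(
            0.0, config.a_noise_sd, n_bad
        )
    else:
        raise RuntimeError("could not draw positive curve parameters; widen trait ranges")
    layer_cycle = np.array(config.true_layer_indices)
    layers = layer_cycle[np.arange(s) % layer_cycle.size]
    habit = np.where(np.arange(s) % 2 == 0, "evergreen", "deciduous")
    slope = np.where(
        habit == "evergreen",
        config.exposure_slope_evergreen,
        config.exposure_slope_deciduous,
    )
    return pd.DataFrame(
        {
            "species": [f"sp{i:02d}" for i in range(s)],
            "wsg": wsg,
            "lma": lma,
            "A": a,
            "B": b,
            "true_layer": layers,
            "true_erd_m": grid.z[layers],
            "leaf_habit": habit,
            "beta0": rng.uniform(*config.beta0_range, s),
            "beta1": rng.uniform(*config.beta1_range, s),
            "max_height_m": np.full(s, 35.0),
            "mort_baseline_logit": np.full(s, logit(config.mortality_baseline)),
            "mort_exposure_slope": slope,
        }
    )


def species_curves(species: pd.DataFrame) -> dict:
    """Vulnerability-curve objects keyed by species id."""
    return {
        row.species: VulnerabilityCurve(row.A, row.B, source="fitted")
        for row in species.itertuples()
    }


def gen_psi_ensemble(
    config: SyntheticConfig,
    forcing: ClimateForcing,
    base_params: SoilParams | None = None,
    grid: SoilGrid | None = None,
) -> np.ndarray:
    """Hydrological ensemble: (n_realizations, n_layers, n_days) Psi fields.

    Realizations jitter the base soil parameters multiplicatively by up to
    ``ensemble_jitter`` (uniform), emulating the spread of a calibrated
    posterior ensemble; each member is an independent column integration
    with the configured warm-up discarded.
    """
    rng = _rng(config, "ensemble")
    grid = grid or SoilGrid()
    base = base_params or SoilParams()
    # surface-flux parameters are tightly constrained by calibration against
    # moisture/ET/discharge observations; the depth-profile parameters
    # (conductivity and root-profile e-folding) stay far more uncertain, as
    # in the calibrated posterior this ensemble emulates
    jitter_fields = {
        "k_sat0": config.ensemble_jitter,
        "k_adj": config.ensemble_jitter,
        "b": config.ensemble_jitter,
        "et_scalar": config.ensemble_jitter,
        "k_efold": config.ensemble_jitter_profile,
        "root_efold": config.ensemble_jitter_profile,
    }
    members = []
    for _ in range(config.n_realizations):
        factors = rng.uniform(
            [1.0 - j for j in jitter_fields.values()],
            [1.0 + j for j in jitter_fields.values()],
        )
        p = replace(
            base, **{f: getattr(base, f) * c for f, c in zip(jitter_fields, factors)}
        )
        state = run_column(p, forcing, grid, warmup_years=config.warmup_years)
        members.append(state.psi)
    return np.stack(members)


def gen_growth(
    species: pd.DataFrame,
    factors: dict,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward growth model at each species' true layer, plus census tables.

    ``factors`` maps species -> (n_depths, n_intervals, 1) interval factor
    array (main structure) computed on the generating hydrology.  Species
    interval growth is ``G = beta0 + beta1 * factor(true layer) + noise``
    with noise SD either ``growth_noise_sd`` (absolute) or
    ``growth_noise_frac`` times the species' noiseless signal SD.

    Returns (growth long frame with noiseless ``growth_true`` and noisy
    ``growth_index``, per-tree census table consistent with the species
    means).
    """
    rng = _rng(config, "growth")
    n_int = config.n_intervals
    rows = []
    for row in species.itertuples():
        f = np.asarray(factors[row.species], dtype=float)
        if f.ndim == 3:
            f = f[..., 0]
        fz = f[row.true_layer]
        if fz.shape[0] != n_int or np.any(~np.isfinite(fz)):
            raise ValueError(
                f"species {row.species}: no factor available at its true layer"
            )
        g_true = row.beta0 + row.beta1 * fz
        if config.growth_noise_sd is not None:
            sd = config.growth_noise_sd
        else:
            sd = config.growth_noise_frac * float(g_true.std())
        g = g_true + rng.normal(0.0, sd, n_int) if sd > 0 else g_true.copy()
        for t in range(n_int):
            rows.append(
                {
                    "species": row.species,
                    "interval": t,
                    "growth_true": g_true[t],
                    "growth_index": g[t],
                }
            )
    growth = pd.DataFrame(rows)

    # per-tree dbh trajectories consistent with the species means
    census_rows = []
    step = config.census_interval_years
    for row in species.itertuples():
        g_sp = growth.loc[growth["species"] == row.species, "growth_index"].to_numpy()
        dbh0 = rng.uniform(30.0, 90.0, config.n_trees_per_species)
        for k in range(config.n_trees_per_species):
            tree_id = f"{row.species}_t{k:03d}"
            dbh = dbh0[k]
            census_rows.append(
                {
                    "tree_id": tree_id,
                    "species": row.species,
                    "dbh_cm": dbh,
                    "date": config.start_year,
                    "status": "alive",
                }
            )
            for t in range(n_int):
                rate = g_sp[t] + (
                    rng.normal(0.0, config.tree_noise_sd)
                    if config.tree_noise_sd > 0
                    else 0.0
                )
                dbh += rate * step
                census_rows.append(
                    {
                        "tree_id": tree_id,
                        "species": row.species,
                        "dbh_cm": dbh,
                        "date": config.start_year + (t + 1) * step,
                        "status": "alive",
                    }
                )
    return growth, pd.DataFrame(census_rows)


def gen_mortality(
    species: pd.DataFrame,
    exposure: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Binomial census mortality linked logistically to exposure.

    Annual death probability: ``logit(p) = baseline + slope * exposure_pct``
    (evergreen slope > deciduous slope by default); interval deaths are
    Binomial(N, 1 - (1 - p)^d).
    """
    if np.any((exposure["exposure_pct"] < 0) | (exposure["exposure_pct"] > 100)):
        raise ValueError("exposure must be in [0, 100] percent")
    rng = _rng(config, "mortality")
    merged = exposure.merge(
        species[["species", "mort_baseline_logit", "mort_exposure_slope"]],
        on="species",
    ).sort_values(["species", "interval"])
    d = config.census_interval_years
    p_annual = expit(
        merged["mort_baseline_logit"].to_numpy()
        + merged["mort_exposure_slope"].to_numpy() * merged["exposure_pct"].to_numpy()
    )
    p_interval = 1.0 - (1.0 - p_annual) ** d
    n = np.full(len(merged), config.n_trees_mortality)
    deaths = rng.binomial(n, p_interval)
    return pd.DataFrame(
        {
            "species": merged["species"].to_numpy(),
            "interval": merged["interval"].to_numpy(),
            "n": n,
            "d": deaths,
            "duration_yr": float(d),
            "p_annual_true": p_annual,
        }
    )


def gen_isotopes(species: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Xylem deuterium from the monotone depth map at each true ERD.

    ``d2h(z) = d2h_deep + (d2h_surface - d2h_deep) * exp(-z / scale)`` plus
    noise: strictly increasing toward the surface.
    """
    rng = _rng(config, "isotopes")
    z = species["true_erd_m"].to_numpy(dtype=float)
    d2h = config.d2h_deep + (config.d2h_surface - config.d2h_deep) * np.exp(
        -z / config.d2h_scale_m
    )
    if config.d2h_noise_sd > 0:
        d2h = d2h + rng.normal(0.0, config.d2h_noise_sd, z.size)
    return pd.DataFrame(
        {
            "species": species["species"].to_numpy(),
            "d2h_permil": d2h,
            "se_permil": np.full(z.size, 1.0),
        }
    )


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, generated from one configuration."""

    config: SyntheticConfig
    grid: SoilGrid
    forcing: ClimateForcing
    vpd_hat_star: np.ndarray
    intervals: list
    species: pd.DataFrame
    curves: dict
    psi_ensemble: np.ndarray       # (R, L, T)
    growth: pd.DataFrame           # species-level series (true and noisy)
    census: pd.DataFrame           # per-tree census table
    exposure: pd.DataFrame
    mortality: pd.DataFrame
    isotopes: pd.DataFrame

    @property
    def mean_psi(self) -> np.ndarray:
        return self.psi_ensemble.mean(axis=0)


def generate_world(
    config: SyntheticConfig,
    grid: SoilGrid | None = None,
    base_params: SoilParams | None = None,
) -> SyntheticWorld:
    """Generate the complete, internally consistent synthetic study system.

    Growth truth is driven by the realization-mean water-potential field
    (the ensemble's central tendency); the inversion is then run against the
    individual realizations, exactly as with the real pipeline.
    """
    grid = grid or SoilGrid()
    forcing = gen_forcing(config)
    vpd_hat_star = gpp_vpd_proxy(forcing.vpd)
    intervals = census_intervals(config.n_years, config.census_interval_years)
    species = gen_species(config, grid)
    curves = species_curves(species)
    psi_ens = gen_psi_ensemble(config, forcing, base_params, grid)
    mean_psi = psi_ens.mean(axis=0)
    factors = {
        sp: interval_factors(curves[sp], mean_psi, vpd_hat_star, intervals, "main")
        for sp in curves
    }
    growth, census = gen_growth(species, factors, config)
    exposure = exposure_table(
        psi_ens,
        dict(zip(species["species"], species["true_layer"])),
        {row.species: curves[row.species].psi20 for row in species.itertuples()},
        intervals,
    )
    mortality = gen_mortality(species, exposure, config)
    isotopes = gen_isotopes(species, config)
    return SyntheticWorld(
        config=config,
        grid=grid,
        forcing=forcing,
        vpd_hat_star=vpd_hat_star,
        intervals=intervals,
        species=species,
        curves=curves,
        psi_ensemble=psi_ens,
        growth=growth,
        census=census,
        exposure=exposure,
        mortality=mortality,
        isotopes=isotopes,
    )
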