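"""Simplified multi-layer soil water balance, ensemble calibration and
drought climatology.

The column model is a daily explicit bucket cascade over the 13-node grid
``Z = (0.01, 0.03, 0.06, 0.12, 0.21, 0.37, 0.62, 1, 1.7, 2.9, 4.7, 7.8, 13) m``
with Campbell retention and unsaturated conductivity:

    psi(theta)  = psi_sat * (theta / theta_sat)^(-b)              [MPa]
    K(theta, z) = K_sat0 * exp(-z / k_efold) * k_adj
                  * (theta / theta_sat)^(2 b + 3)                 [mm d-1]

Each day: a fixed fraction of rainfall is intercepted (counted as canopy
evaporation), the remainder infiltrates layer 1 up to its free pore space
(excess becomes surface runoff), transpiration demand (et_scalar * VPD) is
extracted from layers weighted by an exponential root profile and limited by
water above a residual moisture, and gravity drainage cascades downward at
rate K limited by both donor water and receiver pore space; drainage out of
the bottom layer accumulates as discharge.  The daily water balance closes to
floating-point precision and is asserted against a 1e-6 relative tolerance.

A Latin-Hypercube parameter ensemble is calibrated against observation
streams by equally weighting each stream's RMSE standardized by the stream's
observed standard deviation; the best-k members form the water-potential
ensemble used by the rooting-depth inversion.  Hydrological droughts are
flagged per day-of-year as days more negative than a percentile (default
5th) of the day-of-year climatology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .forcing import DAYS_PER_YEAR, ClimateForcing

__all__ = [
    "DEFAULT_NODE_DEPTHS",
    "SoilGrid",
    "SoilParams",
    "ColumnState",
    "ObservationStream",
    "ObservationBundle",
    "WaterPotentialEnsemble",
    "DroughtFlags",
    "retention_psi",
    "run_column",
    "lhs_sample",
    "calibrate",
    "flag_droughts",
    "vwc_extractor",
    "discharge_extractor",
    "et_extractor",
]

DEFAULT_NODE_DEPTHS = (
    0.01, 0.03, 0.06, 0.12, 0.21, 0.37, 0.62, 1.0, 1.7, 2.9, 4.7, 7.8, 13.0,
)

BALANCE_RTOL = 1e-6
# extraction and drainage shut off as theta approaches this fraction of
# saturation (residual moisture)
RESIDUAL_FRACTION = 0.10
# transpiration declines linearly from full supply at this fraction of
# saturation down to zero at residual (soil-wetness stress factor)
ET_STRESS_FRACTION = 0.40


@dataclass(frozen=True)
class SoilGrid:
    """Vertical discretization: node depths with derived layer interfaces.

    Interfaces sit at arithmetic midpoints of adjacent nodes, with the top at
    0 m and the bottom at ``bottom`` (default 15 m).
    """

    node_depths: tuple = DEFAULT_NODE_DEPTHS
    bottom: float = 15.0

    def __post_init__(self):
        z = np.asarray(self.node_depths, dtype=float)
        if z.ndim != 1 or z.size < 1 or np.any(np.diff(z) <= 0):
            raise ValueError("node depths must be strictly increasing")
        if self.bottom <= z[-1]:
            raise ValueError("bottom must lie below the deepest node")

    @property
    def z(self) -> np.ndarray:
        return np.asarray(self.node_depths, dtype=float)

    @property
    def n_layers(self) -> int:
        return len(self.node_depths)

    @property
    def interfaces(self) -> np.ndarray:
        z = self.z
        return np.concatenate(([0.0], 0.5 * (z[:-1] + z[1:]), [self.bottom]))

    @property
    def thickness(self) -> np.ndarray:
        """Layer thickness in m."""
        return np.diff(self.interfaces)

    def layer_at(self, depth: float) -> int:
        """Index of the node nearest to ``depth`` (m)."""
        return int(np.argmin(np.abs(self.z - depth)))


@dataclass
class SoilParams:
    """Bucket-column parameters (analogues of the land-model roles noted).

    k_sat0 : mm d-1 — saturated conductivity at the surface (HKSAT analogue)
    k_efold : m — e-folding depth of the conductivity profile
    k_adj : — multiplier for macroporosity/direct flow paths (HKSAT_ADJ analogue)
    b : — Campbell retention exponent
    theta_sat : cm3 cm-3 — saturated volumetric moisture
    psi_sat : MPa — air-entry potential (negative, near zero)
    root_efold : m — e-folding depth of the root extraction profile
        (fates_rootb_par analogue)
    intercept_frac : — fraction of rainfall intercepted and evaporated
    et_scalar : mm d-1 kPa-1 — transpiration demand per unit VPD
        (stomatal-slope analogue)
    """

    k_sat0: float = 30.0
    k_efold: float = 100.0
    k_adj: float = 1.0
    b: float = 3.0
    theta_sat: float = 0.45
    psi_sat: float = -0.003
    root_efold: float = 1.2
    intercept_frac: float = 0.12
    et_scalar: float = 4.0

    def validate(self):
        if self.k_sat0 <= 0 or self.k_efold <= 0 or self.k_adj <= 0:
            raise ValueError("conductivity parameters must be positive")
        if self.b <= 0:
            raise ValueError("retention exponent b must be positive")
        if not 0 < self.theta_sat < 1:
            raise ValueError("theta_sat must be in (0, 1)")
        if self.psi_sat >= 0:
            raise ValueError("psi_sat must be negative")
        if self.root_efold <= 0:
            raise ValueError("root_efold must be positive")
        if not 0 <= self.intercept_frac <= 1:
            raise ValueError("intercept_frac must be in [0, 1]")
        if self.et_scalar < 0:
            raise ValueError("et_scalar must be non-negative")
        return self


def retention_psi(theta, params: SoilParams):
    """Campbell retention curve: psi = psi_sat * (theta/theta_sat)^(-b), MPa.

    Strictly increasing in theta, with psi(theta_sat) = psi_sat.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    out = params.psi_sat * (theta / params.theta_sat) ** (-params.b)
    return out if out.ndim else float(out)


@dataclass
class ColumnState:
    """Daily column trajectories from one :func:`run_column` integration."""

    grid: SoilGrid
    theta: np.ndarray      # (n_layers, n_days), cm3 cm-3
    psi: np.ndarray        # (n_layers, n_days), MPa
    et: np.ndarray         # (n_days,), mm d-1 (incl. interception loss)
    runoff: np.ndarray     # (n_days,), mm d-1
    discharge: np.ndarray  # (n_days,), mm d-1 (bottom drainage)
    balance_residual: float  # relative to cumulative precipitation

    @property
    def n_days(self) -> int:
        return self.theta.shape[1]


@dataclass
class ObservationStream:
    """One calibration target: observed daily series plus its extractor.

    ``extractor`` maps a :class:`ColumnState` to the simulated counterpart
    series (same length and units as ``values``).
    """

    name: str
    values: np.ndarray
    extractor: Callable[[ColumnState], np.ndarray]
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"stream {self.name!r} is empty")


ObservationBundle = Sequence[ObservationStream]


def vwc_extractor(grid: SoilGrid, depth: float) -> Callable[[ColumnState], np.ndarray]:
    """Extractor for volumetric water content at the node nearest ``depth``."""
    idx = grid.layer_at(depth)
    return lambda state: state.theta[idx]


def discharge_extractor(state: ColumnState) -> np.ndarray:
    return state.discharge


def et_extractor(state: ColumnState) -> np.ndarray:
    return state.et


def run_column(
    params: SoilParams,
    forcing: ClimateForcing,
    grid: SoilGrid | None = None,
    theta_init_frac: float = 0.75,
    warmup_years: int = 0,
) -> ColumnState:
    """Integrate the daily layered water balance over the forcing period.

    ``warmup_years`` extra years (the first year's forcing repeated) are
    simulated first and discarded, removing the initial-condition transient.
    The returned state covers exactly the forcing period.

    Raises AssertionError if the water balance fails to close to 1e-6
    relative to cumulative precipitation (it closes to float rounding by
    construction).
    """
    params.validate()
    grid = grid or SoilGrid()
    precip_in = forcing.precip
    vpd_in = forcing.vpd
    n_warm = warmup_years * DAYS_PER_YEAR
    if n_warm:
        precip = np.concatenate([np.tile(precip_in[:DAYS_PER_YEAR], warmup_years), precip_in])
        vpd = np.concatenate([np.tile(vpd_in[:DAYS_PER_YEAR], warmup_years), vpd_in])
    else:
        precip, vpd = precip_in, vpd_in

    n_layers = grid.n_layers
    n_days = precip.size
    dz_mm = (grid.thickness * 1000.0).tolist()
    z = grid.z
    theta_sat = params.theta_sat
    theta_res = RESIDUAL_FRACTION * theta_sat
    stress_span = (ET_STRESS_FRACTION - RESIDUAL_FRACTION) * theta_sat
    k_base = (params.k_sat0 * np.exp(-z / params.k_efold) * params.k_adj).tolist()
    root_w = np.exp(-z / params.root_efold)
    root_w = (root_w / root_w.sum()).tolist()
    kexp = 2.0 * params.b + 3.0
    intercept_frac = params.intercept_frac
    et_scalar = params.et_scalar

    theta = [theta_init_frac * theta_sat] * n_layers
    theta_out = np.empty((n_layers, n_days))
    et_out = np.empty(n_days)
    runoff_out = np.empty(n_days)
    discharge_out = np.empty(n_days)

    storage0 = sum(theta[i] * dz_mm[i] for i in range(n_layers))
    p_list = precip.tolist()
    v_list = vpd.tolist()
    rng_layers = range(n_layers)

    for t in range(n_days):
        p = p_list[t]
        intercepted = intercept_frac * p
        through = p - intercepted
        # infiltration into layer 1, excess to surface runoff
        cap = (theta_sat - theta[0]) * dz_mm[0]
        infil = through if through < cap else cap
        theta[0] += infil / dz_mm[0]
        runoff_out[t] = through - infil
        # root-weighted transpiration with a soil-wetness stress factor:
        # full supply above ET_STRESS_FRACTION * theta_sat, declining
        # linearly to zero at residual moisture
        demand = et_scalar * v_list[t]
        taken = 0.0
        if demand > 0.0:
            for i in rng_layers:
                avail = (theta[i] - theta_res) * dz_mm[i]
                if avail <= 0.0:
                    continue
                beta = (theta[i] - theta_res) / stress_span
                if beta > 1.0:
                    beta = 1.0
                take = demand * root_w[i] * beta
                if take > avail:
                    take = avail
                theta[i] -= take / dz_mm[i]
                taken += take
        et_out[t] = taken + intercepted
        # gravity drainage cascade, donor- and receiver-limited
        for i in rng_layers:
            rel = theta[i] / theta_sat
            k = k_base[i] * rel ** kexp
            avail = (theta[i] - theta_res) * dz_mm[i]
            out = k if k < avail else avail
            if out <= 0.0:
                if i == n_layers - 1:
                    discharge_out[t] = 0.0
                continue
            if i < n_layers - 1:
                space = (theta_sat - theta[i + 1]) * dz_mm[i + 1]
                if out > space:
                    out = space
                theta[i] -= out / dz_mm[i]
                theta[i + 1] += out / dz_mm[i + 1]
            else:
                theta[i] -= out / dz_mm[i]
                discharge_out[t] = out
        for i in rng_layers:
            theta_out[i, t] = theta[i]

    storage1 = sum(theta[i] * dz_mm[i] for i in range(n_layers))
    precip_cum = float(np.sum(precip))
    residual = precip_cum - (
        (storage1 - storage0)
        + float(et_out.sum())
        + float(runoff_out.sum())
        + float(discharge_out.sum())
    )
    rel_residual = abs(residual) / max(precip_cum, 1.0)
    assert rel_residual <= BALANCE_RTOL, (
        f"water balance violated: relative residual {rel_residual:.3e}"
    )

    sl = slice(n_warm, None)
    theta_out = theta_out[:, sl]
    psi = params.psi_sat * (theta_out / theta_sat) ** (-params.b)
    return ColumnState(
        grid=grid,
        theta=theta_out,
        psi=psi,
        et=et_out[sl],
        runoff=runoff_out[sl],
        discharge=discharge_out[sl],
        balance_residual=rel_residual,
    )


def lhs_sample(n: int, ranges: dict, seed) -> pd.DataFrame:
    """Latin-Hypercube draws: one sample per equal-probability stratum per dim.

    ``ranges`` maps parameter name -> (lo, hi); returns an (n, d) DataFrame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(ranges)
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("every range must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=names)


@dataclass
class WaterPotentialEnsemble:
    """Top-k calibrated members: Psi(realization, layer, day) plus diagnostics."""

    grid: SoilGrid
    psi: np.ndarray                 # (k, n_layers, n_days), MPa
    params: list                    # SoilParams per member, objective-ascending
    objectives: np.ndarray          # (k,), ascending

    @property
    def n_realizations(self) -> int:
        return self.psi.shape[0]

    @property
    def mean_psi(self) -> np.ndarray:
        """Realization-mean Psi, shape (n_layers, n_days)."""
        return self.psi.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (realization, layer, depth_m, day, psi_mpa)."""
        k, L, T = self.psi.shape
        r, l, d = np.meshgrid(np.arange(k), np.arange(L), np.arange(T), indexing="ij")
        return pd.DataFrame(
            {
                "realization": r.ravel(),
                "layer": l.ravel(),
                "depth_m": self.grid.z[l.ravel()],
                "day": d.ravel(),
                "psi_mpa": self.psi.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: SoilGrid | None = None):
        grid = grid or SoilGrid()
        k = df["realization"].nunique()
        L = df["layer"].nunique()
        T = df["day"].nunique()
        psi = (
            df.sort_values(["realization", "layer", "day"])["psi_mpa"]
            .to_numpy()
            .reshape(k, L, T)
        )
        return cls(grid=grid, psi=psi, params=[], objectives=np.full(k, np.nan))


def _objective(state: ColumnState, observations: ObservationBundle) -> float:
    """Equally weighted mean over streams of RMSE standardized by obs SD."""
    parts = []
    for stream in observations:
        sim = np.asarray(stream.extractor(state), dtype=float)
        obs = stream.values
        if sim.shape != obs.shape:
            raise ValueError(
                f"stream {stream.name!r}: simulated series shape {sim.shape} "
                f"!= observed {obs.shape}"
            )
        sd = float(np.std(obs))
        if sd == 0:
            raise ValueError(f"stream {stream.name!r} has zero variance")
        parts.append(math.sqrt(float(np.mean((sim - obs) ** 2))) / sd)
    return float(np.mean(parts))


def calibrate(
    draws: pd.DataFrame,
    forcing: ClimateForcing,
    observations: ObservationBundle,
    k: int = 100,
    grid: SoilGrid | None = None,
    base_params: SoilParams | None = None,
    warmup_years: int = 0,
) -> WaterPotentialEnsemble:
    """Rank a parameter-draw table by the standardized-RMSE objective.

    Each row of ``draws`` overrides the matching :class:`SoilParams` fields of
    ``base_params``; the k smallest-objective members are returned with their
    water-potential fields, parameters and objectives sorted ascending.
    """
    if k > len(draws):
        raise ValueError(f"k={k} exceeds the {len(draws)} available draws")
    grid = grid or SoilGrid()
    base = base_params or SoilParams()
    valid = {f.name for f in fields(SoilParams)}
    unknown = set(draws.columns) - valid
    if unknown:
        raise ValueError(f"unknown parameter columns: {sorted(unknown)}")

    def member(row) -> SoilParams:
        return replace(base, **{c: float(row[c]) for c in draws.columns})

    objectives = np.empty(len(draws))
    for i, (_, row) in enumerate(draws.iterrows()):
        state = run_column(member(row), forcing, grid, warmup_years=warmup_years)
        objectives[i] = _objective(state, observations)

    order = np.argsort(objectives, kind="stable")[:k]
    # re-run the winners to collect their Psi fields (cheap relative to
    # holding every member's field in memory)
    psi_list, params_list = [], []
    for i in order:
        p = member(draws.iloc[int(i)])
        state = run_column(p, forcing, grid, warmup_years=warmup_years)
        psi_list.append(state.psi)
        params_list.append(p)
    return WaterPotentialEnsemble(
        grid=grid,
        psi=np.stack(psi_list),
        params=params_list,
        objectives=objectives[order],
    )


@dataclass
class DroughtFlags:
    """Per (year, day-of-year) extreme-drought flags for one layer."""

    layer: int
    percentile: float
    thresholds: np.ndarray  # (365,) percentile of the DOY climatology
    flags: np.ndarray       # (n_years, 365) bool

    def interval_counts(self, interval_years: int = 5) -> np.ndarray:
        """Flagged-day counts per census interval (whole intervals only)."""
        n_years = self.flags.shape[0]
        n_int = n_years // interval_years
        per_year = self.flags.sum(axis=1)
        return np.add.reduceat(
            per_year[: n_int * interval_years],
            np.arange(0, n_int * interval_years, interval_years),
        )


def flag_droughts(
    psi: np.ndarray | WaterPotentialEnsemble,
    layer: int,
    percentile: float = 5.0,
    pooling: str = "realization-mean",
) -> DroughtFlags:
    """Flag extreme hydrological droughts at one layer.

    A (year, day-of-year) is flagged when its realization-mean Psi is
    strictly more negative than the given percentile of Psi for that day of
    year, pooled across years.  ``psi`` may be an ensemble (realization,
    layer, day), a (layer, day) field, or a 1-D daily series for ``layer``.

    ``pooling="per-realization"`` pools the percentile across realizations
    and years instead of using the realization mean.
    """
    if isinstance(psi, WaterPotentialEnsemble):
        psi = psi.psi
    psi = np.asarray(psi, dtype=float)
    if psi.ndim == 3:
        ens = psi[:, layer, :]
        series = ens.mean(axis=0)
    elif psi.ndim == 2:
        ens = psi[layer][None, :]
        series = psi[layer]
    else:
        ens = psi[None, :]
        series = psi
    n_days = series.size
    if n_days % DAYS_PER_YEAR != 0:
        raise ValueError("series length must be whole years")
    n_years = n_days // DAYS_PER_YEAR
    if n_years < 2:
        raise ValueError("need at least 2 years to form a day-of-year climatology")

    by_doy = series.reshape(n_years, DAYS_PER_YEAR)
    if pooling == "realization-mean":
        pool = by_doy
    elif pooling == "per-realization":
        pool = ens.reshape(-1, n_years, DAYS_PER_YEAR).reshape(-1, DAYS_PER_YEAR)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    thresholds = np.percentile(pool, percentile, axis=0)
    flags = by_doy < thresholds[None, :]
    return DroughtFlags(
        layer=layer, percentile=percentile, thresholds=thresholds, flags=flags
    )
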