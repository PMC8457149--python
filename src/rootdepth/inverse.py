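"""Inverse estimation of species effective rooting depth (ERD).

The inversion regresses a species' census-interval growth series G on a
daily soil-moisture growth-limitation factor evaluated at every candidate
soil depth, and selects the depth whose dynamics best explain growth.  For
the main model structure the interval regressor at depth z is

    (1 / n_t) * sum_i  FLC*_i|z  *  VPDhat*_i

the interval mean of the product of the standardized fractional leaf
conductance (FLC, from the species vulnerability curve driven by
Psi_soil at z; standardized to [0, 1] within species over the full period)
and the standardized GPP-proxy transform of VPD (VPDhat, standardized to
[0, 1] globally).  Alternate structures treat FLC and VPDhat as separate
additive regressors, or multiply in a standardized seasonal leaf-area
curve.

Per hydrological realization the best depth maximizes R^2 (shallower depth
on ties; AIC available as an alternative criterion); species ERD is the
median of best-fit depths across realizations, with the standard error of
that distribution.  An independent check regresses ERD against xylem-water
deuterium (deeper water is isotopically lighter), which also ranks the
candidate model structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin

from .hydraulics import VulnerabilityCurve

__all__ = [
    "STRUCTURES",
    "gpp_vpd_proxy",
    "standardize01",
    "interval_factors",
    "ERDRegressor",
    "fit_depth",
    "estimate_erd",
    "ERDEstimate",
    "estimate_community_erd",
    "validate_isotopes",
    "select_structure",
]

STRUCTURES = ("main", "additive", "lai")


def gpp_vpd_proxy(vpd, coefficients=(0.0, 2.0, -1.0)):
    """GPP proxy VPDhat*: polynomial of VPD, floored at 0, scaled to [0, 1].

    The default quadratic ``2 v - v^2`` has an interior maximum (growth
    increases with VPD up to a threshold, then declines as stomata close);
    site-specific coefficients are supplied via configuration.
    Standardization is over the full analysis period.
    """
    vpd = np.asarray(vpd, dtype=float)
    raw = np.polynomial.polynomial.polyval(vpd, np.asarray(coefficients, dtype=float))
    raw = np.maximum(raw, 0.0)
    return standardize01(raw)


def standardize01(x, degenerate: float | None = None):
    """Min-max scale a series to [0, 1] over its full extent.

    A constant series is an error unless ``degenerate`` supplies the fill
    value (the FLC* convention maps constant conductance to 1).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        if degenerate is None:
            raise ValueError("cannot standardize a constant series")
        return np.full_like(x, degenerate)
    return (x - lo) / (hi - lo)


def _interval_means(daily: np.ndarray, intervals) -> np.ndarray:
    """Mean of a (..., n_days) array over each half-open day range."""
    return np.stack(
        [daily[..., a:b].mean(axis=-1) for a, b in intervals], axis=-1
    )


def interval_factors(
    curve: VulnerabilityCurve,
    psi: np.ndarray,
    vpd_hat_star: np.ndarray,
    intervals,
    structure: str = "main",
    lai_star: np.ndarray | None = None,
) -> np.ndarray:
    """Census-interval growth-factor regressors for one species.

    Parameters
    ----------
    psi : (n_depths, n_days) soil water potential (MPa <= 0) for one
        hydrological realization (or the realization mean).
    vpd_hat_star : (n_days,) standardized GPP proxy in [0, 1].
    intervals : list of (start, stop) day-index ranges.
    structure : "main" (mean of FLC* x VPDhat*), "additive" (separate
        interval means of FLC* and VPDhat*), or "lai" (FLC* x VPDhat* x LAI*).

    Returns
    -------
    (n_depths, n_intervals, p) array; p = 1 except 2 for "additive".
    """
    psi = np.asarray(psi, dtype=float)
    vpd_hat_star = np.asarray(vpd_hat_star, dtype=float)
    if psi.shape[-1] != vpd_hat_star.size:
        raise ValueError("psi and VPDhat series are misaligned")
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    flc = np.exp(-curve.B * np.abs(psi))  # (d, T)
    # FLC standardized within species over the full period, per depth;
    # a constant (fully unstressed) series maps to 1
    lo = flc.min(axis=-1, keepdims=True)
    hi = flc.max(axis=-1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    span[flat] = 1.0
    flc_star = (flc - lo) / span
    flc_star[flat] = 1.0

    if structure == "main":
        daily = flc_star * vpd_hat_star[None, :]
        return _interval_means(daily, intervals)[..., None]
    if structure == "lai":
        if lai_star is None:
            raise ValueError("structure 'lai' requires a standardized LAI series")
        lai_star = np.asarray(lai_star, dtype=float)
        if lai_star.size != vpd_hat_star.size:
            raise ValueError("LAI series misaligned with the daily calendar")
        daily = flc_star * vpd_hat_star[None, :] * lai_star[None, :]
        return _interval_means(daily, intervals)[..., None]
    # additive: FLC* and VPDhat* enter as separate regressors
    f1 = _interval_means(flc_star, intervals)
    f2 = _interval_means(np.broadcast_to(vpd_hat_star, psi.shape), intervals)
    return np.stack([f1, f2], axis=-1)


def _ols_stats(y: np.ndarray, X: np.ndarray):
    """OLS of y on columns of X (intercept added): coefs, R^2, residual SD, AIC."""
    n = y.size
    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    k = design.shape[1]
    dof = max(n - k, 1)
    aic = n * np.log(max(sse / n, 1e-300)) + 2 * k
    return coef, max(min(r2, 1.0), 0.0), np.sqrt(sse / dof), aic


class ERDRegressor(RegressorMixin, BaseEstimator):
    """Depth-selecting regression of growth on per-depth limitation factors.

    Given an interval-by-depth factor matrix, fits one ordinary
    least-squares regression of the growth series per candidate depth and
    selects the depth with maximum R^2 (or minimum AIC).  Exact ties go to
    the shallower depth — the factor matrix columns must therefore be
    ordered shallow to deep.

    Parameters
    ----------
    depths : sequence of float, optional
        Depth (m) of each factor column, for reporting ``depth_``.
    criterion : {"r2", "aic"}
    positive_slope : bool, default True
        Prefer depths with a positive factor slope (growth rises with the
        limitation factor); falls back to all depths if none qualifies.

    Attributes
    ----------
    best_index_ : int — selected column.
    depth_ : float — selected depth (m), when ``depths`` was given.
    intercept_, coef_ : selected-depth regression coefficients (beta0, beta1...).
    r2_ : float — selected-depth coefficient of determination.
    diagnostics_ : DataFrame — per-depth beta0, beta1, R^2, residual SD, AIC.
    """

    def __init__(self, depths=None, criterion: str = "r2",
                 positive_slope: bool = True):
        self.depths = depths
        self.criterion = criterion
        self.positive_slope = positive_slope

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim == 2:
            X = X[..., None]  # (n_intervals, n_depths) -> p = 1
        if X.ndim != 3 or X.shape[0] != y.size:
            raise ValueError(
                "X must be (n_intervals, n_depths[, p]) aligned with y"
            )
        n, d, p = X.shape
        if n < p + 2:
            raise ValueError(
                f"{n} intervals cannot constrain {p + 1} parameters plus selection"
            )
        if self.criterion not in ("r2", "aic"):
            raise ValueError("criterion must be 'r2' or 'aic'")

        rows = []
        for j in range(d):
            coef, r2, resid_sd, aic = _ols_stats(y, X[:, j, :])
            rows.append(
                {
                    "depth_index": j,
                    "beta0": coef[0],
                    "beta1": coef[1],
                    "r2": r2,
                    "resid_sd": resid_sd,
                    "aic": aic,
                    "coef": coef,
                }
            )
        diag = pd.DataFrame(rows)
        if self.depths is not None:
            diag.insert(1, "depth_m", np.asarray(self.depths, dtype=float))
        # growth must increase with the limitation factor: depths whose
        # fitted slope is negative are physically spurious (anticorrelated
        # dynamics) and only considered if no depth has a positive slope
        cand = diag.index.to_numpy()
        if self.positive_slope:
            pos = diag["beta1"].to_numpy() > 0
            if pos.any():
                cand = cand[pos]
        if self.criterion == "r2":
            scores = diag.loc[cand, "r2"].to_numpy()
            best = int(cand[scores.argmax()])  # first max = shallower
        else:
            scores = diag.loc[cand, "aic"].to_numpy()
            best = int(cand[scores.argmin()])
        sel = diag.iloc[best]
        self.best_index_ = best
        self.depth_ = float(sel["depth_m"]) if self.depths is not None else None
        self.intercept_ = float(sel["coef"][0])
        self.coef_ = np.asarray(sel["coef"][1:], dtype=float)
        self.r2_ = float(sel["r2"])
        self.diagnostics_ = diag.drop(columns="coef")
        self.n_features_in_ = d
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[..., None]
        return self.intercept_ + X[:, self.best_index_, :] @ self.coef_


def fit_depth(
    growth: np.ndarray,
    factors: np.ndarray,
    depths,
    criterion: str = "r2",
):
    """Per-depth growth regressions and the best-fit depth for one species.

    ``factors`` is (n_depths, n_intervals[, p]) from :func:`interval_factors`;
    returns (diagnostics DataFrame, best depth in m).
    """
    factors = np.asarray(factors, dtype=float)
    if factors.ndim == 2:
        factors = factors[..., None]
    X = np.moveaxis(factors, 0, 1)  # (n_intervals, n_depths, p)
    est = ERDRegressor(depths=depths, criterion=criterion).fit(X, growth)
    return est.diagnostics_, est.depth_


@dataclass
class ERDEstimate:
    """Median and spread of per-realization best-fit depths for one species."""

    species: str
    erd: float          # m, member of the soil layer grid (lower median)
    se: float           # m, SD of best depths / sqrt(n realizations)
    best_depths: np.ndarray

    @property
    def n_realizations(self) -> int:
        return self.best_depths.size


def estimate_erd(best_depths, species: str = "") -> ERDEstimate:
    """Summarize per-realization best depths: lower median plus standard error.

    The lower median keeps the estimate on the discrete layer grid for even
    realization counts; SE is the standard deviation (ddof=1) of the depth
    values divided by sqrt(n), 0 for a single realization.
    """
    x = np.sort(np.asarray(best_depths, dtype=float))
    if x.size == 0:
        raise ValueError("no realizations supplied")
    erd = float(x[(x.size - 1) // 2])
    se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return ERDEstimate(species=species, erd=erd, se=se, best_depths=x)


def estimate_community_erd(
    growth: pd.DataFrame,
    curves: dict,
    ensemble_psi: np.ndarray,
    vpd_hat_star: np.ndarray,
    intervals,
    depths,
    structure: str = "main",
    criterion: str = "r2",
    lai_star: np.ndarray | None = None,
):
    """Run the full inversion for every species over every realization.

    Parameters
    ----------
    growth : long frame (species, interval, growth_index).
    curves : species -> :class:`VulnerabilityCurve`; species without a curve
        are skipped (flagged upstream).
    ensemble_psi : (n_realizations, n_depths, n_days).

    Returns
    -------
    erd : DataFrame (species, erd_m, se_m, n_realizations)
    fits : long DataFrame of per (species, realization, depth) diagnostics.
    """
    ensemble_psi = np.asarray(ensemble_psi, dtype=float)
    if ensemble_psi.ndim == 2:
        ensemble_psi = ensemble_psi[None, ...]
    depths = np.asarray(depths, dtype=float)
    n_int = len(intervals)
    wide = growth.pivot(index="species", columns="interval", values="growth_index")
    wide = wide.reindex(columns=range(n_int))

    erd_rows, fit_frames = [], []
    for sp, row in wide.iterrows():
        if sp not in curves or curves[sp] is None:
            continue
        g = row.to_numpy(dtype=float)
        if np.any(~np.isfinite(g)):
            continue
        best = np.empty(ensemble_psi.shape[0])
        for r in range(ensemble_psi.shape[0]):
            factors = interval_factors(
                curves[sp], ensemble_psi[r], vpd_hat_star, intervals,
                structure=structure, lai_star=lai_star,
            )
            diag, best_depth = fit_depth(g, factors, depths, criterion=criterion)
            best[r] = best_depth
            diag = diag.assign(species=sp, realization=r)
            fit_frames.append(diag)
        est = estimate_erd(best, species=sp)
        erd_rows.append(
            {
                "species": sp,
                "erd_m": est.erd,
                "se_m": est.se,
                "n_realizations": est.n_realizations,
            }
        )
    erd_df = pd.DataFrame(erd_rows)
    fits_df = pd.concat(fit_frames, ignore_index=True) if fit_frames else pd.DataFrame()
    return erd_df, fits_df


def validate_isotopes(erd: pd.DataFrame, isotopes: pd.DataFrame) -> dict:
    """Regress species ERD against xylem-water deuterium (independent check).

    ``erd`` carries (species, erd_m); ``isotopes`` carries (species,
    d2h_permil).  Requires >= 3 overlapping species.  Returns slope,
    intercept, r2, p and n.
    """
    merged = erd.merge(isotopes, on="species")
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 overlapping species, got {n}")
    fit = linregress(merged["d2h_permil"], merged["erd_m"])
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": n,
    }


def select_structure(
    growth: pd.DataFrame,
    curves: dict,
    ensemble_psi: np.ndarray,
    vpd_hat_star: np.ndarray,
    intervals,
    depths,
    isotopes: pd.DataFrame,
    structures=STRUCTURES,
    lai_star: np.ndarray | None = None,
    criterion: str = "r2",
):
    """Rank candidate growth-model structures by the isotope validation R^2.

    Runs the full inversion per structure and regresses the resulting ERD
    against xylem deuterium; the structure with the highest R^2 wins, with
    ties resolved in favour of the earlier-listed (more parsimonious)
    candidate.  Returns (best structure name, ranking DataFrame).
    """
    rows = []
    for s in structures:
        erd_df, _ = estimate_community_erd(
            growth, curves, ensemble_psi, vpd_hat_star, intervals, depths,
            structure=s, criterion=criterion, lai_star=lai_star,
        )
        summary = validate_isotopes(erd_df, isotopes)
        rows.append({"structure": s, **summary})
    ranking = pd.DataFrame(rows).sort_values(
        "r2", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return str(ranking.iloc[0]["structure"]), ranking
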