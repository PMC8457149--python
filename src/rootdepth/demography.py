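"""Mortality rates, water-stress exposure and ERD association analyses.

Mortality rate for species s over a census interval of duration d years is
``M = (D / N) * (100 / d)`` (% yr-1), with N the trees >= 10 cm dbh alive at
the first census and D those dead by the second.  Exposure is the percent of
interval days on which soil water potential at the species' ERD layer is
strictly more negative than the species' critical threshold Psi_crit
(Psi at 20% leaf-conductance loss).  Association analyses are per-interval
ordinary least squares of mortality on ERD, split by leaf habit (all
deciduous habits pooled), and Spearman rank correlations of ERD against
branch hydraulic traits.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr

__all__ = [
    "mortality_rate",
    "exposure_fraction",
    "exposure_table",
    "erd_mortality_regression",
    "erd_trait_correlation",
]

logger = logging.getLogger(__name__)

MIN_MORTALITY_DBH_CM = 10.0   # mortality population (distinct from growth's 30 cm)
MIN_ABUNDANCE = 20            # average abundance for regression inclusion


def mortality_rate(n, d, duration):
    """Annualized mortality M = (D/N) * (100/duration) in % yr-1.

    Exact rational arithmetic on integer inputs; vectorized.
    """
    n = np.asarray(n)
    d = np.asarray(d)
    if np.any(n < 1):
        raise ValueError("N must be >= 1 (rate undefined for empty populations)")
    if np.any(d < 0) or np.any(d > n):
        raise ValueError("deaths must satisfy 0 <= D <= N")
    if np.any(np.asarray(duration) <= 0):
        raise ValueError("interval duration must be positive")
    out = (d / n) * (100.0 / duration)
    return out if out.ndim else float(out)


def exposure_fraction(psi_series, psi_crit: float) -> float:
    """Percent of days with psi strictly more negative than psi_crit.

    ``psi_series`` is the daily water potential at the species' ERD layer
    over one census interval (realization-mean by default upstream).
    Boundary days (psi == psi_crit) do not count.
    """
    if psi_crit >= 0:
        raise ValueError("psi_crit must be negative (MPa)")
    psi = np.asarray(psi_series, dtype=float)
    if psi.size == 0:
        raise ValueError("empty interval")
    return float(100.0 * np.count_nonzero(psi < psi_crit) / psi.size)


def exposure_table(
    ensemble_psi: np.ndarray,
    species_layers: dict,
    psi_crit: dict,
    intervals,
    pooling: str = "mean-psi",
) -> pd.DataFrame:
    """Per-species per-interval exposure from a water-potential ensemble.

    Parameters
    ----------
    ensemble_psi : (n_realizations, n_layers, n_days)
    species_layers : species -> ERD layer index
    psi_crit : species -> critical threshold (MPa < 0)
    pooling : "mean-psi" applies the threshold to the realization-mean
        series; "per-realization" averages the per-realization exposure
        fractions instead.
    """
    psi = np.asarray(ensemble_psi, dtype=float)
    if psi.ndim == 2:
        psi = psi[None, ...]
    rows = []
    for sp, layer in species_layers.items():
        crit = psi_crit[sp]
        for t, (a, b) in enumerate(intervals):
            seg = psi[:, layer, a:b]
            if pooling == "mean-psi":
                exp_pct = exposure_fraction(seg.mean(axis=0), crit)
            elif pooling == "per-realization":
                exp_pct = float(
                    np.mean([exposure_fraction(seg[r], crit) for r in range(seg.shape[0])])
                )
            else:
                raise ValueError(f"unknown pooling {pooling!r}")
            rows.append({"species": sp, "interval": t, "exposure_pct": exp_pct})
    return pd.DataFrame(rows)


def erd_mortality_regression(
    mortality: pd.DataFrame,
    erd: pd.DataFrame,
    habits: pd.DataFrame,
    min_species: int = 3,
) -> pd.DataFrame:
    """Per-interval, per-habit-group OLS of mortality rate on ERD.

    ``mortality`` carries (species, interval, n, d, duration_yr) or a
    precomputed ``m_pct_yr`` column; ``habits`` carries (species,
    leaf_habit) with every non-evergreen habit pooled as deciduous.
    Significance is flagged at both alpha = 0.05 and 0.1 (no
    multiple-testing correction).  Group-intervals with fewer than
    ``min_species`` species are skipped with a log entry.
    """
    mort = mortality.copy()
    if "m_pct_yr" not in mort.columns:
        mort["m_pct_yr"] = mortality_rate(
            mort["n"].to_numpy(), mort["d"].to_numpy(), mort["duration_yr"].to_numpy()
        )
    grp = habits.assign(
        group=np.where(habits["leaf_habit"] == "evergreen", "evergreen", "deciduous")
    )[["species", "group"]]
    data = mort.merge(erd[["species", "erd_m"]], on="species").merge(grp, on="species")

    rows = []
    for (interval, group), block in data.groupby(["interval", "group"], sort=True):
        if len(block) < min_species:
            logger.info(
                "skipping interval %s group %s: only %d species",
                interval, group, len(block),
            )
            continue
        x = block["erd_m"].to_numpy(dtype=float)
        y = block["m_pct_yr"].to_numpy(dtype=float)
        if np.unique(x).size < 2 or np.allclose(y, y[0]):
            slope, r2, p = 0.0, 0.0, 1.0
        else:
            fit = linregress(x, y)
            slope, r2, p = float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)
        rows.append(
            {
                "interval": interval,
                "group": group,
                "n_species": len(block),
                "slope": slope,
                "r2": r2,
                "p": p,
                "sig_05": p < 0.05,
                "sig_10": p < 0.1,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_TRAITS = ("kmax_stem", "psi_tlp", "psi88_stem", "safety_margin")


def erd_trait_correlation(
    erd: pd.DataFrame,
    traits: pd.DataFrame,
    trait_columns=DEFAULT_TRAITS,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman rank correlation of ERD with each branch hydraulic trait.

    Deeper ERD is coded as a larger (positive) depth value.  Ties are
    handled by midranks; traits with fewer than ``min_n`` overlapping
    species are skipped.
    """
    data = erd[["species", "erd_m"]].merge(traits, on="species")
    rows = []
    for col in trait_columns:
        if col not in data.columns:
            continue
        sub = data[["erd_m", col]].dropna()
        if len(sub) < min_n:
            logger.info("skipping trait %s: only %d species", col, len(sub))
            continue
        r, p = spearmanr(sub["erd_m"], sub[col])
        rows.append({"trait": col, "spearman_r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
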