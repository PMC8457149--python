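"""Leaf hydraulic vulnerability curves and conductance-loss quantities.

A species' leaf hydraulic conductance declines with increasingly negative
water potential following an exponential vulnerability curve

    K_leaf(psi) = A * exp(-B * |psi|)

with conductance scale ``A`` (mmol m-2 s-1 MPa-1) and decline rate ``B``
(MPa-1), both positive.  The maximum conductance K_max,leaf equals the curve
value at psi = 0, i.e. ``A``, so the fractional leaf conductance

    FLC(psi) = K_leaf(psi) / K_max,leaf = exp(-B * |psi|)

is independent of ``A``.  The water potential at a given fractional loss f
(for example Psi20 at f = 0.2, used as the critical exposure threshold
Psi_crit) is ``ln(1 - f) / B``.

All water potentials are stored as non-positive MPa; the exponential is
evaluated on |psi| with B > 0 so that conductance declines under drying.

For species without measured curves, (A, B) can be predicted from wood
specific gravity (WSG, g cm-3) and leaf mass per area (LMA, g m-2) through
empirical polynomial proxies (:func:`predict_B`, :func:`predict_A`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "VulnerabilityCurve",
    "TraitRecord",
    "VulnerabilityCurveRegressor",
    "fit_vulnerability",
    "predict_B",
    "predict_A",
    "curve_from_traits",
    "kleaf",
    "flc",
    "psi_at_loss",
]

_PSI_POSITIVE_TOL = 1e-12


def _check_psi(psi):
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > _PSI_POSITIVE_TOL):
        raise ValueError("water potential must be non-positive (MPa)")
    return psi


@dataclass
class VulnerabilityCurve:
    """Exponential decline of leaf conductance with water potential.

    Attributes
    ----------
    A : float
        Conductance at psi = 0 (equals K_max,leaf); must be positive.
    B : float
        Decline rate per MPa, stored positive.
    source : str
        ``"fitted"`` (from measurement pairs) or ``"trait-predicted"``.
    residual_variance : float
        Variance of fit residuals (conductance units squared); 0 for
        trait-predicted curves.
    """

    A: float
    B: float
    source: str = "fitted"
    residual_variance: float = 0.0

    def __post_init__(self):
        if not (self.A > 0 and self.B > 0):
            raise ValueError(f"A and B must be positive (got A={self.A}, B={self.B})")

    def kleaf(self, psi):
        """Leaf conductance at water potential ``psi`` (MPa, <= 0)."""
        return self.A * np.exp(-self.B * np.abs(_check_psi(psi)))

    def flc(self, psi):
        """Fractional leaf conductance K(psi)/K_max in (0, 1]."""
        return np.exp(-self.B * np.abs(_check_psi(psi)))

    def psi_at_loss(self, f: float) -> float:
        """Water potential (MPa) at fractional conductance loss ``f`` in [0, 1)."""
        if not 0 <= f < 1:
            raise ValueError("loss fraction must be in [0, 1)")
        return float(np.log(1.0 - f) / self.B)

    @property
    def psi20(self) -> float:
        """Psi at 20% conductance loss — the critical threshold Psi_crit."""
        return self.psi_at_loss(0.2)

    @property
    def kmax(self) -> float:
        return self.A


@dataclass
class TraitRecord:
    """Per-species trait bundle used for curve prediction and correlations.

    Branch-level hydraulic traits are optional inputs used only in the
    ERD-trait association analyses; psi-valued fields are MPa and
    non-positive.
    """

    species: str
    wsg: float
    lma: float
    leaf_habit: str = "evergreen"
    kmax_stem: float | None = None
    psi_tlp: float | None = None
    psi88_stem: float | None = None
    psi_min: float | None = None
    safety_margin: float | None = field(default=None)

    def __post_init__(self):
        if self.wsg <= 0 or self.lma <= 0:
            raise ValueError("WSG and LMA must be positive")
        for name in ("psi_tlp", "psi88_stem", "psi_min"):
            v = getattr(self, name)
            if v is not None and v > 0:
                raise ValueError(f"{name} must be non-positive MPa")
        if (
            self.safety_margin is None
            and self.psi_min is not None
            and self.psi88_stem is not None
        ):
            self.safety_margin = self.psi_min - self.psi88_stem


class VulnerabilityCurveRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the exponential vulnerability curve.

    Fits ``K = A * exp(-B * |psi|)`` to (psi, K) measurement pairs.  The fit
    is initialised from the closed-form log-linear regression of ln K on
    |psi| (exact on noiseless exponential data) and, when ``refine`` is True,
    polished by nonlinear least squares in the conductance domain.

    Parameters
    ----------
    refine : bool, default True
        Run nonlinear least squares from the log-linear start.

    Attributes
    ----------
    A_, B_ : float
        Fitted curve parameters (both positive).
    residual_variance_ : float
        Mean squared residual in conductance units.
    n_obs_ : int
        Number of measurement pairs used.
    """

    def __init__(self, refine: bool = True):
        self.refine = refine

    def fit(self, X, y):
        psi = _check_psi(np.asarray(X, dtype=float).reshape(-1))
        k = np.asarray(y, dtype=float).reshape(-1)
        if psi.shape != k.shape:
            raise ValueError("psi and K must have the same length")
        if psi.size < 3:
            raise ValueError("need at least 3 measurement pairs")
        if np.unique(psi).size < 2:
            raise ValueError("measurements must span at least 2 distinct psi values")
        if np.any(k <= 0):
            raise ValueError("conductance values must be positive")

        x = np.abs(psi)
        # closed-form log-linear start: ln K = ln A - B x
        slope, intercept = np.polyfit(x, np.log(k), 1)
        a0, b0 = float(np.exp(intercept)), float(-slope)
        if self.refine:
            try:
                (a_hat, b_hat), _ = curve_fit(
                    lambda xx, a, b: a * np.exp(-b * xx), x, k, p0=(a0, max(b0, 1e-8))
                )
            except RuntimeError:  # no convergence: keep the log-linear solution
                a_hat, b_hat = a0, b0
        else:
            a_hat, b_hat = a0, b0
        if a_hat <= 0 or b_hat <= 0:
            raise ValueError(
                f"fitted parameters not positive (A={a_hat:.4g}, B={b_hat:.4g}); "
                "data do not describe a declining curve"
            )
        self.A_ = float(a_hat)
        self.B_ = float(b_hat)
        resid = k - self.A_ * np.exp(-self.B_ * x)
        self.residual_variance_ = float(np.mean(resid**2))
        self.n_obs_ = int(psi.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        psi = _check_psi(np.asarray(X, dtype=float).reshape(-1))
        return self.A_ * np.exp(-self.B_ * np.abs(psi))

    def to_curve(self) -> VulnerabilityCurve:
        return VulnerabilityCurve(
            self.A_, self.B_, source="fitted", residual_variance=self.residual_variance_
        )


def fit_vulnerability(pairs) -> VulnerabilityCurve:
    """Fit a :class:`VulnerabilityCurve` from (psi, K) measurement pairs.

    ``pairs`` is an iterable of (psi <= 0 MPa, K > 0) tuples, or a 2-column
    array.  Requires >= 3 pairs spanning >= 2 distinct psi values.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (psi, K) two-column data")
    est = VulnerabilityCurveRegressor().fit(arr[:, 0], arr[:, 1])
    return est.to_curve()


def predict_B(wsg, lma):
    """Predict decline rate B (MPa-1) from WSG (g cm-3) and LMA (g m-2).

    Empirical polynomial proxy:
    ``B = 5.57 - 20.7 WSG + 14.99 WSG^2 - 0.004 WSG LMA + 0.09 LMA - 0.0001 LMA^2``.
    A non-positive result is returned as-is with a warning; callers should
    flag the species and exclude trait-predicted curves rather than clamp.
    """
    wsg = np.asarray(wsg, dtype=float)
    lma = np.asarray(lma, dtype=float)
    if np.any(wsg <= 0) or np.any(lma <= 0):
        raise ValueError("WSG and LMA must be positive")
    b = (
        5.57
        - 20.7 * wsg
        + 14.99 * wsg**2
        - 0.004 * wsg * lma
        + 0.09 * lma
        - 0.0001 * lma**2
    )
    if np.any(b <= 0):
        warnings.warn(
            "predicted B is non-positive for some inputs; trait-predicted "
            "curve is unusable for those species",
            stacklevel=2,
        )
    return b if b.ndim else float(b)


def predict_A(b, lma):
    """Predict conductance scale A from decline rate B and LMA (g m-2).

    ``A = -2.36 - 4.42 B - 0.3 B^2 + 0.12 B LMA + 0.08 LMA - 0.001 LMA^2``.
    Non-positive predictions flag the species (curve unusable).
    """
    b = np.asarray(b, dtype=float)
    lma = np.asarray(lma, dtype=float)
    if np.any(lma <= 0):
        raise ValueError("LMA must be positive")
    a = -2.36 - 4.42 * b - 0.3 * b**2 + 0.12 * b * lma + 0.08 * lma - 0.001 * lma**2
    if np.any(a <= 0):
        warnings.warn(
            "predicted A is non-positive for some inputs; trait-predicted "
            "curve is unusable for those species",
            stacklevel=2,
        )
    return a if a.ndim else float(a)


def curve_from_traits(wsg: float, lma: float) -> VulnerabilityCurve | None:
    """Chain the trait proxies B(WSG, LMA) then A(B, LMA) into a curve.

    Returns None (species flagged) when either prediction is non-positive.
    """
    b = predict_B(wsg, lma)
    if b <= 0:
        return None
    a = predict_A(b, lma)
    if a <= 0:
        return None
    return VulnerabilityCurve(a, b, source="trait-predicted")


def kleaf(psi, curve: VulnerabilityCurve):
    """Leaf conductance at ``psi`` for ``curve`` (module-level convenience)."""
    return curve.kleaf(psi)


def flc(psi, curve: VulnerabilityCurve):
    """Fractional leaf conductance at ``psi``; in (0, 1], independent of A."""
    return curve.flc(psi)


def psi_at_loss(f: float, curve: VulnerabilityCurve) -> float:
    """Water potential at fractional loss ``f``; ``f=0.2`` gives Psi_crit."""
    return curve.psi_at_loss(f)
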