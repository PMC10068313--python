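"""Force-dependent bond kinetics.

Bell's phenomenological model relates the dissociation rate of a single
receptor/ligand bond to a constant pulling force F:

    k_off(F) = k0_off * exp(F * x_beta / kB*T)

where ``k0_off`` is the zero-force off-rate and ``x_beta`` (a length, nm)
is the force sensitivity — positive for slip bonds (force accelerates
dissociation), negative for catch bonds.  This module provides the model,
the fold-change calculus used to reason about ligand discrimination under
force, and Bell-Evans dynamic force spectroscopy (most-probable rupture
force versus pulling speed) together with the corresponding fits.

Units: forces in pN, rates in 1/s, lengths in nm and thermal energy in
pN nm — except the Bell-Evans functions, which operate in simulation
units (energy kB*T = 1, lengths in Angstrom, time in tau) to match how
pulling simulations report their output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize

from .exceptions import FitInputError, InvalidParameterError

__all__ = [
    "TemperatureContext",
    "BODY_TEMPERATURE",
    "BellBond",
    "ForceSensitivityRelation",
    "BellEvansParams",
    "membrane_off_rate",
    "fold_change_under_force",
    "fit_bell",
    "bell_evans_force",
    "fit_bell_evans",
    "fit_xbeta_log_slope",
]


@dataclass(frozen=True)
class TemperatureContext:
    """Boltzmann constant and absolute temperature.

    Defaults give kB*T = 0.0138 * 310.15 = 4.2801 pN nm (physiological
    temperature).  The proofreading module uses its own verbatim constant
    4.2797 pN nm; see :mod:`forcekin.proofreading`.
    """

    k_B: float = 0.0138  # pN nm / K
    T: float = 310.15  # K

    def __post_init__(self) -> None:
        if not (self.k_B > 0 and self.T > 0):
            raise InvalidParameterError("k_B and T must be positive")

    @property
    def k_B_T(self) -> float:
        return self.k_B * self.T


BODY_TEMPERATURE = TemperatureContext()


@dataclass
class BellBond:
    """A bond's zero-force off-rate (1/s) and force-sensitivity length (nm)."""

    k0_off: float
    x_beta: float
    se_k0_off: Optional[float] = None
    se_x_beta: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k0_off) and self.k0_off > 0):
            raise InvalidParameterError(f"k0_off must be positive, got {self.k0_off}")
        if not np.isfinite(self.x_beta):
            raise InvalidParameterError("x_beta must be finite")

    def to_dict(self) -> dict:
        """Round-trippable config representation (YAML/JSON friendly)."""
        return {"k0_off": self.k0_off, "x_beta_nm": self.x_beta,
                "kB_pN_nm_per_K": BODY_TEMPERATURE.k_B, "T_K": BODY_TEMPERATURE.T}

    @classmethod
    def from_dict(cls, d: dict) -> "BellBond":
        return cls(k0_off=float(d["k0_off"]), x_beta=float(d["x_beta_nm"]))


@dataclass
class ForceSensitivityRelation:
    """Linear dependence of x_beta on the log10 of a rate or affinity.

    Evaluates x_beta = slope * log10(argument) + intercept, with the
    argument either an off-rate (1/s) or a dissociation constant (uM).
    """

    slope: float  # nm per log10 unit
    intercept: float  # nm
    argument_kind: Literal["k_off", "K_D"] = "k_off"
    se_slope: Optional[float] = None
    se_intercept: Optional[float] = None

    def x_beta(self, argument: float) -> float:
        if argument <= 0:
            raise InvalidParameterError("relation argument must be positive")
        return self.slope * math.log10(argument) + self.intercept

    __call__ = x_beta


@dataclass
class BellEvansParams:
    """Bell-Evans fit output in simulation units (kB*T = 1, lengths in A).

    ``k_off_tau`` is the dissociation rate per simulation time unit tau;
    ``x_beta`` is in Angstrom.  ``identifiable`` is False when the fitted
    F-vs-ln(v) slope is non-positive (x_beta unbounded).
    """

    k_off_tau: float
    x_beta: float
    kappa: float
    se_k_off_tau: Optional[float] = None
    se_x_beta: Optional[float] = None
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.identifiable and not (self.k_off_tau > 0):
            raise InvalidParameterError("k_off_tau must be positive")
        if not (self.kappa > 0):
            raise InvalidParameterError("kappa must be positive")


def membrane_off_rate(bond: BellBond, force: float,
                      temp: TemperatureContext = BODY_TEMPERATURE) -> float:
    """Off-rate under a constant pulling force (Bell's model).

    Parameters
    ----------
    bond : BellBond
    force : float
        Tensile force on the bond, pN (must be finite and >= 0).
    temp : TemperatureContext

    Returns
    -------
    float
        k0_off * exp(F * x_beta / kB*T), in 1/s.
    """
    if not np.isfinite(force) or force < 0:
        raise InvalidParameterError(f"force must be finite and >= 0, got {force}")
    return bond.k0_off * math.exp(force * bond.x_beta / temp.k_B_T)


def fold_change_under_force(k_off_A: float, k_off_B: float,
                            relation: ForceSensitivityRelation, force: float,
                            temp: TemperatureContext = BODY_TEMPERATURE) -> float:
    """Ratio of membrane off-rates k_m(B)/k_m(A) under force.

    Each ligand's x_beta is taken from ``relation`` evaluated at its own
    zero-force off-rate.  When x_beta varies with k_off, force amplifies
    (positive slope) or dampens (negative slope) the zero-force fold
    difference between two ligands; with a 100-fold k_off difference,
    15 pN and slope +/-0.3 nm per decade this gives roughly 820- and
    12-fold differences respectively.
    """
    if not (k_off_A > 0 and k_off_B > 0):
        raise InvalidParameterError("off-rates must be positive")
    km_A = membrane_off_rate(BellBond(k_off_A, relation(k_off_A)), force, temp)
    km_B = membrane_off_rate(BellBond(k_off_B, relation(k_off_B)), force, temp)
    return km_B / km_A


def _linear_wls(x: np.ndarray, y: np.ndarray,
                w: Optional[np.ndarray]) -> tuple[float, float, float, float, float]:
    """Weighted least squares y = a + b x.

    Returns (a, b, se_a, se_b, cov_ab).  With weights given they are taken
    as inverse variances and the covariance is (X'WX)^-1; otherwise the
    residual variance estimate s^2 = RSS/(n-2) scales (X'X)^-1.
    """
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    if w is None:
        W = np.eye(n)
        XtWX = X.T @ X
        beta = np.linalg.solve(XtWX, X.T @ y)
        resid = y - X @ beta
        dof = max(n - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(XtWX)
    else:
        W = np.diag(w)
        XtWX = X.T @ W @ X
        beta = np.linalg.solve(XtWX, X.T @ W @ y)
        cov = np.linalg.inv(XtWX)
    a, b = beta
    return float(a), float(b), float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])), float(cov[0, 1])


def fit_bell(forces: Sequence[float], rates: Sequence[float],
             rate_errors: Optional[Sequence[float]] = None,
             temp: TemperatureContext = BODY_TEMPERATURE,
             method: Literal["log-linear", "nonlinear"] = "log-linear") -> BellBond:
    """Fit Bell's model to off-rates measured at several forces.

    The default fit is linear regression of ln(rate) on force (intercept
    ln k0_off, slope x_beta/kB*T), which matches the multiplicative error
    structure of the exponential model and yields closed-form standard
    errors.  ``method='nonlinear'`` performs the equivalent nonlinear
    least squares directly on the rates.  When ``rate_errors`` are given
    the log-linear fit uses inverse-variance weights (delta method:
    se(ln k) = se(k)/k).

    Requires at least three distinct force points and strictly positive
    rates.
    """
    F = np.asarray(forces, dtype=float)
    k = np.asarray(rates, dtype=float)
    if F.shape != k.shape or F.ndim != 1:
        raise FitInputError("forces and rates must be 1-D and equally long")
    if len(np.unique(F)) < 3:
        raise FitInputError("need >= 3 distinct force points for a Bell fit")
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        raise FitInputError("all rates must be positive and finite")

    w = None
    if rate_errors is not None:
        se = np.asarray(rate_errors, dtype=float)
        if np.any(se <= 0):
            raise FitInputError("rate errors must be positive")
        w = (k / se) ** 2  # inverse variance of ln(rate)

    ln_k0, slope, se_ln_k0, se_slope, _ = _linear_wls(F, np.log(k), w)
    kBT = temp.k_B_T
    bond = BellBond(k0_off=math.exp(ln_k0), x_beta=slope * kBT,
                    se_k0_off=math.exp(ln_k0) * se_ln_k0, se_x_beta=se_slope * kBT)
    if method == "log-linear":
        return bond
    if method != "nonlinear":
        raise ValueError(f"unknown method {method!r}")
    # refine in rate space, seeded by the log-linear solution
    sigma = np.asarray(rate_errors, dtype=float) if rate_errors is not None else None
    popt, pcov = optimize.curve_fit(
        lambda f, k0, xb: k0 * np.exp(f * xb / kBT), F, k,
        p0=[bond.k0_off, bond.x_beta], sigma=sigma,
        absolute_sigma=sigma is not None, maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    return BellBond(k0_off=popt[0], x_beta=popt[1],
                    se_k0_off=perr[0], se_x_beta=perr[1])


def bell_evans_force(v: float, params: BellEvansParams, k_B_T: float = 1.0) -> float:
    """Most-probable rupture force at constant pulling speed.

    F = (kB*T / x_beta) * ln(x_beta * kappa * v / (kB*T * k_off))

    in simulation units (speed in A/tau, force in kB*T/A).  The product
    kappa*v is the loading rate.  When the logarithm's argument is <= 1
    the formula would give a negative force, which has no meaning in this
    phenomenology (rupture is then dominated by spontaneous dissociation);
    0 is returned with a warning.
    """
    if v <= 0:
        raise InvalidParameterError("pulling speed must be positive")
    arg = params.x_beta * params.kappa * v / (k_B_T * params.k_off_tau)
    if arg <= 1.0:
        warnings.warn("Bell-Evans log argument <= 1; rupture force clamped to 0",
                      stacklevel=2)
        return 0.0
    return (k_B_T / params.x_beta) * math.log(arg)


def fit_bell_evans(speeds: Sequence[float], f_max_means: Sequence[float],
                   f_max_sems: Optional[Sequence[float]] = None,
                   kappa: float = 0.12, k_B_T: float = 1.0) -> BellEvansParams:
    """Fit the Bell-Evans model to mean rupture forces at several speeds.

    Weighted least squares of F on ln(v): the slope is kB*T/x_beta and the
    intercept fixes k_off_tau = (x_beta * kappa / kB*T) * exp(-b/slope).
    Standard errors follow from the linear-fit covariance by the delta
    method.  A non-positive slope (e.g. identical forces at all speeds)
    leaves x_beta unbounded; the result is flagged non-identifiable.
    """
    v = np.asarray(speeds, dtype=float)
    F = np.asarray(f_max_means, dtype=float)
    if len(np.unique(v)) < 3:
        raise FitInputError("need >= 3 distinct pulling speeds")
    if np.any(v <= 0):
        raise FitInputError("speeds must be positive")
    order = np.argsort(v)
    if not np.all(np.diff(F[order]) >= 0):
        warnings.warn("mean rupture forces are not monotone in speed", stacklevel=2)
    w = None
    if f_max_sems is not None:
        sem = np.asarray(f_max_sems, dtype=float)
        if np.any(sem <= 0):
            raise FitInputError("SEMs must be positive")
        w = 1.0 / sem**2
    b, a, se_b, se_a, cov_ab = _linear_wls(np.log(v), F, w)
    if a <= 0:
        return BellEvansParams(k_off_tau=math.nan, x_beta=math.inf, kappa=kappa,
                               identifiable=False)
    x_beta = k_B_T / a
    k_off = (x_beta * kappa / k_B_T) * math.exp(-b / a)
    # delta method: x_beta = kT/a; ln k_off = ln(kappa/a) - b/a
    se_x_beta = k_B_T * se_a / a**2
    dlnk_da = -1.0 / a + b / a**2
    dlnk_db = -1.0 / a
    var_lnk = (dlnk_da**2 * se_a**2 + dlnk_db**2 * se_b**2
               + 2 * dlnk_da * dlnk_db * cov_ab)
    return BellEvansParams(k_off_tau=k_off, x_beta=x_beta, kappa=kappa,
                           se_k_off_tau=k_off * math.sqrt(max(var_lnk, 0.0)),
                           se_x_beta=se_x_beta)


def fit_xbeta_log_slope(pairs: Sequence[tuple[float, float]],
                        x_beta_errors: Optional[Sequence[float]] = None,
                        argument_kind: Literal["k_off", "K_D"] = "k_off",
                        ) -> ForceSensitivityRelation:
    """Regress force sensitivity on the log10 of a rate or affinity.

    ``pairs`` are (abscissa, x_beta) tuples; the abscissa (k_off or K_D)
    must be positive.  Ordinary least squares on log10(abscissa), or
    inverse-variance weighted when x_beta standard errors are supplied.
    This is the negative-correlation statistic of the study: higher
    affinity (smaller K_D, slower k_off) pairs with larger x_beta.
    """
    if len(pairs) < 2:
        raise FitInputError("need >= 2 (abscissa, x_beta) pairs")
    absc = np.array([p[0] for p in pairs], dtype=float)
    xb = np.array([p[1] for p in pairs], dtype=float)
    if np.any(absc <= 0):
        raise FitInputError("abscissae must be positive")
    if len(np.unique(absc)) < 2:
        raise FitInputError("need >= 2 distinct abscissae")
    w = None
    if x_beta_errors is not None:
        se = np.asarray(x_beta_errors, dtype=float)
        w = 1.0 / se**2
    intercept, slope, se_int, se_slope, _ = _linear_wls(np.log10(absc), xb, w)
    return ForceSensitivityRelation(slope=slope, intercept=intercept,
                                    argument_kind=argument_kind,
                                    se_slope=se_slope, se_intercept=se_int)
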