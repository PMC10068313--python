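"""Equilibrium and kinetic binding analysis for biosensor data.

Langmuir isotherm fits of steady-state binding (free or
standard-curve-constrained Bmax), hyperbolic Rmax extraction from the
conformation-specific antibody signal used to quantify active
immobilised ligand, mono-exponential dissociation fits, and the
on-rate identity k_on = k_off / K_D.  Double referencing (reference
channel and buffer-injection subtraction) is assumed done upstream;
:func:`subtract_buffer_baseline` helps with the latter when raw paired
injections are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

from .exceptions import FitInputError, InvalidParameterError

__all__ = [
    "LangmuirFit", "HyperbolicFit", "DissociationFit", "StandardCurvePoint",
    "fit_langmuir", "fit_w6_32_rmax", "constrained_bmax", "report_kd",
    "fit_dissociation", "on_rate", "subtract_buffer_baseline",
]

#: minimum ratio max[analyte]/K_D for a design to count as saturated
SATURATION_RATIO = 2.5
#: constrained-vs-free reporting threshold, uM
CONSTRAINED_KD_CUTOFF = 20.0


@dataclass
class LangmuirFit:
    K_D: float  # uM
    Bmax: float  # RU
    se_K_D: Optional[float]
    se_Bmax: Optional[float]
    saturation_ratio: float
    bmax_mode: str  # "free" | "fixed"


@dataclass
class HyperbolicFit:
    Rmax: float
    K_t: float
    se_Rmax: Optional[float]
    se_K_t: Optional[float]
    ok: bool = True


@dataclass
class DissociationFit:
    k_off: float  # 1/s
    R0: float
    offset: float
    se_k_off: Optional[float]
    ok: bool = True


@dataclass
class StandardCurvePoint:
    """One (antibody Rmax, receptor Bmax) calibration pair.

    Only pairs measured on a saturated design (max concentration at
    least ``SATURATION_RATIO`` times the fitted K_D) qualify for the
    standard curve.
    """

    rmax_antibody: float  # RU
    bmax_receptor: float  # RU
    saturation_ratio: float

    @property
    def qualifies(self) -> bool:
        return self.saturation_ratio >= SATURATION_RATIO


def _langmuir(C, Bmax, KD):
    return Bmax * C / (KD + C)


def fit_langmuir(concentrations: Sequence[float], responses: Sequence[float],
                 bmax: float | str = "free") -> LangmuirFit:
    """Fit the 1:1 steady-state isotherm B = Bmax*C/(K_D + C).

    ``bmax`` is either "free" (both parameters fitted; needs >= 3
    concentrations) or a fixed value in RU (only K_D fitted; >= 2
    concentrations).  Warns when the design does not reach saturation
    (max C < 2.5 K_D), in which case the free-Bmax K_D is poorly
    identified.
    """
    C = np.asarray(concentrations, dtype=float)
    B = np.asarray(responses, dtype=float)
    if np.any(C <= 0):
        raise FitInputError("concentrations must be positive")
    free = isinstance(bmax, str)
    if free and bmax != "free":
        raise ValueError(f"bmax must be 'free' or a number, got {bmax!r}")
    if len(np.unique(C)) < (3 if free else 2):
        raise FitInputError("too few distinct concentrations for this mode")

    model = Model(_langmuir)
    bmax0 = float(B.max()) * 1.5 if free else float(bmax)
    half = bmax0 / 2.0
    kd0 = float(C[np.argmin(np.abs(B - half))]) if np.any(B > 0) else float(np.median(C))
    params = model.make_params(Bmax=dict(value=bmax0, min=1e-12, vary=free),
                               KD=dict(value=max(kd0, C.min() / 10), min=1e-12))
    result = model.fit(B, params, C=C)
    if not result.success:
        for kd_try in (C.min(), np.median(C), C.max() * 10):
            params["KD"].value = kd_try
            result = model.fit(B, params, C=C)
            if result.success:
                break
        else:
            raise FitInputError("Langmuir fit did not converge")
    KD = float(result.params["KD"].value)
    sat = float(C.max()) / KD
    if sat < SATURATION_RATIO:
        warnings.warn(f"unsaturated design: max[C]/K_D = {sat:.2f} < "
                      f"{SATURATION_RATIO}", stacklevel=2)
    se_kd = result.params["KD"].stderr
    se_bm = result.params["Bmax"].stderr if free else None
    return LangmuirFit(K_D=KD, Bmax=float(result.params["Bmax"].value),
                       se_K_D=float(se_kd) if se_kd is not None else None,
                       se_Bmax=float(se_bm) if se_bm is not None else None,
                       saturation_ratio=sat, bmax_mode="free" if free else "fixed")


def _hyperbolic(t, Rmax, Kt):
    return Rmax * t / (Kt + t)


def fit_w6_32_rmax(t: Sequence[float], response: Sequence[float]) -> HyperbolicFit:
    """Maximal antibody binding from R = Rmax*t/(K_t + t).

    The empirically chosen hyperbolic time course of the slow antibody
    injection; K_t is a nuisance parameter.  A flat trace leaves Rmax
    unidentified and the result is flagged.
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(response, dtype=float)
    if np.any(t <= 0):
        raise FitInputError("time samples must be positive")
    if len(t) < 3:
        raise FitInputError("need >= 3 samples")
    spread = R.max() - R.min()
    if spread <= 1e-12 * max(abs(R.max()), 1.0):
        return HyperbolicFit(Rmax=float(R.mean()), K_t=math.nan, se_Rmax=None,
                             se_K_t=None, ok=False)
    model = Model(_hyperbolic)
    params = model.make_params(Rmax=dict(value=float(R.max()) * 1.2, min=1e-12),
                               Kt=dict(value=float(np.median(t)), min=1e-12))
    result = model.fit(R, params, t=t)
    se_r = result.params["Rmax"].stderr
    se_k = result.params["Kt"].stderr
    return HyperbolicFit(Rmax=float(result.params["Rmax"].value),
                         K_t=float(result.params["Kt"].value),
                         se_Rmax=float(se_r) if se_r is not None else None,
                         se_K_t=float(se_k) if se_k is not None else None,
                         ok=bool(result.success))


def constrained_bmax(standard_curve: Sequence[StandardCurvePoint],
                     rmax_antibody: float, through_origin: bool = True) -> float:
    """Predict a receptor Bmax from the antibody standard curve.

    Regresses receptor Bmax on antibody Rmax over the qualifying
    calibration points (saturated designs only) — through the origin by
    default, since both scale with the number of active immobilised
    sites.  A single qualifying point degenerates to the ratio rule.
    Raises when no point qualifies.
    """
    pts = [p for p in standard_curve if p.qualifies]
    if not pts:
        raise FitInputError("no standard-curve points with saturated designs; "
                            "cannot constrain Bmax")
    x = np.array([p.rmax_antibody for p in pts], dtype=float)
    y = np.array([p.bmax_receptor for p in pts], dtype=float)
    if through_origin or len(pts) == 1:
        slope = float(np.sum(x * y) / np.sum(x * x))
        return slope * rmax_antibody
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0] + coef[1] * rmax_antibody)


def report_kd(free_K_D: Optional[float], constrained_K_D: Optional[float]) -> float:
    """Reporting rule: constrained K_D when it exceeds 20 uM, else free.

    Weak binders never saturate, so their free-Bmax fit is unreliable
    and the standard-curve-constrained estimate is preferred; for
    stronger binders the direct fit stands.
    """
    if constrained_K_D is None:
        if free_K_D is None:
            raise InvalidParameterError("no K_D estimate available")
        return free_K_D
    if free_K_D is None:
        return constrained_K_D
    return constrained_K_D if constrained_K_D > CONSTRAINED_KD_CUTOFF else free_K_D


def _mono_exp(t, R0, k, c):
    return R0 * np.exp(-k * t) + c


def fit_dissociation(t: Sequence[float], response: Sequence[float],
                     with_offset: bool = False, skip_samples: int = 1,
                     ) -> DissociationFit:
    """Off-rate from a mono-exponential fit of the dissociation phase.

    R(t) = R0*exp(-k_off*t) (+ optional constant offset).  The first
    ``skip_samples`` points after injection stop are excluded to avoid
    the transition artefact.  A rising trace is rejected; a flat trace
    yields a flagged near-zero rate.
    """
    t = np.asarray(t, dtype=float)[skip_samples:]
    R = np.asarray(response, dtype=float)[skip_samples:]
    if len(t) < 4:
        raise FitInputError("too few samples in the dissociation window")
    n3 = max(len(R) // 3, 1)
    if np.mean(R[-n3:]) > np.mean(R[:n3]) + 1e-9 * max(abs(R).max(), 1.0):
        raise FitInputError("dissociation trace is rising; not a decay")
    model = Model(_mono_exp)
    span = float(R[0] - R[-1])
    k0 = 1.0 / max(float(t[-1] - t[0]) / 3.0, 1e-9)
    params = model.make_params(R0=dict(value=max(span, 1e-9), min=0),
                               k=dict(value=k0, min=1e-9),
                               c=dict(value=float(R[-1]), vary=with_offset))
    if not with_offset:
        params["c"].value = 0.0
    result = model.fit(R, params, t=t)
    k = float(result.params["k"].value)
    se = result.params["k"].stderr
    flat = abs(span) <= 1e-9 * max(abs(R).max(), 1.0)
    return DissociationFit(k_off=k, R0=float(result.params["R0"].value),
                           offset=float(result.params["c"].value),
                           se_k_off=float(se) if se is not None else None,
                           ok=bool(result.success) and not flat)


def on_rate(k_off: float, K_D: float) -> float:
    """k_on = k_off / K_D (uM^-1 s^-1 for k_off in 1/s and K_D in uM)."""
    if k_off <= 0 or K_D <= 0:
        raise InvalidParameterError("k_off and K_D must be positive")
    return k_off / K_D


def subtract_buffer_baseline(response: Sequence[float],
                             buffer_before: Sequence[float],
                             buffer_after: Sequence[float]) -> np.ndarray:
    """Subtract the average of the flanking buffer injections (double referencing)."""
    before = np.asarray(buffer_before, dtype=float)
    after = np.asarray(buffer_after, dtype=float)
    return np.asarray(response, dtype=float) - (before + after) / 2.0
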