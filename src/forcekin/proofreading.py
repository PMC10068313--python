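"""Kinetic proofreading of T-cell antigen recognition under mechanical force.

A ligand-bound receptor must traverse N sequential modification steps,
each at rate k_p, before it signals; dissociation (at the membrane
off-rate k_m_off) resets the chain.  At steady state the concentration
of signalling receptor-ligand complex is

    C_N = (1 + k_m_off(F) / k_p)^(-N) * C_T,

with C_T the total bound complex from two-species equilibrium binding.
Force enters through Bell's model with an affinity-dependent force
sensitivity, x_beta(K_D) = slope * log10(K_D) + intercept, so that

    k_m_off(F) = k_on * K_D * exp(x_beta(K_D) * F / kBT).

Potency P is the ligand concentration needed to reach a fixed C_N
threshold; on a log10 scale and for ligand concentrations well below
receptor saturation it reduces to P = lambda + N*log10(1 + k_m_off/k_p),
with lambda an offset proportional to the threshold.  Discrimination
power alpha is the log-fold change in potency per log-fold change in
off-rate between a strong and a weak agonist.

The default x_beta(K_D) relation uses the measured 1G4 panel slope,
-0.029 nm per decade of K_D, with the logarithm taken over K_D in
molar units; on this package's uM scale that is
x_beta = -0.029*log10(K_D/uM) + 0.064 nm.  This convention makes the
physiological-affinity ligands slip bonds that cross over to catch
bonds only in the very-low-affinity regime (K_D above ~160 uM) —
matching the flow-chamber phenomenology — and gives the model its
documented behaviour: potency rises with force for agonist-range
affinities (force costs sensitivity) and discrimination power decays
monotonically with force.  Both coefficients are configurable.  kBT is
fixed at the verbatim 4.2797 pN nm of this model's formulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bell_kinetics import ForceSensitivityRelation
from .exceptions import FitInputError, InvalidParameterError

__all__ = [
    "KBT_PROOFREADING", "DEFAULT_RELATION", "KPParams", "KPFitResult",
    "membrane_off_rate_from_KD", "bound_complex", "signalling_occupancy",
    "potency", "discrimination_power", "fit_potency", "f_test_nested",
]

KBT_PROOFREADING = 4.2797  # pN nm
# -0.029*log10(K_D in M) - 0.11, rewritten for K_D in uM (-0.029*(-6) - 0.11)
DEFAULT_RELATION = ForceSensitivityRelation(slope=-0.029, intercept=0.064,
                                            argument_kind="K_D")


@dataclass
class KPParams:
    """Proofreading model state.

    N may be non-integer (an effective step count); k_on is in
    uM^-1 s^-1, forces in pN, concentrations in uM.  ``lambda_`` is the
    threshold-proportional offset of the linearised potency formula, in
    log10(uM); ``threshold`` is the absolute C_N level used by the full
    numeric solve.
    """

    N: float = 2.46
    k_p: float = 2.15  # 1/s
    k_on: float = 0.0447  # uM^-1 s^-1
    F: float = 0.0  # pN
    lambda_: float = 0.0  # log10 uM
    relation: ForceSensitivityRelation = field(
        default_factory=lambda: replace(DEFAULT_RELATION))
    threshold: float = 1e-4  # uM, C_N level defining potency
    R_0: float = 1.0  # uM, total receptor for the full equilibrium solve
    k_B_T: float = KBT_PROOFREADING

    def __post_init__(self) -> None:
        if not (self.N >= 0 and self.k_p > 0 and self.k_on > 0 and self.F >= 0):
            raise InvalidParameterError("require N >= 0, k_p > 0, k_on > 0, F >= 0")


def membrane_off_rate_from_KD(K_D: float, F: float,
                              params: Optional[KPParams] = None) -> float:
    """Membrane off-rate (1/s) from affinity, via the empirical x_beta(K_D).

    k_m_off(F) = k_on * K_D * exp(x_beta(K_D) * F / kBT), with K_D in uM.
    At F = 0 this is the detailed-balance identity k_off = k_on * K_D.
    """
    if K_D <= 0 or F < 0:
        raise InvalidParameterError("K_D must be positive and F >= 0")
    p = params if params is not None else KPParams()
    return p.k_on * K_D * math.exp(p.relation(K_D) * F / p.k_B_T)


def bound_complex(L_0: float, R_0: float, koffm: float, k_on: float) -> float:
    """Total receptor-ligand complex C_T (uM) at two-species equilibrium.

    Closed-form root of the quadratic mass-action balance with
    dissociation constant koffm/k_on; satisfies
    0 <= C_T <= min(L_0, R_0).  A numerically negative discriminant is
    clamped to zero with a warning.
    """
    if min(L_0, R_0, koffm) < 0 or k_on <= 0:
        raise InvalidParameterError("concentrations and rates must be >= 0, k_on > 0")
    K = koffm / k_on
    b = L_0 + R_0 + K
    disc = b * b - 4.0 * L_0 * R_0
    if disc < 0:
        if disc < -1e-9 * b * b:
            warnings.warn("negative discriminant in bound_complex; clamped to 0",
                          stacklevel=2)
        disc = 0.0
    return 0.5 * (b - math.sqrt(disc))


def signalling_occupancy(C_T: float, koffm: float, N: float, k_p: float) -> float:
    """Concentration of receptors that completed all N steps.

    C_N = (1 + koffm/k_p)^(-N) * C_T; always <= C_T.
    """
    if C_T < 0 or koffm < 0 or k_p <= 0 or N < 0:
        raise InvalidParameterError("invalid proofreading inputs")
    return C_T * (1.0 + koffm / k_p) ** (-N)


def log_potency_linearized(K_D: float, params: KPParams) -> float:
    """log10 potency in the ligand-limited regime.

    P = lambda + N * log10(1 + k_m_off(F)/k_p); exact when the ligand
    concentration at threshold is far below receptor saturation, which
    is the regime the model is fitted in.
    """
    km = membrane_off_rate_from_KD(K_D, params.F, params)
    return params.lambda_ + params.N * math.log10(1.0 + km / params.k_p)


def potency(K_D: float, params: Optional[KPParams] = None,
            mode: Literal["linearized", "numeric"] = "numeric") -> float:
    """Ligand concentration (uM) needed to reach the C_N threshold.

    ``numeric`` solves C_N(L_0) = threshold by monotone bisection on
    L_0 in [1e-8, 1e6] uM (C_N is strictly increasing in L_0);
    ``linearized`` evaluates the closed form, interpreting lambda_ as
    log10(threshold-setting concentration).  Returns uM; an unreachable
    threshold (C_N at saturating ligand below threshold) returns inf.
    """
    p = params if params is not None else KPParams()
    if mode == "linearized":
        return 10.0 ** log_potency_linearized(K_D, p)
    km = membrane_off_rate_from_KD(K_D, p.F, p)

    def cn(L0: float) -> float:
        return signalling_occupancy(bound_complex(L0, p.R_0, km, p.k_on),
                                    km, p.N, p.k_p)

    lo, hi = 1e-8, 1e6
    if cn(hi) < p.threshold:
        return math.inf
    if cn(lo) >= p.threshold:
        return lo
    return float(optimize.brentq(lambda L0: cn(L0) - p.threshold, lo, hi,
                                 rtol=1e-6))


def discrimination_power(params: Optional[KPParams] = None,
                         koff_hi: float = 0.5,
                         koff_lo: float = 10.0 ** 1.5) -> float:
    """Discrimination power alpha between a strong and a weak agonist.

    alpha = [log10 P(weak) - log10 P(strong)] / [log10 koff_weak -
    log10 koff_strong], with the defaults koff = 0.5 s^-1 (higher
    affinity) and 10^1.5 s^-1 (lower affinity).  Uses the linearised
    potency, in which the lambda offset cancels; alpha = 1 would mean
    potency tracks off-rate proportionally, alpha = 0 no discrimination.
    """
    p = params if params is not None else KPParams()
    kd_hi, kd_lo = koff_hi / p.k_on, koff_lo / p.k_on
    num = log_potency_linearized(kd_lo, p) - log_potency_linearized(kd_hi, p)
    return num / (math.log10(koff_lo) - math.log10(koff_hi))


# ---------------------------------------------------------------------------
# fitting potency-vs-affinity data

@dataclass
class KPFitResult:
    """Fit of per-condition force (and threshold offset) to potency data."""

    conditions: list
    F: dict  # condition -> pN
    se_F: dict
    lambda_: dict  # condition -> log10 uM (same value repeated in global mode)
    se_lambda: dict
    mode: str
    sse: float
    df: int
    n_points: int

    @property
    def n_free(self) -> int:
        return self.n_points - self.df


def _predict(kd: np.ndarray, cond_idx: np.ndarray, F: np.ndarray,
             lam: np.ndarray, base: KPParams) -> np.ndarray:
    """Vectorised linearised log-potency for all data rows."""
    xb = base.relation.slope * np.log10(kd) + base.relation.intercept
    km = base.k_on * kd * np.exp(xb * F[cond_idx] / base.k_B_T)
    return lam[cond_idx] + base.N * np.log10(1.0 + km / base.k_p)


def fit_potency(data: pd.DataFrame,
                mode: Literal["global_lambda", "local_lambda"] = "global_lambda",
                base: Optional[KPParams] = None,
                weight_by_sem: bool = False) -> KPFitResult:
    """Fit forces (and threshold offsets) to log-potency vs affinity data.

    ``data`` columns: ``condition, ligand, KD_uM, logP_obs`` (and ``sem``
    when weighting).  N, k_p, k_on and the x_beta(K_D) relation are held
    fixed at ``base``; the free parameters are one force per condition
    and either a single shared lambda (``global_lambda``) or one per
    condition (``local_lambda``).  Least squares with multi-start on F;
    standard errors from the Jacobian at the optimum.
    """
    base = base if base is not None else KPParams()
    conditions = list(dict.fromkeys(data["condition"]))
    for c in conditions:
        if (data["condition"] == c).sum() < 2:
            raise FitInputError(f"condition {c!r} has < 2 antigens")
    n_cond = len(conditions)
    y = data["logP_obs"].to_numpy(dtype=float)
    kd = data["KD_uM"].to_numpy(dtype=float)
    cidx = {c: i for i, c in enumerate(conditions)}
    cond_idx = data["condition"].map(cidx).to_numpy(dtype=np.int64)
    w = np.ones_like(y)
    if weight_by_sem:
        sem = data["sem"].to_numpy(dtype=float)
        if np.any(sem <= 0):
            raise FitInputError("SEMs must be positive for weighting")
        w = 1.0 / sem

    n_lam = n_cond if mode == "local_lambda" else 1

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        F = theta[:n_cond]
        lam = theta[n_cond:] if n_lam == n_cond else np.repeat(theta[n_cond], n_cond)
        return F, lam

    def resid(theta: np.ndarray) -> np.ndarray:
        F, lam = unpack(theta)
        return w * (_predict(kd, cond_idx, F, lam, base) - y)

    lam0 = float(np.median(y)) - 1.0
    best = None
    for f0 in (10.0, 40.0, 100.0):
        theta0 = np.concatenate([np.full(n_cond, f0), np.full(n_lam, lam0)])
        lower = np.concatenate([np.zeros(n_cond), np.full(n_lam, -np.inf)])
        upper = np.full(n_cond + n_lam, np.inf)
        try:
            res = optimize.least_squares(resid, theta0, bounds=(lower, upper))
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitInputError("potency fit failed to converge from all starts")

    theta = best.x
    n_free = n_cond + n_lam
    df = len(y) - n_free
    sse = float(np.sum(best.fun**2))
    # covariance from the Jacobian; residual variance estimated from the fit
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (sse / max(df, 1))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(n_free, math.nan)
    F, lam = unpack(theta)
    se_F = se[:n_cond]
    se_lam = se[n_cond:] if n_lam == n_cond else np.repeat(se[n_cond], n_cond)
    return KPFitResult(
        conditions=conditions,
        F={c: float(F[i]) for i, c in enumerate(conditions)},
        se_F={c: float(se_F[i]) for i, c in enumerate(conditions)},
        lambda_={c: float(lam[i]) for i, c in enumerate(conditions)},
        se_lambda={c: float(se_lam[i]) for i, c in enumerate(conditions)},
        mode=mode, sse=sse, df=df, n_points=len(y))


def f_test_nested(global_fit: KPFitResult, local_fit: KPFitResult,
                  ) -> tuple[float, float]:
    """Extra-sum-of-squares F test of a nested model pair.

    The global (fewer-parameter) model is the null; returns (F, p).
    F = ((SSE_g - SSE_l)/(df_g - df_l)) / (SSE_l/df_l), with p from the
    F(df_g - df_l, df_l) distribution.
    """
    if local_fit.df >= global_fit.df:
        raise FitInputError("local model must have more free parameters")
    if local_fit.sse > global_fit.sse + 1e-12:
        raise FitInputError("SSE of the larger model exceeds the nested model; "
                            "fits are not properly nested")
    d1 = global_fit.df - local_fit.df
    d2 = local_fit.df
    if local_fit.sse <= 0:
        return math.inf, 0.0
    F = ((global_fit.sse - local_fit.sse) / d1) / (local_fit.sse / d2)
    F = max(F, 0.0)
    return float(F), float(stats.f.sf(F, d1, d2))
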