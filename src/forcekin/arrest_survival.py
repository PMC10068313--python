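"""Single-bond survival analysis for laminar-flow-chamber arrest data.

In the flow-chamber assay, receptor-coated microspheres flow over a
low-density ligand surface; transient bead arrests report single-bond
lifetimes and the flow velocity sets the tensile force on the bond.
This module turns tables of arrest events into force-resolved off-rates
and Bell-model parameters:

1. pool events into velocity bins and convert bin-mean velocity to force;
2. exclude bins whose binding linear density (arrests per mm travelled)
   is not distinguishable from the ligand-free control;
3. build empirical survival curves and subtract the non-specific
   (ligand-free) arrest population;
4. estimate the off-rate per bin three ways — from survival at 1 s, at
   2 s, and by fitting an exponential decay with a plateau term;
5. fit Bell's model across bins and, across ligands, regress the force
   sensitivity x_beta on log10(K_D).

Event tables use the columns ``duration_s, velocity_um_s, condition,
ligand, density_label, experiment_id``; trajectory summaries use
``experiment_id, condition, ligand, density_label, bin_label,
n_arrests, total_distance_mm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Model

from .bell_kinetics import BODY_TEMPERATURE, BellBond, ForceSensitivityRelation, \
    TemperatureContext, fit_bell, fit_xbeta_log_slope
from .chamber import BeadModel, ChamberGeometry, force_for_velocity_bin
from .exceptions import CorrectionError, FitInputError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_VELOCITY_BINS", "SurvivalCurve", "OffRateEstimate", "BLDResult",
    "ForceSpectrumResult", "detect_arrests", "binding_linear_density",
    "specificity_filter", "empirical_survival", "survival_at",
    "correct_nonspecific", "qc_min_events", "off_rate_at_time",
    "fit_exponential_plateau", "ligand_force_spectrum",
    "xbeta_affinity_correlation", "assign_velocity_bins", "bin_label",
]

#: velocity bin edges in um/s; bins are half-open [lo, hi)
DEFAULT_VELOCITY_BINS: tuple[float, ...] = (2, 10, 20, 40, 60, 80, 120)

EVENT_COLUMNS = ["duration_s", "velocity_um_s", "condition", "ligand",
                 "density_label", "experiment_id"]


def bin_label(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})"


def assign_velocity_bins(df: pd.DataFrame,
                         edges: Sequence[float] = DEFAULT_VELOCITY_BINS) -> pd.DataFrame:
    """Attach a ``bin_label`` column; events outside the edge range are dropped."""
    edges = list(edges)
    v = df["velocity_um_s"].to_numpy()
    idx = np.searchsorted(edges, v, side="right") - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    out = df.loc[ok].copy()
    labels = [bin_label(edges[i], edges[i + 1]) for i in idx[ok]]
    out["bin_label"] = labels
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("velocity-range rule: dropped %d events outside [%g, %g) um/s",
                    n_drop, edges[0], edges[-1])
    return out


# ---------------------------------------------------------------------------
# arrest detection

def detect_arrests(positions: Sequence[float], velocity_threshold: float,
                   fps: float = 50.0) -> pd.DataFrame:
    """Detect arrests in a uniformly sampled bead x-position track.

    An arrest is a maximal run of frames whose instantaneous speed is
    below ``velocity_threshold`` (um/s); its duration is the run length
    times the frame interval.  The reported bead velocity is the median
    speed outside arrests.  Returns a table with ``duration_s`` and
    ``velocity_um_s`` (empty for tracks shorter than two frames).
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        return pd.DataFrame(columns=["duration_s", "velocity_um_s"])
    speed = np.abs(np.diff(x)) * fps
    arrested = speed < velocity_threshold
    free = speed[~arrested]
    v_free = float(np.median(free)) if free.size else 0.0
    durations = []
    run = 0
    for flag in arrested:
        if flag:
            run += 1
        elif run:
            durations.append(run / fps)
            run = 0
    if run:
        durations.append(run / fps)
    return pd.DataFrame({"duration_s": durations,
                         "velocity_um_s": [v_free] * len(durations)})


# ---------------------------------------------------------------------------
# binding linear density and specificity filter

@dataclass
class BLDResult:
    """Per-experiment binding linear densities with geometric aggregates."""

    values: np.ndarray  # arrests / mm, one per experiment
    geo_mean: float
    geo_sem_factor: float  # multiplicative: lower bar = geo_mean / factor


def binding_linear_density(summaries: pd.DataFrame) -> BLDResult:
    """Arrests per mm travelled, aggregated geometrically across experiments.

    geo-mean = exp(mean ln BLD); the geometric SEM is the multiplicative
    factor exp(sd(ln BLD)/sqrt(n)).
    """
    if len(summaries) == 0:
        raise InvalidParameterError("need at least one trajectory summary")
    d = summaries["total_distance_mm"].to_numpy(dtype=float)
    n = summaries["n_arrests"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise InvalidParameterError("total distance must be positive")
    bld = n / d
    pos = bld[bld > 0]
    if pos.size == 0:
        return BLDResult(values=bld, geo_mean=0.0, geo_sem_factor=math.nan)
    ln = np.log(pos)
    geo_mean = float(np.exp(ln.mean()))
    if pos.size > 1:
        factor = float(np.exp(ln.std(ddof=1) / math.sqrt(pos.size)))
    else:
        factor = math.nan
    return BLDResult(values=bld, geo_mean=geo_mean, geo_sem_factor=factor)


def specificity_filter(bld_pairs: pd.DataFrame,
                       mode: Literal["divide", "subtract"] = "divide",
                       ) -> tuple[list[str], pd.DataFrame]:
    """Exclude velocity bins whose binding is not above background.

    ``bld_pairs`` has one row per (bin_label, experiment_id) with columns
    ``bld_sample`` and ``bld_control``.  Per bin, the per-experiment
    fold change sample/control is aggregated geometrically; bins whose
    lower error bound falls below 1 (binding mostly non-specific) are
    excluded.  The lower bound is geo-mean divided by the geometric SEM
    factor (error bars on a log scale are multiplicative); a literal
    subtraction mode is provided as an alternative reading.

    Returns (retained bin labels, per-bin summary table).
    """
    rows = []
    retained = []
    for label, grp in bld_pairs.groupby("bin_label", sort=False):
        s = grp["bld_sample"].to_numpy(dtype=float)
        c = grp["bld_control"].to_numpy(dtype=float)
        ok = (s > 0) & (c > 0)
        if not ok.any():
            logger.warning("specificity rule: bin %s dropped (no usable control pairs)",
                           label)
            rows.append({"bin_label": label, "fold_geo_mean": math.nan,
                         "geo_sem_factor": math.nan, "lower_bound": math.nan,
                         "retained": False})
            continue
        ln_fold = np.log(s[ok] / c[ok])
        gm = math.exp(ln_fold.mean())
        gf = math.exp(ln_fold.std(ddof=1) / math.sqrt(ok.sum())) if ok.sum() > 1 else 1.0
        lower = gm / gf if mode == "divide" else gm * (2.0 - gf)
        keep = lower >= 1.0
        if keep:
            retained.append(label)
        else:
            logger.info("specificity rule: bin %s excluded (lower bound %.3g < 1)",
                        label, lower)
        rows.append({"bin_label": label, "fold_geo_mean": gm, "geo_sem_factor": gf,
                     "lower_bound": lower, "retained": keep})
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival curves

@dataclass
class SurvivalCurve:
    """Empirical single-bond survival, s(t) = P(duration >= t).

    ``times`` is the sorted set of observed durations and ``survival``
    the fraction of arrests at least that long — a left-continuous step
    function starting at 1 (s(0) = 1 implicitly).  Raw durations are
    retained on uncorrected curves for the event-count QC rule.
    """

    times: np.ndarray
    survival: np.ndarray
    n_events: int
    durations: Optional[np.ndarray] = None
    condition: Optional[str] = None
    corrected: bool = False


def empirical_survival(durations: Sequence[float],
                       condition: Optional[str] = None) -> SurvivalCurve:
    """Survival curve on the grid of observed durations."""
    d = np.sort(np.asarray(durations, dtype=float))
    if d.size == 0:
        raise InvalidParameterError("need at least one duration")
    times = np.unique(d)
    # fraction of events with duration >= t
    surv = 1.0 - np.searchsorted(d, times, side="left") / d.size
    return SurvivalCurve(times=times, survival=surv, n_events=int(d.size),
                         durations=d, condition=condition)


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Evaluate the step function s(t) = P(duration >= t)."""
    idx = int(np.searchsorted(curve.times, t, side="left"))
    if idx >= curve.times.size:
        # beyond the last observed time; a corrected curve keeps its tail value
        return float(curve.survival[-1]) if curve.corrected else 0.0
    return float(curve.survival[idx])


def correct_nonspecific(sample: SurvivalCurve, control: SurvivalCurve,
                        w_sample: float, w_control: float,
                        mode: Literal["weighted", "pointwise"] = "weighted",
                        ) -> SurvivalCurve:
    """Remove the non-specific arrest population from a survival curve.

    The sample surface produces a mixture of specific and non-specific
    arrests; the ligand-free control measures the non-specific component
    alone.  With arrest densities (arrests per unit distance) w_s and
    w_c, the specific survival is the mixture inversion

        s_corr(t) = (w_s s_s(t) - w_c s_c(t)) / (w_s - w_c),

    clipped to [0, 1].  ``mode='pointwise'`` instead subtracts the
    control curve directly (s_s - s_c, renormalised to start at 1),
    the literal reading of "subtracting control data".  A bin whose
    control density reaches the sample density is fully non-specific
    and the correction is refused.
    """
    if w_control < 0 or w_sample <= 0:
        raise InvalidParameterError("weights must be positive")
    if w_control >= w_sample:
        raise CorrectionError(
            f"control arrest density ({w_control:.3g}) >= sample ({w_sample:.3g}); "
            "bin is fully non-specific")
    s_c = np.array([survival_at(control, t) for t in sample.times])
    if mode == "weighted":
        s = (w_sample * sample.survival - w_control * s_c) / (w_sample - w_control)
    elif mode == "pointwise":
        s = sample.survival - s_c
        if s[0] > 0:
            s = s / s[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SurvivalCurve(times=sample.times.copy(), survival=np.clip(s, 0.0, 1.0),
                         n_events=sample.n_events, durations=sample.durations,
                         condition=sample.condition, corrected=True)


def qc_min_events(curve: SurvivalCurve, t_lo: float = 1.0, t_hi: float = 2.0,
                  min_events: int = 15) -> bool:
    """Event-count quality rule: require >= 15 raw durations in (1 s, 2 s].

    The interval is half-open: a duration of exactly 1 s does not count,
    exactly 2 s does.
    """
    if curve.durations is None:
        raise InvalidParameterError("curve has no raw durations attached")
    d = curve.durations
    return int(np.count_nonzero((d > t_lo) & (d <= t_hi))) >= min_events


# ---------------------------------------------------------------------------
# off-rate estimators

@dataclass
class OffRateEstimate:
    """A per-bin off-rate with provenance.

    ``method`` is one of ``at_1s``, ``at_2s`` or ``exp_fit``; the latter
    carries the fitted amplitude A and plateau B.  ``ok`` is False for
    flagged (non-identifiable or non-converged) estimates.
    """

    method: str
    value: float
    se: Optional[float] = None
    amplitude: Optional[float] = None
    plateau: Optional[float] = None
    ok: bool = True


def off_rate_at_time(curve: SurvivalCurve, t: float = 1.0) -> OffRateEstimate:
    """Off-rate from the survival fraction at time t: k = -ln(s)/t.

    When no event falls exactly at t the survival at the first
    subsequent event time is used (the step function's value there).
    """
    if t <= 0:
        raise InvalidParameterError("t must be positive")
    if curve.times[-1] < t and not curve.corrected:
        raise FitInputError(f"no event at or after t = {t} s")
    s = survival_at(curve, t)
    if s <= 0:
        raise FitInputError(f"survival is 0 at t = {t} s; off-rate undefined")
    value = -math.log(s) / t
    se = None
    if curve.n_events and 0 < s < 1:
        se = math.sqrt((1.0 - s) / (curve.n_events * s)) / t
    return OffRateEstimate(method=f"at_{t:g}s", value=value, se=se)


def _exp_plateau(t, A, b, k):
    B = A * b
    return (A - B) * np.exp(-k * t) + B


def fit_exponential_plateau(curve: SurvivalCurve, window: float = 5.0,
                            fix_plateau: Optional[float] = None) -> OffRateEstimate:
    """Fit s(t) = (A - B) exp(-k t) + B to the first ``window`` seconds.

    The plateau B absorbs the long-lived arrest subpopulation that makes
    the raw survival non-exponential.  The fit is parametrised as
    B = A * b with bounds 0 <= A <= 1.05, 0 <= b <= 1, enforcing
    0 <= B <= A <= 1.05.  ``fix_plateau`` pins b (use 0.0 for a pure
    exponential).  Non-convergence or a rate collapsing to the lower
    bound returns a flagged estimate.
    """
    mask = curve.times <= window
    t = curve.times[mask]
    s = curve.survival[mask]
    if np.unique(t).size < 5:
        raise FitInputError("need >= 5 distinct time points within the fit window")
    model = Model(_exp_plateau)
    # initial rate from the early log-slope, floored to keep it positive
    s0 = np.clip(s, 1e-9, None)
    k0 = max((np.log(s0[0]) - np.log(s0[min(len(s0) - 1, 10)])) /
             max(t[min(len(t) - 1, 10)] - t[0], 1e-9), 0.05)
    params = model.make_params(A=dict(value=min(1.0, max(s[0], 0.1)), min=0, max=1.05),
                               b=dict(value=float(s[-1]) if fix_plateau is None else fix_plateau,
                                      min=0, max=1, vary=fix_plateau is None),
                               k=dict(value=float(k0), min=1e-6))
    result = model.fit(s, params, t=t)
    k = float(result.params["k"].value)
    A = float(result.params["A"].value)
    B = A * float(result.params["b"].value)
    se = result.params["k"].stderr
    # rate is unidentifiable when the decaying component has no amplitude
    flagged = (not result.success) or k <= 1e-5 or (A - B) < 1e-3
    return OffRateEstimate(method="exp_fit", value=k,
                           se=float(se) if se is not None else None,
                           amplitude=A, plateau=B, ok=not flagged)


# ---------------------------------------------------------------------------
# the per-ligand pipeline

@dataclass
class ForceSpectrumResult:
    """Per-bin estimates and per-method Bell fits for one ligand."""

    table: pd.DataFrame  # bin_label, force_pN, n_events, qc_pass, koff_<m>, se_<m>
    bells: dict  # method -> BellBond | None
    excluded: list  # (bin_label, rule) pairs
    specificity: Optional[pd.DataFrame] = None


METHODS = ("at_1s", "at_2s", "exp_fit")


def _bin_weights(events_bin: pd.DataFrame, ctrl_bin: pd.DataFrame,
                 summaries: Optional[pd.DataFrame], label: str) -> tuple[float, float]:
    """Arrest densities (per mm) for sample and control in one bin."""
    if summaries is None:
        return float(len(events_bin)), float(len(ctrl_bin))
    sub = summaries[summaries["bin_label"] == label]
    sam = sub[sub["condition"] == "specific"]
    con = sub[sub["condition"] == "no_pMHC"]
    if len(sam) == 0 or sam["total_distance_mm"].sum() <= 0:
        return float(len(events_bin)), float(len(ctrl_bin))
    w_s = sam["n_arrests"].sum() / sam["total_distance_mm"].sum()
    w_c = (con["n_arrests"].sum() / con["total_distance_mm"].sum()
           if len(con) and con["total_distance_mm"].sum() > 0 else 0.0)
    return float(w_s), float(w_c)


def ligand_force_spectrum(events: pd.DataFrame, controls: Optional[pd.DataFrame] = None,
                          bead: BeadModel = BeadModel(),
                          geom: ChamberGeometry = ChamberGeometry(),
                          summaries: Optional[pd.DataFrame] = None,
                          edges: Sequence[float] = DEFAULT_VELOCITY_BINS,
                          temp: TemperatureContext = BODY_TEMPERATURE,
                          correction_mode: Literal["weighted", "pointwise"] = "weighted",
                          fit_method: Literal["log-linear", "nonlinear"] = "log-linear",
                          ) -> ForceSpectrumResult:
    """Full per-ligand pipeline: events -> per-bin off-rates -> Bell fit.

    For every velocity bin: compute the bond force from the bin-mean
    bead velocity, correct the survival curve for non-specific arrests
    using the paired control, apply the event-count QC rule, and
    estimate the off-rate with all three estimators.  Bell's model is
    then fitted per estimator over the surviving bins (at least three
    required; otherwise per-bin estimates are still reported and the
    Bell fit is None for that method).
    """
    ev = assign_velocity_bins(events, edges)
    ct = assign_velocity_bins(controls, edges) if controls is not None and len(controls) \
        else None

    spec_table = None
    retained_bins = None
    if summaries is not None:
        pairs = _specificity_pairs(summaries)
        if pairs is not None and len(pairs):
            retained_bins, spec_table = specificity_filter(pairs)

    rows = []
    excluded: list[tuple[str, str]] = []
    labels = [bin_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    for label in labels:
        ev_bin = ev[ev["bin_label"] == label]
        if len(ev_bin) == 0:
            excluded.append((label, "no-events"))
            continue
        if retained_bins is not None and label not in retained_bins:
            excluded.append((label, "specificity"))
            logger.info("bin %s excluded by specificity rule", label)
            continue
        ct_bin = ct[ct["bin_label"] == label] if ct is not None else ct
        force = force_for_velocity_bin(float(ev_bin["velocity_um_s"].mean()), bead, geom)
        curve = empirical_survival(ev_bin["duration_s"], condition="specific")
        if ct_bin is not None and len(ct_bin):
            w_s, w_c = _bin_weights(ev_bin, ct_bin, summaries, label)
            ctrl_curve = empirical_survival(ct_bin["duration_s"], condition="no_pMHC")
            try:
                corrected = correct_nonspecific(curve, ctrl_curve, w_s, w_c,
                                                mode=correction_mode)
            except CorrectionError:
                excluded.append((label, "fully-nonspecific"))
                logger.info("bin %s excluded: control density >= sample", label)
                continue
        else:
            corrected = curve
        qc = qc_min_events(curve)
        if not qc:
            logger.info("min-events rule: bin %s fails (<15 events in (1,2] s)", label)
        row: dict = {"bin_label": label, "force_pN": force,
                     "n_events": int(curve.n_events), "qc_pass": qc}
        for m in METHODS:
            est = _estimate(corrected, m)
            row[f"koff_{m}"] = est.value if est is not None else math.nan
            row[f"se_{m}"] = (est.se if est is not None and est.se is not None
                              else math.nan)
            row[f"ok_{m}"] = bool(est is not None and est.ok)
        rows.append(row)

    table = pd.DataFrame(rows)
    bells: dict[str, Optional[BellBond]] = {}
    for m in METHODS:
        bells[m] = None
        if len(table) == 0:
            continue
        use = table[table["qc_pass"] & table[f"ok_{m}"] &
                    np.isfinite(table[f"koff_{m}"])]
        if len(use) >= 3:
            se = use[f"se_{m}"].to_numpy()
            errs = se if np.all(np.isfinite(se)) and np.all(se > 0) else None
            try:
                bells[m] = fit_bell(use["force_pN"], use[f"koff_{m}"],
                                    rate_errors=errs, temp=temp, method=fit_method)
            except FitInputError:
                bells[m] = None
        else:
            logger.info("Bell fit skipped for %s: %d surviving bins (< 3)",
                        m, len(use))
    return ForceSpectrumResult(table=table, bells=bells, excluded=excluded,
                               specificity=spec_table)


def _estimate(curve: SurvivalCurve, method: str) -> Optional[OffRateEstimate]:
    try:
        if method == "at_1s":
            return off_rate_at_time(curve, 1.0)
        if method == "at_2s":
            return off_rate_at_time(curve, 2.0)
        if method == "exp_fit":
            return fit_exponential_plateau(curve)
    except (FitInputError, InvalidParameterError):
        return None
    raise ValueError(f"unknown method {method!r}")


def _specificity_pairs(summaries: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Per-(bin, experiment) sample and control BLDs from trajectory summaries."""
    need = {"experiment_id", "condition", "bin_label", "n_arrests", "total_distance_mm"}
    if not need.issubset(summaries.columns):
        return None
    rows = []
    for (label, exp), grp in summaries.groupby(["bin_label", "experiment_id"]):
        sam = grp[grp["condition"] == "specific"]
        con = grp[grp["condition"] == "no_pMHC"]
        if len(sam) == 0 or len(con) == 0:
            continue
        ds, dc = sam["total_distance_mm"].sum(), con["total_distance_mm"].sum()
        if ds <= 0 or dc <= 0:
            continue
        rows.append({"bin_label": label, "experiment_id": exp,
                     "bld_sample": sam["n_arrests"].sum() / ds,
                     "bld_control": con["n_arrests"].sum() / dc})
    return pd.DataFrame(rows)


def xbeta_affinity_correlation(fits: Sequence[tuple[BellBond, float]],
                               ) -> ForceSensitivityRelation:
    """Regress fitted x_beta on log10(K_D) across a ligand panel.

    ``fits`` holds (BellBond, K_D in uM) pairs.  Inverse-variance weights
    are used when every bond carries an x_beta standard error.
    """
    pairs = [(kd, bond.x_beta) for bond, kd in fits]
    errors = [bond.se_x_beta for bond, _ in fits]
    se = errors if all(e is not None and e > 0 for e in errors) else None
    return fit_xbeta_log_slope(pairs, x_beta_errors=se, argument_kind="K_D")
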