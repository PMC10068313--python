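"""Synthetic-data generators with known ground truth.

Every measured input of the force-spectroscopy study has a generator
here, so the full analysis chain can be exercised end to end without
any instrument data: flow-chamber arrest tables (Bell-model lifetimes
with a long-lived plateau subpopulation, non-specific arrests, frame
quantisation and movie-end censoring), Langmuir binding isotherms,
mono-exponential dissociation traces, potency-vs-affinity datasets
drawn from the proofreading model, and a toy two-chain protein complex
for the pulling simulator.  All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bell_kinetics import BODY_TEMPERATURE, BellBond, TemperatureContext, \
    membrane_off_rate
from .chamber import BeadModel, ChamberGeometry, force_for_velocity_bin
from .arrest_survival import DEFAULT_VELOCITY_BINS, bin_label
from .exceptions import InvalidParameterError
from .proofreading import KPParams, log_potency_linearized

__all__ = [
    "LFCSimConfig", "AssaySimOutput", "simulate_arrest_table",
    "simulate_isotherm", "simulate_dissociation_trace",
    "simulate_potency_dataset", "ToyComplex", "make_toy_complex",
]


# ---------------------------------------------------------------------------
# laminar flow chamber

@dataclass
class LFCSimConfig:
    """Study conditions for one simulated flow-chamber dataset.

    Specific arrest lifetimes are a mixture: with probability
    ``plateau_fraction`` an arrest comes from a very slow exponential
    (rate ``plateau_rate``) emulating the long-lived subpopulation seen
    in real survival curves; otherwise from Exp(k(F)) with k(F) from
    Bell's model at the bin force.  Non-specific arrests occur on both
    sample and control surfaces at ``nonspecific_bld`` arrests/mm with
    Exp(``nonspecific_rate``) lifetimes.  The probability that an
    encounter produces a bond decays logistically with flow velocity
    (midpoint ``binding_v50``, width ``binding_width``), emulating
    encounter-time-limited binding; it shapes arrest counts only, never
    lifetimes.  Durations are quantised to the frame interval and
    censored at the movie end; sub-half-frame arrests are unobservable
    and omitted.
    """

    true_bond: BellBond = field(default_factory=lambda: BellBond(0.29, 0.3))
    plateau_fraction: float = 0.10
    plateau_rate: float = 0.05  # 1/s
    nonspecific_rate: float = 1.0  # 1/s
    nonspecific_bld: float = 0.05  # arrests/mm on any surface
    specific_bld: float = 3.5  # arrests/mm at density 1, slow flow
    binding_v50: float = 80.0  # um/s
    binding_width: float = 15.0  # um/s
    densities: tuple[float, ...] = (1.0,)
    velocity_bins: tuple[float, ...] = DEFAULT_VELOCITY_BINS
    n_beads: int = 300
    n_experiments: int = 3
    experiment_scatter: float = 0.15  # sd of lognormal day-to-day BLD factor
    movie_length: float = 90.0  # s
    fps: float = 50.0
    ligand: str = "synthetic"
    bead: BeadModel = field(default_factory=BeadModel)
    geom: ChamberGeometry = field(default_factory=ChamberGeometry)

    def __post_init__(self) -> None:
        if not (0 <= self.plateau_fraction <= 1):
            raise InvalidParameterError("plateau_fraction must be in [0, 1]")
        if min(self.plateau_rate, self.nonspecific_rate, self.fps) <= 0:
            raise InvalidParameterError("rates and fps must be positive")


@dataclass
class AssaySimOutput:
    """Arrest events, trajectory summaries and the ground-truth ledger."""

    events: pd.DataFrame  # sample surface (specific + unlabelled non-specific)
    controls: pd.DataFrame  # ligand-free surface
    summaries: pd.DataFrame
    truth: dict


def _binding_probability(v: float, cfg: LFCSimConfig) -> float:
    return 1.0 / (1.0 + math.exp((v - cfg.binding_v50) / cfg.binding_width))


def _quantize(durations: np.ndarray, fps: float, movie_length: float,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-quantise and censor; returns (durations, censored flags).

    Durations round to the nearest frame; arrests shorter than half a
    frame are undetectable and dropped.
    """
    dt = 1.0 / fps
    q = np.round(durations / dt) * dt
    keep = q >= dt
    q = q[keep]
    censored = q >= movie_length
    q = np.minimum(q, movie_length)
    return q, censored


def simulate_arrest_table(config: Optional[LFCSimConfig] = None,
                          seed: int = 0,
                          temp: TemperatureContext = BODY_TEMPERATURE,
                          ) -> AssaySimOutput:
    """Simulate a full flow-chamber dataset in the analysis CSV schemas.

    Per experiment, velocity bin and ligand density: bead velocities are
    drawn uniformly within the bin, the bond force follows from the
    bin's hydrodynamics, and arrest counts are Poisson with mean
    BLD x total distance (specific BLD scales linearly with density and
    with the logistic encounter factor).  The control table replays the
    non-specific process on a ligand-free surface of equal distance.
    """
    cfg = config if config is not None else LFCSimConfig()
    rng = np.random.default_rng(seed)
    edges = cfg.velocity_bins
    ev_rows, ctrl_rows, sum_rows = [], [], []
    truth_bins = {}
    for e in range(cfg.n_experiments):
        exp_id = f"exp{e:02d}"
        day_factor = float(np.exp(rng.normal(0.0, cfg.experiment_scatter)))
        for lo, hi in zip(edges[:-1], edges[1:]):
            label = bin_label(lo, hi)
            v_mean = 0.5 * (lo + hi)
            force = force_for_velocity_bin(v_mean, cfg.bead, cfg.geom)
            k_force = membrane_off_rate(cfg.true_bond, force, temp)
            # distance travelled by the bead ensemble in this condition
            distance_mm = cfg.n_beads * v_mean * cfg.movie_length * 1e-3
            for density in cfg.densities:
                dens_label = f"d{density:g}"
                bld_spec = (cfg.specific_bld * density * day_factor
                            * _binding_probability(v_mean, cfg))
                n_spec = rng.poisson(bld_spec * distance_mm)
                n_ns = rng.poisson(cfg.nonspecific_bld * day_factor * distance_mm)
                is_plateau = rng.random(n_spec) < cfg.plateau_fraction
                d_spec = np.where(
                    is_plateau,
                    rng.exponential(1.0 / cfg.plateau_rate, n_spec),
                    rng.exponential(1.0 / max(k_force, 1e-12), n_spec))
                d_ns = rng.exponential(1.0 / cfg.nonspecific_rate, n_ns)
                d_all = np.concatenate([d_spec, d_ns])
                q, censored = _quantize(d_all, cfg.fps, cfg.movie_length)
                v_draw = rng.uniform(lo, hi, q.size)
                for d, v, c in zip(q, v_draw, censored):
                    ev_rows.append((d, v, "specific", cfg.ligand, dens_label,
                                    exp_id, bool(c)))
                sum_rows.append({"experiment_id": exp_id, "condition": "specific",
                                 "ligand": cfg.ligand, "density_label": dens_label,
                                 "bin_label": label, "n_arrests": int(q.size),
                                 "total_distance_mm": distance_mm})
                key = (exp_id, label, dens_label)
                truth_bins[key] = {"force_pN": force, "koff_per_s": k_force,
                                   "n_specific": int(n_spec),
                                   "n_nonspecific": int(n_ns)}
            # one paired ligand-free control per bin and experiment
            n_c = rng.poisson(cfg.nonspecific_bld * day_factor * distance_mm)
            d_c = rng.exponential(1.0 / cfg.nonspecific_rate, n_c)
            qc, cen_c = _quantize(d_c, cfg.fps, cfg.movie_length)
            v_draw = rng.uniform(lo, hi, qc.size)
            for d, v, c in zip(qc, v_draw, cen_c):
                ctrl_rows.append((d, v, "no_pMHC", "none", "d0", exp_id, bool(c)))
            sum_rows.append({"experiment_id": exp_id, "condition": "no_pMHC",
                             "ligand": "none", "density_label": "d0",
                             "bin_label": label, "n_arrests": int(qc.size),
                             "total_distance_mm": distance_mm})
    cols = ["duration_s", "velocity_um_s", "condition", "ligand",
            "density_label", "experiment_id", "censored"]
    events = pd.DataFrame(ev_rows, columns=cols)
    controls = pd.DataFrame(ctrl_rows, columns=cols)
    truth = {"k0_off": cfg.true_bond.k0_off, "x_beta_nm": cfg.true_bond.x_beta,
             "plateau_fraction": cfg.plateau_fraction,
             "plateau_rate": cfg.plateau_rate,
             "nonspecific_rate": cfg.nonspecific_rate,
             "bins": {f"{k[0]}|{k[1]}|{k[2]}": v for k, v in truth_bins.items()}}
    return AssaySimOutput(events=events, controls=controls,
                          summaries=pd.DataFrame(sum_rows), truth=truth)


# ---------------------------------------------------------------------------
# biosensor traces

def simulate_isotherm(KD: float, Bmax: float, concentrations: Sequence[float],
                      noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Langmuir isotherm samples with additive Gaussian noise (RU)."""
    if KD <= 0 or Bmax <= 0:
        raise InvalidParameterError("KD and Bmax must be positive")
    rng = np.random.default_rng(seed)
    C = np.asarray(concentrations, dtype=float)
    B = Bmax * C / (KD + C) + rng.normal(0.0, noise_sd, C.size)
    return pd.DataFrame({"conc_uM": C, "response_RU": B})


def simulate_dissociation_trace(koff: float, R0: float = 100.0, fps: float = 100.0,
                                duration: float = 2.0, noise_sd: float = 0.0,
                                seed: int = 0) -> pd.DataFrame:
    """Mono-exponential dissociation trace R0*exp(-koff t) with noise."""
    if koff < 0 or R0 <= 0 or fps <= 0:
        raise InvalidParameterError("invalid trace parameters")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / fps)
    R = R0 * np.exp(-koff * t) + rng.normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"t_s": t, "response_RU": R})


def simulate_potency_dataset(conditions: dict, KDs: Sequence[float],
                             noise_sd: float = 0.1, seed: int = 0,
                             base: Optional[KPParams] = None) -> pd.DataFrame:
    """Potency-vs-affinity tables drawn from the proofreading model.

    ``conditions`` maps a label to (force pN, lambda); per antigen the
    observed log10 potency is the forward model value plus Gaussian
    noise of sd ``noise_sd``.  Returns the schema consumed by
    :func:`forcekin.proofreading.fit_potency`.
    """
    base = base if base is not None else KPParams()
    rng = np.random.default_rng(seed)
    rows = []
    for cond, (F, lam) in conditions.items():
        p = replace(base, F=float(F), lambda_=float(lam))
        for i, kd in enumerate(KDs):
            mu = log_potency_linearized(float(kd), p)
            rows.append({"condition": cond, "ligand": f"L{i}", "KD_uM": float(kd),
                         "logP_obs": mu + rng.normal(0.0, noise_sd),
                         "sem": max(noise_sd, 1e-6)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy structure for the pulling simulator

@dataclass
class ToyComplex:
    """A synthetic two-chain complex with a planted binding interface.

    ``pdb_text`` is a minimal CA-only PDB; ``interface_pairs`` the
    planted inter-chain residue contacts as (chain, resi, chain, resi);
    ``contact_cutoff`` the CA-CA distance (Angstrom) that recovers
    exactly those pairs.
    """

    pdb_text: str
    interface_pairs: list
    contact_cutoff: float
    chain_ids: tuple[str, str] = ("A", "B")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.pdb_text)


def make_toy_complex(n_res_per_chain: int = 26, interface_window: int = 14,
                     seed: int = 0, jitter: float = 0.03,
                     contact_cutoff: float = 5.8) -> ToyComplex:
    """Build a synthetic two-helix complex with a planted interface.

    Each chain is an idealised alpha-helix (2.3 Angstrom radius,
    1.5 Angstrom rise, 100 degrees per residue), which gives the chains
    internal (i, i+3) contacts and hence bending stiffness once those
    become springs.  Chain B runs parallel to A at an axis separation of
    7 Angstrom over a central window of ``interface_window`` residues
    and bows away steeply outside it, so only window residues whose
    side faces the partner fall under the contact cutoff.  The planted
    inter-chain pairs are computed from the generated geometry itself
    and are exactly what a CA-CA cutoff of ``contact_cutoff`` recovers.
    A small seeded jitter makes different seeds produce distinct but
    equivalent structures.
    """
    n = n_res_per_chain
    m = interface_window
    if not (0 < m <= n):
        raise InvalidParameterError("interface window must be within the chain")
    rng = np.random.default_rng(seed)
    radius, rise, phi = 2.3, 1.5, math.radians(100.0)
    idx = np.arange(n)
    ang = phi * idx
    helix = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                             rise * idx])
    a_xyz = helix.copy()
    lo = (n - m) // 2
    sep = np.empty(n)
    for i in range(n):
        d = max(lo - i, i - (lo + m - 1), 0)
        sep[i] = 7.0 + 2.5 * d  # steep bow keeps off-window pairs apart
    # B faces A: mirror the azimuth so surfaces oppose, offset along +x
    b_xyz = np.column_stack([sep - radius * np.cos(ang),
                             radius * np.sin(ang), rise * idx + 0.75])
    coords = np.vstack([a_xyz, b_xyz]) + rng.normal(0.0, jitter, (2 * n, 3))

    # planted contacts straight from the geometry
    pairs = []
    for i in range(n):
        for j in range(n):
            d = float(np.linalg.norm(coords[i] - coords[n + j]))
            if d < contact_cutoff:
                pairs.append(("A", i + 1, "B", j + 1))

    lines = []
    serial = 1
    for ci, chain in enumerate("AB"):
        for r in range(n):
            x, yy, zz = coords[ci * n + r]
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain}{r + 1:4d}    "
                f"{x:8.3f}{yy:8.3f}{zz:8.3f}  1.00  0.00           C")
            serial += 1
        lines.append("TER")
    lines.append("END")
    return ToyComplex(pdb_text="\n".join(lines) + "\n", interface_pairs=pairs,
                      contact_cutoff=contact_cutoff)
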