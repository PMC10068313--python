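"""Structure-based coarse-grained pulling simulations.

One bead per residue (placed at the alpha-carbon), with a Go-type
potential built from the native structure: residue pairs in contact in
the native state attract, all other pairs only repel.  To probe the
mechanical strength of a receptor/ligand interface the complex is
stretched between two harmonic springs — one anchored in space at one
chain's C-terminus, the other attached to the partner chain's
C-terminus and retracted at constant speed — while the spring force is
recorded.  Rupture forces over a range of pulling speeds are summarised
by the Bell-Evans model, yielding an effective (k_off*tau, x_beta) per
construct; deleting subsets of interface contacts generates constructs
of graded stability whose x_beta-vs-log10(k_off) slope is the module's
headline statistic.

Model choices (where the source parameterisation leaves freedom):
intra-molecular contacts are harmonic springs (stiffness matched to the
curvature of the corresponding Lennard-Jones well, 72*eps/r0^2), which
prevents unfolding of the individual chains so that force traces show a
single rupture peak; inter-molecular contacts are 12-6 Lennard-Jones
wells of depth eps with minimum at the native distance; consecutive and
next-nearest backbone neighbours carry harmonic springs at their native
distances (the latter acting as a bending stiffness); everything else
repels as eps*(sigma/r)^12.  Simulation units: energy kB*T = 1, length
Angstrom, time tau; integration is Langevin (BAOAB), which reduces to
velocity Verlet in the frictionless limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial import cKDTree

from .bell_kinetics import BellEvansParams, ForceSensitivityRelation, \
    fit_bell_evans, fit_xbeta_log_slope
from .exceptions import FitInputError, InvalidParameterError

__all__ = [
    "CGStructure", "Deletion", "CGTopology", "PullingProtocol", "PullTrace",
    "RuptureResult", "load_structure", "native_contacts", "build_model",
    "run_pulling", "detect_rupture", "force_spectrum", "potential_gradient",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2}
DEFAULT_VDW = 1.7


@dataclass
class CGStructure:
    """One bead per residue, with heavy atoms cached for contact detection."""

    coords: np.ndarray  # (N, 3) alpha-carbon positions, Angstrom
    chains: list  # chain id per bead
    resnums: list  # residue number per bead
    heavy_xyz: list  # per bead: (n_atoms, 3) heavy-atom coordinates
    heavy_elements: list  # per bead: element symbols
    missing_ca: list = field(default_factory=list)  # (chain, resnum) skipped

    @property
    def n_beads(self) -> int:
        return len(self.chains)

    def terminus(self, chain: str, which: Literal["N", "C"] = "C") -> int:
        """Bead index of a chain terminus."""
        idx = [i for i, c in enumerate(self.chains) if c == chain]
        if not idx:
            raise InvalidParameterError(f"chain {chain!r} not in structure")
        return idx[0] if which == "N" else idx[-1]


def load_structure(path, chain_map: Optional[dict] = None) -> CGStructure:
    """Read a PDB file into a one-bead-per-residue representation.

    Beads sit at the alpha-carbon; all heavy atoms are cached for the
    contact criterion.  Among altloc duplicates the highest-occupancy
    conformer is kept.  ``chain_map`` (pdb chain id -> role label)
    restricts and relabels chains; residues without an alpha-carbon are
    recorded in ``missing_ca`` and skipped.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise InvalidParameterError(f"no models in {path}")
    model = st[0]
    coords, chains, resnums, hx, he, missing = [], [], [], [], [], []
    wanted = set(chain_map) if chain_map else None
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        label = chain_map[chain.name] if chain_map else chain.name
        for res in chain:
            # among altloc duplicates keep the highest-occupancy conformer
            best: dict = {}
            for a in res:
                if a.is_hydrogen():
                    continue
                kept = best.get(a.name)
                if kept is None or a.occ > kept.occ:
                    best[a.name] = a
            ca = best.get("CA")
            atoms = [(a.pos, a.element.name) for a in best.values()]
            if ca is None or not atoms:
                if res.het_flag != "W":
                    missing.append((label, res.seqid.num))
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            chains.append(label)
            resnums.append(res.seqid.num)
            hx.append(np.array([[p.x, p.y, p.z] for p, _ in atoms]))
            he.append([el for _, el in atoms])
    if chain_map:
        found = set(chains)
        absent = set(chain_map.values()) - found
        if absent:
            raise InvalidParameterError(f"mapped chains absent from PDB: {absent}")
    if not coords:
        raise InvalidParameterError(f"no usable residues in {path}")
    return CGStructure(coords=np.asarray(coords, dtype=float), chains=chains,
                       resnums=resnums, heavy_xyz=hx, heavy_elements=he,
                       missing_ca=missing)


def native_contacts(structure: CGStructure,
                    criterion: Literal["overlap", "cutoff"] = "overlap",
                    cutoff: float = 4.5, scale: float = 1.24) -> pd.DataFrame:
    """Native contact map from heavy-atom proximity.

    ``overlap``: residues i, j are in contact when any heavy-atom pair
    is closer than scale*(r_vdw_i + r_vdw_j) (default scale 1.24).
    ``cutoff``: plain heavy-atom distance cutoff (default 4.5 Angstrom).
    Sequential neighbour pairs (i, i+1) and (i, i+2) within a chain are
    excluded.  Returns a table with columns ``i, j, r0, kind`` where r0
    is the native CA-CA distance and kind is intra/inter (same or
    different chain).
    """
    n = structure.n_beads
    atom_xyz, atom_res, atom_rad = [], [], []
    for i in range(n):
        for xyz, el in zip(structure.heavy_xyz[i], structure.heavy_elements[i]):
            atom_xyz.append(xyz)
            atom_res.append(i)
            atom_rad.append(VDW_RADII.get(el, DEFAULT_VDW))
    atom_xyz = np.asarray(atom_xyz)
    atom_res = np.asarray(atom_res)
    atom_rad = np.asarray(atom_rad)
    if criterion == "overlap":
        search_r = scale * 2.0 * atom_rad.max()
    elif criterion == "cutoff":
        search_r = cutoff
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    tree = cKDTree(atom_xyz)
    pairs = tree.query_pairs(search_r, output_type="ndarray")
    seen = set()
    for a, b in pairs:
        ri, rj = int(atom_res[a]), int(atom_res[b])
        if ri == rj:
            continue
        i, j = (ri, rj) if ri < rj else (rj, ri)
        if (i, j) in seen:
            continue
        d = float(np.linalg.norm(atom_xyz[a] - atom_xyz[b]))
        if criterion == "overlap":
            if d >= scale * (atom_rad[a] + atom_rad[b]):
                continue
        elif d >= cutoff:
            continue
        if structure.chains[i] == structure.chains[j] and abs(i - j) <= 2:
            continue  # (i, i+1) and (i, i+2) are backbone, not contacts
        seen.add((i, j))
    rows = []
    for i, j in sorted(seen):
        r0 = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        kind = "intra" if structure.chains[i] == structure.chains[j] else "inter"
        rows.append({"i": i, "j": j, "r0": r0, "kind": kind})
    return pd.DataFrame(rows, columns=["i", "j", "r0", "kind"])


@dataclass
class Deletion:
    """Delete inter-molecular contacts between residue sets.

    Removes contacts joining residues of ``chain_a`` (optionally
    restricted to the inclusive residue-number range ``residues``) with
    any residue of ``chain_b``.  Mirrors the contact-deletion constructs
    used to generate complexes of graded stability.
    """

    chain_a: str
    chain_b: str
    residues: Optional[tuple[int, int]] = None


@dataclass
class CGTopology:
    """Arrays defining the coarse-grained potential (simulation units)."""

    coords0: np.ndarray
    chains: list
    bond_ij: np.ndarray  # consecutive + next-nearest backbone springs
    bond_r0: np.ndarray
    bond_k: np.ndarray
    harm_ij: np.ndarray  # intra-molecular native contacts as springs
    harm_r0: np.ndarray
    harm_k: np.ndarray
    lj_ij: np.ndarray  # inter-molecular native contacts, 12-6 wells
    lj_r0: np.ndarray
    lj_eps: np.ndarray
    excl: np.ndarray  # (N, N) uint8; 1 = no generic repulsion
    sigma_rep: float
    eps_rep: float
    structure: CGStructure

    @property
    def n_beads(self) -> int:
        return self.coords0.shape[0]

    @property
    def stiffest(self) -> float:
        parts = [self.bond_k.max() if self.bond_k.size else 0.0,
                 self.harm_k.max() if self.harm_k.size else 0.0]
        # LJ curvature at the minimum is 72 eps / r0^2
        if self.lj_eps.size:
            parts.append(float((72.0 * self.lj_eps / self.lj_r0**2).max()))
        return max(parts)


def build_model(structure: CGStructure, contacts: pd.DataFrame,
                construct: Optional[Sequence[Deletion]] = None,
                epsilon: float = 1.0, epsilon_inter: Optional[float] = None,
                k_bond: float = 50.0, k_angle: float = 15.0,
                sigma_rep: float = 4.0, eps_rep: float = 1.0,
                disulphides: Optional[Sequence[tuple[int, int]]] = None,
                ) -> CGTopology:
    """Assemble the coarse-grained topology, applying contact deletions.

    Backbone springs join (i, i+1) at stiffness ``k_bond`` and
    (i, i+2) at ``k_angle`` (bending stiffness), both at native lengths,
    so the native configuration is a stationary point of the potential.
    Intra-molecular contacts become harmonic springs (stiffness
    72*eps/r0^2, the matching Lennard-Jones curvature); inter-molecular
    contacts stay Lennard-Jones with depth ``epsilon``.  ``construct``
    deletions remove inter-molecular contacts only — backbone springs
    are never touched.  ``disulphides`` adds stiff springs between bead
    index pairs.
    """
    n = structure.n_beads
    valid_chains = set(structure.chains)
    drop = np.zeros(len(contacts), dtype=bool)
    if construct:
        for d in construct:
            if d.chain_a not in valid_chains or d.chain_b not in valid_chains:
                raise InvalidParameterError(
                    f"deletion references unknown chain: {d.chain_a}/{d.chain_b}")
            for idx, row in contacts.iterrows():
                if row["kind"] != "inter":
                    continue
                ci, cj = structure.chains[row["i"]], structure.chains[row["j"]]
                ni, nj = structure.resnums[row["i"]], structure.resnums[row["j"]]
                for (ca, ra, cb) in (((ci), (ni), (cj)), ((cj), (nj), (ci))):
                    if ca == d.chain_a and cb == d.chain_b:
                        if d.residues is None or d.residues[0] <= ra <= d.residues[1]:
                            drop[contacts.index.get_loc(idx)] = True
    kept = contacts.loc[~drop]

    bond_ij, bond_r0, bond_k = [], [], []
    for i in range(n - 1):
        for off, k in ((1, k_bond), (2, k_angle)):
            j = i + off
            if j < n and structure.chains[i] == structure.chains[j]:
                bond_ij.append((i, j))
                bond_r0.append(float(np.linalg.norm(
                    structure.coords[i] - structure.coords[j])))
                bond_k.append(k)
    if disulphides:
        for i, j in disulphides:
            bond_ij.append((i, j))
            bond_r0.append(float(np.linalg.norm(
                structure.coords[i] - structure.coords[j])))
            bond_k.append(k_bond)

    intra = kept[kept["kind"] == "intra"]
    inter = kept[kept["kind"] == "inter"]
    harm_ij = intra[["i", "j"]].to_numpy(dtype=np.int64).reshape(-1, 2)
    harm_r0 = intra["r0"].to_numpy(dtype=float)
    harm_k = 72.0 * epsilon / np.maximum(harm_r0, 1e-9) ** 2
    lj_ij = inter[["i", "j"]].to_numpy(dtype=np.int64).reshape(-1, 2)
    lj_r0 = inter["r0"].to_numpy(dtype=float)
    eps_i = epsilon if epsilon_inter is None else epsilon_inter
    lj_eps = np.full(lj_r0.shape, eps_i, dtype=float)

    excl = np.zeros((n, n), dtype=np.uint8)
    for (i, j) in bond_ij:
        excl[i, j] = excl[j, i] = 1
    for arr in (harm_ij, lj_ij):
        for i, j in arr:
            excl[i, j] = excl[j, i] = 1
    # deleted native pairs keep their exclusion: they become simply
    # non-interacting at long range, not sterically forbidden partners
    for idx, row in contacts.loc[drop].iterrows():
        excl[int(row["i"]), int(row["j"])] = 1
        excl[int(row["j"]), int(row["i"])] = 1

    return CGTopology(
        coords0=structure.coords.copy(), chains=list(structure.chains),
        bond_ij=np.asarray(bond_ij, dtype=np.int64).reshape(-1, 2),
        bond_r0=np.asarray(bond_r0, dtype=float),
        bond_k=np.asarray(bond_k, dtype=float),
        harm_ij=harm_ij, harm_r0=harm_r0, harm_k=np.asarray(harm_k, dtype=float),
        lj_ij=lj_ij, lj_r0=lj_r0, lj_eps=lj_eps, excl=excl,
        sigma_rep=sigma_rep, eps_rep=eps_rep, structure=structure)


# ---------------------------------------------------------------------------
# Langevin engine

@njit(cache=True)
def _forces_into(x, f, bond_ij, bond_r0, bond_k, harm_ij, harm_r0, harm_k,
                 lj_ij, lj_r0, lj_eps, excl, sigma_rep, eps_rep, rep_cut):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pot = 0.0
    for b in range(bond_ij.shape[0]):
        i, j = bond_ij[b, 0], bond_ij[b, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[b]
        pot += 0.5 * bond_k[b] * dr * dr
        fac = bond_k[b] * dr / r
        f[i, 0] += fac * dx0
        f[i, 1] += fac * dx1
        f[i, 2] += fac * dx2
        f[j, 0] -= fac * dx0
        f[j, 1] -= fac * dx1
        f[j, 2] -= fac * dx2
    for b in range(harm_ij.shape[0]):
        i, j = harm_ij[b, 0], harm_ij[b, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - harm_r0[b]
        pot += 0.5 * harm_k[b] * dr * dr
        fac = harm_k[b] * dr / r
        f[i, 0] += fac * dx0
        f[i, 1] += fac * dx1
        f[i, 2] += fac * dx2
        f[j, 0] -= fac * dx0
        f[j, 1] -= fac * dx1
        f[j, 2] -= fac * dx2
    for b in range(lj_ij.shape[0]):
        i, j = lj_ij[b, 0], lj_ij[b, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        s6 = (lj_r0[b] * lj_r0[b] / r2) ** 3
        pot += lj_eps[b] * (s6 * s6 - 2.0 * s6)
        # dU/dr = 12 eps (s6 - s12)/r ; force on j is -dU/dr * dx/r
        fac = 12.0 * lj_eps[b] * (s6 * s6 - s6) / r2
        f[i, 0] -= fac * dx0
        f[i, 1] -= fac * dx1
        f[i, 2] -= fac * dx2
        f[j, 0] += fac * dx0
        f[j, 1] += fac * dx1
        f[j, 2] += fac * dx2
    cut2 = rep_cut * rep_cut
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excl[i, j] == 1:
                continue
            dx0 = x[j, 0] - x[i, 0]
            if dx0 > rep_cut or dx0 < -rep_cut:
                continue
            dx1 = x[j, 1] - x[i, 1]
            if dx1 > rep_cut or dx1 < -rep_cut:
                continue
            dx2 = x[j, 2] - x[i, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 > cut2:
                continue
            s2 = sigma_rep * sigma_rep / r2
            s12 = s2 ** 6
            pot += eps_rep * s12
            fac = 12.0 * eps_rep * s12 / r2
            f[i, 0] -= fac * dx0
            f[i, 1] -= fac * dx1
            f[i, 2] -= fac * dx2
            f[j, 0] += fac * dx0
            f[j, 1] += fac * dx1
            f[j, 2] += fac * dx2
    return pot


@njit(cache=True, inline="always")
def _springs_into(x, f, t, fix_idx, pull_idx, fix_anchor, pull_anchor0,
                  pull_dir, kappa, v_pull):
    pot = 0.0
    fspring = 0.0
    for d in range(3):
        dxa = fix_anchor[d] - x[fix_idx, d]
        f[fix_idx, d] += kappa * dxa
        pot += 0.5 * kappa * dxa * dxa
        anchor = pull_anchor0[d] + v_pull * t * pull_dir[d]
        dxb = anchor - x[pull_idx, d]
        f[pull_idx, d] += kappa * dxb
        pot += 0.5 * kappa * dxb * dxb
        fspring += kappa * dxb * pull_dir[d]
    return pot, fspring


@njit(cache=True)
def _run_pull(x0, bond_ij, bond_r0, bond_k, harm_ij, harm_r0, harm_k,
              lj_ij, lj_r0, lj_eps, excl, sigma_rep, eps_rep, rep_cut,
              fix_idx, pull_idx, pull_dir, kappa, v_pull,
              dt, gamma, kT, n_steps, stride, seed, stop_on_rupture):
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    vel = np.random.standard_normal((n, 3)) * math.sqrt(kT)
    f = np.zeros((n, 3))
    fix_anchor = x0[fix_idx].copy()
    pull_anchor0 = x0[pull_idx].copy()
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0 else 0.0

    n_rec = n_steps // stride + 1
    t_out = np.empty(n_rec)
    f_out = np.empty(n_rec)
    intact_out = np.empty(n_rec)
    epot_out = np.empty(n_rec)
    ekin_out = np.empty(n_rec)

    pot = _forces_into(x, f, bond_ij, bond_r0, bond_k, harm_ij, harm_r0,
                       harm_k, lj_ij, lj_r0, lj_eps, excl, sigma_rep,
                       eps_rep, rep_cut)
    spot, fspring = _springs_into(x, f, 0.0, fix_idx, pull_idx, fix_anchor,
                                  pull_anchor0, pull_dir, kappa, v_pull)
    pot += spot
    rec = 0
    f_peak = 0.0
    blew_up = False
    step = 0
    while step <= n_steps:
        if step % stride == 0:
            t = step * dt
            n_intact = 0
            for b in range(lj_ij.shape[0]):
                i, j = lj_ij[b, 0], lj_ij[b, 1]
                dxr = 0.0
                for d in range(3):
                    dd = x[j, d] - x[i, d]
                    dxr += dd * dd
                if math.sqrt(dxr) < 1.5 * lj_r0[b]:
                    n_intact += 1
            ekin = 0.0
            for i in range(n):
                for d in range(3):
                    ekin += 0.5 * vel[i, d] * vel[i, d]
            t_out[rec] = t
            f_out[rec] = fspring
            intact_out[rec] = n_intact / max(lj_ij.shape[0], 1)
            epot_out[rec] = pot
            ekin_out[rec] = ekin
            if not math.isfinite(pot) or pot > 1e8:
                blew_up = True
                rec += 1
                break
            if fspring > f_peak:
                f_peak = fspring
            rec += 1
            if (stop_on_rupture and lj_ij.shape[0] > 0 and n_intact == 0
                    and fspring < 0.1 * f_peak and f_peak > 0.0):
                break
        # BAOAB step
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d]
                x[i, d] += 0.5 * dt * vel[i, d]
        if c2 > 0.0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * vel[i, d]
        step += 1
        pot = _forces_into(x, f, bond_ij, bond_r0, bond_k, harm_ij, harm_r0,
                           harm_k, lj_ij, lj_r0, lj_eps, excl, sigma_rep,
                           eps_rep, rep_cut)
        spot, fspring = _springs_into(x, f, step * dt, fix_idx, pull_idx,
                                      fix_anchor, pull_anchor0, pull_dir,
                                      kappa, v_pull)
        pot += spot
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d]
    return (t_out[:rec], f_out[:rec], intact_out[:rec], epot_out[:rec],
            ekin_out[:rec], x, blew_up)


@dataclass
class PullingProtocol:
    """Constant-speed pulling protocol.

    The spring on ``fix_chain``'s C-terminus is anchored in space; the
    spring on ``pull_chain``'s C-terminus retracts at ``speed`` (A/tau)
    along the initial attachment-to-attachment axis.  ``dt`` defaults to
    0.1/sqrt(k_max), an order below the stiffest oscillation period.
    """

    speed: float = 0.002  # A / tau
    kappa: float = 0.12  # kT / A^2
    fix_chain: str = "A"
    pull_chain: str = "B"
    gamma: float = 1.0  # 1 / tau
    kT: float = 1.0
    dt: Optional[float] = None
    max_pull_distance: float = 60.0  # A of anchor travel
    stride: int = 200
    stop_on_rupture: bool = True

    def __post_init__(self) -> None:
        if self.speed < 0 or self.kappa <= 0:
            raise InvalidParameterError("need speed >= 0 and kappa > 0")


@dataclass
class PullTrace:
    """Recorded pulling trajectory."""

    t: np.ndarray
    force: np.ndarray  # spring force along the pulling axis, kT/A
    frac_intact: np.ndarray  # fraction of inter-molecular contacts intact
    e_pot: np.ndarray
    e_kin: np.ndarray
    final_coords: np.ndarray
    blew_up: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "F": self.force,
                             "frac_intact": self.frac_intact})


def run_pulling(topology: CGTopology, protocol: PullingProtocol,
                seed: int = 0) -> PullTrace:
    """Integrate one pulling trajectory.

    The timestep is auto-derived from the stiffest interaction unless
    given; an energy blow-up aborts with diagnostics in the trace.
    """
    st = topology.structure
    fix_idx = st.terminus(protocol.fix_chain, "C")
    pull_idx = st.terminus(protocol.pull_chain, "C")
    axis = topology.coords0[pull_idx] - topology.coords0[fix_idx]
    norm = float(np.linalg.norm(axis))
    if norm <= 0:
        raise InvalidParameterError("attachment beads coincide")
    pull_dir = axis / norm
    k_max = max(topology.stiffest, protocol.kappa)
    dt = protocol.dt if protocol.dt is not None else 0.1 / math.sqrt(k_max)
    if protocol.speed > 0:
        n_steps = int(protocol.max_pull_distance / (protocol.speed * dt))
    else:
        n_steps = int(200.0 / dt)  # 200 tau of equilibrium dynamics
    rep_cut = 2.5 * topology.sigma_rep
    out = _run_pull(topology.coords0, topology.bond_ij, topology.bond_r0,
                    topology.bond_k, topology.harm_ij, topology.harm_r0,
                    topology.harm_k, topology.lj_ij, topology.lj_r0,
                    topology.lj_eps, topology.excl, topology.sigma_rep,
                    topology.eps_rep, rep_cut, fix_idx, pull_idx, pull_dir,
                    protocol.kappa, protocol.speed, dt, protocol.gamma,
                    protocol.kT, n_steps, protocol.stride, seed,
                    protocol.stop_on_rupture)
    t, f, intact, epot, ekin, xfinal, blew = out
    if blew:
        warnings.warn("energy blow-up during pulling; trajectory aborted",
                      stacklevel=2)
    return PullTrace(t=t, force=f, frac_intact=intact, e_pot=epot, e_kin=ekin,
                     final_coords=xfinal, blew_up=bool(blew))


@dataclass
class RuptureResult:
    f_max: float
    ruptured: bool
    multi_peak: bool = False


def detect_rupture(trace: PullTrace, smooth_window: int = 11,
                   peak_fraction: float = 0.5) -> RuptureResult:
    """Peak rupture force from a (lightly smoothed) force trace.

    F_max is the maximum of the moving-average-smoothed trace.  The
    rupture is validated by requiring all inter-molecular contacts
    broken by the end of the trace with the force back below 10% of the
    peak; otherwise the trajectory is flagged unruptured (caller should
    extend the simulation).  Multiple separated excursions above
    ``peak_fraction`` of the maximum set the multi-peak flag; the global
    maximum is returned regardless.
    """
    f = trace.force
    if f.size == 0:
        return RuptureResult(f_max=math.nan, ruptured=False)
    w = min(smooth_window, f.size)
    kernel = np.ones(w) / w
    fs = np.convolve(f, kernel, mode="same")
    f_max = float(fs.max())
    ruptured = bool(trace.frac_intact[-1] == 0.0
                    and fs[-1] < 0.25 * max(f_max, 1e-12))
    above = fs > peak_fraction * f_max
    # count separated runs above the fraction threshold
    runs = int(np.count_nonzero(np.diff(above.astype(int)) == 1) + int(above[0]))
    return RuptureResult(f_max=f_max, ruptured=ruptured, multi_peak=runs > 1)


@dataclass
class ForceSpectrumSimResult:
    """Rupture series, per-construct Bell-Evans fits and the slope."""

    ruptures: pd.DataFrame  # construct, speed, f_max_mean, f_max_sem, n
    params: dict  # construct -> BellEvansParams
    relation: Optional[ForceSensitivityRelation]


def force_spectrum(structure: CGStructure, contacts: pd.DataFrame,
                   constructs: dict, speeds: Sequence[float], n: int = 20,
                   protocol: Optional[PullingProtocol] = None, seed: int = 0,
                   epsilon: float = 1.0,
                   epsilon_inter: Optional[float] = None) -> ForceSpectrumSimResult:
    """Rupture-force spectrum over contact-deletion constructs.

    ``constructs`` maps a label to a deletion list (empty list = the
    intact complex).  For each construct and speed, ``n`` replicate
    trajectories yield mean and SEM of the peak force; the Bell-Evans
    model is fitted per construct and x_beta is regressed on
    log10(k_off*tau) across constructs (the negative-slope statistic).
    Requires >= 3 speeds; the relation needs >= 2 identifiable
    constructs.
    """
    if len(speeds) < 3:
        raise FitInputError("need >= 3 pulling speeds")
    proto = protocol if protocol is not None else PullingProtocol()
    rows = []
    params: dict[str, BellEvansParams] = {}
    rng = np.random.default_rng(seed)
    for label, deletions in constructs.items():
        topo = build_model(structure, contacts, construct=deletions,
                           epsilon=epsilon, epsilon_inter=epsilon_inter)
        means, sems = [], []
        for v in speeds:
            p = PullingProtocol(**{**proto.__dict__, "speed": float(v)})
            fmax = []
            for _ in range(n):
                s = int(rng.integers(0, 2**31 - 1))
                trace = run_pulling(topo, p, seed=s)
                r = detect_rupture(trace)
                if math.isfinite(r.f_max):
                    fmax.append(r.f_max)
            fmax = np.asarray(fmax)
            mean = float(fmax.mean())
            sem = float(fmax.std(ddof=1) / math.sqrt(fmax.size)) if fmax.size > 1 \
                else math.nan
            means.append(mean)
            sems.append(sem)
            rows.append({"construct": label, "speed": float(v),
                         "f_max_mean": mean, "f_max_sem": sem, "n": int(fmax.size)})
        sems_arr = np.asarray(sems)
        errs = sems_arr if np.all(np.isfinite(sems_arr)) and np.all(sems_arr > 0) \
            else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params[label] = fit_bell_evans(speeds, means, errs, kappa=proto.kappa,
                                           k_B_T=proto.kT)
    pairs, errors = [], []
    for label, p in params.items():
        if p.identifiable and p.k_off_tau > 0:
            pairs.append((p.k_off_tau, p.x_beta))
            errors.append(p.se_x_beta)
    relation = None
    if len(pairs) >= 2:
        se = errors if all(e is not None and e > 0 for e in errors) else None
        relation = fit_xbeta_log_slope(pairs, x_beta_errors=se,
                                       argument_kind="k_off")
    return ForceSpectrumSimResult(ruptures=pd.DataFrame(rows), params=params,
                                  relation=relation)


def potential_gradient(topology: CGTopology, coords: Optional[np.ndarray] = None,
                       ) -> np.ndarray:
    """Force on every bead (negative potential gradient), pulling springs off.

    At the native configuration this should vanish up to the weak
    generic repulsion between near-cutoff pairs — the stationarity
    property of a structure-based model.
    """
    x = topology.coords0 if coords is None else np.asarray(coords, dtype=float)
    f = np.zeros_like(x)
    _forces_into(x, f, topology.bond_ij, topology.bond_r0, topology.bond_k,
                 topology.harm_ij, topology.harm_r0, topology.harm_k,
                 topology.lj_ij, topology.lj_r0, topology.lj_eps,
                 topology.excl, topology.sigma_rep, topology.eps_rep,
                 2.5 * topology.sigma_rep)
    return f
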