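"""Laminar flow chamber hydrodynamics.

Maps flow conditions to the tensile force on a single receptor/ligand
bond tethering a microsphere to the chamber floor.  Near the wall the
flow is simple shear, v(z) = G z.  A sphere of radius ``a`` held by a
bond of length ``L`` experiences a drag force R, a torque Gamma, and a
lever-arm amplification, combining into

    R     = c_drag   * mu * a^2 * G        (c_drag   = 1.7005 * 6 pi)
    Gamma = c_torque * mu * a^3 * G        (c_torque = 0.9440 * 4)
    F     = (R + Gamma / a) * sqrt(a / (2 L))

SI internally; the API takes velocities in um/s, flow rates in ul/s and
returns forces in pN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import InvalidParameterError

__all__ = ["ChamberGeometry", "BeadModel", "shear_from_flow",
           "shear_from_bead_velocity", "bond_force", "force_for_velocity_bin"]

#: printed drag prefactor, approximately the "32" of R ~ 32 mu a^2 G
DRAG_COEFF = 1.7005 * 6 * math.pi
TORQUE_COEFF = 0.9440 * 4


@dataclass(frozen=True)
class ChamberGeometry:
    """Flow-cell dimensions in mm (default 12 x 2 x 0.25 mm channel)."""

    length_mm: float = 12.0
    width_mm: float = 2.0
    height_mm: float = 0.25

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise InvalidParameterError("chamber dimensions must be positive")


@dataclass(frozen=True)
class BeadModel:
    """Microsphere, medium and tether parameters.

    Defaults: 4.5 um tosyl-activated beads (radius 2.25 um), aqueous
    medium at 1 mPa s, 30 nm bond/linker length.  ``translation_factor``
    is the wall-drag reduction of a sphere translating in contact with a
    plane (0.7431), used to infer shear rate from observed bead velocity.
    ``torque_with_pi`` switches the torque prefactor from the as-printed
    0.9440*4 to the literature form 0.9440*4*pi.
    """

    radius_um: float = 2.25
    viscosity_pa_s: float = 1.0e-3
    bond_length_nm: float = 30.0
    drag_coeff: float = DRAG_COEFF
    torque_coeff: float = TORQUE_COEFF
    translation_factor: float = 0.7431
    torque_with_pi: bool = False

    def __post_init__(self) -> None:
        if min(self.radius_um, self.viscosity_pa_s, self.bond_length_nm) <= 0:
            raise InvalidParameterError("bead parameters must be positive")


def shear_from_flow(Q_ul_s: float, geom: ChamberGeometry = ChamberGeometry()) -> float:
    """Wall shear rate (1/s) from volumetric flow rate (ul/s).

    Plane-Poiseuille wall shear G = 6 Q / (l H^2) for a channel of width
    l and height H (H << l).
    """
    if Q_ul_s < 0:
        raise InvalidParameterError("flow rate must be >= 0")
    Q = Q_ul_s * 1e-9  # m^3/s
    l = geom.width_mm * 1e-3
    H = geom.height_mm * 1e-3
    return 6.0 * Q / (l * H * H)


def shear_from_bead_velocity(v_um_s: float, bead: BeadModel = BeadModel()) -> float:
    """Shear rate (1/s) from the translation velocity of a sedimented bead.

    A sphere rolling/sliding along the wall moves slower than the
    undisturbed fluid at its centre height; v = c_t * a * G with
    c_t = ``bead.translation_factor``.
    """
    if v_um_s < 0:
        raise InvalidParameterError("velocity must be >= 0")
    return (v_um_s * 1e-6) / (bead.translation_factor * bead.radius_um * 1e-6)


def bond_force(G: float, bead: BeadModel = BeadModel()) -> float:
    """Tensile force (pN) on the tethering bond at shear rate G (1/s)."""
    if G < 0:
        raise InvalidParameterError("shear rate must be >= 0")
    a = bead.radius_um * 1e-6
    L = bead.bond_length_nm * 1e-9
    mu = bead.viscosity_pa_s
    c_t = bead.torque_coeff * (math.pi if bead.torque_with_pi else 1.0)
    R = bead.drag_coeff * mu * a * a * G
    torque_over_a = c_t * mu * a * a * G
    F = (R + torque_over_a) * math.sqrt(a / (2.0 * L))
    return F * 1e12


def force_for_velocity_bin(mean_velocity_um_s: float,
                           bead: BeadModel = BeadModel(),
                           geom: ChamberGeometry = ChamberGeometry()) -> float:
    """Bond force (pN) for a velocity bin, from its mean bead velocity.

    Composition of :func:`shear_from_bead_velocity` and
    :func:`bond_force`; the chamber geometry does not enter (force
    depends on local shear only) but is accepted for interface symmetry.
    """
    return bond_force(shear_from_bead_velocity(mean_velocity_um_s, bead), bead)
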