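"""Backbone geometry and Gaussian conformational restraints.

A coarse-grained peptide is represented by one backbone bead per residue.
Its secondary-structure state (amphipathic helix vs extended-disordered
chain) is imposed by Gaussian restraining potentials acting on the angles
theta between three consecutive beads and the dihedrals phi between four
consecutive beads:

    V(x) = -K * exp(-(x - x_min)**2 / sigma)

with x in degrees and sigma in degrees**2 (the literal printed form, so
sigma plays the role of a squared width). The potential is a negative
Gaussian well of depth K centred on the target geometry; far from the
target it decays to zero, leaving the chain unrestrained rather than
harmonically trapped. Analytic forces are

    F = -dV/dx * dx/dr = -2*K*(x - x_min)/sigma * exp(-(x-x_min)**2/sigma) * dx/dr.

The dihedral deviation is wrapped into (-180, 180] before squaring so the
well is periodic and has no cliff at +/-180 degrees.

The numeric defaults for the two states are illustrative placeholders
(the original parameterisation lives in prior work and is not printed
here); every entry point accepts explicit :class:`RestraintParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .units import wrap_degrees

__all__ = [
    "DegenerateGeometryError",
    "RestraintParams",
    "BeadChain",
    "RestraintEnergyReport",
    "HELICAL_DEFAULTS",
    "EXTENDED_DEFAULTS",
    "default_params",
    "compute_angle",
    "compute_dihedral",
    "angle_restraint_energy",
    "angle_restraint_force",
    "dihedral_restraint_energy",
    "dihedral_restraint_force",
    "chain_restraint_energy",
    "chain_restraint_forces",
]

_RAD2DEG = 180.0 / np.pi
_EPS_GUARD = 1e-12  # guard on the arccos / norm arguments at degenerate geometry


class DegenerateGeometryError(ValueError):
    """Raised when coincident or collinear beads make an angle undefined."""


@dataclass(frozen=True)
class RestraintParams:
    """Per-state Gaussian restraint parameters.

    Parameters
    ----------
    state : {"helical", "extended"}
    K_angle, K_dihedral : float
        Well depths, kJ/mol (>= 0).
    theta_min, phi_min : float
        Target angle / dihedral, degrees. theta_min in (0, 180),
        phi_min in (-180, 180].
    sigma_angle, sigma_dihedral : float
        Gaussian width parameters, degrees**2 (> 0).
    """

    state: str
    K_angle: float
    theta_min: float
    sigma_angle: float
    K_dihedral: float
    phi_min: float
    sigma_dihedral: float

    def __post_init__(self):
        if self.state not in ("helical", "extended"):
            raise ValueError(f"state must be 'helical' or 'extended', got {self.state!r}")
        if self.K_angle < 0 or self.K_dihedral < 0:
            raise ValueError("restraint depths K must be >= 0 (kJ/mol)")
        if self.sigma_angle <= 0 or self.sigma_dihedral <= 0:
            raise ValueError("sigma must be > 0 (degrees**2)")
        if not 0.0 < self.theta_min < 180.0:
            raise ValueError(f"theta_min must lie in (0, 180) degrees, got {self.theta_min}")
        if not -180.0 < self.phi_min <= 180.0:
            raise ValueError(f"phi_min must lie in (-180, 180] degrees, got {self.phi_min}")

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "K_angle": self.K_angle,
            "theta_min": self.theta_min,
            "sigma_angle": self.sigma_angle,
            "K_dihedral": self.K_dihedral,
            "phi_min": self.phi_min,
            "sigma_dihedral": self.sigma_dihedral,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RestraintParams":
        return cls(**{k: d[k] for k in (
            "state", "K_angle", "theta_min", "sigma_angle",
            "K_dihedral", "phi_min", "sigma_dihedral")})

    def replace(self, **kw) -> "RestraintParams":
        return replace(self, **kw)


#: Illustrative placeholder parameters for the helix-locked state.
HELICAL_DEFAULTS = RestraintParams(
    state="helical", K_angle=10.0, theta_min=96.0, sigma_angle=200.0,
    K_dihedral=10.0, phi_min=-120.0, sigma_dihedral=200.0)

#: Illustrative placeholder parameters for the extended-disordered state.
EXTENDED_DEFAULTS = RestraintParams(
    state="extended", K_angle=10.0, theta_min=127.0, sigma_angle=200.0,
    K_dihedral=10.0, phi_min=180.0, sigma_dihedral=200.0)


def default_params(state: str) -> RestraintParams:
    """Return the placeholder defaults for ``state``."""
    if state == "helical":
        return HELICAL_DEFAULTS
    if state == "extended":
        return EXTENDED_DEFAULTS
    raise ValueError(f"unknown state {state!r}")


@dataclass
class BeadChain:
    """Ordered backbone beads of a peptide segment.

    ``positions`` is an (n, 3) array in nm, one bead per residue id.
    At least four beads are required so that the chain defines at least
    one dihedral.
    """

    residue_ids: np.ndarray
    positions: np.ndarray
    state: str = "helical"

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.residue_ids)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} residue ids (expected ({n}, 3))")
        if n < 4:
            raise ValueError("a bead chain needs >= 4 beads to define a dihedral")
        bond = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if np.any(bond <= 0):
            raise ValueError("consecutive beads must not coincide")
        if self.state not in ("helical", "extended"):
            raise ValueError(f"state must be 'helical' or 'extended', got {self.state!r}")

    @property
    def n_beads(self) -> int:
        return len(self.residue_ids)

    def center_of_mass(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class RestraintEnergyReport:
    """Per-term breakdown of the chain restraint energy (kJ/mol)."""

    total: float
    per_angle_terms: list = field(default_factory=list)      # (first bead idx, theta deg, V)
    per_dihedral_terms: list = field(default_factory=list)   # (first bead idx, phi deg, V)


# ---------------------------------------------------------------------------
# geometry

def _as_vec(r, name):
    v = np.asarray(r, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


def compute_angle(ri, rj, rk) -> float:
    """Angle theta_ijk (degrees) at the middle bead j, in [0, 180]."""
    ri, rj, rk = _as_vec(ri, "ri"), _as_vec(rj, "rj"), _as_vec(rk, "rk")
    a = ri - rj
    b = rk - rj
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS_GUARD or nb < _EPS_GUARD:
        raise DegenerateGeometryError(
            f"coincident beads in angle triplet (|ri-rj|={na:.3g}, |rk-rj|={nb:.3g})")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def compute_dihedral(ri, rj, rk, rl) -> float:
    """Four-quadrant dihedral phi_ijkl (degrees) in (-180, 180].

    Uses the atan2 construction: cos phi from the normals of the two bond
    planes, sin phi from their cross product projected on the central
    bond, so cis is 0 degrees and trans is 180 degrees, and mirroring the
    four points negates phi.
    """
    ri, rj = _as_vec(ri, "ri"), _as_vec(rj, "rj")
    rk, rl = _as_vec(rk, "rk"), _as_vec(rl, "rl")
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    nn1, nn2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if nb2 < _EPS_GUARD:
        raise DegenerateGeometryError("central beads j, k coincide (dihedral undefined)")
    if nn1 < _EPS_GUARD or nn2 < _EPS_GUARD:
        raise DegenerateGeometryError(
            "collinear beads leave a dihedral plane undefined "
            f"(|b1 x b2|={nn1:.3g}, |b2 x b3|={nn2:.3g})")
    cos_phi = np.dot(n1, n2)
    sin_phi = np.dot(np.cross(n1, n2), b2) / nb2
    phi = float(np.degrees(np.arctan2(sin_phi, cos_phi)))
    return 180.0 if phi == -180.0 else phi


# ---------------------------------------------------------------------------
# Gaussian restraint energies

def _gauss_energy(dev, K, sigma):
    return -K * np.exp(-(dev * dev) / sigma)


def _gauss_dVdx(dev, K, sigma):
    # dV/dx in kJ/mol per degree
    return 2.0 * K * dev / sigma * np.exp(-(dev * dev) / sigma)


def angle_restraint_energy(theta: float, p: RestraintParams) -> float:
    """Gaussian angle restraint V(theta) = -K exp(-(theta-theta_min)^2/sigma)."""
    return float(_gauss_energy(theta - p.theta_min, p.K_angle, p.sigma_angle))


def dihedral_restraint_energy(phi: float, p: RestraintParams) -> float:
    """Gaussian dihedral restraint with the deviation wrapped into (-180, 180]."""
    dev = wrap_degrees(phi - p.phi_min)
    return float(_gauss_energy(dev, p.K_dihedral, p.sigma_dihedral))


# ---------------------------------------------------------------------------
# analytic gradients

def _angle_gradients(ri, rj, rk):
    """theta (degrees) and d theta/dr for the three beads, radians/nm."""
    a = ri - rj
    b = rk - rj
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS_GUARD or nb < _EPS_GUARD:
        raise DegenerateGeometryError("coincident beads in angle triplet")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    s = np.sqrt(max(1.0 - c * c, _EPS_GUARD))
    dthe_dri = -(b / (na * nb) - c * a / (na * na)) / s
    dthe_drk = -(a / (na * nb) - c * b / (nb * nb)) / s
    dthe_drj = -(dthe_dri + dthe_drk)
    theta = float(np.degrees(np.arccos(c)))
    return theta, (dthe_dri, dthe_drj, dthe_drk)


def _dihedral_gradients(ri, rj, rk, rl):
    """phi (degrees) and d phi/dr for the four beads, radians/nm."""
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    if nb2 < _EPS_GUARD or n1sq < _EPS_GUARD or n2sq < _EPS_GUARD:
        raise DegenerateGeometryError("degenerate geometry in dihedral quadruplet")
    cos_phi = np.dot(n1, n2)
    sin_phi = np.dot(np.cross(n1, n2), b2) / nb2
    phi = float(np.degrees(np.arctan2(sin_phi, cos_phi)))
    dphi_dri = -nb2 / n1sq * n1
    dphi_drl = nb2 / n2sq * n2
    s12 = np.dot(b1, b2) / (nb2 * nb2)
    s32 = np.dot(b3, b2) / (nb2 * nb2)
    dphi_drj = -(1.0 + s12) * dphi_dri + s32 * dphi_drl
    dphi_drk = s12 * dphi_dri - (1.0 + s32) * dphi_drl
    return phi, (dphi_dri, dphi_drj, dphi_drk, dphi_drl)


def angle_restraint_force(ri, rj, rk, p: RestraintParams):
    """Analytic forces (kJ/mol/nm) of the angle restraint on beads i, j, k."""
    ri, rj, rk = _as_vec(ri, "ri"), _as_vec(rj, "rj"), _as_vec(rk, "rk")
    theta, grads = _angle_gradients(ri, rj, rk)
    dVdtheta = _gauss_dVdx(theta - p.theta_min, p.K_angle, p.sigma_angle)
    # dV/dtheta is per degree; the positional gradients are radians/nm.
    pref = -dVdtheta * _RAD2DEG
    return tuple(pref * g for g in grads)


def dihedral_restraint_force(ri, rj, rk, rl, p: RestraintParams):
    """Analytic forces (kJ/mol/nm) of the dihedral restraint on beads i..l."""
    ri, rj = _as_vec(ri, "ri"), _as_vec(rj, "rj")
    rk, rl = _as_vec(rk, "rk"), _as_vec(rl, "rl")
    phi, grads = _dihedral_gradients(ri, rj, rk, rl)
    dev = wrap_degrees(phi - p.phi_min)
    dVdphi = _gauss_dVdx(dev, p.K_dihedral, p.sigma_dihedral)
    pref = -dVdphi * _RAD2DEG
    return tuple(pref * g for g in grads)


# ---------------------------------------------------------------------------
# whole-chain evaluation

def chain_restraint_energy(chain: BeadChain | np.ndarray,
                           p: RestraintParams) -> RestraintEnergyReport:
    """Total restraint energy: one angle term per consecutive triplet and one
    dihedral term per consecutive quadruplet along the chain."""
    pos = chain.positions if isinstance(chain, BeadChain) else np.asarray(chain, float)
    n = len(pos)
    if n < 4:
        raise ValueError(f"chain restraints need >= 4 beads, got {n}")
    angle_terms = []
    for i in range(n - 2):
        theta = compute_angle(pos[i], pos[i + 1], pos[i + 2])
        angle_terms.append((i, theta, angle_restraint_energy(theta, p)))
    dihedral_terms = []
    for i in range(n - 3):
        phi = compute_dihedral(pos[i], pos[i + 1], pos[i + 2], pos[i + 3])
        dihedral_terms.append((i, phi, dihedral_restraint_energy(phi, p)))
    total = sum(t[2] for t in angle_terms) + sum(t[2] for t in dihedral_terms)
    return RestraintEnergyReport(total=float(total),
                                 per_angle_terms=angle_terms,
                                 per_dihedral_terms=dihedral_terms)


def chain_restraint_forces(positions: np.ndarray, p: RestraintParams) -> np.ndarray:
    """Analytic restraint forces (kJ/mol/nm) on every bead of a chain.

    Reference (pure numpy) implementation; the simulation engine uses a
    compiled kernel that is cross-checked against this function.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 4:
        raise ValueError(f"chain restraints need >= 4 beads, got {n}")
    forces = np.zeros_like(pos)
    for i in range(n - 2):
        fi, fj, fk = angle_restraint_force(pos[i], pos[i + 1], pos[i + 2], p)
        forces[i] += fi
        forces[i + 1] += fj
        forces[i + 2] += fk
    for i in range(n - 3):
        fi, fj, fk, fl = dihedral_restraint_force(
            pos[i], pos[i + 1], pos[i + 2], pos[i + 3], p)
        forces[i] += fi
        forces[i + 1] += fj
        forces[i + 2] += fk
        forces[i + 3] += fl
    return forces
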