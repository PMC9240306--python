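"""Minimal overdamped Langevin engine for a restrained bead chain near an
implicit membrane slab.

The membrane is an attractive Gaussian well in z of depth
``well_depth_per_bead`` centred on the mean phosphate plane, plus a static
lattice of explicit phosphate beads so the contact analysis consumes the
same data model as real trajectories. Dynamics are Brownian
(Euler-Maruyama):

    x(t+dt) = x(t) + F dt / gamma + sqrt(2 kB T dt / gamma) * N(0, 1)

which samples the Boltzmann distribution of the potential; no inertia,
thermostat or barostat is involved. The box is periodic in xy with
reflecting walls in z, so the binding equilibrium is confined but
unbiased.

The well can couple to every bead independently (``coupling="per_bead"``,
the default) or to the chain's centre of mass (``coupling="com"``), whose
z marginal is then exactly Boltzmann in the well potential regardless of
the chain's internal interactions — the configuration used when an
analytically solvable binding equilibrium is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .contacts import Trajectory
from .restraints import BeadChain, RestraintParams
from .units import KB, LADDER

__all__ = [
    "MembraneModel",
    "SimulationConfig",
    "membrane_energy_force",
    "langevin_step",
    "run_trajectory",
    "run_temperature_ladder",
    "default_phosphate_lattice",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MembraneModel:
    """Implicit membrane slab: a Gaussian well in z at the phosphate plane.

    ``well_depth_per_bead`` (kJ/mol, >= 0) and ``well_width`` (nm, > 0)
    set E(z) = -depth * exp(-(z - plane_z)^2 / (2 width^2)); ``box`` is
    the (Lx, Ly, Lz) xy-periodic slab box in nm.
    """

    plane_z: float
    well_depth_per_bead: float
    well_width: float
    box: tuple
    coupling: str = "per_bead"

    def __post_init__(self):
        if self.well_depth_per_bead < 0:
            raise ValueError("well_depth_per_bead must be >= 0 kJ/mol")
        if self.well_width <= 0:
            raise ValueError("well_width must be > 0 nm")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError(f"box must be three positive lengths (nm), got {self.box}")
        if not 0 <= self.plane_z <= self.box[2]:
            raise ValueError("plane_z must lie inside the box")
        if self.coupling not in ("per_bead", "com"):
            raise ValueError(f"coupling must be 'per_bead' or 'com', got {self.coupling!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Engine parameters: dt (ps), friction gamma (kJ/mol ps/nm^2),
    temperature (K), step counts and seed, plus harmonic bond terms
    (bond_k kJ/mol/nm^2, bond_r0 nm) between consecutive beads."""

    dt: float
    temperature: float
    n_steps: int
    friction: float = 1.0
    save_interval: int = 1
    seed: int = 0
    bond_k: float = 0.0
    bond_r0: float = 0.35

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0 ps")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 K")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def membrane_energy_force(z, m: MembraneModel):
    """Energy (kJ/mol) and force -dE/dz (kJ/mol/nm) of the membrane well
    at height(s) ``z``; vectorised over arrays."""
    z = np.asarray(z, dtype=float)
    d = z - m.plane_z
    inv2w2 = 1.0 / (2.0 * m.well_width ** 2)
    g = np.exp(-d * d * inv2w2)
    energy = -m.well_depth_per_bead * g
    force = -2.0 * inv2w2 * m.well_depth_per_bead * d * g
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def langevin_step(positions: np.ndarray, forces: np.ndarray,
                  cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One Euler-Maruyama update (reference implementation; the engine
    proper uses a compiled kernel with identical arithmetic)."""
    positions = np.asarray(positions, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if positions.shape != forces.shape:
        raise ValueError(f"shape mismatch: positions {positions.shape} vs forces {forces.shape}")
    if not np.all(np.isfinite(forces)):
        bad = np.argwhere(~np.isfinite(forces))
        raise FloatingPointError(f"non-finite force at bead/component {bad[0].tolist()}")
    sigma = np.sqrt(2.0 * KB * cfg.temperature * cfg.dt / cfg.friction)
    return positions + forces * cfg.dt / cfg.friction + sigma * rng.standard_normal(positions.shape)


def default_phosphate_lattice(m: MembraneModel, spacing: float = 0.5) -> np.ndarray:
    """Square lattice of phosphate beads at the mean phosphate plane."""
    nx = max(2, int(round(m.box[0] / spacing)))
    ny = max(2, int(round(m.box[1] / spacing)))
    xs = (np.arange(nx) + 0.5) * m.box[0] / nx
    ys = (np.arange(ny) + 0.5) * m.box[1] / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(),
                            np.full(X.size, m.plane_z)])


def _chain_positions(chain) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(chain, BeadChain):
        return chain.positions.copy(), chain.residue_ids.copy()
    pos = np.atleast_2d(np.asarray(chain, dtype=float)).copy()
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError(f"chain positions must be (n, 3), got {pos.shape}")
    return pos, np.arange(1, len(pos) + 1)


def run_trajectory(chain, m: MembraneModel, p: RestraintParams | None,
                   cfg: SimulationConfig, phosphates: np.ndarray | None = None,
                   start_distance: float | None = 4.0,
                   noise_chunk: int = 20000) -> Trajectory:
    """Simulate the chain and return saved frames as a :class:`Trajectory`.

    The chain's centre of mass starts ``start_distance`` nm above the
    phosphate plane (pass None to keep the supplied coordinates). Frames
    are saved every ``save_interval`` steps, the initial configuration
    included. ``p=None`` disables the conformational restraints (the
    chain may then be any length >= 1).
    """
    pos, residue_ids = _chain_positions(chain)
    n = len(pos)
    if p is not None and n < 4:
        raise ValueError("conformational restraints need a chain of >= 4 beads")
    if start_distance is not None:
        pos[:, 2] += (m.plane_z + start_distance) - pos[:, 2].mean()
    if np.any(pos[:, 2] < 0) or np.any(pos[:, 2] > m.box[2]):
        raise ValueError("initial chain extends outside the z walls of the box")
    if phosphates is None:
        phosphates = default_phosphate_lattice(m)

    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(2.0 * KB * cfg.temperature * cfg.dt / cfg.friction)
    mobility_dt = cfg.dt / cfg.friction
    inv2w2 = 1.0 / (2.0 * m.well_width ** 2)
    use_restraints = p is not None
    K_a, th0, s_a = (p.K_angle, p.theta_min, p.sigma_angle) if use_restraints else (0.0, 0.0, 1.0)
    K_d, ph0, s_d = (p.K_dihedral, p.phi_min, p.sigma_dihedral) if use_restraints else (0.0, 0.0, 1.0)

    n_saved = cfg.n_steps // cfg.save_interval
    frames = np.empty((n_saved + 1, n, 3))
    frames[0] = pos

    def advance(n_sub):
        noise = sigma * rng.standard_normal((n_sub, n, 3))
        status = _kernels.run_steps(
            pos, noise, mobility_dt,
            float(m.box[0]), float(m.box[1]), float(m.box[2]),
            float(m.plane_z), float(m.well_depth_per_bead), inv2w2,
            m.coupling == "com",
            float(cfg.bond_k), float(cfg.bond_r0),
            use_restraints, K_a, th0, s_a, K_d, ph0, s_d)
        if status != 0:
            raise FloatingPointError(
                f"non-finite force encountered (T={cfg.temperature} K, seed={cfg.seed}); "
                "reduce dt or soften the potentials")

    for k in range(n_saved):
        advance(cfg.save_interval)
        frames[k + 1] = pos
    remainder = cfg.n_steps % cfg.save_interval
    if remainder:
        advance(remainder)

    return Trajectory(
        residue_ids=residue_ids,
        peptide=frames,
        phosphates=phosphates,
        box=np.asarray(m.box, dtype=float),
        temperature=cfg.temperature,
        metadata={
            "engine": "overdamped-langevin",
            "seed": int(cfg.seed),
            "dt_ps": cfg.dt,
            "friction": cfg.friction,
            "n_steps": int(cfg.n_steps),
            "save_interval": int(cfg.save_interval),
            "bond_k": cfg.bond_k,
            "bond_r0": cfg.bond_r0,
            "membrane": {"plane_z": m.plane_z, "depth": m.well_depth_per_bead,
                         "width": m.well_width, "coupling": m.coupling},
            "restraints": p.to_dict() if p is not None else None,
        },
    )


def run_temperature_ladder(chain, m: MembraneModel, p: RestraintParams | None,
                           cfg_base: SimulationConfig,
                           temps=LADDER, phosphates: np.ndarray | None = None,
                           start_distance: float | None = 4.0) -> list:
    """One trajectory per temperature with independent seeds derived from
    the base seed; default ladder 310-450 K in 10 K steps."""
    temps = list(temps)
    if not temps:
        raise ValueError("temperature ladder must be nonempty")
    children = np.random.SeedSequence(cfg_base.seed).spawn(len(temps))
    out = []
    for T, child in zip(temps, children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = cfg_base.replace(temperature=float(T), seed=seed)
        logger.info("ladder run at %s K (seed %s)", T, seed)
        out.append(run_trajectory(chain, m, p, cfg, phosphates=phosphates,
                                  start_distance=start_distance))
    return out
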