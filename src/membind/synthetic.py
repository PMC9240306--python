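"""Ground-truth generators for every pipeline input.

Each generator is a pure function of its seed and embeds its ground
truth (occupancies, melting midpoint, PMF parameters) in the generated
object's metadata so tests never re-derive it.

* two-state Markov trajectories emulate bound/unbound residue-membrane
  contact dynamics with known stationary occupancy;
* melting ensembles place a prescribed logistic occupancy-vs-temperature
  law on the simulation temperature ladder;
* umbrella windows draw exact (inverse-CDF, autocorrelation-free)
  Boltzmann samples from an analytic PMF under the harmonic bias;
* toy bilayer patches and peptide chains match the study's system
  composition (167 DOPE:DOPS:DOPC lipids per leaflet in 84:50:33 ratio;
  a 33-residue segment, residues 65-97, started 4 nm above the surface).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .contacts import Trajectory
from .restraints import BeadChain, RestraintParams, default_params
from .units import KB, KCAL, LADDER
from .wham import UmbrellaWindow

__all__ = [
    "TwoStateSpec",
    "AnalyticPMF",
    "DEFAULT_COMPOSITION",
    "gen_markov_binding_trajectory",
    "gen_melting_ensemble",
    "gen_umbrella_samples",
    "gen_bilayer_patch",
    "gen_peptide_chain",
]

#: lipids per leaflet in the synaptic-membrane-mimicking patch
DEFAULT_COMPOSITION = {"DOPE": 84, "DOPS": 50, "DOPC": 33}


@dataclass
class TwoStateSpec:
    """Two-state (bound/unbound) Markov dynamics of residue-membrane contact.

    Either ``occupancy`` (stationary bound fraction per residue; scalar or
    one value per residue) or explicit per-frame rates ``k_on``/``k_off``
    must be given. ``bound_z`` / ``unbound_z`` are heights above the
    phosphate plane and must fall strictly inside / outside the 1 nm
    contact threshold. ``switching_rate`` = k_on + k_off controls frame-
    to-frame correlation when only the occupancy is given.
    """

    n_frames: int
    occupancy: float | np.ndarray | None = None
    k_on: np.ndarray | None = None
    k_off: np.ndarray | None = None
    residue_ids: np.ndarray = field(default_factory=lambda: np.arange(65, 98))
    bound_z: float = 0.5
    unbound_z: float = 3.0
    switching_rate: float = 0.5
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 < self.bound_z < 1.0:
            raise ValueError("bound_z must lie strictly inside the 1 nm threshold")
        if self.unbound_z <= 1.0:
            raise ValueError("unbound_z must lie strictly outside the 1 nm threshold")
        R = len(self.residue_ids)
        if self.k_on is not None or self.k_off is not None:
            if self.k_on is None or self.k_off is None:
                raise ValueError("give both k_on and k_off, or neither")
            self.k_on = np.broadcast_to(np.asarray(self.k_on, float), (R,)).copy()
            self.k_off = np.broadcast_to(np.asarray(self.k_off, float), (R,)).copy()
            if np.any((self.k_on < 0) | (self.k_on > 1)) or np.any((self.k_off < 0) | (self.k_off > 1)):
                raise ValueError("per-frame rates must lie in [0, 1]")
            if np.any(self.k_on + self.k_off <= 0):
                raise ValueError("k_on + k_off must be > 0")
            self.occupancy = self.k_on / (self.k_on + self.k_off)
        else:
            if self.occupancy is None:
                raise ValueError("give occupancy or rates")
            occ = np.broadcast_to(np.asarray(self.occupancy, float), (R,)).copy()
            if np.any((occ < 0) | (occ > 1)):
                raise ValueError("occupancy must lie in [0, 1]")
            if not 0 < self.switching_rate <= 1:
                raise ValueError("switching_rate must lie in (0, 1]")
            self.occupancy = occ
            self.k_on = self.switching_rate * occ
            self.k_off = self.switching_rate * (1.0 - occ)


@njit(cache=False)
def _markov_states(u, k_on, k_off, init):
    """Iterate per-residue two-state chains; u is (F, R) uniforms."""
    F, R = u.shape
    states = np.empty((F, R), dtype=np.int8)
    for r in range(R):
        s = init[r]
        for f in range(F):
            if s == 1:
                if u[f, r] < k_off[r]:
                    s = 0
            else:
                if u[f, r] < k_on[r]:
                    s = 1
            states[f, r] = s
    return states


def gen_markov_binding_trajectory(spec: TwoStateSpec,
                                  plane_z: float = 0.5,
                                  xy_spacing: float = 0.5) -> Trajectory:
    """Trajectory whose residues toggle between ``bound_z`` and
    ``unbound_z`` above a phosphate lattice via a two-state Markov chain.

    Residues sit at fixed lattice xy positions, each exactly above a
    phosphate bead, so the contact criterion reduces to the z height;
    the stationary contact index equals the requested occupancy.
    """
    R = len(spec.residue_ids)
    rng = np.random.default_rng(spec.seed)
    # initial states from the stationary law, then exact Markov updates
    init = (rng.random(R) < spec.occupancy).astype(np.int8)
    u = rng.random((spec.n_frames, R))
    states = _markov_states(u, spec.k_on, spec.k_off, init)

    side = int(np.ceil(np.sqrt(R)))
    box_xy = side * xy_spacing
    ix, iy = np.divmod(np.arange(R), side)
    x = (ix + 0.5) * xy_spacing
    y = (iy + 0.5) * xy_spacing
    z = np.where(states == 1, plane_z + spec.bound_z, plane_z + spec.unbound_z)
    peptide = np.empty((spec.n_frames, R, 3))
    peptide[:, :, 0] = x
    peptide[:, :, 1] = y
    peptide[:, :, 2] = z
    phosphates = np.column_stack([x, y, np.full(R, plane_z)])
    box = np.array([box_xy, box_xy, plane_z + spec.unbound_z + 1.0])
    return Trajectory(
        residue_ids=spec.residue_ids,
        peptide=peptide,
        phosphates=phosphates,
        box=box,
        temperature=spec.temperature,
        metadata={
            "generator": "two-state-markov",
            "seed": int(spec.seed),
            "occupancy": np.asarray(spec.occupancy).tolist(),
            "k_on": spec.k_on.tolist(),
            "k_off": spec.k_off.tolist(),
            "bound_z": spec.bound_z,
            "unbound_z": spec.unbound_z,
        },
    )


def gen_melting_ensemble(Tm: float, width: float, temps=LADDER,
                         n_frames: int = 20000, seed: int = 0,
                         residue_ids=None, switching_rate: float = 0.5) -> list:
    """One two-state trajectory per ladder temperature with occupancy
    following the logistic law occ(T) = 1 / (1 + exp((T - Tm)/width))."""
    if width <= 0:
        raise ValueError("width must be > 0 K")
    if residue_ids is None:
        residue_ids = np.arange(65, 98)
    children = np.random.SeedSequence(seed).spawn(len(list(temps)))
    out = []
    for T, child in zip(temps, children):
        # overflow-safe logistic; width -> 0 degenerates to a step at Tm
        x = (T - Tm) / width
        occ = 1.0 / (1.0 + math.exp(x)) if x < 500 else 0.0
        spec = TwoStateSpec(
            n_frames=n_frames, occupancy=occ, residue_ids=residue_ids,
            switching_rate=switching_rate, temperature=float(T),
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        traj = gen_markov_binding_trajectory(spec)
        traj.metadata.update({"generator": "melting-ensemble",
                              "Tm": Tm, "width": width, "base_seed": int(seed)})
        out.append(traj)
    return out


@dataclass(frozen=True)
class AnalyticPMF:
    """Closed-form 1-D PMF used as the umbrella-sampling oracle.

    Forms (parameters in ``params``):

    - ``harmonic``: curvature*(xi - location)^2, curvature kJ/mol/nm^2
    - ``square_well``: flat well of depth ``depth_kcal`` on
      [location - half_width, location + half_width], tanh walls of
      softness ``softness`` nm
    - ``double_well``: two negative Gaussians (depth1_kcal @ loc1/width1,
      depth2_kcal @ loc2/width2)
    - ``morse_like``: depth_kcal * ((1 - exp(-(xi-location)/width))^2 - 1)
    """

    form: str
    params: dict
    domain: tuple

    _FORMS = ("harmonic", "square_well", "double_well", "morse_like")

    def __post_init__(self):
        if self.form not in self._FORMS:
            raise ValueError(f"form must be one of {self._FORMS}, got {self.form!r}")
        if self.domain[1] <= self.domain[0]:
            raise ValueError(f"invalid domain {self.domain}")

    def energy(self, xi):
        """PMF value(s) in kJ/mol."""
        xi = np.asarray(xi, dtype=float)
        p = self.params
        if self.form == "harmonic":
            u = p["curvature"] * (xi - p["location"]) ** 2
        elif self.form == "square_well":
            d = p["depth_kcal"] * KCAL
            a = p["location"] - p["half_width"]
            b = p["location"] + p["half_width"]
            s = p.get("softness", 0.1)

            def raw(x):
                return 0.25 * (1 + np.tanh((x - a) / s)) * (1 + np.tanh((b - x) / s))

            # normalised so the well floor is exactly -depth at `location`
            u = -d * raw(xi) / raw(p["location"])
        elif self.form == "double_well":
            u = (-p["depth1_kcal"] * KCAL
                 * np.exp(-(xi - p["loc1"]) ** 2 / (2 * p["width1"] ** 2))
                 - p["depth2_kcal"] * KCAL
                 * np.exp(-(xi - p["loc2"]) ** 2 / (2 * p["width2"] ** 2)))
        else:  # morse_like
            d = p["depth_kcal"] * KCAL
            u = d * ((1.0 - np.exp(-(xi - p["location"]) / p["width"])) ** 2 - 1.0)
        return float(u) if u.ndim == 0 else u


def gen_umbrella_samples(pmf: AnalyticPMF, centers=None,
                         force_constant: float = 1000.0,
                         temperature: float = 300.0,
                         n_per_window: int = 20000, seed: int = 0,
                         path_length: float = 1.2, n_windows: int = 11) -> list:
    """Exact biased Boltzmann samples from ``pmf`` for each umbrella window.

    Sampling is inverse-CDF on a 1e-4 nm grid of the density
    exp(-(U + k/2 (xi-c)^2)/kBT), so the draws are independent and the
    only WHAM error left is statistical. Default centers: ``n_windows``
    evenly spaced over ``path_length`` nm starting at the PMF's
    ``location`` parameter.
    """
    if centers is None:
        start = pmf.params.get("location", pmf.domain[0])
        centers = np.linspace(start, start + path_length, n_windows)
    centers = np.asarray(centers, dtype=float)
    if np.any((centers < pmf.domain[0]) | (centers > pmf.domain[1])):
        raise ValueError("window centers must lie inside the PMF domain")
    grid = np.arange(pmf.domain[0], pmf.domain[1] + 1e-12, 1e-4)
    U = pmf.energy(grid)
    kT = KB * temperature
    children = np.random.SeedSequence(seed).spawn(len(centers))
    windows = []
    for c, child in zip(centers, children):
        w = U + 0.5 * force_constant * (grid - c) ** 2
        dens = np.exp(-(w - w.min()) / kT)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
            raise ValueError(f"unnormalizable biased density in window at {c:g} nm")
        cdf /= cdf[-1]
        rng = np.random.default_rng(child.generate_state(1)[0] % (2 ** 31))
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(c), samples=samples,
                                      force_constant=force_constant))
    return windows


def gen_bilayer_patch(n_per_leaflet: int = 167,
                      composition: dict | None = None,
                      area: float | None = None,
                      upper_z: float = 4.0, thickness: float = 4.0,
                      jitter: float = 0.05, seed: int = 0):
    """Two leaflets of labelled phosphate beads on a jittered lattice.

    Returns ``(coords, labels, box)``: coords is (2*n_per_leaflet, 3) nm,
    labels the lipid name per bead, box the (Lx, Ly, Lz) patch box. The
    default composition is the 84:50:33 (5:3:2) DOPE:DOPS:DOPC synaptic
    mixture. Lipid identity affects labels only, never geometry.
    """
    if composition is None:
        composition = dict(DEFAULT_COMPOSITION)
    if sum(composition.values()) != n_per_leaflet:
        raise ValueError(
            f"composition {composition} sums to {sum(composition.values())}, "
            f"expected n_per_leaflet={n_per_leaflet}")
    if area is None:
        area = 0.64 * n_per_leaflet  # ~0.64 nm^2 per lipid headgroup
    L = math.sqrt(area)
    side = int(np.ceil(np.sqrt(n_per_leaflet)))
    spacing = L / side
    rng = np.random.default_rng(seed)

    leaflet_labels = [name for name, cnt in composition.items() for _ in range(cnt)]
    coords = []
    labels = []
    for z in (upper_z, upper_z - thickness):
        idx = np.arange(n_per_leaflet)
        ix, iy = np.divmod(idx, side)
        x = (ix + 0.5) * spacing + rng.uniform(-jitter, jitter, n_per_leaflet)
        y = (iy + 0.5) * spacing + rng.uniform(-jitter, jitter, n_per_leaflet)
        coords.append(np.column_stack([x % L, y % L, np.full(n_per_leaflet, z)]))
        order = rng.permutation(n_per_leaflet)
        labels.extend(leaflet_labels[i] for i in order)
    coords = np.vstack(coords)
    box = np.array([L, L, upper_z + 2.0])
    return coords, labels, box


def gen_peptide_chain(residue_range=(65, 97), state: str = "helical",
                      start_distance: float = 4.0,
                      params: RestraintParams | None = None,
                      bond_length: float = 0.35,
                      plane_z: float = 0.0) -> BeadChain:
    """Ideal-geometry bead chain with every angle at theta_min and every
    dihedral at phi_min of the state's restraint parameters, centre of
    mass placed ``start_distance`` nm above the phosphate plane."""
    lo, hi = residue_range
    if hi < lo + 3:
        raise ValueError("residue range must span >= 4 residues")
    if params is None:
        params = default_params(state)
    n = hi - lo + 1
    theta = math.radians(params.theta_min)
    phi = math.radians(params.phi_min)
    b = bond_length

    pos = np.zeros((n, 3))
    pos[1] = [b, 0.0, 0.0]
    pos[2] = pos[1] + b * np.array([-math.cos(theta), math.sin(theta), 0.0])
    for i in range(3, n):
        bc = pos[i - 1] - pos[i - 2]
        bc /= np.linalg.norm(bc)
        ab = pos[i - 2] - pos[i - 3]
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        mvec = np.cross(nvec, bc)
        d = np.array([-b * math.cos(theta),
                      b * math.sin(theta) * math.cos(phi),
                      b * math.sin(theta) * math.sin(phi)])
        pos[i] = pos[i - 1] + d[0] * bc + d[1] * mvec + d[2] * nvec
    pos -= pos.mean(axis=0)
    pos[:, 2] += plane_z + start_distance
    return BeadChain(residue_ids=np.arange(lo, hi + 1), positions=pos, state=params.state)
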