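"""Membrane-contact statistics and melting-curve analysis.

The binding of each residue to the membrane is scored by a contact index:
the fraction of trajectory frames in which the residue's backbone bead
lies within a distance threshold (default 1 nm) of the nearest lipid
phosphate bead. Averaging the per-residue indexes over the whole
construct gives a global contact index; plotted against the temperature
of a simulation ladder it traces a melting curve of membrane binding,
whose logistic midpoint Tm summarises the overall binding affinity.

Distances use minimum-image convention in the periodic xy plane and
plain differences along z (slab geometry). Phosphates of both leaflets
enter the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

__all__ = [
    "Trajectory",
    "ContactProfile",
    "MeltingCurve",
    "MeltFitError",
    "residue_contact_index",
    "contact_profile",
    "global_contact_index",
    "melting_curve",
    "fit_melting_temperature",
    "segment_convergence",
]

@njit(cache=False)
def _min_dist_kernel(beads, phosphates, box_x, box_y):
    """Minimum bead-phosphate distance per (frame, bead); xy min-image."""
    F, R = beads.shape[0], beads.shape[1]
    P = phosphates.shape[0]
    out = np.empty((F, R))
    for f in range(F):
        for r in range(R):
            best = 1e30
            bx, by, bz = beads[f, r, 0], beads[f, r, 1], beads[f, r, 2]
            for p in range(P):
                dx = bx - phosphates[p, 0]
                dy = by - phosphates[p, 1]
                dx -= box_x * np.round(dx / box_x)
                dy -= box_y * np.round(dy / box_y)
                dz = bz - phosphates[p, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < best:
                    best = d2
            out[f, r] = np.sqrt(best)
    return out


@dataclass
class Trajectory:
    """Frames of peptide backbone beads over a static phosphate lattice.

    Attributes
    ----------
    residue_ids : (R,) int array
    peptide : (F, R, 3) float array, nm
    phosphates : (P, 3) float array, nm (static lipid headgroup beads)
    box : (3,) float array, nm; xy-periodic slab box
    temperature : float, K
    metadata : dict
        Provenance: seed, generator/engine name, ground-truth parameters.
    """

    residue_ids: np.ndarray
    peptide: np.ndarray
    phosphates: np.ndarray
    box: np.ndarray
    temperature: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.peptide = np.asarray(self.peptide, dtype=float)
        self.phosphates = np.asarray(self.phosphates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.peptide.ndim != 3 or self.peptide.shape[1] != len(self.residue_ids):
            raise ValueError(
                f"peptide must be (F, {len(self.residue_ids)}, 3), got {self.peptide.shape}")
        if self.peptide.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.phosphates.ndim != 2 or self.phosphates.shape[1] != 3:
            raise ValueError(f"phosphates must be (P, 3), got {self.phosphates.shape}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def n_frames(self) -> int:
        return self.peptide.shape[0]

    @property
    def n_residues(self) -> int:
        return self.peptide.shape[1]


@dataclass
class ContactProfile:
    """Per-residue contact indexes at one temperature."""

    temperature: float
    per_residue: dict  # residue_id -> contact index in [0, 1]

    def __post_init__(self):
        for rid, v in self.per_residue.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"contact index of residue {rid} outside [0,1]: {v}")

    def values(self) -> np.ndarray:
        return np.array([self.per_residue[r] for r in sorted(self.per_residue)])


@dataclass
class MeltingCurve:
    """(temperature, global contact index) points, sorted by temperature."""

    temperatures: np.ndarray
    global_index: np.ndarray
    fitted: dict | None = None  # set by fit_melting_temperature

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.global_index = np.asarray(self.global_index, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.global_index < 0) | (self.global_index > 1)):
            raise ValueError("global contact indexes must lie in [0, 1]")


class MeltFitError(RuntimeError):
    """Melting-curve fit failed to converge; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------

def _min_phosphate_distance(bead_xyz: np.ndarray, phosphates: np.ndarray,
                            box: np.ndarray) -> np.ndarray:
    """Per-frame minimum bead-phosphate distance; xy minimum-image, plain z."""
    beads = np.ascontiguousarray(bead_xyz)[:, None, :]
    return _min_dist_kernel(beads, np.ascontiguousarray(phosphates),
                            float(box[0]), float(box[1]))[:, 0]


def _frame_slice(n_frames: int, burn_in: float) -> slice:
    if not 0.0 <= burn_in < 1.0:
        raise ValueError(f"burn_in must be a fraction in [0, 1), got {burn_in}")
    return slice(int(round(burn_in * n_frames)), n_frames)


def residue_contact_index(traj: Trajectory, residue_id: int,
                          threshold: float = 1.0, burn_in: float = 0.0) -> float:
    """Fraction of frames in which ``residue_id`` is within ``threshold`` nm
    of the nearest phosphate bead."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0 nm, got {threshold}")
    matches = np.nonzero(traj.residue_ids == residue_id)[0]
    if len(matches) == 0:
        raise KeyError(
            f"residue {residue_id} not in trajectory; valid ids: "
            f"{traj.residue_ids.min()}..{traj.residue_ids.max()}")
    sl = _frame_slice(traj.n_frames, burn_in)
    dmin = _min_phosphate_distance(traj.peptide[sl, matches[0], :],
                                   traj.phosphates, traj.box)
    return float(np.mean(dmin < threshold))


def contact_profile(traj: Trajectory, threshold: float = 1.0,
                    burn_in: float = 0.0) -> ContactProfile:
    """Contact index of every residue of the trajectory."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0 nm, got {threshold}")
    sl = _frame_slice(traj.n_frames, burn_in)
    dmin = _min_dist_kernel(np.ascontiguousarray(traj.peptide[sl]),
                            np.ascontiguousarray(traj.phosphates),
                            float(traj.box[0]), float(traj.box[1]))
    frac = (dmin < threshold).mean(axis=0)
    per = {int(rid): float(frac[i]) for i, rid in enumerate(traj.residue_ids)}
    return ContactProfile(temperature=traj.temperature, per_residue=per)


def global_contact_index(profile: ContactProfile) -> float:
    """Unweighted mean of the per-residue contact indexes."""
    if not profile.per_residue:
        raise ValueError("empty contact profile")
    return float(np.mean(list(profile.per_residue.values())))


def melting_curve(profiles: Sequence[ContactProfile]) -> MeltingCurve:
    """Assemble (T, global contact index) points from per-temperature profiles."""
    if len(profiles) < 2:
        raise ValueError("need profiles at >= 2 temperatures for a melting curve")
    temps = np.array([p.temperature for p in profiles])
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures make the ladder ambiguous")
    order = np.argsort(temps)
    gci = np.array([global_contact_index(profiles[i]) for i in order])
    return MeltingCurve(temperatures=temps[order], global_index=gci)


def _logistic(T, c_low, c_high, Tm, w):
    return c_low + (c_high - c_low) / (1.0 + np.exp((T - Tm) / w))


def fit_melting_temperature(curve: MeltingCurve):
    """Fit c(T) = c_low + (c_high - c_low)/(1 + exp((T - Tm)/w)).

    Returns ``(Tm, width, diagnostics)``; Tm is the inflection point of
    the fitted logistic, constrained to the sampled temperature range.
    ``diagnostics`` reports plateaus, rms residual, parameter standard
    errors, and a low-confidence flag when the curve spans less than 0.2
    in global contact index. The fit result is also stored on
    ``curve.fitted``.
    """
    T = curve.temperatures
    c = curve.global_index
    span = float(c.max() - c.min())
    t_lo, t_hi = float(T.min()), float(T.max())
    # initial midpoint: temperature closest to the half-way index
    mid = 0.5 * (c.max() + c.min())
    p0 = [float(c.min()), float(c.max()),
          float(T[np.argmin(np.abs(c - mid))]), 0.1 * (t_hi - t_lo)]
    bounds = ([-0.5, -0.5, t_lo, 1e-3], [1.5, 1.5, t_hi, 10.0 * (t_hi - t_lo)])
    try:
        popt, pcov = curve_fit(_logistic, T, c, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as exc:
        resid = _logistic(T, *p0) - c
        raise MeltFitError(f"melting-curve fit did not converge: {exc}",
                           residuals=resid) from exc
    resid = _logistic(T, *popt) - c
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    diagnostics = {
        "c_low": float(popt[0]),
        "c_high": float(popt[1]),
        "rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        "stderr": {"c_low": float(perr[0]), "c_high": float(perr[1]),
                   "Tm": float(perr[2]), "width": float(perr[3])},
        "low_confidence": span <= 0.2,
    }
    Tm, width = float(popt[2]), float(popt[3])
    curve.fitted = {"Tm": Tm, "width": width, **diagnostics}
    return Tm, width, diagnostics


def segment_convergence(traj: Trajectory, n_segments: int = 3,
                        threshold: float = 1.0):
    """Split the run into consecutive equal segments and compare profiles.

    Returns ``(profiles, max_deviation)`` where ``max_deviation`` is the
    largest absolute contact-index difference over residues and segment
    pairs. Remainder frames are dropped from the end.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    seg_len = traj.n_frames // n_segments
    if seg_len < 1:
        raise ValueError(
            f"{traj.n_frames} frames cannot form {n_segments} segments")
    profiles = []
    for s in range(n_segments):
        sub = Trajectory(
            residue_ids=traj.residue_ids,
            peptide=traj.peptide[s * seg_len:(s + 1) * seg_len],
            phosphates=traj.phosphates,
            box=traj.box,
            temperature=traj.temperature,
            metadata={**traj.metadata, "segment": s},
        )
        profiles.append(contact_profile(sub, threshold=threshold))
    vals = np.stack([p.values() for p in profiles])
    max_dev = 0.0
    for a in range(n_segments):
        for b in range(a + 1, n_segments):
            max_dev = max(max_dev, float(np.max(np.abs(vals[a] - vals[b]))))
    return profiles, max_dev
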