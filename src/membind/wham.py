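"""Umbrella-sampling analysis: histograms, WHAM, PMF and binding free energy.

Umbrella sampling biases the reaction coordinate xi (the centre-of-mass
distance between peptide and bilayer) with harmonic restraints
w_i(xi) = k/2 (xi - xi_i)^2 at a ladder of window centres. The weighted
histogram analysis method recovers the unbiased distribution p(xi) from
the biased window histograms by iterating the self-consistency pair

    p(b)  = sum_i n_i(b) / sum_i N_i exp((F_i - w_i(b)) / kB T)
    F_i   = -kB T ln sum_b p(b) exp(-w_i(b) / kB T)

to convergence. The potential of mean force is G(xi) = -kB T ln p(xi),
zeroed on the detached plateau, and the membrane-binding free energy is
the plateau-to-minimum depth, reported positive-favourable in kcal/mol.

No Jacobian (2 ln xi) correction is applied to the 1-D distance
coordinate; the profile is used as sampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import KCAL, kbt

__all__ = [
    "UmbrellaWindow",
    "Histograms",
    "PMFProfile",
    "WhamConvergenceError",
    "bias_potential",
    "build_histograms",
    "window_overlap",
    "wham_solve",
    "pmf_from_probability",
    "binding_free_energy",
    "compute_pmf",
    "bootstrap_binding_free_energy",
]

logger = logging.getLogger(__name__)


@dataclass
class UmbrellaWindow:
    """One biased sampling window: restraint centre (nm), force constant
    (kJ/mol/nm^2) and the scalar reaction-coordinate samples (nm)."""

    center: float
    samples: np.ndarray
    force_constant: float = 1000.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0 kJ/mol/nm^2")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class Histograms:
    """Per-window counts on a shared xi grid."""

    counts: np.ndarray        # (W, B)
    edges: np.ndarray         # (B+1,)
    n_dropped: np.ndarray     # (W,) samples outside the range

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class PMFProfile:
    """Potential of mean force on a xi grid.

    ``free_energy`` is in kJ/mol, NaN on empty bins; ``reference``
    documents the zeroing convention; ``window_free_energies`` are the
    WHAM shift constants F_i (relative to window 0).
    """

    grid: np.ndarray
    free_energy: np.ndarray
    reference: str = "unshifted"
    window_free_energies: np.ndarray | None = None
    counts: np.ndarray | None = None

    @property
    def free_energy_kcal(self) -> np.ndarray:
        return self.free_energy / KCAL


class WhamConvergenceError(RuntimeError):
    def __init__(self, message, residual=None, n_iter=None):
        super().__init__(message)
        self.residual = residual
        self.n_iter = n_iter


def bias_potential(xi, w: UmbrellaWindow):
    """Harmonic umbrella bias k/2 (xi - center)^2 in kJ/mol."""
    xi = np.asarray(xi, dtype=float)
    v = 0.5 * w.force_constant * (xi - w.center) ** 2
    return float(v) if v.ndim == 0 else v


def build_histograms(windows, bin_width: float = 0.02,
                     xi_range: tuple | None = None) -> Histograms:
    """Bin all windows on one shared grid.

    ``xi_range`` defaults to the span of all samples; samples outside an
    explicit range are dropped and counted per window.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0 nm")
    for i, w in enumerate(windows):
        if w.samples.size == 0:
            raise ValueError(f"window {i} (center {w.center}) is empty")
    if xi_range is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
    else:
        lo, hi = map(float, xi_range)
        if hi <= lo:
            raise ValueError(f"invalid xi range {xi_range}")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(windows), n_bins))
    dropped = np.zeros(len(windows), dtype=int)
    for i, w in enumerate(windows):
        inside = (w.samples >= edges[0]) & (w.samples <= edges[-1])
        dropped[i] = int(np.sum(~inside))
        if dropped[i]:
            logger.warning("window %d: %d samples outside [%g, %g] dropped",
                           i, dropped[i], edges[0], edges[-1])
        counts[i], _ = np.histogram(w.samples[inside], bins=edges)
    return Histograms(counts=counts, edges=edges, n_dropped=dropped)


def window_overlap(hist: Histograms) -> np.ndarray:
    """Adjacent-pair overlap: sum_b min(p_i(b), p_{i+1}(b)) of the
    normalised per-window histograms, in [0, 1]."""
    W = hist.counts.shape[0]
    if W < 2:
        raise ValueError("need >= 2 windows for overlap")
    p = hist.counts / hist.counts.sum(axis=1, keepdims=True)
    return np.array([np.minimum(p[i], p[i + 1]).sum() for i in range(W - 1)])


def wham_solve(hist: Histograms, windows, temperature: float,
               tol: float = 1e-7, max_iter: int = 100000):
    """Iterate the WHAM equations to self-consistency.

    Returns ``(p, F, info)``: the normalised unbiased bin probabilities,
    window free energies relative to F_0 = 0, and an info dict with the
    iteration count and final residual. Convergence: max |delta F| <
    tol * kB T between successive iterations.
    """
    kT = kbt(temperature)
    counts = hist.counts
    W, B = counts.shape
    if W != len(windows):
        raise ValueError("histogram/window count mismatch")
    centers = hist.centers
    N = counts.sum(axis=1)
    # adjacency diagnostics on windows ordered by center
    order = np.argsort([w.center for w in windows])
    ov = (window_overlap(Histograms(counts=counts[order], edges=hist.edges,
                                    n_dropped=hist.n_dropped[order]))
          if W >= 2 else np.array([1.0]))
    if np.any(ov == 0.0):
        i = int(np.argmin(ov))
        ci, cj = windows[order[i]].center, windows[order[i + 1]].center
        raise ValueError(
            f"disjoint histograms: no overlap between windows centred at "
            f"{ci:g} and {cj:g} nm; the grid has an unsampled gap there")
    if np.any(ov < 0.05):
        warnings.warn(
            f"adjacent window overlap below 0.05 (min {ov.min():.3f}); "
            "WHAM may be poorly conditioned", RuntimeWarning, stacklevel=2)

    bias = np.stack([bias_potential(centers, w) for w in windows])  # (W, B)
    exp_neg_bias = np.exp(-bias / kT)
    total_counts = counts.sum(axis=0)
    F = np.zeros(W)
    for it in range(1, max_iter + 1):
        denom = (N[:, None] * np.exp(F[:, None] / kT) * exp_neg_bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_counts / denom, 0.0)
        s = p.sum()
        if s <= 0:
            raise WhamConvergenceError("all-zero probability in WHAM update")
        p /= s
        weights = exp_neg_bias @ p
        F_new = -kT * np.log(weights)
        F_new -= F_new[0]
        resid = float(np.max(np.abs(F_new - F)))
        F = F_new
        if resid < tol * kT:
            return p, F, {"n_iter": it, "residual": resid}
    raise WhamConvergenceError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(last residual {resid:.3g} kJ/mol)", residual=resid, n_iter=max_iter)


def pmf_from_probability(p: np.ndarray, grid: np.ndarray, temperature: float,
                         plateau_window: tuple | None = None,
                         counts: np.ndarray | None = None) -> PMFProfile:
    """G(xi) = -kB T ln p(xi), zeroed on the detached plateau.

    Empty bins (p = 0) are NaN, never interpolated. ``plateau_window``
    defaults to the last 0.2 nm of the grid.
    """
    p = np.asarray(p, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be >= 0")
    if not np.any(p > 0):
        raise ValueError("all-zero probability: PMF undefined everywhere")
    kT = kbt(temperature)
    with np.errstate(divide="ignore"):
        G = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0)), np.nan)
    if plateau_window is None:
        plateau_window = (grid[-1] - 0.2, grid[-1])
        ref = "plateau: last 0.2 nm of grid"
    else:
        ref = f"plateau: [{plateau_window[0]:g}, {plateau_window[1]:g}] nm"
    mask = (grid >= plateau_window[0]) & (grid <= plateau_window[1]) & np.isfinite(G)
    if not np.any(mask):
        raise ValueError(f"no defined bins in plateau window {plateau_window}")
    G -= np.nanmean(G[mask])
    return PMFProfile(grid=grid, free_energy=G, reference=ref, counts=counts)


def binding_free_energy(pmf: PMFProfile, bound_window: tuple,
                        plateau_window: tuple | None = None) -> float:
    """Plateau-to-minimum binding free energy in kcal/mol (positive =
    favourable binding)."""
    grid, G = pmf.grid, pmf.free_energy
    if plateau_window is None:
        plateau_window = (grid[-1] - 0.2, grid[-1])
    bmask = (grid >= bound_window[0]) & (grid <= bound_window[1]) & np.isfinite(G)
    pmask = (grid >= plateau_window[0]) & (grid <= plateau_window[1]) & np.isfinite(G)
    if not np.any(bmask):
        raise ValueError(f"no defined bins in bound window {bound_window}")
    if not np.any(pmask):
        raise ValueError(f"no defined bins in plateau window {plateau_window}")
    dg_kj = float(np.mean(G[pmask]) - np.min(G[bmask]))
    return dg_kj / KCAL


def compute_pmf(windows, temperature: float, bin_width: float = 0.02,
                xi_range: tuple | None = None, tol: float = 1e-7,
                max_iter: int = 100000,
                plateau_window: tuple | None = None) -> PMFProfile:
    """Histogram -> WHAM -> PMF pipeline for a set of umbrella windows."""
    hist = build_histograms(windows, bin_width=bin_width, xi_range=xi_range)
    p, F, info = wham_solve(hist, windows, temperature, tol=tol, max_iter=max_iter)
    pmf = pmf_from_probability(p, hist.centers, temperature,
                               plateau_window=plateau_window,
                               counts=hist.counts.sum(axis=0))
    pmf.window_free_energies = F
    return pmf


def bootstrap_binding_free_energy(windows, temperature: float,
                                  bound_window: tuple,
                                  plateau_window: tuple | None = None,
                                  n_boot: int = 50, seed: int = 0,
                                  **pmf_kw):
    """Case-resampling bootstrap of the binding free energy.

    Resamples each window's xi values with replacement; returns
    ``(dg, dg_se, samples)`` in kcal/mol.
    """
    pmf = compute_pmf(windows, temperature, plateau_window=plateau_window, **pmf_kw)
    dg = binding_free_energy(pmf, bound_window, plateau_window)
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        resampled = [
            UmbrellaWindow(center=w.center, force_constant=w.force_constant,
                           samples=rng.choice(w.samples, size=w.n_samples))
            for w in windows]
        bp = compute_pmf(resampled, temperature, plateau_window=plateau_window,
                         **pmf_kw)
        out[b] = binding_free_energy(bp, bound_window, plateau_window)
    return dg, float(out.std(ddof=1)), out
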