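"""File formats: GRO coordinates, the multi-frame XYZ trajectory dialect,
two-column umbrella series, and TSV outputs with provenance headers.

Trajectory dialect (plain text, human-diffable)::

    <n_beads>
    frame=<int> time=<ps> temperature=<K> box=<Lx>,<Ly>,<Lz> n_peptide=<int>
    BB<resid> <x> <y> <z>        (one line per peptide bead, nm)
    PO4 <x> <y> <z>              (one line per phosphate bead, nm)
    ... next frame ...

Umbrella series are two numeric columns (time, xi) with ``#``/``@``
comment lines tolerated, matching XVG-style pull output.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .contacts import MeltingCurve, Trajectory
from .wham import PMFProfile, UmbrellaWindow

__all__ = [
    "GroParseError",
    "GroFrame",
    "read_gro",
    "write_gro",
    "read_trajectory_xyz",
    "write_trajectory_xyz",
    "read_umbrella_series",
    "write_umbrella_series",
    "read_window_manifest",
    "write_window_manifest",
    "provenance_header",
    "write_profile_tsv",
    "write_melting_tsv",
    "write_pmf_tsv",
]

PACKAGE_VERSION = "0.1.0"


class GroParseError(ValueError):
    """GRO file could not be parsed; message carries the offending line."""


@dataclass
class GroFrame:
    """One GRO frame: labels, positions (nm) and the box vector."""

    names: list
    resids: np.ndarray
    resnames: list
    positions: np.ndarray
    box: np.ndarray
    title: str = ""


def read_gro(path) -> GroFrame:
    """Read a single-frame GRO file (positions in nm) via MDAnalysis."""
    import MDAnalysis as mda

    # cheap structural pre-check so malformed count lines fail with a
    # line number instead of an opaque downstream error
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: truncated GRO file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].split()[0])
    except (ValueError, IndexError) as exc:
        raise GroParseError(
            f"{path}:2: malformed atom-count line {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise GroParseError(
            f"{path}:2: atom count {n_atoms} but only {len(lines) - 3} atom lines")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="GRO")
        except Exception as exc:
            raise GroParseError(f"{path}: GRO parse failed: {exc}") from exc
        box = u.dimensions[:3] / 10.0 if u.dimensions is not None else np.zeros(3)
        return GroFrame(
            names=[str(n) for n in u.atoms.names],
            resids=np.asarray(u.atoms.resids, dtype=int),
            resnames=[str(r) for r in u.atoms.resnames],
            positions=u.atoms.positions / 10.0,  # Angstrom -> nm
            box=np.asarray(box, dtype=float),
            title=lines[0].strip(),
        )


def write_gro(path, names, resids, resnames, positions, box,
              title="membind coordinates"):
    """Write a single-frame GRO file (fixed-precision, nm)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if not (len(names) == len(resids) == len(resnames) == n):
        raise ValueError("names/resids/resnames/positions lengths differ")
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            fh.write(f"{int(resids[i]) % 100000:5d}{resnames[i]:<5.5s}"
                     f"{names[i]:>5.5s}{(i + 1) % 100000:5d}"
                     f"{positions[i, 0]:8.3f}{positions[i, 1]:8.3f}{positions[i, 2]:8.3f}\n")
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# trajectory dialect

def write_trajectory_xyz(path, traj: Trajectory, time_step: float = 1.0):
    """Write a Trajectory in the package's multi-frame XYZ dialect."""
    R = traj.n_residues
    P = len(traj.phosphates)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{R + P}\n")
            fh.write(f"frame={f} time={f * time_step:g} "
                     f"temperature={traj.temperature:g} "
                     f"box={traj.box[0]:g},{traj.box[1]:g},{traj.box[2]:g} "
                     f"n_peptide={R}\n")
            for i, rid in enumerate(traj.residue_ids):
                x, y, z = traj.peptide[f, i]
                fh.write(f"BB{int(rid)} {x:.6f} {y:.6f} {z:.6f}\n")
            for p in range(P):
                x, y, z = traj.phosphates[p]
                fh.write(f"PO4 {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_xyz(path) -> Trajectory:
    """Read the multi-frame XYZ dialect back into a Trajectory."""
    frames_pep = []
    phosphates = None
    residue_ids = None
    temperature = None
    box = None
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            if not header.strip():
                continue
            try:
                n_beads = int(header.split()[0])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: expected bead count, got {header!r}") from exc
            comment = fh.readline()
            lineno += 1
            meta = dict(kv.split("=", 1) for kv in comment.split() if "=" in kv)
            if "n_peptide" not in meta or "box" not in meta:
                raise ValueError(
                    f"{path}:{lineno}: frame comment must carry n_peptide= and box=")
            n_pep = int(meta["n_peptide"])
            temperature = float(meta.get("temperature", 300.0))
            box = np.array([float(v) for v in meta["box"].split(",")])
            pep = np.empty((n_pep, 3))
            rids = np.empty(n_pep, dtype=int)
            phos = []
            for i in range(n_beads):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 'NAME x y z'")
                name = parts[0]
                xyz = [float(v) for v in parts[1:]]
                if i < n_pep:
                    if not name.startswith("BB"):
                        raise ValueError(
                            f"{path}:{lineno}: peptide bead must be BB<resid>, got {name}")
                    rids[i] = int(name[2:])
                    pep[i] = xyz
                else:
                    phos.append(xyz)
            frames_pep.append(pep)
            if residue_ids is None:
                residue_ids = rids
                phosphates = np.array(phos) if phos else np.empty((0, 3))
    if not frames_pep:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(
        residue_ids=residue_ids,
        peptide=np.stack(frames_pep),
        phosphates=phosphates,
        box=box,
        temperature=temperature,
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# umbrella series

def read_umbrella_series(path):
    """Read (times, xi) from two-column text, skipping #/@ comment lines."""
    times, xis = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two numeric columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                xis.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {s!r}") from exc
    return np.array(times), np.array(xis)


def write_umbrella_series(path, times, xis, comments=()):
    """Write a two-column (time, xi) series with leading # comments."""
    times = np.asarray(times, dtype=float)
    xis = np.asarray(xis, dtype=float)
    if times.shape != xis.shape:
        raise ValueError("times and xi values must have equal length")
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for t, x in zip(times, xis):
            fh.write(f"{t:.17g} {x:.17g}\n")


def read_window_manifest(path):
    """Load umbrella windows from a YAML manifest.

    The manifest maps window entries to their sample files::

        temperature: 300.0
        windows:
          - {center: 1.0, force_constant: 1000.0, series: win00.dat}
    """
    import os

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "windows" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'windows' list")
    base = os.path.dirname(os.path.abspath(path))
    windows = []
    for i, entry in enumerate(doc["windows"]):
        for key in ("center", "series"):
            if key not in entry:
                raise ValueError(f"{path}: window {i} lacks '{key}'")
        series = entry["series"]
        if not os.path.isabs(series):
            series = os.path.join(base, series)
        _, xi = read_umbrella_series(series)
        windows.append(UmbrellaWindow(
            center=float(entry["center"]),
            force_constant=float(entry.get("force_constant", 1000.0)),
            samples=xi))
    return windows, doc


def write_window_manifest(path, windows, series_paths, temperature=None,
                          extra=None):
    """Write the YAML manifest matching ``read_window_manifest``."""
    doc = {"windows": [
        {"center": float(w.center), "force_constant": float(w.force_constant),
         "series": str(s)}
        for w, s in zip(windows, series_paths)]}
    if temperature is not None:
        doc["temperature"] = float(temperature)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# provenance + TSV outputs

def provenance_header(config: dict | None = None, seed=None) -> list:
    """Comment lines recording package version, config hash and seed."""
    lines = [f"membind {PACKAGE_VERSION}"]
    if config is not None:
        digest = hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]
        lines.append(f"config_hash={digest}")
    if seed is not None:
        lines.append(f"seed={seed}")
    return lines


def _write_tsv(path, df, config=None, seed=None):
    buf = _io.StringIO()
    for line in provenance_header(config, seed):
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_profile_tsv(path, profile, config=None, seed=None):
    """Per-residue contact indexes as TSV (residue, contact_index)."""
    import pandas as pd

    df = pd.DataFrame({
        "residue": sorted(profile.per_residue),
        "contact_index": [profile.per_residue[r] for r in sorted(profile.per_residue)],
    })
    df.insert(0, "temperature", profile.temperature)
    _write_tsv(path, df, config, seed)


def write_melting_tsv(path, curve: MeltingCurve, config=None, seed=None):
    """Melting curve as TSV (temperature, global_contact_index)."""
    import pandas as pd

    df = pd.DataFrame({
        "temperature": curve.temperatures,
        "global_contact_index": curve.global_index,
    })
    _write_tsv(path, df, config, seed)


def write_pmf_tsv(path, pmf: PMFProfile, config=None, seed=None):
    """PMF as TSV (xi, G kJ/mol, G kcal/mol, counts)."""
    import pandas as pd

    df = pd.DataFrame({
        "xi": pmf.grid,
        "free_energy_kJ_mol": pmf.free_energy,
        "free_energy_kcal_mol": pmf.free_energy_kcal,
        "counts": pmf.counts if pmf.counts is not None else np.nan,
    })
    _write_tsv(path, df, config, seed)
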