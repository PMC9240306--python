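"""YAML run configuration: validated, unit-annotated loading.

A run config bundles the restraint block, the simulation engine block,
the implicit membrane, and the analysis/WHAM settings::

    seed: 1
    restraints: {state: helical, K_angle: 10.0, theta_min: 96.0,
                 sigma_angle: 200.0, K_dihedral: 10.0, phi_min: -120.0,
                 sigma_dihedral: 200.0}
    membrane:   {plane_z: 1.0, well_depth_per_bead: 12.0, well_width: 0.3,
                 box: [4.0, 4.0, 6.0], coupling: per_bead}
    simulator:  {dt: 0.0005, friction: 1.0, temperature: 310.0,
                 n_steps: 100000, save_interval: 200, bond_k: 100.0,
                 bond_r0: 0.35}
    peptide:    {residue_first: 65, residue_last: 97, start_distance: 4.0}
    analysis:   {threshold: 1.0, segments: 3, burn_in: 0.0}
    wham:       {temperature: 300.0, bin_width: 0.02, tol: 1.0e-7}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .restraints import RestraintParams
from .simulate import MembraneModel, SimulationConfig

__all__ = ["RunConfig", "load_run_config"]

_ANALYSIS_DEFAULTS = {"threshold": 1.0, "segments": 3, "burn_in": 0.0}
_WHAM_DEFAULTS = {"temperature": None, "bin_width": 0.02, "tol": 1e-7,
                  "plateau": None, "bound": None}
_PEPTIDE_DEFAULTS = {"residue_first": 65, "residue_last": 97,
                     "start_distance": 4.0, "bond_length": 0.35}


@dataclass
class RunConfig:
    seed: int
    restraints: RestraintParams | None
    membrane: MembraneModel | None
    simulator: SimulationConfig | None
    peptide: dict = field(default_factory=lambda: dict(_PEPTIDE_DEFAULTS))
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    wham: dict = field(default_factory=lambda: dict(_WHAM_DEFAULTS))
    raw: dict = field(default_factory=dict)


def _check(cond, message):
    if not cond:
        raise ValueError(message)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    _check(isinstance(doc, dict), f"{path}: top level must be a mapping")

    seed = int(doc.get("seed", 0))

    restraints = None
    if "restraints" in doc:
        try:
            restraints = RestraintParams.from_dict(doc["restraints"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: restraints block incomplete: {exc}") from exc

    membrane = None
    if "membrane" in doc:
        mb = doc["membrane"]
        _check(isinstance(mb, dict), f"{path}: membrane must be a mapping")
        try:
            membrane = MembraneModel(
                plane_z=float(mb["plane_z"]),
                well_depth_per_bead=float(mb["well_depth_per_bead"]),
                well_width=float(mb["well_width"]),
                box=tuple(float(v) for v in mb["box"]),
                coupling=mb.get("coupling", "per_bead"))
        except KeyError as exc:
            raise ValueError(
                f"{path}: membrane block lacks {exc} "
                "(need plane_z nm, well_depth_per_bead kJ/mol, "
                "well_width nm, box [nm,nm,nm])") from exc

    simulator = None
    if "simulator" in doc:
        sb = doc["simulator"]
        try:
            simulator = SimulationConfig(
                dt=float(sb["dt"]),
                temperature=float(sb["temperature"]),
                n_steps=int(sb["n_steps"]),
                friction=float(sb.get("friction", 1.0)),
                save_interval=int(sb.get("save_interval", 1)),
                seed=int(sb.get("seed", seed)),
                bond_k=float(sb.get("bond_k", 0.0)),
                bond_r0=float(sb.get("bond_r0", 0.35)))
        except KeyError as exc:
            raise ValueError(
                f"{path}: simulator block lacks {exc} "
                "(need dt ps, temperature K, n_steps)") from exc

    peptide = {**_PEPTIDE_DEFAULTS, **doc.get("peptide", {})}
    _check(peptide["residue_last"] >= peptide["residue_first"] + 3,
           f"{path}: peptide range must span >= 4 residues")
    _check(peptide["start_distance"] > 0,
           f"{path}: start_distance must be > 0 nm")

    analysis = {**_ANALYSIS_DEFAULTS, **doc.get("analysis", {})}
    _check(analysis["threshold"] > 0,
           f"{path}: analysis.threshold must be > 0 nm")
    _check(0 <= analysis["burn_in"] < 1,
           f"{path}: analysis.burn_in must be a fraction in [0, 1)")
    _check(int(analysis["segments"]) >= 2,
           f"{path}: analysis.segments must be >= 2")

    wham = {**_WHAM_DEFAULTS, **doc.get("wham", {})}
    if wham["temperature"] is not None:
        _check(float(wham["temperature"]) > 0,
               f"{path}: wham.temperature must be > 0 K")
    _check(float(wham["bin_width"]) > 0,
           f"{path}: wham.bin_width must be > 0 nm")

    return RunConfig(seed=seed, restraints=restraints, membrane=membrane,
                     simulator=simulator, peptide=peptide, analysis=analysis,
                     wham=wham, raw=doc)
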