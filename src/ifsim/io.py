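"""Readers and writers: XYZ/PDB structures, CSV tables, config files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SubunitModel

__all__ = [
    "write_xyz",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_pdb",
    "energies_to_csv",
    "load_config",
    "save_config",
]

_ELEMENT = {"COIL1": "C", "LINKER": "N", "COIL2": "O"}


def _xyz_frame(fh, positions, labels, comment=""):
    fh.write(f"{len(positions)}\n{comment}\n")
    for p, lab in zip(positions, labels):
        fh.write(
            f"{_ELEMENT.get(str(lab), 'C')} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n"
        )


def write_xyz(path, model: SubunitModel, comment: str = "") -> None:
    """Single-frame XYZ (coordinates in nm, element encodes the segment)."""
    with open(path, "w") as fh:
        _xyz_frame(fh, model.positions, model.segment_labels, comment)


def write_xyz_trajectory(path, traj) -> None:
    """Multi-frame XYZ; the comment line carries the frame time and seed."""
    labels = traj.model.segment_labels
    with open(path, "w") as fh:
        for t, pos in zip(traj.times, traj.positions):
            _xyz_frame(
                fh, pos, labels, f"t={t:.6g} seed={traj.config.seed}"
            )


def read_xyz_trajectory(path):
    """Read a multi-frame XYZ written by `write_xyz_trajectory`.

    Returns (times, positions) with times NaN where not recorded.
    """
    times, frames = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        t = float("nan")
        for tok in comment.split():
            if tok.startswith("t="):
                t = float(tok[2:])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(x) for x in ln.split()[1:4]] for ln in block])
        times.append(t)
        i += 2 + n
    return np.asarray(times), np.asarray(frames)


def write_pdb(path, model: SubunitModel) -> None:
    """CA-style pseudo-atom PDB (one atom per bead, chains per dimer),
    coordinates converted from nm to Angstrom."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = model.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = model.positions * 10.0
    atoms.atom_name = np.full(n, "CA")
    atoms.res_name = np.full(n, "GLY")
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.where(model.chain_id == 0, "A", "B")
    atoms.element = np.full(n, "C")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def energies_to_csv(traj, path) -> None:
    """Per-frame energy breakdown table."""
    rows = [
        {"time": t, **bd.as_dict()}
        for t, bd in zip(traj.times, traj.energies)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    """JSON or YAML config, by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
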