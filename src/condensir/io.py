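"""File formats: PDB structures, columnar frame tables, 2D cubes, reports.

The columnar frame table is the package's canonical plain-text
trajectory format (grammar in the README): comment/header lines
starting with '#', then one whitespace-separated row per atom with
columns ``atom_id chain_id resid role name x y z`` (coordinates in
Angstrom).  2D spectral cubes are stored as one text file with the
pump/probe/Tw axes in header lines and one matrix block per waiting
time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .frames import Frame
from .hbonds import ACFResult
from .spectra import Spectrum2D

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP", "TIP3", "TIP4", "SPC"}

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _assign_roles(atoms: struc.AtomArray) -> np.ndarray:
    roles = np.full(atoms.array_length(), "other", dtype="U8")
    water = np.isin(atoms.res_name, list(WATER_RESNAMES))
    elements = atoms.element
    roles[water & (elements == "O")] = "water_O"
    roles[water & (elements == "H")] = "water_H"
    protein = ~water
    roles[protein & (atoms.atom_name == "O")] = "amide_O"
    roles[protein & np.isin(atoms.atom_name, ["H", "HN"])] = "amide_H"
    return roles


def read_structure(path) -> Frame:
    """Read a PDB file into a Frame; roles from residue/atom names."""
    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    water = np.isin(atoms.res_name, list(WATER_RESNAMES))
    chain_letters = atoms.chain_id
    chain_ids = np.full(atoms.array_length(), -1, dtype=int)
    mapping = {}
    for i, (c, w) in enumerate(zip(chain_letters, water)):
        if w:
            continue
        if c not in mapping:
            mapping[c] = len(mapping)
        chain_ids[i] = mapping[c]
    box = None
    periodic = False
    cell = atoms.box
    if cell is not None:
        box = np.array([cell[0, 0], cell[1, 1], cell[2, 2]])
        periodic = bool(np.all(box > 0))
    return Frame(coords=atoms.coord, chain_ids=chain_ids,
                 resids=atoms.res_id.astype(int), roles=_assign_roles(atoms),
                 box=box, periodic=periodic,
                 names=atoms.atom_name.astype("U6"))


def write_structure(frame: Frame, path) -> None:
    """Write a Frame as PDB (chain ids mapped to single letters)."""
    n = frame.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coords.astype(np.float32)
    is_water = np.char.startswith(frame.roles.astype("U8"), "water")
    atoms.res_name = np.where(is_water, "HOH", "GLY").astype("U5")
    atoms.res_id = frame.resids + 1
    letters = np.array([_CHAIN_ALPHABET[c % len(_CHAIN_ALPHABET)]
                        if c >= 0 else "W" for c in frame.chain_ids])
    atoms.chain_id = letters.astype("U4")
    default_names = {"amide_O": "O", "amide_H": "H",
                     "water_O": "O", "water_H": "H1", "other": "CA"}
    if frame.names is not None:
        atoms.atom_name = frame.names.astype("U6")
    else:
        atoms.atom_name = np.array([default_names[r] for r in frame.roles],
                                   dtype="U6")
    atoms.element = np.array([nm[0] for nm in atoms.atom_name], dtype="U2")
    atoms.hetero = is_water
    if frame.box is not None:
        atoms.box = np.diag(frame.box).astype(np.float32)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


# --------------------------------------------------------------------------
# Columnar frame table
# --------------------------------------------------------------------------

def write_frame_table(frame: Frame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# condensir-frame 1\n")
        if frame.box is not None:
            fh.write("# box %.6f %.6f %.6f\n" % tuple(frame.box))
        fh.write(f"# periodic {str(frame.periodic).lower()}\n")
        fh.write("# atom_id chain_id resid role name x y z\n")
        names = frame.names if frame.names is not None \
            else np.full(frame.n_atoms, "X", dtype="U6")
        for i in range(frame.n_atoms):
            x, y, z = frame.coords[i]
            fh.write(f"{i} {frame.chain_ids[i]} {frame.resids[i]} "
                     f"{frame.roles[i]} {names[i]} "
                     f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_frame_table(path) -> Frame:
    box = None
    periodic = False
    chain, resid, roles, names, coords = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "box":
                    box = np.array([float(v) for v in parts[1:4]])
                elif parts and parts[0] == "periodic":
                    periodic = parts[1] == "true"
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            try:
                chain.append(int(parts[1]))
                resid.append(int(parts[2]))
                roles.append(parts[3])
                names.append(parts[4])
                coords.append([float(v) for v in parts[5:8]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return Frame(coords=np.array(coords), chain_ids=np.array(chain),
                 resids=np.array(resid), roles=np.array(roles, dtype="U8"),
                 box=box, periodic=periodic, names=np.array(names, dtype="U6"))


# --------------------------------------------------------------------------
# 2D spectral cubes with explicit axes
# --------------------------------------------------------------------------

def write_spectrum2d(spec: Spectrum2D, path) -> None:
    with open(path, "w") as fh:
        fh.write("# condensir-2dir 1\n")
        fh.write("# pump " + " ".join(f"{v:.6f}" for v in spec.pump) + "\n")
        fh.write("# probe " + " ".join(f"{v:.6f}" for v in spec.probe) + "\n")
        fh.write("# tw_ps " + " ".join(f"{v:.6f}" for v in spec.waiting_times)
                 + "\n")
        for i, tw in enumerate(spec.waiting_times):
            fh.write(f"# tw {tw:.6f}\n")
            np.savetxt(fh, spec.cube[i], fmt="%.8e")


def read_spectrum2d(path) -> Spectrum2D:
    pump = probe = tws = None
    blocks, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "pump":
                    pump = np.array([float(v) for v in parts[1:]])
                elif parts[0] == "probe":
                    probe = np.array([float(v) for v in parts[1:]])
                elif parts[0] == "tw_ps":
                    tws = np.array([float(v) for v in parts[1:]])
                elif parts[0] == "tw":
                    if current:
                        blocks.append(np.array(current))
                        current = []
                continue
            current.append([float(v) for v in line.split()])
    if current:
        blocks.append(np.array(current))
    if pump is None or probe is None or tws is None:
        raise ValueError(f"{path}: missing pump/probe/tw_ps axis headers")
    return Spectrum2D(pump=pump, probe=probe, waiting_times=tws,
                      cube=np.stack(blocks))


# --------------------------------------------------------------------------
# Tabular / report outputs
# --------------------------------------------------------------------------

def write_acf(acf: ACFResult, path) -> None:
    header = "lag_ps C"
    if acf.baseline is not None:
        header += f"  (baseline {acf.baseline:.8f} removed)"
    np.savetxt(path, np.column_stack([acf.lags, acf.c]), fmt="%.8e",
               header=header)


def read_acf(path) -> ACFResult:
    data = np.loadtxt(path)
    return ACFResult(lags=data[:, 0], c=data[:, 1],
                     n_origins=np.zeros(len(data), dtype=int))


def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
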