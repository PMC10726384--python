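"""Core in-memory containers for multi-chain configurations.

Coordinates are stored in Angstrom throughout the package.  Periodic
systems are restricted to orthorhombic boxes (three edge lengths);
minimum-image distances are computed component-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised atom roles.  ``amide_O`` is the backbone carbonyl oxygen,
#: ``amide_H`` the backbone amide hydrogen; water atoms are labelled by
#: element.  Everything else is ``other``.
ROLES = ("amide_O", "amide_H", "water_O", "water_H", "other")


@dataclass
class Frame:
    """A single configuration of atoms grouped into chains.

    Parameters
    ----------
    coords : (n_atoms, 3) float array, Angstrom.
    chain_ids : (n_atoms,) integer array; water molecules conventionally
        carry chain id -1 and are not treated as protein chains.
    resids : (n_atoms,) integer array, residue / molecule index.
    roles : (n_atoms,) string array drawn from :data:`ROLES`.
    box : (3,) edge lengths in Angstrom, or None for a non-periodic frame.
    periodic : whether minimum-image conventions apply.
    names : optional per-atom names (PDB-style).
    """

    coords: np.ndarray
    chain_ids: np.ndarray
    resids: np.ndarray
    roles: np.ndarray
    box: np.ndarray | None = None
    periodic: bool = False
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = len(self.coords)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        self.roles = np.asarray(self.roles, dtype="U8")
        for arr, name in ((self.chain_ids, "chain_ids"),
                          (self.resids, "resids"), (self.roles, "roles")):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown atom roles: {sorted(bad)}")
        if self.periodic:
            if self.box is None:
                raise ValueError("periodic frame requires box lengths")
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("periodic box edge lengths must be positive")
        elif self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def protein_chain_ids(self) -> np.ndarray:
        """Sorted unique chain ids of protein chains (chain id >= 0)."""
        ids = np.unique(self.chain_ids)
        return ids[ids >= 0]

    def select(self, mask: np.ndarray) -> "Frame":
        """Sub-frame with atoms where ``mask`` is true."""
        return replace(
            self,
            coords=self.coords[mask],
            chain_ids=self.chain_ids[mask],
            resids=self.resids[mask],
            roles=self.roles[mask],
            names=None if self.names is None else self.names[mask],
        )


def minimum_image_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d``."""
    d = np.asarray(d, dtype=float)
    if box is None:
        return d
    return d - box * np.round(d / box)


def pairwise_min_distance(a: np.ndarray, b: np.ndarray,
                          box: np.ndarray | None = None) -> float:
    """Minimum atom-atom distance between coordinate sets ``a`` and ``b``.

    Brute-force O(len(a)*len(b)); minimum image if ``box`` is given.
    """
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, box)
    return float(np.sqrt((d ** 2).sum(axis=-1)).min())


@dataclass
class PeptideStructure:
    """Backbone-only peptide chain with per-residue amide groups.

    ``atoms`` maps atom name ('N', 'CA', 'C', 'O', 'H') to an
    (n_residues, 3) coordinate array; rows of 'H' may be NaN where no
    amide hydrogen exists (N-terminus, proline).
    """

    atoms: dict
    proline_flags: np.ndarray
    chain_id: int = 0

    def __post_init__(self) -> None:
        self.proline_flags = np.asarray(self.proline_flags, dtype=bool)

    @property
    def n_residues(self) -> int:
        return len(self.atoms["CA"])

    def co_lengths(self) -> np.ndarray:
        """Per-residue C=O bond lengths in Angstrom."""
        return np.linalg.norm(self.atoms["O"] - self.atoms["C"], axis=1)

    def co_units(self) -> np.ndarray:
        """Per-residue unit vectors pointing from C to O."""
        v = self.atoms["O"] - self.atoms["C"]
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "PeptideStructure":
        """Rigid-body copy: ``x -> R x + t``."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = {k: v @ R.T + t for k, v in self.atoms.items()}
        return PeptideStructure(atoms, self.proline_flags.copy(), self.chain_id)

    def to_frame(self, box: np.ndarray | None = None,
                 periodic: bool = False) -> Frame:
        """Flatten into a :class:`Frame` (amide H rows that are NaN are dropped)."""
        coords, chain, resid, roles, names = [], [], [], [], []
        role_of = {"N": "other", "CA": "other", "C": "other",
                   "O": "amide_O", "H": "amide_H"}
        for name in ("N", "CA", "C", "O", "H"):
            if name not in self.atoms:
                continue
            xyz = self.atoms[name]
            for i in range(self.n_residues):
                if np.any(np.isnan(xyz[i])):
                    continue
                coords.append(xyz[i])
                chain.append(self.chain_id)
                resid.append(i)
                roles.append(role_of[name])
                names.append(name)
        return Frame(np.array(coords), np.array(chain), np.array(resid),
                     np.array(roles), box=box, periodic=periodic,
                     names=np.array(names, dtype="U4"))


def merge_frames(frames: list[Frame], box: np.ndarray | None = None,
                 periodic: bool = False) -> Frame:
    """Concatenate frames into one (chain ids are kept as-is)."""
    if not frames:
        raise ValueError("nothing to merge")
    names = None
    if all(f.names is not None for f in frames):
        names = np.concatenate([f.names for f in frames])
    return Frame(
        np.concatenate([f.coords for f in frames]),
        np.concatenate([f.chain_ids for f in frames]),
        np.concatenate([f.resids for f in frames]),
        np.concatenate([f.roles for f in frames]),
        box=box, periodic=periodic, names=names,
    )
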