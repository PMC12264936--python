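"""Molecular geometries for the PCl*3 model ligand and XYZ file I/O."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MolecularGeometry", "read_xyz", "write_xyz", "XYZParseError"]

_ELEMENT_RE = re.compile(r"^[A-Z][a-z]?[a-z]?$")


class XYZParseError(ValueError):
    """Raised when an XYZ file does not follow the standard layout."""


@dataclass
class MolecularGeometry:
    """Atoms of a model-ligand system.

    The virtual ligand replaces the substituents of a phosphine PR3 by three
    chlorine pseudo-atoms (Cl*) bound to phosphorus; every other atom is part
    of the chemical environment that feels the steric (ovoid) potential.

    Parameters
    ----------
    symbols : list of str
        Element symbols, one per atom.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian coordinates in Angstrom.
    p_index : int
        Index of the phosphorus atom.
    cl_indices : sequence of int
        Indices of the three Cl* pseudo-atoms.
    env_indices : sequence of int, optional
        Indices of environment atoms.  Defaults to every atom that is
        neither P nor Cl*.
    """

    symbols: list
    coords: np.ndarray
    p_index: int
    cl_indices: tuple
    env_indices: tuple = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbols and coords length mismatch")
        self.cl_indices = tuple(int(i) for i in self.cl_indices)
        if len(self.cl_indices) != 3:
            raise ValueError("exactly three Cl* indices are required")
        self.p_index = int(self.p_index)
        core = {self.p_index, *self.cl_indices}
        if len(core) != 4:
            raise ValueError("P and Cl* indices must be distinct")
        if self.env_indices is None:
            self.env_indices = tuple(
                i for i in range(len(self.symbols)) if i not in core
            )
        else:
            self.env_indices = tuple(int(i) for i in self.env_indices)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def transformed(self, rotation=None, translation=None) -> "MolecularGeometry":
        """Return a rigidly rotated/translated copy."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return MolecularGeometry(
            list(self.symbols), coords, self.p_index, self.cl_indices,
            self.env_indices,
        )


def read_xyz(path, p_index=None, cl_indices=None) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment, element x y z rows).

    P and Cl* assignment: if not given, the first P atom is the center and
    the first three Cl atoms are the pseudo-substituents.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError as exc:
        raise XYZParseError(f"{path}:1: bad atom count line") from exc
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) != count:
        raise XYZParseError(
            f"{path}: count line says {count} atoms but {len(rows)} rows follow"
        )
    symbols, coords = [], []
    for lineno, row in enumerate(rows, start=3):
        parts = row.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}:{lineno}: expected 'El x y z'")
        sym = parts[0]
        if not _ELEMENT_RE.match(sym):
            raise XYZParseError(f"{path}:{lineno}: bad element symbol {sym!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise XYZParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
        symbols.append(sym)
        coords.append(xyz)
    if p_index is None:
        p_candidates = [i for i, s in enumerate(symbols) if s == "P"]
        if not p_candidates:
            raise XYZParseError(f"{path}: no phosphorus atom found")
        p_index = p_candidates[0]
    if cl_indices is None:
        cl_indices = tuple(
            i for i, s in enumerate(symbols) if s == "Cl" and i != p_index
        )[:3]
        if len(cl_indices) != 3:
            raise XYZParseError(f"{path}: fewer than three Cl atoms found")
    return MolecularGeometry(symbols, np.array(coords), p_index, cl_indices)


def write_xyz(geom: MolecularGeometry, path, comment: str = "") -> None:
    """Write a geometry to a standard XYZ file (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{geom.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(geom.symbols, geom.coords):
            fh.write(f"{sym} {x:.12f} {y:.12f} {z:.12f}\n")
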