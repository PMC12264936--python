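"""Descriptor space: dissociation-energy tables, PCA and the ligand database.

A ligand's electronic/steric character is encoded by its dissociation
energies against a fixed panel of metal–fragment complexes (L + Fg_i ->
LFg_i).  Principal component analysis of those energies over the candidate
set yields the m-dimensional descriptor vector ``x`` whose components are
exactly uncorrelated — the property the projection and surrogate machinery
assumes.  The PCA transform is frozen with the database so every later
descriptor uses the identical linear map.

The packaged ligand database covers 21 monodentate phosphines with their
best-fit virtual-ligand parameters ``p = (r0, a1, b1)`` and residual
``l_min`` (the descriptor-space distance between the real ligand and its
virtual counterpart, a reaction-independent reliability index).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .vl_model import VLParams

__all__ = [
    "FRAGMENTS",
    "DissociationTable",
    "build_dissociation_table",
    "PCAModel",
    "fit_pca",
    "LigandRecord",
    "load_param_db",
    "save_param_db",
    "builtin_ligand_db",
    "IncompleteTableError",
    "ParamDBError",
]

#: The 16-fragment panel used to build descriptors.  The first four are the
#: fragments named in the screening study; the remaining identifiers are
#: synthetic placeholders (the panel is an identifier registry only — the
#: fragments' quantum-chemical geometries are outside this package's scope).
FRAGMENTS = (
    "Cr(CO)5",
    "Pd(PH3)3",
    "AgCl",
    "[PdCl3]-",
    "Fg05", "Fg06", "Fg07", "Fg08", "Fg09", "Fg10",
    "Fg11", "Fg12", "Fg13", "Fg14", "Fg15", "Fg16",
)


class IncompleteTableError(RuntimeError):
    """A dissociation energy could not be computed for a ligand/fragment pair."""


class ParamDBError(ValueError):
    """Malformed ligand parameter database."""


@dataclass
class DissociationTable:
    """Complete |R| x m table of dissociation energies (kcal/mol)."""

    data: pd.DataFrame  # rows = ligand ids, columns = fragment ids

    def __post_init__(self):
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("ligand/fragment labels must be unique")
        if self.data.isna().any().any():
            raise ValueError("dissociation table has missing cells")

    @property
    def n_ligands(self) -> int:
        return self.data.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.data.shape[1]

    @property
    def n_entries(self) -> int:
        return int(self.data.size)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def build_dissociation_table(
    ligands, fragments, energy_fn: Callable[[str, str], float]
) -> DissociationTable:
    """Evaluate ``energy_fn(ligand, fragment)`` for every pair.

    Raises :class:`IncompleteTableError` naming the pair on any failure.
    """
    ligands, fragments = list(ligands), list(fragments)
    if not ligands or not fragments:
        raise ValueError("ligand and fragment lists must be nonempty")
    table = np.empty((len(ligands), len(fragments)))
    for i, lig in enumerate(ligands):
        for j, fg in enumerate(fragments):
            try:
                e = float(energy_fn(lig, fg))
            except Exception as exc:
                raise IncompleteTableError(
                    f"dissociation energy failed for ({lig}, {fg}): {exc}"
                ) from exc
            if not np.isfinite(e):
                raise IncompleteTableError(
                    f"non-finite dissociation energy for ({lig}, {fg})"
                )
            table[i, j] = e
    return DissociationTable(pd.DataFrame(table, index=ligands, columns=fragments))


@dataclass
class PCAModel:
    """Frozen PCA transform: ``x = Q (e - mean)``.

    ``loadings`` rows are the orthonormal principal axes (all m retained; the
    energies are transformed directly without variance standardization).
    """

    mean: np.ndarray                # (m,) column means, kcal/mol
    loadings: np.ndarray            # (m, m) orthonormal, rows = components
    explained_variance: np.ndarray  # (m,)
    zero_variance_tol: float = 1e-10

    @property
    def m(self) -> int:
        return self.mean.size

    @property
    def zero_variance_components(self) -> np.ndarray:
        """Boolean mask of components with (numerically) zero variance."""
        scale = max(float(self.explained_variance.max()), 1.0)
        return self.explained_variance <= self.zero_variance_tol * scale

    def to_descriptor(self, energies) -> np.ndarray:
        """Map an m-vector of dissociation energies to PC scores."""
        e = np.asarray(energies, dtype=float)
        if e.shape != (self.m,):
            raise ValueError(f"expected {self.m} energies, got shape {e.shape}")
        return self.loadings @ (e - self.mean)

    def from_descriptor(self, x) -> np.ndarray:
        """Inverse transform (exact: all components are retained)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.m,):
            raise ValueError(f"expected {self.m} scores, got shape {x.shape}")
        return self.loadings.T @ x + self.mean

    def transform(self, energies_matrix) -> np.ndarray:
        E = np.atleast_2d(np.asarray(energies_matrix, dtype=float))
        return (E - self.mean) @ self.loadings.T


def fit_pca(table: DissociationTable) -> PCAModel:
    """PCA of the raw dissociation energies (covariance, no standardization).

    All m components are retained, so the transform is an orthonormal change
    of basis and the scores are exactly uncorrelated.  Zero-variance
    components of rank-deficient tables are kept and flagged.
    """
    E = table.values()
    if E.shape[0] < 2:
        raise ValueError("PCA needs at least two ligands")
    mean = E.mean(axis=0)
    centered = E - mean
    # SVD-based PCA with a deterministic sign convention (largest-magnitude
    # loading entry positive per component)
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    var = np.zeros(E.shape[1])
    var[: s.size] = s**2 / (E.shape[0] - 1)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    loadings = vt * signs[:, None]
    return PCAModel(mean=mean, loadings=loadings, explained_variance=var)


@dataclass
class LigandRecord:
    """One real ligand with its virtual-ligand representation."""

    id: str
    name: str
    p: VLParams
    l_min: float
    x: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.l_min < 0:
            raise ValueError("l_min must be nonnegative")


_DB_COLUMNS = ["id", "name", "r0", "a1", "b1", "l_min"]


def _records_from_frame(df: pd.DataFrame, source) -> list:
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        raise ParamDBError(f"{source}: missing columns {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        row = int(df.index[df["id"] == dup][-1]) + 2
        raise ParamDBError(f"{source}: duplicate ligand id {dup!r} at row {row}")
    records = []
    for idx, row in df.iterrows():
        try:
            rec = LigandRecord(
                id=str(row["id"]),
                name=str(row["name"]),
                p=VLParams(float(row["r0"]), float(row["a1"]), float(row["b1"])),
                l_min=float(row["l_min"]),
            )
        except (TypeError, ValueError) as exc:
            raise ParamDBError(f"{source}: row {int(idx) + 2}: {exc}") from exc
        records.append(rec)
    return records


def load_param_db(source) -> list:
    """Load a ligand parameter database from CSV or JSON.

    Columns/keys: ``id, name, r0, a1, b1, l_min``.
    """
    path = Path(source)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        df = pd.DataFrame(raw)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return _records_from_frame(df, path.name)


def save_param_db(records, sink) -> None:
    """Write records to CSV or JSON at full float precision."""
    path = Path(sink)
    rows = [
        {
            "id": r.id,
            "name": r.name,
            "r0": r.p.r0,
            "a1": r.p.a1,
            "b1": r.p.b1,
            "l_min": r.l_min,
        }
        for r in records
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(
            path, index=False, float_format="%.17g"
        )


def builtin_ligand_db() -> list:
    """The packaged database of 21 monodentate phosphine ligands."""
    ref = importlib.resources.files("vligand.data") / "ligand_params.csv"
    with importlib.resources.as_file(ref) as path:
        return load_param_db(path)
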