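"""Molecular alignment and CoMSIA-style similarity fields.

Molecules sharing a common skeleton are superposed by a least-squares
rigid-body fit over mapped skeleton atoms, then Gaussian similarity fields
are evaluated on a rectangular grid around the aligned set.  At grid point
``q`` the field of probe type ``P`` is

    f_P(q) = - sum_atoms  w_P * w_atom * exp(-alpha * r(atom, q)^2)

with distance attenuation ``alpha`` (default 0.3 1/A^2) and unit probe
weight.  Atom weights per probe: van der Waals radius cubed (steric),
partial charge (electrostatic), atomic hydrophobicity parameter
(hydrophobic) and donor/acceptor flags (H-bond fields).  The Gaussian form
avoids the singularities of Lennard-Jones/Coulomb fields at the atoms, so
no cutoffs are needed.

Per-atom properties (charge, vdW radius, hydrophobicity, donor/acceptor
typing) are supplied in a TSV sidecar rather than perceived from the graph,
keeping this module free of charge/perception models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "PROBES",
    "Molecule",
    "SkeletonMapping",
    "FieldGrid",
    "AlignmentError",
    "superpose",
    "build_grid",
    "similarity_field",
    "compute_field_blocks",
    "assemble_descriptor_matrix",
    "read_sdf",
    "read_atom_properties",
    "load_molecules",
]

PROBES = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")


class AlignmentError(ValueError):
    """Degenerate skeleton mapping (too few or collinear anchor atoms)."""


@dataclass
class Molecule:
    """An aligned small molecule with per-atom probe properties.

    Coordinates in Angstrom, charges in elementary charge units, vdW radii
    in Angstrom, hydrophobicity dimensionless, donor/acceptor as 0/1 flags.
    """

    id: str
    elements: list[str]
    coords: np.ndarray          # (n_atoms, 3)
    charge: np.ndarray
    vdw: np.ndarray
    hydrophobicity: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("molecule needs at least one atom")
        for name in ("charge", "vdw", "hydrophobicity", "donor", "acceptor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per atom")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw <= 0):
            raise ValueError("vdW radii must be positive")

    def atom_weights(self, probe: str) -> np.ndarray:
        if probe == "steric":
            return self.vdw ** 3
        if probe == "electrostatic":
            return self.charge
        if probe == "hydrophobic":
            return self.hydrophobicity
        if probe == "donor":
            return self.donor
        if probe == "acceptor":
            return self.acceptor
        raise ValueError(f"unknown probe {probe!r}; expected one of {PROBES}")


@dataclass
class SkeletonMapping:
    """Ordered (template_atom_index, molecule_atom_index) anchor pairs."""

    template_id: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise AlignmentError("need at least 3 mapped atom pairs")
        t_idx = [t for t, _ in self.pairs]
        if len(set(t_idx)) != len(t_idx):
            raise AlignmentError("duplicate template indices in mapping")


@dataclass
class FieldGrid:
    """Axis-aligned rectangular grid geometry (Angstrom)."""

    origin: np.ndarray          # (3,)
    spacing: float
    counts: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points, shape (n_points, 3), x fastest-varying last."""
        axes = [self.origin[d] + self.spacing * np.arange(self.counts[d])
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def superpose(mobile: Molecule, template: Molecule,
              mapping: SkeletonMapping) -> tuple[Molecule, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``template``.

    The optimal proper rotation (Kabsch solution) and translation over the
    mapped anchor pairs are applied to *all* atoms of the mobile molecule.
    Returns the transformed molecule and the anchor RMSD in Angstrom.
    """
    t_idx = np.array([t for t, _ in mapping.pairs])
    m_idx = np.array([m for _, m in mapping.pairs])
    if t_idx.max() >= len(template.elements) or m_idx.max() >= len(mobile.elements):
        raise AlignmentError("mapping index out of range")
    P = template.coords[t_idx]
    Q = mobile.coords[m_idx]
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    if np.linalg.matrix_rank(Q - Qc, tol=1e-8) < 2:
        raise AlignmentError("mapped atoms are collinear or coincident")
    rot, _ = Rotation.align_vectors(P - Pc, Q - Qc)
    moved = rot.apply(mobile.coords - Qc) + Pc
    rmsd = float(np.sqrt(((rot.apply(Q - Qc) + Pc - P) ** 2).sum(axis=1).mean()))
    return replace(mobile, coords=moved), rmsd


def build_grid(molecules: Iterable[Molecule], spacing: float = 2.0,
               margin: float = 4.0) -> FieldGrid:
    """Grid enclosing the aligned set's bounding box plus ``margin``."""
    if spacing <= 0 or margin <= 0:
        raise ValueError("spacing and margin must be positive")
    mols = list(molecules)
    if not mols:
        raise ValueError("empty molecule set")
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    counts = tuple(int(np.floor((hi[d] - lo[d]) / spacing)) + 1
                   for d in range(3))
    return FieldGrid(origin=lo, spacing=spacing, counts=counts)


def similarity_field(mol: Molecule, grid: "FieldGrid | np.ndarray", probe: str,
                     alpha: float = 0.3,
                     probe_weight: float = 1.0) -> np.ndarray:
    """Gaussian similarity field of one molecule, vectorized over points.

    ``grid`` may be a :class:`FieldGrid` or an explicit ``(n, 3)`` array of
    evaluation points.
    """
    w = mol.atom_weights(probe)
    pts = grid.points() if isinstance(grid, FieldGrid) else np.asarray(grid)
    d2 = cdist(pts.reshape(-1, 3), mol.coords, metric="sqeuclidean")
    return -(np.exp(-alpha * d2) @ w) * probe_weight


def compute_field_blocks(molecules: Sequence[Molecule], grid: FieldGrid,
                         probes: Sequence[str] = PROBES,
                         alpha: float = 0.3) -> dict[str, np.ndarray]:
    """Per-probe field blocks, each of shape (n_molecules, n_grid_points)."""
    return {p: np.vstack([similarity_field(m, grid, p, alpha=alpha)
                          for m in molecules])
            for p in probes}


def assemble_descriptor_matrix(
        blocks: Mapping[str, np.ndarray], drop_sigma: float = 0.01,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Block-scale, concatenate and variance-filter the field blocks.

    Each probe block is divided by the standard deviation of *all* its
    entries (CoMSIA block scaling, so no probe dominates by sheer
    magnitude); columns whose per-column standard deviation after scaling
    falls below ``drop_sigma`` are dropped.  Returns the descriptor matrix
    and a retained-column -> (probe, grid point index) map.
    """
    scaled, names = [], []
    n_mol = None
    for probe, block in blocks.items():
        block = np.asarray(block, dtype=float)
        if n_mol is None:
            n_mol = block.shape[0]
        if n_mol < 2:
            raise ValueError("need at least 2 molecules")
        sd = block.std()
        scaled.append(block / sd if sd > 0 else block)
        names.extend((probe, j) for j in range(block.shape[1]))
    X = np.hstack(scaled)
    keep = X.std(axis=0) >= drop_sigma
    if not keep.any():
        raise ValueError("all descriptor columns dropped: no variance above "
                         f"drop_sigma={drop_sigma}")
    column_map = [name for name, k in zip(names, keep) if k]
    return X[:, keep], column_map


# ---------------------------------------------------------------------------
# file I/O: SDF structures + per-atom property sidecar

def read_sdf(path) -> list[tuple[str, list[str], np.ndarray]]:
    """Read molecule ids, element symbols and coordinates from an SDF file."""
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable molecule #{i} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(a).x,
                            conf.GetAtomPosition(a).y,
                            conf.GetAtomPosition(a).z]
                           for a in range(mol.GetNumAtoms())])
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        out.append((name, elements, coords))
    return out


def read_skeleton_mappings(path, template_id: str) -> dict[str, SkeletonMapping]:
    """Mapping TSV: molecule_id, template_atom_index, molecule_atom_index."""
    df = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "template_atom_index", "molecule_atom_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping file missing columns: {sorted(missing)}")
    return {
        str(mol_id): SkeletonMapping(
            template_id,
            list(zip(grp["template_atom_index"].astype(int),
                     grp["molecule_atom_index"].astype(int))))
        for mol_id, grp in df.groupby("molecule_id")
    }


def read_atom_properties(path) -> pd.DataFrame:
    """Sidecar TSV: molecule_id, atom_index, charge, vdw, hydrophobicity,
    donor, acceptor."""
    df = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "atom_index", "charge", "vdw",
                "hydrophobicity", "donor", "acceptor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    return df


def load_molecules(sdf_path, props_path) -> list[Molecule]:
    """Join SDF structures with the per-atom property sidecar."""
    props = read_atom_properties(props_path).set_index(
        ["molecule_id", "atom_index"]).sort_index()
    mols = []
    for name, elements, coords in read_sdf(sdf_path):
        try:
            p = props.loc[name]
        except KeyError:
            raise KeyError(f"no sidecar properties for molecule {name!r}")
        p = p.reindex(range(len(elements)))
        if p.isna().any().any():
            raise ValueError(f"incomplete sidecar properties for {name!r}")
        mols.append(Molecule(
            id=name, elements=elements, coords=coords,
            charge=p["charge"].to_numpy(),
            vdw=p["vdw"].to_numpy(),
            hydrophobicity=p["hydrophobicity"].to_numpy(),
            donor=p["donor"].to_numpy(),
            acceptor=p["acceptor"].to_numpy(),
        ))
    return mols
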