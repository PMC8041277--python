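"""Structure I/O, the preorientation convention, and rigid transforms.

All coordinates are in Angstrom in a right-handed laboratory frame whose +z
axis is the membrane normal.  Structures entering the pipeline are assumed to
be preoriented in the OPM sense: membrane parallel to the x-y plane and the
transmembrane-region center of mass at z = 0.  :func:`check_preorientation`
verifies (but does not enforce) that convention.

PDB parsing and writing are delegated to :mod:`biotite`; this module only
defines the lightweight containers the rest of the pipeline works with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as bstruc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    CongruenceError,
    EmptyStructureError,
    PdbFormatError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: Standard atomic masses (u) for elements common in protein structures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "CU": 63.546, "NA": 22.990, "K": 39.098,
    "CL": 35.45,
}

#: Half-thickness (A) of the default transmembrane slab used when no explicit
#: residue range is given; matches a typical lipid bilayer half-thickness.
DEFAULT_TM_HALF_THICKNESS = 15.0

# PDB coordinate columns are 8.3 fixed width: representable range
# is -999.999 .. 9999.999.
_PDB_COORD_MAX = 1.0e4
_PDB_COORD_MIN = -1.0e3


def element_mass(element: str) -> float:
    """Atomic mass for ``element``; unknown elements get carbon's mass.

    Sloppy PDB files frequently carry blank or bogus element columns; mapping
    them to carbon keeps mass-weighted centroids well defined.
    """
    mass = ATOMIC_MASSES.get(element.strip().upper())
    if mass is None:
        warnings.warn(
            f"unknown element {element!r}: using carbon mass", stacklevel=2
        )
        mass = ATOMIC_MASSES["C"]
    return mass


@dataclass
class StructureModel:
    """A set of atoms with identity — the unit that is docked and assessed.

    Parameters
    ----------
    chain_ids, residue_numbers, residue_names, atom_names, elements
        Per-atom annotation arrays, all of length ``n_atoms``.
    coords
        ``(n_atoms, 3)`` float array, Angstrom.
    tm_residue_range
        Optional ``(first, last)`` residue numbers (inclusive) marking the
        transmembrane region.  When absent, a slab |z| <= 15 A on C-alpha
        positions is used as the default TM selection.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    tm_residue_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        for name in ("chain_ids", "residue_numbers", "residue_names",
                     "atom_names", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.coords)
        if n == 0:
            raise EmptyStructureError("structure has no atoms")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name in ("chain_ids", "residue_numbers", "residue_names",
                     "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of atoms")

    # -- convenience ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.elements])

    def residue_keys(self) -> np.ndarray:
        """Per-atom ``"chain:resnum"`` labels for residue grouping."""
        return np.array([
            f"{c}:{r}" for c, r in zip(self.chain_ids, self.residue_numbers)
        ])

    def select(self, mask: np.ndarray) -> "StructureModel":
        if not np.any(mask):
            raise SelectionError("selection matched no atoms")
        return StructureModel(
            self.chain_ids[mask], self.residue_numbers[mask],
            self.residue_names[mask], self.atom_names[mask],
            self.elements[mask], self.coords[mask],
            tm_residue_range=self.tm_residue_range,
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))

    def heavy_mask(self) -> np.ndarray:
        elems = np.char.upper(np.char.strip(self.elements.astype(str)))
        return elems != "H"

    def calpha_mask(self) -> np.ndarray:
        return np.char.strip(self.atom_names.astype(str)) == "CA"


@dataclass
class Ensemble:
    """Ordered conformational frames congruent with one topology.

    ``frames`` is ``(n_frames, n_atoms, 3)``; ``frame_interval`` is metadata
    only (ps between saved frames).
    """

    frames: np.ndarray
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise CongruenceError(
                f"frames must be (n_frames>=1, n_atoms, 3), got {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: ``x' = R (x - c) + c + t``.

    ``rotation`` must be orthonormal with determinant +1 (tolerance 1e-8).
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=np.float64))
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=np.float64))
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=np.float64) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        # with x' = R(x-c)+c+t, the inverse about the same center is
        # x = R^T(x'-c)+c - R^T t
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation),
            center=self.center,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), np.zeros(3))


# ---------------------------------------------------------------------------
# biotite bridge
# ---------------------------------------------------------------------------

def _from_atom_array(arr: bstruc.AtomArray) -> StructureModel:
    return StructureModel(
        chain_ids=np.asarray(arr.chain_id),
        residue_numbers=np.asarray(arr.res_id),
        residue_names=np.asarray(arr.res_name),
        atom_names=np.asarray(arr.atom_name),
        elements=np.asarray(arr.element),
        coords=np.asarray(arr.coord, dtype=np.float64),
    )


def _to_atom_array(s: StructureModel) -> bstruc.AtomArray:
    arr = bstruc.AtomArray(s.n_atoms)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.residue_numbers.astype(int)
    arr.res_name = s.residue_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.coord = s.coords.astype(np.float32)
    return arr


def read_pdb(path, protein_only: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Multi-model files yield the *first* model only; ensembles must go through
    :func:`read_ensemble`.  With ``protein_only`` (default) HETATM records are
    dropped, so a waters-only file raises :class:`EmptyStructureError`.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    if protein_only:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no atoms read from {path}")
    return _from_atom_array(arr)


def read_ensemble(path, protein_only: bool = True,
                  frame_interval: float = 5.0) -> tuple[StructureModel, Ensemble]:
    """Read a multi-model PDB as (topology, ensemble).

    Topology comes from the first MODEL; each MODEL block becomes one frame.
    Models with differing atom counts raise :class:`CongruenceError`.
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # AtomArrayStack, all models
    except Exception as exc:  # biotite raises on inhomogeneous models
        raise CongruenceError(f"models in {path} are not congruent: {exc}") from exc
    if protein_only:
        stack = stack[..., ~stack.hetero]
    if stack.array_length() == 0:
        raise EmptyStructureError(f"no atoms read from {path}")
    topo = _from_atom_array(stack[0])
    ens = Ensemble(frames=np.asarray(stack.coord, dtype=np.float64),
                   frame_interval=frame_interval)
    return topo, ens


def tm_selection_mask(s: StructureModel,
                      half_thickness: float = DEFAULT_TM_HALF_THICKNESS) -> np.ndarray:
    """Mask of atoms belonging to the transmembrane region.

    If ``s.tm_residue_range`` is set, all atoms of residues in that inclusive
    range are selected.  Otherwise every residue whose C-alpha lies inside the
    slab |z| <= ``half_thickness`` is selected (the assumed bilayer span).
    """
    if s.tm_residue_range is not None:
        lo, hi = s.tm_residue_range
        mask = (s.residue_numbers >= lo) & (s.residue_numbers <= hi)
    else:
        ca = s.calpha_mask()
        in_slab = np.abs(s.coords[:, 2]) <= half_thickness
        tm_res = set(s.residue_keys()[ca & in_slab])
        mask = np.isin(s.residue_keys(), list(tm_res))
    if not np.any(mask):
        raise SelectionError("transmembrane selection matched no atoms")
    return mask


def check_preorientation(s: StructureModel, tolerance_z: float = 3.0,
                         mass_weighted: bool = True) -> float:
    """Return the z offset (A) of the transmembrane-region center of mass.

    A preoriented structure returns ~0.  Offsets beyond ``tolerance_z``
    trigger a warning (not an error): docking a badly placed structure is
    legal but the bilayer constraint then acts about the wrong plane.
    """
    mask = tm_selection_mask(s)
    z = s.coords[mask, 2]
    if mass_weighted:
        w = np.array([element_mass(e) for e in s.elements[mask]])
        offset = float(np.average(z, weights=w))
    else:
        offset = float(np.mean(z))
    if abs(offset) > tolerance_z:
        warnings.warn(
            f"transmembrane center of mass sits at z = {offset:.2f} A "
            f"(>|{tolerance_z}| A): structure may not be preoriented",
            stacklevel=2,
        )
    return offset


def apply_transform(s: StructureModel, t: RigidTransform) -> StructureModel:
    """Rigidly move a structure; topology is untouched."""
    return s.with_coords(t.apply(s.coords))


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


def _relabel_colliding_chains(receptor: StructureModel,
                              ligand: StructureModel) -> StructureModel:
    rec_chains = set(receptor.chain_ids.astype(str))
    lig_chains = list(dict.fromkeys(ligand.chain_ids.astype(str)))
    if not rec_chains.intersection(lig_chains):
        return ligand
    free = [c for c in _CHAIN_ALPHABET
            if c not in rec_chains and c not in lig_chains]
    mapping = {}
    for c in lig_chains:
        mapping[c] = free.pop(0) if c in rec_chains else c
    logger.warning("ligand chain ids collide with receptor; relabeling %s",
                   {k: v for k, v in mapping.items() if k != v})
    new_ids = np.array([mapping[c] for c in ligand.chain_ids.astype(str)])
    return replace(ligand, chain_ids=new_ids)


def _check_pdb_range(coords: np.ndarray, what: str) -> None:
    if coords.max() >= _PDB_COORD_MAX or coords.min() <= _PDB_COORD_MIN:
        raise PdbFormatError(
            f"{what} coordinates exceed the PDB fixed-column range "
            f"({_PDB_COORD_MIN:g} .. {_PDB_COORD_MAX:g} A)"
        )


def write_pdb(s: StructureModel, path) -> None:
    """Write a single structure as PDB."""
    _check_pdb_range(s.coords, "structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(str(path))


def write_ensemble_pdb(topology: StructureModel, ens: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    if ens.n_atoms != topology.n_atoms:
        raise CongruenceError("ensemble does not match topology atom count")
    _check_pdb_range(ens.frames, "ensemble")
    stack = bstruc.stack([_to_atom_array(topology)] * ens.n_frames)
    stack.coord = ens.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_model_pdb(receptor: StructureModel, ligand: StructureModel,
                    path) -> None:
    """Write a docked model: receptor then ligand in one PDB file.

    Ligand chains colliding with receptor chain ids are relabeled (warning
    logged).  Round-trips through :func:`read_pdb`.
    """
    ligand = _relabel_colliding_chains(receptor, ligand)
    _check_pdb_range(receptor.coords, "receptor")
    _check_pdb_range(ligand.coords, "ligand")
    merged = StructureModel(
        chain_ids=np.concatenate([receptor.chain_ids.astype("U4"),
                                  ligand.chain_ids.astype("U4")]),
        residue_numbers=np.concatenate([receptor.residue_numbers,
                                        ligand.residue_numbers]),
        residue_names=np.concatenate([receptor.residue_names.astype("U5"),
                                      ligand.residue_names.astype("U5")]),
        atom_names=np.concatenate([receptor.atom_names.astype("U6"),
                                   ligand.atom_names.astype("U6")]),
        elements=np.concatenate([receptor.elements.astype("U2"),
                                 ligand.elements.astype("U2")]),
        coords=np.vstack([receptor.coords, ligand.coords]),
    )
    write_pdb(merged, path)


def split_complex(s: StructureModel,
                  receptor_chains) -> tuple[StructureModel, StructureModel]:
    """Split one structure into (receptor, ligand) by chain membership."""
    receptor_chains = set(receptor_chains)
    mask = np.isin(s.chain_ids.astype(str), list(receptor_chains))
    if not mask.any() or mask.all():
        raise SelectionError(
            f"chains {sorted(receptor_chains)} do not split the complex"
        )
    return s.select(mask), s.select(~mask)
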