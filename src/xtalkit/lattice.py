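"""The 12-parameter crystal representation and the deterministic builder.

A Z'=1 crystal is fully specified by the cell lengths (a, b, c), cell
angles (alpha, beta, gamma), the fractional centroid of the canonical
conformer, a rotation-vector orientation relative to the conformer's
standardized inertial frame, plus the space group — see
:class:`CrystalParams`.  ``build_unit_cell`` maps parameters (and a rigid
conformer) to an explicit unit cell; ``extract_crystal_params`` inverts it.

The builder core (``_place_molecule``) runs on either NumPy arrays or
autodiff tensors, so crystal coordinates are differentiable functions of
the 12 parameters away from wrap boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from . import geometry
from .chem_io import CrystalEntry, MoleculeRecord
from .spacegroups import SpaceGroup

__all__ = [
    "CrystalParams",
    "SupercellStructure",
    "cell_matrix",
    "frac_cart",
    "select_canonical_conformer",
    "standardize_orientation",
    "extract_crystal_params",
    "build_unit_cell",
    "build_supercell",
    "supercell_encloses_check",
]

cell_matrix = geometry.cell_matrix
standardize_orientation = geometry.standardize_orientation


@dataclass
class CrystalParams:
    """The 12 generative coordinates of a Z'=1 molecular crystal."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    frac_centroid: np.ndarray  # fractional, each component in [0, 1)
    orientation: np.ndarray  # rotation vector (radians)
    space_group: SpaceGroup

    def __post_init__(self):
        self.frac_centroid = np.asarray(self.frac_centroid, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.frac_centroid.shape != (3,) or self.orientation.shape != (3,):
            raise ValueError("frac_centroid and orientation must be 3-vectors")
        if ((self.frac_centroid < 0) | (self.frac_centroid >= 1)).any():
            raise ValueError("frac_centroid components must lie in [0, 1)")
        geometry.triclinic_volume(
            self.a, self.b, self.c, self.alpha, self.beta, self.gamma
        )

    def as_vector(self) -> np.ndarray:
        """The 12 real parameters (space group carried separately)."""
        return np.concatenate(
            [
                [self.a, self.b, self.c, self.alpha, self.beta, self.gamma],
                self.frac_centroid,
                self.orientation,
            ]
        )

    @classmethod
    def from_vector(cls, vec, space_group: SpaceGroup) -> "CrystalParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (12,):
            raise ValueError("parameter vector must have length 12")
        return cls(
            a=vec[0], b=vec[1], c=vec[2],
            alpha=vec[3], beta=vec[4], gamma=vec[5],
            frac_centroid=vec[6:9] % 1.0,
            orientation=vec[9:12],
            space_group=space_group,
        )


@dataclass
class SupercellStructure:
    """Explicit atoms of an N x N x N supercell with graph labels.

    Labels: 0 = canonical conformer, 1 = within ``r_max + r_c`` of the
    canonical centroid (message sources), 2s are discarded at build time.
    ``symmetry_map[i]`` gives, for every atom, the index of its label-0
    image (identity on label-0 atoms).
    """

    coords: np.ndarray
    labels: np.ndarray
    molecule_image_index: np.ndarray
    symmetry_map: np.ndarray
    atomic_numbers: np.ndarray  # per retained atom
    canonical_indices: np.ndarray
    r_max: float
    r_c: float
    entry: CrystalEntry
    N: int
    atom_in_mol: np.ndarray | None = None  # index within the molecule
    frac_shifts: np.ndarray | None = None  # (N^3, 3) lattice translations

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def canonical_centroid(self) -> np.ndarray:
        return self.coords[self.canonical_indices].mean(axis=0)


def frac_cart(coords, matrix, direction: str):
    """Convert between fractional and Cartesian coordinates (row vectors)."""
    if direction == "to_cart":
        return geometry.frac_to_cart(coords, matrix)
    if direction == "to_frac":
        return geometry.cart_to_frac(coords, matrix)
    raise ValueError("direction must be 'to_cart' or 'to_frac'")


def select_canonical_conformer(entry: CrystalEntry) -> int:
    """Index of the molecule whose wrapped fractional centroid is nearest
    the origin (ties broken by lowest index)."""
    Minv = np.linalg.inv(entry.cell_matrix())
    cents = entry.unit_cell_coords.mean(axis=1) @ Minv
    cents = cents % 1.0
    norms = np.linalg.norm(cents, axis=1)
    return int(np.argmin(np.round(norms / 1e-9)))


def extract_crystal_params(entry: CrystalEntry) -> CrystalParams:
    """Invert the builder: recover the 12 parameters of an existing cell.

    Raises if the unit-cell molecules are not congruent images of each
    other (their sorted intramolecular distance multisets must agree).
    """
    ref = geometry.sorted_distance_multiset(entry.unit_cell_coords[0])
    for m in range(1, entry.Z):
        other = geometry.sorted_distance_multiset(entry.unit_cell_coords[m])
        if not np.allclose(ref, other, atol=1e-5):
            raise ValueError(
                f"{entry.identifier}: unit-cell molecules are not congruent "
                "symmetry images"
            )

    idx = select_canonical_conformer(entry)
    coords = entry.unit_cell_coords[idx]
    Minv = np.linalg.inv(entry.cell_matrix())
    frac_centroid = (coords.mean(axis=0) @ Minv) % 1.0
    rotation, _ = geometry.standardize_orientation(coords)
    orientation = geometry.matrix_to_rotvec(rotation)
    return CrystalParams(
        a=entry.a, b=entry.b, c=entry.c,
        alpha=entry.alpha, beta=entry.beta, gamma=entry.gamma,
        frac_centroid=frac_centroid,
        orientation=orientation,
        space_group=entry.space_group,
    )


def canonical_conformer_record(entry: CrystalEntry) -> MoleculeRecord:
    """The canonical molecule in its standardized inertial frame."""
    idx = select_canonical_conformer(entry)
    _, std = geometry.standardize_orientation(entry.unit_cell_coords[idx])
    return replace(entry.molecule, coords=std)


def _place_molecule(vec, std_coords, ops, wrap_shifts=None):
    """Backend-agnostic builder core.

    ``vec`` is the 12-parameter vector (array or Tensor); ``std_coords``
    the standardized, centered conformer.  Returns ``(M, [cart image
    coords])``.  ``wrap_shifts`` freezes the (piecewise-constant) centroid
    wrap so tensor runs stay differentiable; pass shifts captured from a
    NumPy run when differentiating.
    """
    M = geometry.cell_matrix(vec[0], vec[1], vec[2], vec[3], vec[4], vec[5])
    Minv = geometry.inv3(M)
    R = geometry.rotvec_to_matrix(vec[9:12])
    placed = ad.matmul(std_coords, ad.transpose(R))  # rotate rigid conformer
    frac_mol = ad.add(ad.matmul(placed, Minv), vec[6:9])
    images = []
    shifts_out = []
    for k, op in enumerate(ops):
        f = ad.add(ad.matmul(frac_mol, op.W.T), op.t)
        if wrap_shifts is None:
            c = ad.mean(f, axis=0).data if ad.is_tensor(f) else f.mean(axis=0)
            cent = np.floor(c + 1e-9)  # tolerance: exact-0 centroids stay put
        else:
            cent = wrap_shifts[k]
        shifts_out.append(cent)
        f = ad.add(f, -cent)
        images.append(ad.matmul(f, M))
    return M, images, shifts_out


def build_unit_cell(
    params: CrystalParams, conformer: MoleculeRecord, identifier: str | None = None
) -> CrystalEntry:
    """Deterministically build the explicit unit cell from the parameters.

    The conformer must be in standardized orientation with centroid at the
    origin; it is rotated by the orientation vector, its centroid placed at
    the fractional centroid, and the remaining Z-1 images generated by the
    space-group operators (each image wrapped so its centroid lies in the
    home cell).
    """
    ops = params.space_group.ops
    if not ops:
        raise ValueError("space group operator set is empty")
    std = np.asarray(conformer.coords, dtype=float)
    cent = std.mean(axis=0)
    if np.linalg.norm(cent) > 1e-8:
        std = std - cent
    _, images, _ = _place_molecule(params.as_vector(), std, ops)
    unit_cell = np.stack(images)
    molecule = replace(conformer, coords=unit_cell[0])
    return CrystalEntry(
        identifier=identifier or f"built-{conformer.identifier}",
        molecule=molecule,
        a=params.a, b=params.b, c=params.c,
        alpha=params.alpha, beta=params.beta, gamma=params.gamma,
        space_group=params.space_group,
        Z=len(ops),
        unit_cell_coords=unit_cell,
    )


def build_supercell(
    entry: CrystalEntry, N: int = 3, r_c: float = 6.0,
    label_cutoff: float | None = None,
) -> SupercellStructure:
    """Expand a unit cell to an N x N x N supercell and label its atoms.

    Generates ``Z * N^3`` molecule images centered on the home cell, labels
    atoms (0 canonical / 1 within ``r_max + r_c`` of the canonical
    centroid), discards label-2 atoms, and records the symmetry map onto
    the canonical conformer.
    """
    if N < 1 or N % 2 == 0:
        raise ValueError("N must be a positive odd integer")
    M = entry.cell_matrix()
    canon = select_canonical_conformer(entry)
    n_at = entry.molecule.n_atoms
    canon_coords = entry.unit_cell_coords[canon]
    centroid = canon_coords.mean(axis=0)
    rmax = geometry.r_max(canon_coords)
    cut = rmax + r_c if label_cutoff is None else label_cutoff

    half = (N - 1) // 2
    shifts = np.array(
        [
            (i, j, k)
            for i in range(-half, half + 1)
            for j in range(-half, half + 1)
            for k in range(-half, half + 1)
        ],
        dtype=float,
    )
    cart_shifts = shifts @ M

    coords_list, labels, mol_idx, atom_in_mol = [], [], [], []
    image = 0
    for s in cart_shifts:
        at_home = np.allclose(s, 0.0)
        for m in range(entry.Z):
            block = entry.unit_cell_coords[m] + s
            if at_home and m == canon:
                lab = np.zeros(n_at, dtype=int)
            else:
                d = np.linalg.norm(block - centroid, axis=1)
                lab = np.where(d <= cut, 1, 2)
            keep = lab < 2
            if keep.any():
                coords_list.append(block[keep])
                labels.append(lab[keep])
                mol_idx.append(np.full(keep.sum(), image))
                atom_in_mol.append(np.flatnonzero(keep))
            image += 1

    coords = np.concatenate(coords_list)
    labels = np.concatenate(labels)
    mol_idx = np.concatenate(mol_idx)
    atom_in_mol = np.concatenate(atom_in_mol)

    canonical_indices = np.flatnonzero(labels == 0)
    if len(canonical_indices) != n_at:
        raise RuntimeError("canonical conformer mislabeled")
    # atom k of any molecule image maps onto canonical atom k
    symmetry_map = canonical_indices[atom_in_mol]
    atomic_numbers = entry.molecule.atomic_numbers[atom_in_mol]

    return SupercellStructure(
        coords=coords,
        labels=labels,
        molecule_image_index=mol_idx,
        symmetry_map=symmetry_map,
        atomic_numbers=atomic_numbers,
        canonical_indices=canonical_indices,
        r_max=rmax,
        r_c=r_c,
        entry=entry,
        N=N,
        atom_in_mol=atom_in_mol,
        frac_shifts=shifts,
    )


def supercell_encloses_check(entry: CrystalEntry, N: int, r_c: float) -> bool:
    """True iff every atom that could be labeled 1 is generated by the
    N x N x N supercell.

    Generated molecules are those whose wrapped centroids lie in the N^3
    cell block, and an atom within ``r_max + r_c`` of the canonical
    centroid can belong to a molecule centered up to ``r_max`` further
    out — so the sphere of radius ``2 r_max + r_c`` about the canonical
    centroid must fit inside the supercell parallelepiped.
    """
    M = entry.cell_matrix()
    canon = select_canonical_conformer(entry)
    coords = entry.unit_cell_coords[canon]
    centroid = coords.mean(axis=0)
    radius = 2.0 * geometry.r_max(coords) + r_c
    fc = centroid @ np.linalg.inv(M)

    half = (N - 1) // 2
    vol = abs(np.linalg.det(M))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        spacing = vol / np.linalg.norm(np.cross(M[j], M[k]))  # per unit cell
        lo, hi = -half, half + 1
        if (fc[i] - lo) * spacing < radius or (hi - fc[i]) * spacing < radius:
            return False
    return True
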