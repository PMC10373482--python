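"""Deterministic synthetic molecules, crystals, and labeled datasets.

Everything every other module needs for testing and desk-scale training
is generated here with no downloads: rigid geometric conformers with a
minimum interatomic distance, crystals built from known ground-truth
parameters (so round-trip tests have an oracle), and conformer datasets
whose packing-coefficient labels follow a planted smooth function with a
known noise floor.

Fixture molecules are geometric clusters rather than chemically exact
structures; a small set of literature-geometry molecules (benzene-like
ring, urea-like fragment) is included for featurizer paths that care
about chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import CrystalEntry, MoleculeRecord, featurize, molecular_volume
from .geometry import standardize_orientation
from .lattice import CrystalParams, build_unit_cell
from .spacegroups import TABLE, SpaceGroup, get_space_group

__all__ = [
    "FixtureSpec",
    "make_molecule",
    "make_crystal",
    "make_density_dataset",
    "benzene_like",
    "urea_like",
]

MIN_DIST = 1.1  # Å, hard floor on interatomic distances


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic fixture set."""

    seed: int = 0
    n_atoms_range: tuple = (4, 30)
    elements: tuple = (6, 7, 8)
    c_pack_range: tuple = (0.55, 0.85)
    space_groups: tuple = ("P1", "P-1", "P21", "P21/c", "P212121", "C2/c", "Pbca", "Pna21")
    n_entries: int = 10

    def rng(self, index: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, index))


def make_molecule(spec: FixtureSpec, index: int, featurized: bool = True) -> MoleculeRecord:
    """A rigid connected conformer, deterministic under (seed, index).

    Atoms are grown one at a time at bonding distance (1.4-1.6 Å) from a
    random existing atom, rejecting any placement closer than 1.1 Å to the
    cluster; the result is connected with realistic nearest-neighbor
    spacing.
    """
    rng = spec.rng(index)
    lo, hi = spec.n_atoms_range
    n = int(rng.integers(lo, hi + 1))
    coords = [np.zeros(3)]
    attempts = 0
    while len(coords) < n:
        base = coords[int(rng.integers(len(coords)))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = base + rng.uniform(1.4, 1.6) * direction
        d = np.linalg.norm(np.asarray(coords) - cand, axis=1)
        attempts += 1
        if (d >= MIN_DIST).all() or attempts > 10_000:
            coords.append(cand)
            attempts = 0
    zs = rng.choice(spec.elements, size=n)
    mol = MoleculeRecord(
        identifier=f"fix-{spec.seed}-{index}",
        atomic_numbers=np.asarray(zs, dtype=int),
        coords=np.asarray(coords),
    )
    return featurize(mol) if featurized else mol


def _standardized(mol: MoleculeRecord) -> MoleculeRecord:
    from dataclasses import replace

    _, std = standardize_orientation(mol.coords)
    return replace(mol, coords=std)


def make_crystal(
    spec: FixtureSpec, index: int, space_group: str | SpaceGroup | None = None
) -> tuple[CrystalParams, CrystalEntry]:
    """A crystal with known ground-truth parameters plus the built entry.

    Cell lengths are rescaled so the packing coefficient lands inside the
    spec's target range; the fractional centroid is kept near the origin
    so the canonical-conformer choice is unambiguous.
    """
    rng = spec.rng(index)
    mol = _standardized(make_molecule(spec, index))
    if space_group is None:
        group = get_space_group(spec.space_groups[index % len(spec.space_groups)])
    elif isinstance(space_group, str):
        group = get_space_group(space_group)
    else:
        group = space_group
    Z = group.multiplicity
    v_mol = mol.mol_volume if mol.mol_volume is not None else molecular_volume(mol)

    c_pack = rng.uniform(*spec.c_pack_range)
    # random near-orthogonal shape, then scale to the target cell volume
    ratios = rng.uniform(0.8, 1.25, size=3)
    angles = np.full(3, 90.0)
    if group.symbol in ("P21", "P21/c", "C2/c"):
        angles[1] = rng.uniform(95.0, 115.0)  # monoclinic beta
    elif group.symbol in ("P1", "P-1"):
        angles = rng.uniform(80.0, 100.0, size=3)
    cosang = np.cos(np.radians(angles))
    shape_factor = np.sqrt(
        1 - cosang[0] ** 2 - cosang[1] ** 2 - cosang[2] ** 2
        + 2 * np.prod(cosang)
    )
    target_volume = Z * v_mol / c_pack
    scale = (target_volume / (np.prod(ratios) * shape_factor)) ** (1.0 / 3.0)
    lengths = ratios * scale

    frac_centroid = rng.uniform(0.02, 0.2, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    orientation = axis * rng.uniform(0.1, 3.0)

    params = CrystalParams(
        a=lengths[0], b=lengths[1], c=lengths[2],
        alpha=angles[0], beta=angles[1], gamma=angles[2],
        frac_centroid=frac_centroid,
        orientation=orientation,
        space_group=group,
    )
    entry = build_unit_cell(params, mol, identifier=f"xtal-{spec.seed}-{index}")
    return params, entry


def make_packed_crystal(
    spec: FixtureSpec, index: int, space_group: str | SpaceGroup | None = None,
    gap_range: tuple = (1.02, 1.10),
) -> tuple[CrystalParams, CrystalEntry]:
    """A vdW-respecting ("pristine") crystal fixture.

    Starting from :func:`make_crystal`, cell lengths are rescaled until
    the tightest intermolecular contact sits just above the vdW radius
    sum (ratio drawn from ``gap_range``).  These emulate the contact
    structure of experimental crystals: dense but clash-free — the
    property that distortion or Gaussian resampling destroys.
    """
    from .lattice import build_supercell
    from .scoring import _intermolecular_pairs

    rng = spec.rng(900_000 + index)
    params, entry = make_crystal(spec, index, space_group=space_group)
    mol = _standardized(entry.molecule)
    target = rng.uniform(*gap_range)
    n_candidates = 6

    def min_ratio(p: CrystalParams) -> float:
        e = build_unit_cell(p, mol)
        cell = build_supercell(e, N=3, r_c=6.0)
        dist, ci, ii = _intermolecular_pairs(cell)
        if len(dist) == 0:
            return np.inf
        zs = cell.atomic_numbers
        from .elements import vdw_radius

        r_sum = np.array(
            [vdw_radius(int(zs[i])) + vdw_radius(int(zs[j])) for i, j in zip(ci, ii)]
        )
        return float((dist / r_sum).min())

    def settle(vec0: np.ndarray) -> np.ndarray:
        """Rescale lengths until the tightest contact ratio hits target."""
        vec = vec0.copy()
        for _ in range(12):
            p = CrystalParams.from_vector(vec, params.space_group)
            ratio = min_ratio(p)
            if not np.isfinite(ratio):
                vec[:3] *= 0.8
                continue
            if abs(ratio - target) < 0.01:
                break
            vec[:3] *= (target / ratio) ** 0.6  # damped rescale
        return vec

    # several random poses; keep the densest clash-free result
    best_vec, best_volume = None, np.inf
    base = params.as_vector()
    for k in range(n_candidates):
        cand = base.copy()
        if k > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            cand[9:12] = axis * rng.uniform(0.1, 3.0)
            cand[6:9] = rng.uniform(0.02, 0.2, size=3)
        cand = settle(cand)
        vol = np.prod(cand[:3])
        if vol < best_volume:
            best_vec, best_volume = cand, vol
    params = CrystalParams.from_vector(best_vec, params.space_group)
    entry = build_unit_cell(params, mol, identifier=f"packed-{spec.seed}-{index}")
    return params, entry


def make_density_dataset(
    spec: FixtureSpec, n: int | None = None, noise_sigma: float = 0.01
) -> list:
    """Labeled conformers: c_pack = planted smooth function + N(0, sigma^2).

    The planted function depends only on (n_atoms, V_mol); a learner's
    achievable MAE is floored at ``sigma * sqrt(2/pi)``.
    """
    if n is None:
        n = spec.n_entries
    out = []
    for i in range(n):
        mol = make_molecule(spec, i)
        label = planted_c_pack(mol.n_atoms, float(mol.mol_volume))
        noisy = label + noise_sigma * spec.rng(10_000_000 + i).standard_normal()
        out.append((mol, float(noisy)))
    return out


def planted_c_pack(n_atoms: float, v_mol: float) -> float:
    """Fixed smooth deterministic label function on molecule descriptors."""
    x = n_atoms / 24.0 + v_mol / 480.0
    return 0.55 + 0.25 / (1.0 + np.exp(-6.0 * (x - 0.5)))


# ----------------------------------------------------------------------
# small literature-geometry molecules for chemistry-aware paths
# ----------------------------------------------------------------------

def benzene_like(with_hydrogens: bool = True) -> MoleculeRecord:
    """Planar six-ring with ideal benzene geometry (C-C 1.39, C-H 1.09 Å)."""
    angles = np.radians(np.arange(6) * 60.0)
    ring = np.stack([1.39 * np.cos(angles), 1.39 * np.sin(angles), np.zeros(6)], axis=1)
    zs = [6] * 6
    coords = [ring]
    if with_hydrogens:
        hyd = np.stack(
            [(1.39 + 1.09) * np.cos(angles), (1.39 + 1.09) * np.sin(angles), np.zeros(6)],
            axis=1,
        )
        coords.append(hyd)
        zs += [1] * 6
    return MoleculeRecord("benzene-like", np.array(zs), np.concatenate(coords))


def urea_like(with_hydrogens: bool = True) -> MoleculeRecord:
    """Planar urea-like fragment: C=O with two amine nitrogens."""
    atoms = [
        (6, [0.0, 0.0, 0.0]),
        (8, [0.0, 1.23, 0.0]),
        (7, [1.16, -0.66, 0.0]),
        (7, [-1.16, -0.66, 0.0]),
    ]
    if with_hydrogens:
        atoms += [
            (1, [2.02, -0.14, 0.0]),
            (1, [1.18, -1.67, 0.0]),
            (1, [-2.02, -0.14, 0.0]),
            (1, [-1.18, -1.67, 0.0]),
        ]
    zs = np.array([z for z, _ in atoms])
    coords = np.array([xyz for _, xyz in atoms])
    return MoleculeRecord("urea-like", zs, coords)
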