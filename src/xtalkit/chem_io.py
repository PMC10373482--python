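"""Molecule and crystal I/O, featurization, and the filter cascade.

Crystals are exchanged as plain-text CIF (cell block, ``x,y,z``-style
symmetry operator loop, fractional atom sites); bare conformers as XYZ.
No crystallographic-database access is required anywhere.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from . import elements, geometry
from .spacegroups import SpaceGroup, format_op, get_space_group, parse_op

N_ATOM_FEATURES = 8
N_MOL_FEATURES = 16
_VOLUME_MC_POINTS = 100_000
_VOLUME_MC_SEED = 1729  # fixed: molecular volume must be reproducible

RUNTIME_FILTERS = (
    "z_prime_one",
    "max_atoms",
    "max_atomic_number",
    "z_range",
    "z_wyckoff",
    "packing_coefficient_range",
    "overlapping_atoms",
)

PROCESSING_FILTERS = (
    "entry_not_empty",
    "entry_has_atoms",
    "valid_cell",
    "not_polymeric",
)


# ----------------------------------------------------------------------
# records
# ----------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    """A rigid conformer with optional feature annotations."""

    identifier: str
    atomic_numbers: np.ndarray
    coords: np.ndarray
    atom_features: np.ndarray | None = None
    mol_features: np.ndarray | None = None
    n_donors: int = 0
    n_acceptors: int = 0
    mol_volume: float | None = None
    donor_flags: np.ndarray | None = None
    acceptor_flags: np.ndarray | None = None

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atomic_numbers), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.atomic_numbers) < 1:
            raise ValueError("molecule has no atoms")
        if self.atom_features is not None:
            self.atom_features = np.asarray(self.atom_features, dtype=float)
            if self.atom_features.shape != (self.n_atoms, N_ATOM_FEATURES):
                raise ValueError("atom_features must be (n_atoms, 8)")
        if self.mol_features is not None:
            self.mol_features = np.asarray(self.mol_features, dtype=float)
            if self.mol_features.shape != (N_MOL_FEATURES,):
                raise ValueError("mol_features must have length 16")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def has_overlapping_atoms(self) -> bool:
        d = np.linalg.norm(
            self.coords[:, None, :] - self.coords[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return bool((d == 0.0).any())


@dataclass
class CrystalEntry:
    """A Z'=1 molecular crystal: one conformer plus its unit-cell images."""

    identifier: str
    molecule: MoleculeRecord
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: SpaceGroup
    Z: int
    unit_cell_coords: np.ndarray  # (Z, n_atoms, 3) Cartesian Å
    is_polymeric: bool = False

    def __post_init__(self):
        self.unit_cell_coords = np.asarray(self.unit_cell_coords, dtype=float)
        if self.Z <= 0:
            raise ValueError("Z must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.unit_cell_coords.shape != (self.Z, self.molecule.n_atoms, 3):
            raise ValueError("unit_cell_coords must be (Z, n_atoms, 3)")
        geometry.triclinic_volume(
            self.a, self.b, self.c, self.alpha, self.beta, self.gamma
        )  # raises on non-positive volume

    @property
    def cell_lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def cell_angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def cell_volume(self) -> float:
        return geometry.triclinic_volume(
            self.a, self.b, self.c, self.alpha, self.beta, self.gamma
        )

    def cell_matrix(self) -> np.ndarray:
        return geometry.cell_matrix(
            self.a, self.b, self.c, self.alpha, self.beta, self.gamma
        )


@dataclass
class FilterReport:
    """Per-entry pass/fail flags keyed by filter name."""

    filters: tuple
    flags: dict = field(default_factory=dict)  # identifier -> {filter: bool}

    def passed(self, identifier: str) -> bool:
        return all(self.flags[identifier].values())

    @property
    def survivors(self) -> list[str]:
        return [ident for ident in self.flags if self.passed(ident)]

    def to_text(self) -> str:
        header = ["identifier", *self.filters, "pass"]
        lines = ["\t".join(header)]
        for ident, row in self.flags.items():
            cells = [ident] + [
                ("ok" if row[f] else "FAIL") for f in self.filters
            ] + [("ok" if self.passed(ident) else "FAIL")]
            lines.append("\t".join(cells))
        return "\n".join(lines)


# ----------------------------------------------------------------------
# hydrogen handling and featurization
# ----------------------------------------------------------------------

def strip_hydrogens(mol: MoleculeRecord) -> MoleculeRecord:
    """Delete all hydrogen atoms, recording donor flags before deletion.

    A heavy N/O/S atom with a covalently bonded hydrogen is flagged as a
    hydrogen-bond donor; N/O/F atoms are flagged as acceptors.  Existing
    annotations on hydrogen-free input are preserved.
    """
    z = mol.atomic_numbers
    heavy = z != 1
    if not heavy.any():
        raise ValueError(f"{mol.identifier}: all-hydrogen molecule rejected")
    if heavy.all():
        out = replace(mol)
        if out.acceptor_flags is None:
            out.acceptor_flags = np.isin(z, (7, 8, 9)).astype(float)
            out.n_acceptors = int(out.acceptor_flags.sum())
        if out.donor_flags is None:
            out.donor_flags = np.zeros(mol.n_atoms)
        return out

    coords = mol.coords
    h_idx = np.flatnonzero(~heavy)
    donor = np.zeros(mol.n_atoms)
    for hi in h_idx:
        d = np.linalg.norm(coords - coords[hi], axis=1)
        d[hi] = np.inf
        cut = 1.3 * (elements.covalent_radius(1) + np.array(
            [elements.covalent_radius(int(zz)) for zz in z]
        ))
        bonded = np.flatnonzero((d <= cut) & heavy)
        for bi in bonded:
            if z[bi] in (7, 8, 16):
                donor[bi] = 1.0

    acceptor = np.isin(z, (7, 8, 9)).astype(float)
    keep = np.flatnonzero(heavy)
    return MoleculeRecord(
        identifier=mol.identifier,
        atomic_numbers=z[keep],
        coords=coords[keep],
        n_donors=int(donor[keep].sum()),
        n_acceptors=int(acceptor[keep].sum()),
        donor_flags=donor[keep],
        acceptor_flags=acceptor[keep],
    )


def bond_graph(mol: MoleculeRecord, scale: float = 1.3) -> nx.Graph:
    """Distance-based covalent bond graph (edge if d <= scale * (r_i + r_j))."""
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    rc = np.array(
        [elements.covalent_radius(int(z)) for z in mol.atomic_numbers]
    )
    d = np.linalg.norm(
        mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1
    )
    cut = scale * (rc[:, None] + rc[None, :])
    ii, jj = np.nonzero((d <= cut) & (d > 0))
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    return g


def molecular_volume(mol: MoleculeRecord) -> float:
    """Volume of the union of atomic vdW spheres, by Monte Carlo integration.

    Sampling happens in the molecule's standardized inertial frame so the
    estimate is invariant under rigid motion of the input; the stream is
    seeded with a fixed constant for reproducibility.
    """
    if mol.n_atoms >= 3:
        try:
            _, coords = geometry.standardize_orientation(mol.coords)
        except ValueError:
            coords = mol.coords - mol.coords.mean(axis=0)
    else:
        coords = mol.coords - mol.coords.mean(axis=0)
    radii = elements.vdw_radii_array(mol.atomic_numbers)
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    rng = np.random.default_rng(_VOLUME_MC_SEED)
    pts = rng.uniform(lo, hi, size=(_VOLUME_MC_POINTS, 3))
    inside = np.zeros(_VOLUME_MC_POINTS, dtype=bool)
    for xyz, r in zip(coords, radii):
        inside |= ((pts - xyz) ** 2).sum(axis=1) <= r * r
    box = float(np.prod(hi - lo))
    return box * inside.mean()


def _ring_count(mol: MoleculeRecord) -> int:
    g = bond_graph(mol)
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def featurize(mol: MoleculeRecord) -> MoleculeRecord:
    """Attach the 8 per-atom and 16 per-molecule input features.

    Atom features: atomic number, period, group, electronegativity,
    covalent radius, vdW radius, donor flag, acceptor flag.

    Molecule features: n_atoms, mass, vdW volume, three principal inertial
    moments, radius of gyration, ring count, rotatable-bond count (0 for
    rigid conformers), donor/acceptor counts, planarity, max centroid-atom
    distance, and three composition fractions (C / N+O / other).
    """
    if (mol.atomic_numbers == 1).any():
        raise ValueError("strip hydrogens before featurization")
    if mol.has_overlapping_atoms():
        raise ValueError(f"{mol.identifier}: exactly overlapping atoms")
    z = mol.atomic_numbers
    if (z < 1).any() or (z > elements.MAX_Z).any():
        raise ValueError(f"{mol.identifier}: atomic number outside 1..100")

    donor = mol.donor_flags
    acceptor = mol.acceptor_flags
    if acceptor is None:
        acceptor = np.isin(z, (7, 8, 9)).astype(float)
    if donor is None:
        donor = np.zeros(mol.n_atoms)

    atom_features = np.column_stack(
        [
            z.astype(float),
            [elements.period(int(x)) for x in z],
            [elements.group(int(x)) for x in z],
            [elements.electronegativity(int(x)) for x in z],
            [elements.covalent_radius(int(x)) for x in z],
            [elements.vdw_radius(int(x)) for x in z],
            donor,
            acceptor,
        ]
    )

    coords = mol.coords - mol.coords.mean(axis=0)
    moments = np.sort(np.linalg.eigvalsh(geometry.inertia_tensor(coords)))
    rg = float(np.sqrt((coords**2).sum(axis=1).mean()))
    gyr = coords.T @ coords / mol.n_atoms
    gvals = np.sort(np.linalg.eigvalsh(gyr))
    planarity = float(gvals[0] / max(gvals.sum(), 1e-12))
    volume = molecular_volume(mol) if mol.mol_volume is None else mol.mol_volume
    masses = np.array([elements.mass(int(x)) for x in z])
    n_donors = int(donor.sum())
    n_acceptors = int(acceptor.sum())

    mol_features = np.array(
        [
            float(mol.n_atoms),
            float(masses.sum()),
            float(volume),
            moments[0],
            moments[1],
            moments[2],
            rg,
            float(_ring_count(mol)),
            0.0,  # rotatable bonds: conformers are rigid here
            float(n_donors),
            float(n_acceptors),
            planarity,
            geometry.r_max(mol.coords),
            float((z == 6).sum()) / mol.n_atoms,
            float(np.isin(z, (7, 8)).sum()) / mol.n_atoms,
            float((~np.isin(z, (6, 7, 8))).sum()) / mol.n_atoms,
        ]
    )

    return replace(
        mol,
        atom_features=atom_features,
        mol_features=mol_features,
        mol_volume=float(volume),
        n_donors=n_donors,
        n_acceptors=n_acceptors,
        donor_flags=donor,
        acceptor_flags=acceptor,
    )


# ----------------------------------------------------------------------
# packing coefficient and filters
# ----------------------------------------------------------------------

def packing_coefficient(entry: CrystalEntry) -> float:
    """Fraction of the unit cell occupied by molecular volume: Z*V_mol/V_cell."""
    v_mol = entry.molecule.mol_volume
    if v_mol is None:
        v_mol = molecular_volume(entry.molecule)
        entry.molecule.mol_volume = float(v_mol)
    v_cell = entry.cell_volume
    if v_cell <= 0:
        raise ValueError("zero cell volume")
    return entry.Z * v_mol / v_cell


def crystal_density(entry: CrystalEntry) -> float:
    """Mass density in g/cm^3 (trivial mass-weighted transform of c_pack)."""
    masses = np.array([elements.mass(int(z)) for z in entry.molecule.atomic_numbers])
    grams = entry.Z * masses.sum() / 6.02214076e23
    return grams / (entry.cell_volume * 1e-24)


def _runtime_flags(entry: CrystalEntry) -> dict:
    mol = entry.molecule
    flags = {}
    flags["z_prime_one"] = entry.unit_cell_coords.shape[0] == entry.Z
    flags["max_atoms"] = mol.n_atoms <= 100
    flags["max_atomic_number"] = bool((mol.atomic_numbers <= 100).all())
    flags["z_range"] = 0 < entry.Z <= 18
    flags["z_wyckoff"] = entry.Z == entry.space_group.multiplicity
    try:
        cp = packing_coefficient(entry)
        flags["packing_coefficient_range"] = 0.55 < cp < 0.85
    except ValueError:
        flags["packing_coefficient_range"] = False
    coords = entry.unit_cell_coords.reshape(-1, 3)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    flags["overlapping_atoms"] = bool((d2 > 0).all())
    return flags


def _processing_flags(entry: CrystalEntry | None) -> dict:
    flags = {}
    flags["entry_not_empty"] = entry is not None
    flags["entry_has_atoms"] = (
        entry is not None and entry.molecule.n_atoms >= 1
    )
    ok_cell = False
    if entry is not None:
        try:
            ok_cell = entry.cell_volume > 0
        except ValueError:
            ok_cell = False
    flags["valid_cell"] = ok_cell
    flags["not_polymeric"] = entry is not None and not entry.is_polymeric
    return flags


def apply_filters(entries, stage: str = "runtime") -> FilterReport:
    """Mark every entry against the filter cascade; filters never raise.

    ``stage`` is ``"processing"`` (structural sanity) or ``"runtime"``
    (Z'=1, size, atomic-number, Z-multiplicity, packing-coefficient and
    overlap checks).
    """
    if stage not in ("processing", "runtime"):
        raise ValueError("stage must be 'processing' or 'runtime'")
    names = PROCESSING_FILTERS if stage == "processing" else RUNTIME_FILTERS
    report = FilterReport(filters=names)
    for i, entry in enumerate(entries):
        ident = entry.identifier if entry is not None else f"<empty-{i}>"
        if stage == "processing":
            report.flags[ident] = _processing_flags(entry)
        else:
            report.flags[ident] = _runtime_flags(entry)
    return report


# ----------------------------------------------------------------------
# CIF I/O (plain-text, small-molecule dialect)
# ----------------------------------------------------------------------

def _cif_tokens(text: str):
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield from shlex.split(line, posix=True)


def _parse_cif(text: str) -> tuple[dict, list[dict]]:
    """Parse one data block into scalars and loop tables."""
    tokens = list(_cif_tokens(text))
    scalars: dict[str, str] = {}
    loops: list[dict] = []
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.startswith("data_"):
            i += 1
        elif tok == "loop_":
            i += 1
            headers = []
            while i < n and tokens[i].startswith("_"):
                headers.append(tokens[i].lower())
                i += 1
            rows = []
            while i < n and not tokens[i].startswith("_") and tokens[i] != "loop_" and not tokens[i].startswith("data_"):
                rows.append(tokens[i : i + len(headers)])
                i += len(headers)
            loops.append(
                {h: [r[k] for r in rows if len(r) == len(headers)] for k, h in enumerate(headers)}
            )
        elif tok.startswith("_"):
            if i + 1 >= n:
                raise ValueError(f"dangling CIF tag {tok}")
            scalars[tok.lower()] = tokens[i + 1]
            i += 2
        else:
            raise ValueError(f"unexpected CIF token {tok!r}")
    return scalars, loops


def _cif_number(s: str) -> float:
    # strip standard-uncertainty suffix: "1.234(5)"
    return float(s.split("(")[0])


def read_crystal_cif(path) -> CrystalEntry:
    """Read a small-molecule CIF into a :class:`CrystalEntry`.

    The asymmetric unit is expanded to the full unit cell by the file's
    symmetry operators; atom coordinates come back in Cartesian Å.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        scalars, loops = _parse_cif(text)
    except ValueError as exc:
        raise ValueError(f"CIF parse failure in {path}: {exc}") from exc

    try:
        cell = [
            _cif_number(scalars[f"_cell_length_{k}"]) for k in "abc"
        ] + [
            _cif_number(scalars[f"_cell_angle_{k}"])
            for k in ("alpha", "beta", "gamma")
        ]
    except KeyError as exc:
        raise ValueError(f"incomplete CIF entry {path}: missing cell") from exc

    symbol = scalars.get(
        "_symmetry_space_group_name_h-m",
        scalars.get("_space_group_name_h-m_alt", "P1"),
    )

    op_strings = []
    sites = None
    for loop in loops:
        for key in (
            "_symmetry_equiv_pos_as_xyz",
            "_space_group_symop_operation_xyz",
        ):
            if key in loop:
                op_strings = loop[key]
        if "_atom_site_fract_x" in loop:
            sites = loop
    if sites is None or not sites.get("_atom_site_fract_x"):
        raise ValueError(f"incomplete CIF entry {path}: missing atom sites")
    if not op_strings:
        op_strings = ["x,y,z"]

    try:
        group = get_space_group(symbol)
        if len(group.ops) != len(op_strings):
            group = SpaceGroup.from_strings(symbol, op_strings)
    except KeyError:
        group = SpaceGroup.from_strings(symbol, op_strings)

    symbols = sites.get("_atom_site_type_symbol") or sites["_atom_site_label"]
    zs = []
    for s in symbols:
        sym = "".join(ch for ch in s if ch.isalpha())
        sym = sym[:2].capitalize() if sym[:2].capitalize() in elements.Z_FROM_SYMBOL else sym[:1].upper()
        if sym not in elements.Z_FROM_SYMBOL:
            raise ValueError(f"unknown element symbol {s!r} in {path}")
        zs.append(elements.Z_FROM_SYMBOL[sym])
    frac = np.column_stack(
        [
            [_cif_number(v) for v in sites["_atom_site_fract_x"]],
            [_cif_number(v) for v in sites["_atom_site_fract_y"]],
            [_cif_number(v) for v in sites["_atom_site_fract_z"]],
        ]
    )
    zs = np.asarray(zs, dtype=int)

    M = geometry.cell_matrix(*cell)
    identifier = ""
    for line in text.splitlines():
        if line.strip().startswith("data_"):
            identifier = line.strip()[5:]
            break

    if len(op_strings) > 1:
        # asymmetric unit + operators: expand molecule-wise
        mol_coords = frac @ M
        molecule = MoleculeRecord(identifier, zs, mol_coords)
        images = _expand_molecule(frac, group, M)
        Z = len(images)
        unit_cell = np.stack(images)
    else:
        # P1-style full cell: segment into molecules by connectivity
        cart = frac @ M
        allmol = MoleculeRecord(identifier, zs, cart)
        comps = sorted(
            nx.connected_components(bond_graph(allmol)), key=min
        )
        mols = [np.sort(np.fromiter(c, dtype=int)) for c in comps]
        sizes = {len(m) for m in mols}
        if len(sizes) != 1:
            raise ValueError(f"{path}: unit cell molecules differ in size (Z'>1?)")
        cents = np.stack([frac[m].mean(axis=0) % 1.0 for m in mols])
        canonical = int(np.argmin(np.linalg.norm(cents, axis=1)))
        molecule = MoleculeRecord(
            identifier, zs[mols[canonical]], cart[mols[canonical]]
        )
        order = [canonical] + [k for k in range(len(mols)) if k != canonical]
        unit_cell = np.stack([cart[mols[k]] for k in order])
        Z = len(mols)

    return CrystalEntry(
        identifier=identifier or "cif-entry",
        molecule=molecule,
        a=cell[0], b=cell[1], c=cell[2],
        alpha=cell[3], beta=cell[4], gamma=cell[5],
        space_group=group,
        Z=Z,
        unit_cell_coords=unit_cell,
    )


def _expand_molecule(frac: np.ndarray, group: SpaceGroup, M: np.ndarray):
    """Apply each operator to the whole molecule, wrapping by its centroid."""
    images = []
    for op in group.ops:
        f = op.apply(frac)
        cent = f.mean(axis=0)
        f = f - np.floor(cent)
        images.append(f @ M)
    return images


def write_crystal_cif(entry: CrystalEntry, path, mode: str = "asymmetric") -> None:
    """Write a CIF re-readable by :func:`read_crystal_cif`.

    ``mode="asymmetric"`` stores the canonical molecule plus the symmetry
    operator loop; ``mode="full"`` stores every unit-cell atom under a
    single identity operator.
    """
    if entry.cell_volume <= 0:  # pragma: no cover - constructor also checks
        raise ValueError("degenerate cell")
    if mode not in ("asymmetric", "full"):
        raise ValueError("mode must be 'asymmetric' or 'full'")
    M = entry.cell_matrix()
    Minv = np.linalg.inv(M)
    lines = [f"data_{entry.identifier}"]
    for tag, val in zip(
        ("a", "b", "c"), (entry.a, entry.b, entry.c)
    ):
        lines.append(f"_cell_length_{tag} {val:.10f}")
    for tag, val in zip(
        ("alpha", "beta", "gamma"), (entry.alpha, entry.beta, entry.gamma)
    ):
        lines.append(f"_cell_angle_{tag} {val:.10f}")
    lines.append(f"_symmetry_space_group_name_H-M '{entry.space_group.symbol}'")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    if mode == "asymmetric":
        for op in entry.space_group.ops:
            lines.append(f"'{format_op(op)}'")
        mols = [entry.unit_cell_coords[0]]
    else:
        lines.append("'x,y,z'")
        mols = list(entry.unit_cell_coords)
    lines.append("loop_")
    lines.append("_atom_site_label")
    lines.append("_atom_site_type_symbol")
    lines.append("_atom_site_fract_x")
    lines.append("_atom_site_fract_y")
    lines.append("_atom_site_fract_z")
    counter: dict[str, int] = {}
    for cart in mols:
        frac = cart @ Minv
        for z, f in zip(entry.molecule.atomic_numbers, frac):
            sym = elements.SYMBOLS[int(z)]
            counter[sym] = counter.get(sym, 0) + 1
            lines.append(
                f"{sym}{counter[sym]} {sym} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# XYZ / SDF conformer I/O
# ----------------------------------------------------------------------

def read_xyz(path) -> MoleculeRecord:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    ident = lines[1].strip() or "xyz-molecule"
    zs, coords = [], []
    for line in lines[2 : 2 + n]:
        sym, x, y, z = line.split()[:4]
        zs.append(elements.Z_FROM_SYMBOL[sym.capitalize()])
        coords.append([float(x), float(y), float(z)])
    return MoleculeRecord(ident, np.array(zs), np.array(coords))


def write_xyz(mol: MoleculeRecord, path) -> None:
    lines = [str(mol.n_atoms), mol.identifier]
    for z, (x, y, zc) in zip(mol.atomic_numbers, mol.coords):
        lines.append(
            f"{elements.SYMBOLS[int(z)]} {x:.10f} {y:.10f} {zc:.10f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sdf(path) -> MoleculeRecord:
    """Minimal V2000 SDF reader (atom block only; bonds are recomputed)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    ident = lines[0].strip() or "sdf-molecule"
    counts = lines[3]
    n_atoms = int(counts[0:3])
    zs, coords = [], []
    for line in lines[4 : 4 + n_atoms]:
        x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
        sym = line[31:34].strip()
        zs.append(elements.Z_FROM_SYMBOL[sym.capitalize()])
        coords.append([x, y, z])
    return MoleculeRecord(ident, np.array(zs), np.array(coords))
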