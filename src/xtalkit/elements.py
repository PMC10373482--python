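"""Per-element constants used by featurization and the vdW contact score.

Values are bundled (Pauling electronegativities, covalent radii, Bondi-style
van der Waals radii) so the package runs fully offline.  Elements outside
the curated set fall back to period/group derived from Z and conservative
radius defaults; the runtime filters cap atomic number at 100 anyway.
"""

from __future__ import annotations

import numpy as np

MAX_Z = 100

SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
]

Z_FROM_SYMBOL = {s: z for z, s in enumerate(SYMBOLS) if z > 0}

_PERIOD_STARTS = [1, 3, 11, 19, 37, 55, 87]

# atomic masses (amu), rounded; enough for density/derived-feature work
_MASSES = {
    1: 1.008, 2: 4.003, 3: 6.94, 4: 9.012, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.95,
    19: 39.098, 20: 40.078, 26: 55.845, 29: 63.546, 30: 65.38,
    34: 78.971, 35: 79.904, 53: 126.904,
}

# Pauling electronegativities for the organic/organometallic mainstream
_ELECTRONEGATIVITY = {
    1: 2.20, 3: 0.98, 4: 1.57, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44,
    9: 3.98, 11: 0.93, 12: 1.31, 13: 1.61, 14: 1.90, 15: 2.19,
    16: 2.58, 17: 3.16, 19: 0.82, 20: 1.00, 26: 1.83, 29: 1.90,
    30: 1.65, 34: 2.55, 35: 2.96, 53: 2.66,
}

# covalent radii (Å), Cordero-style
_COVALENT_RADIUS = {
    1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57, 14: 1.11,
    15: 1.07, 16: 1.05, 17: 1.02, 26: 1.32, 29: 1.32, 30: 1.22,
    34: 1.20, 35: 1.20, 53: 1.39,
}

# van der Waals radii (Å), Bondi-style; single source of truth for the
# featurizer, the molecular-volume integrator, and the vdW score
_VDW_RADIUS = {
    1: 1.20, 2: 1.40, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 10: 1.54,
    14: 2.10, 15: 1.80, 16: 1.80, 17: 1.75, 18: 1.88, 26: 2.04,
    29: 1.96, 30: 2.01, 34: 1.90, 35: 1.85, 36: 2.02, 53: 1.98,
    54: 2.16,
}


def period(z: int) -> int:
    p = 0
    for start in _PERIOD_STARTS:
        if z >= start:
            p += 1
    return p


def group(z: int) -> int:
    """Nominal periodic-table group (1-18); lanthanides/actinides map to 3."""
    if z in (1,):
        return 1
    if z == 2:
        return 18
    offsets = {3: 1, 11: 1, 19: 1, 37: 1, 55: 1, 87: 1}
    for start, nxt in zip(_PERIOD_STARTS, _PERIOD_STARTS[1:] + [MAX_Z + 1]):
        if start <= z < nxt:
            pos = z - start + 1
            width = nxt - start
            if width <= 8:  # short periods: groups 1,2,13..18
                return pos if pos <= 2 else 10 + pos
            if width == 18:
                return pos
            # long periods with f-block: collapse f elements to group 3
            if pos <= 2:
                return pos
            if pos <= 16:
                return 3
            return pos - 14
    return 3


def mass(z: int) -> float:
    return _MASSES.get(z, 2.0 * z + 1.0)


def electronegativity(z: int) -> float:
    return _ELECTRONEGATIVITY.get(z, 1.8)


def covalent_radius(z: int) -> float:
    return _COVALENT_RADIUS.get(z, 1.4)


def vdw_radius(z: int) -> float:
    return _VDW_RADIUS.get(z, 2.0)


def vdw_radii_array(atomic_numbers) -> np.ndarray:
    zs = np.asarray(atomic_numbers, dtype=int)
    bad = zs[(zs < 1) | (zs > MAX_Z)]
    if bad.size:
        raise KeyError(f"no vdW radius for atomic number {int(bad[0])}")
    return np.array([vdw_radius(int(z)) for z in zs])
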