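"""Space-group general-position operators acting in fractional coordinates.

A bundled table covers the space groups that dominate molecular crystal
data sets (P1, P-1, P21, P21/c, P212121, C2/c, Pbca, Pna21); anything else
can be constructed directly from CIF-style operator strings such as
``"-x, y+1/2, -z+1/2"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SymOp", "SpaceGroup", "parse_op", "format_op", "get_space_group", "TABLE"]


@dataclass(frozen=True)
class SymOp:
    """Affine operator ``frac -> W @ frac + t``."""

    W: np.ndarray
    t: np.ndarray

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.W.T + self.t

    def __str__(self) -> str:
        return format_op(self)


_TERM = re.compile(r"([+-]?)\s*(\d+(?:\.\d+)?(?:/\d+)?|[xyz])")


def parse_op(s: str) -> SymOp:
    """Parse a CIF ``_symmetry_equiv_pos_as_xyz`` string."""
    parts = s.lower().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"malformed symmetry operator: {s!r}")
    W = np.zeros((3, 3))
    t = np.zeros(3)
    for row, expr in enumerate(parts):
        pos = 0
        matched = False
        for m in _TERM.finditer(expr):
            if m.start() != pos:
                raise ValueError(f"malformed symmetry operator: {s!r}")
            pos = m.end()
            matched = True
            sign = -1.0 if m.group(1) == "-" else 1.0
            tok = m.group(2)
            if tok in "xyz":
                W[row, "xyz".index(tok)] += sign
            elif "/" in tok:
                num, den = tok.split("/")
                t[row] += sign * float(num) / float(den)
            else:
                t[row] += sign * float(tok)
        if not matched or pos != len(expr):
            raise ValueError(f"malformed symmetry operator: {s!r}")
    return SymOp(W=W, t=t % 1.0)


_FRACTIONS = {0.5: "1/2", 0.25: "1/4", 0.75: "3/4", 1 / 3: "1/3", 2 / 3: "2/3"}


def format_op(op: SymOp) -> str:
    rows = []
    for i in range(3):
        terms = []
        for j, var in enumerate("xyz"):
            w = op.W[i, j]
            if abs(w) > 1e-9:
                sign = "-" if w < 0 else ("+" if terms else "")
                terms.append(f"{sign}{var}")
        tv = op.t[i] % 1.0
        if abs(tv) > 1e-9:
            for val, txt in _FRACTIONS.items():
                if abs(tv - val) < 1e-9:
                    terms.append(f"+{txt}")
                    break
            else:
                terms.append(f"+{tv:.6f}")
        rows.append("".join(terms) or "0")
    return ",".join(rows)


@dataclass(frozen=True)
class SpaceGroup:
    symbol: str
    ops: tuple = field(default_factory=tuple)

    @property
    def multiplicity(self) -> int:
        """Wyckoff multiplicity of the general position."""
        return len(self.ops)

    @classmethod
    def from_strings(cls, symbol: str, op_strings) -> "SpaceGroup":
        ops = tuple(parse_op(s) for s in op_strings)
        if not ops:
            raise ValueError("operator set is empty")
        return cls(symbol=symbol, ops=ops)


_TABLE_STRINGS = {
    "P1": ["x,y,z"],
    "P-1": ["x,y,z", "-x,-y,-z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "P21/c": ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"],
    "P212121": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
    ],
    "C2/c": [
        "x,y,z",
        "-x,y,-z+1/2",
        "-x,-y,-z",
        "x,-y,z+1/2",
        "x+1/2,y+1/2,z",
        "-x+1/2,y+1/2,-z+1/2",
        "-x+1/2,-y+1/2,-z",
        "x+1/2,-y+1/2,z+1/2",
    ],
    "Pbca": [
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "-x,y+1/2,-z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x,-y,-z",
        "x+1/2,y,-z+1/2",
        "x,-y+1/2,z+1/2",
        "-x+1/2,y+1/2,z",
    ],
    "Pna21": [
        "x,y,z",
        "-x,-y,z+1/2",
        "x+1/2,-y+1/2,z",
        "-x+1/2,y+1/2,z+1/2",
    ],
}

TABLE = {
    name: SpaceGroup.from_strings(name, strings)
    for name, strings in _TABLE_STRINGS.items()
}

_ALIASES = {
    "P 1": "P1",
    "P -1": "P-1",
    "P 21": "P21",
    "P 21/c": "P21/c",
    "P 21 21 21": "P212121",
    "C 2/c": "C2/c",
    "P b c a": "Pbca",
    "P n a 21": "Pna21",
}


def get_space_group(symbol: str) -> SpaceGroup:
    key = symbol.strip()
    key = _ALIASES.get(key, key)
    if key not in TABLE:
        raise KeyError(
            f"space group {symbol!r} not in bundled table; "
            "construct a SpaceGroup from operator strings instead"
        )
    return TABLE[key]
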