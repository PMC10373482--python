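"""Loss and score functions for density regression and crystal scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import elements
from .lattice import SupercellStructure

__all__ = [
    "ScoreRecord",
    "CorrelationTable",
    "smoothed_l1",
    "softmax_pair",
    "stretch_score",
    "vdw_score",
    "pearson_feature_correlations",
    "quantile_filter",
    "size_normalize",
    "VDW_CLIP",
    "STRETCH_SATURATION",
]

VDW_CLIP = 14.0
VDW_PAIR_RANGE = 6.0  # Å; intermolecular pairs considered by the vdW score
STRETCH_SATURATION = 16.0
_CORR_MIN_ABS_R = 0.05
_CORR_MIN_INCIDENCE = 0.05


@dataclass
class ScoreRecord:
    """Per-structure score bundle."""

    identifier: str
    logits: np.ndarray
    p_real: float
    stretched: float
    vdw: float
    size_normalized: float

    @staticmethod
    def header() -> str:
        return "identifier\tp_real\tstretched_score\tvdw_score\tnormalized_score"

    def to_row(self) -> str:
        return (
            f"{self.identifier}\t{self.p_real:.6f}\t{self.stretched:.6f}"
            f"\t{self.vdw:.6f}\t{self.size_normalized:.6f}"
        )


def smoothed_l1(x: float, y: float):
    """Piecewise loss: (x-y)^2/2 for |x-y| < 1, |x-y| - 0.5 beyond.

    Continuous at |x-y| = 1 (both branches give 0.5).  Vectorized.
    """
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    out = np.where(d < 1.0, 0.5 * d**2, d - 0.5)
    return float(out) if out.ndim == 0 else out


def softmax_pair(logits) -> float:
    """Overflow-safe p_real = exp(l1) / (exp(l1) + exp(l2))."""
    logits = np.asarray(logits, dtype=float)
    if logits.shape[-1] != 2:
        raise ValueError("expected a pair of logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    p = e[..., 0] / e.sum(axis=-1)
    return float(p) if p.ndim == 0 else p


def stretch_score(p):
    """Monotone readability transform of the softmax output.

    Implemented as ``log10(p / (1 - p))`` clipped to ±16: zero at
    p = 0.5, antisymmetric about it, and saturating at double precision
    extremes near ±16.
    """
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("softmax output must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        score = np.log10(arr) - np.log10(1.0 - arr)
    score = np.clip(score, -STRETCH_SATURATION, STRETCH_SATURATION)
    return float(score) if score.ndim == 0 else score


def stretch_from_logits(logits):
    """Stretched score straight from the logit pair.

    Analytically equal to ``stretch_score(softmax_pair(logits))`` —
    ``log10`` of the odds ratio is ``(l_real - l_fake)/ln(10)`` — but exact
    under logit exchange: swapping the two logits flips the sign bit-for-bit.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.shape[-1] != 2:
        raise ValueError("expected a pair of logits")
    score = (logits[..., 0] - logits[..., 1]) / np.log(10.0)
    score = np.clip(score, -STRETCH_SATURATION, STRETCH_SATURATION)
    return float(score) if score.ndim == 0 else score


def _intermolecular_pairs(supercell: SupercellStructure):
    """(canonical, image) atom pairs within the vdW pair range."""
    canon = supercell.canonical_indices
    images = np.flatnonzero(supercell.labels == 1)
    if len(images) == 0:
        return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.linalg.norm(
        supercell.coords[canon][:, None, :] - supercell.coords[images][None, :, :],
        axis=-1,
    )
    ci, ii = np.nonzero(d <= VDW_PAIR_RANGE)
    return d[ci, ii], canon[ci], images[ii]


def vdw_score(supercell: SupercellStructure, radii_table=None) -> float:
    """Geometric validity score over intermolecular vdW contacts.

    For every canonical-to-image atom pair within 6 Å with distance
    ``r_n`` below the vdW radius sum ``r_n_vdw``, the pair contributes
    ``-ln((r_n_vdw - r_n) / r_0)`` with ``r_0 = 1 Å``; the crystal score
    is the worst (minimum) contribution, clipped at 14.  With no
    overlapping pair the score is the clip value.  Strictly decreasing as
    any overlapping pair is pushed closer.
    """
    dist, canon_idx, image_idx = _intermolecular_pairs(supercell)
    if len(dist) == 0:
        return VDW_CLIP
    if radii_table is None:
        r_of = elements.vdw_radius
    else:
        def r_of(z, _table=radii_table):
            if z not in _table:
                raise KeyError(f"no vdW radius for atomic number {z}")
            return _table[z]
    z_all = supercell.atomic_numbers
    r_sum = np.array(
        [r_of(int(z_all[i])) + r_of(int(z_all[j])) for i, j in zip(canon_idx, image_idx)]
    )
    overlap = r_sum - dist
    overlapping = overlap > 0
    if not overlapping.any():
        return VDW_CLIP
    scores = -np.log(overlap[overlapping] / 1.0)
    return float(min(scores.min(), VDW_CLIP))


@dataclass
class CorrelationTable:
    """Pearson correlations of a value series against feature columns."""

    names: list
    r: np.ndarray
    incidence: np.ndarray
    retained: np.ndarray

    def to_text(self) -> str:
        lines = ["feature\tpearson_r\tincidence\tretained"]
        for name, r, inc, keep in zip(
            self.names, self.r, self.incidence, self.retained
        ):
            rtxt = "nan" if np.isnan(r) else f"{r:.4f}"
            lines.append(f"{name}\t{rtxt}\t{inc:.4f}\t{'yes' if keep else 'no'}")
        return "\n".join(lines)


def pearson_feature_correlations(values, features: dict) -> CorrelationTable:
    """Pearson r of ``values`` against each named feature column.

    A feature is retained only when ``|r| >= 0.05`` and it is non-zero in
    at least 5% of the rows; zero-variance features get ``r = nan`` and
    are never retained.
    """
    values = np.asarray(values, dtype=float)
    names, rs, incid, kept = [], [], [], []
    for name, col in features.items():
        col = np.asarray(col, dtype=float)
        if col.shape != values.shape:
            raise ValueError(f"feature {name!r} length mismatch")
        incidence = float((col != 0).mean())
        if col.std() == 0 or values.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(values, col)[0, 1])
        retained = (
            not np.isnan(r)
            and abs(r) >= _CORR_MIN_ABS_R
            and incidence >= _CORR_MIN_INCIDENCE
        )
        names.append(name)
        rs.append(r)
        incid.append(incidence)
        kept.append(retained)
    return CorrelationTable(
        names=names,
        r=np.array(rs),
        incidence=np.array(incid),
        retained=np.array(kept),
    )


def quantile_filter(test_scores, candidate_scores, q: float) -> float:
    """Fraction of candidates strictly below the empirical q-quantile
    (linear interpolation) of the test distribution."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    test_scores = np.asarray(test_scores, dtype=float)
    candidate_scores = np.asarray(candidate_scores, dtype=float)
    if len(test_scores) == 0 or len(candidate_scores) == 0:
        raise ValueError("score lists must be nonempty")
    threshold = np.quantile(test_scores, q)
    return float((candidate_scores < threshold).mean())


def size_normalize(score: float, n_atoms: int):
    """Score divided by the number of atoms per molecule."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return score / n_atoms
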