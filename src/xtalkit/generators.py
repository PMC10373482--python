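"""Synthetic ("fake") crystal generators.

Two sources of negative examples for discriminator training:

* a multivariate Gaussian over crystal parameters fitted to dataset
  statistics, sampled in a reduced-length space where cell lengths are
  divided by ``(Z * V_mol)^(1/3)`` so draws are invariant to molecule
  size and cell occupancy, and
* a controlled distortion of existing crystals: standardize the 12
  parameters by per-parameter dataset mean/std, add isotropic Gaussian
  noise of scale ``c_dis``, destandardize, and rebuild.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import MoleculeRecord, molecular_volume
from .lattice import CrystalParams
from .spacegroups import SpaceGroup

__all__ = [
    "ParamStats",
    "DistortionConfig",
    "reduce_lengths",
    "expand_lengths",
    "fit_param_gaussian",
    "sample_gaussian_crystals",
    "standardize_params",
    "destandardize_params",
    "distort_crystal",
]

_COV_REG = 1e-10


@dataclass
class ParamStats:
    """Mean/std/covariance of 12-parameter vectors in reduced-length space."""

    mean: np.ndarray
    std: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (12,) or self.std.shape != (12,):
            raise ValueError("mean and std must be 12-vectors")
        if self.cov.shape != (12, 12):
            raise ValueError("covariance must be 12x12")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if (self.std <= 0).any():
            raise ValueError("stds must be strictly positive")
        if np.linalg.eigvalsh(self.cov).min() < -1e-8:
            raise ValueError("covariance must be positive semidefinite")

    def to_text(self) -> str:
        lines = ["# crystal parameter statistics (reduced-length space)"]
        lines.append("mean\t" + "\t".join(f"{v:.10g}" for v in self.mean))
        lines.append("std\t" + "\t".join(f"{v:.10g}" for v in self.std))
        for row in self.cov:
            lines.append("cov\t" + "\t".join(f"{v:.10g}" for v in row))
        return "\n".join(lines)

    @classmethod
    def from_text(cls, text: str) -> "ParamStats":
        mean = std = None
        cov_rows = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            tag, *vals = line.split("\t")
            vals = np.array([float(v) for v in vals])
            if tag == "mean":
                mean = vals
            elif tag == "std":
                std = vals
            elif tag == "cov":
                cov_rows.append(vals)
        return cls(mean=mean, std=std, cov=np.stack(cov_rows))


@dataclass(frozen=True)
class DistortionConfig:
    c_dis: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.c_dis < 0:
            raise ValueError("c_dis must be non-negative")


def _length_scale(Z: int, v_mol: float) -> float:
    if Z < 1 or v_mol <= 0:
        raise ValueError("need Z >= 1 and V_mol > 0")
    return (Z * v_mol) ** (1.0 / 3.0)


def reduce_lengths(params: CrystalParams, Z: int, v_mol: float) -> np.ndarray:
    """12-vector with cell lengths divided by (Z*V_mol)^(1/3).

    This is the unique power law making the sampled cell volume scale as
    ``Z * V_mol`` — i.e. the packing coefficient distribution becomes
    independent of molecule size and cell occupancy.
    """
    vec = params.as_vector()
    vec[:3] = vec[:3] / _length_scale(Z, v_mol)
    return vec


def expand_lengths(vec: np.ndarray, Z: int, v_mol: float) -> np.ndarray:
    out = np.asarray(vec, dtype=float).copy()
    out[:3] = out[:3] * _length_scale(Z, v_mol)
    return out


def fit_param_gaussian(dataset) -> ParamStats:
    """Fit the 12-dimensional Gaussian over reduced parameter vectors.

    ``dataset`` is an iterable of ``(CrystalParams, Z, V_mol)`` triples.
    Degenerate covariances are ridge-regularized to stay usable.
    """
    rows = [reduce_lengths(p, Z, v) for p, Z, v in dataset]
    if not rows:
        raise ValueError("empty dataset")
    X = np.stack(rows)
    mean = X.mean(axis=0)
    if len(X) > 1:
        cov = np.cov(X, rowvar=False)
        std = X.std(axis=0, ddof=1)
    else:
        cov = np.zeros((12, 12))
        std = np.zeros(12)
    cov = cov + _COV_REG * np.eye(12)
    std = np.maximum(std, np.sqrt(_COV_REG))
    return ParamStats(mean=mean, std=std, cov=cov)


def _wrap_into_valid(vec: np.ndarray) -> np.ndarray:
    """Fold a raw 12-vector into the valid parameter domain.

    Lengths are reflected positive (floor 1 Å), angles reflected into
    (0, 180) and then pulled toward 90° until the cell volume is positive,
    fractional centroids wrapped to [0, 1).  Deterministic.
    """
    out = np.asarray(vec, dtype=float).copy()
    out[:3] = np.abs(out[:3])
    out[:3] = np.maximum(out[:3], 1.0)
    # reflect angles into (0, 180)
    ang = np.abs(out[3:6]) % 360.0
    ang = np.where(ang > 180.0, 360.0 - ang, ang)
    ang = np.clip(ang, 10.0, 170.0)
    for _ in range(60):
        ca, cb, cg = np.cos(np.radians(ang))
        if 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg > 1e-6:
            break
        ang = 90.0 + 0.5 * (ang - 90.0)  # shrink toward orthogonal
    out[3:6] = ang
    out[6:9] = out[6:9] % 1.0
    return out


def sample_gaussian_crystals(
    stats: ParamStats,
    conformer: MoleculeRecord,
    space_group: SpaceGroup,
    n: int,
    seed: int = 0,
) -> list[CrystalParams]:
    """Draw ``n`` parameter sets from the fitted Gaussian (reduced space),
    expand them for this conformer/space group, and fold each into the
    valid domain.  Deterministic under ``seed``; never rejects a draw."""
    rng = np.random.default_rng(seed)
    v_mol = conformer.mol_volume
    if v_mol is None:
        v_mol = molecular_volume(conformer)
    Z = space_group.multiplicity
    draws = rng.multivariate_normal(stats.mean, stats.cov, size=n, method="cholesky")
    out = []
    for d in draws:
        vec = _wrap_into_valid(expand_lengths(d, Z, v_mol))
        out.append(CrystalParams.from_vector(vec, space_group))
    return out


def standardize_params(vec: np.ndarray, stats: ParamStats) -> np.ndarray:
    return (np.asarray(vec, dtype=float) - stats.mean) / stats.std


def destandardize_params(vec: np.ndarray, stats: ParamStats) -> np.ndarray:
    return np.asarray(vec, dtype=float) * stats.std + stats.mean


def distort_crystal(
    params: CrystalParams,
    stats: ParamStats,
    config: DistortionConfig,
    Z: int | None = None,
    v_mol: float = 1.0,
) -> CrystalParams:
    """Perturb a crystal: ``destandardize(standardize(C) + c_dis * z)``.

    Standardization is per-parameter (diagonal) in reduced-length space;
    ``z ~ N(0, I_12)`` drawn deterministically from ``config.seed``.
    ``c_dis = 0`` returns the input parameters exactly.
    """
    if Z is None:
        Z = params.space_group.multiplicity
    reduced = reduce_lengths(params, Z, v_mol)
    z = np.random.default_rng(config.seed).standard_normal(12)
    standardized = standardize_params(reduced, stats)
    if config.c_dis == 0.0:
        noisy = standardized
    else:
        noisy = standardized + config.c_dis * z
    vec = expand_lengths(destandardize_params(noisy, stats), Z, v_mol)
    if config.c_dis == 0.0:
        return CrystalParams.from_vector(params.as_vector(), params.space_group)
    return CrystalParams.from_vector(_wrap_into_valid(vec), params.space_group)
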