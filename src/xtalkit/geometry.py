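"""Rigid-body geometry: inertial frames, rotation encodings, cell algebra.

Functions that sit on the generative path (``rotvec_to_matrix``,
``cell_matrix``, ``inv3``, ``frac_to_cart``) are written against
:mod:`xtalkit.autodiff` dispatch helpers and therefore stay differentiable
when handed :class:`~xtalkit.autodiff.Tensor` inputs.  Extraction-side
helpers (``standardize_orientation``, ``matrix_to_rotvec``) are plain
NumPy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from . import autodiff as ad

_SIGN_TOL = 1e-8


def centroid(coords) -> np.ndarray:
    """Center of geometry (unweighted atom mean)."""
    return np.asarray(coords, dtype=float).mean(axis=0)


def inertia_tensor(coords: np.ndarray) -> np.ndarray:
    """Unit-mass inertia tensor about the center of geometry."""
    x = np.asarray(coords, dtype=float)
    x = x - x.mean(axis=0)
    r2 = (x**2).sum(axis=1)
    return np.eye(3) * r2.sum() - x.T @ x


def r_max(coords: np.ndarray) -> float:
    """Maximum centroid-to-atom distance."""
    x = np.asarray(coords, dtype=float)
    x = x - x.mean(axis=0)
    return float(np.linalg.norm(x, axis=1).max())


def standardize_orientation(coords: np.ndarray):
    """Rotate a conformer into its standardized inertial frame.

    The principal inertial axes are aligned with the Cartesian axes
    (smallest moment along x).  Axis directions are fixed to have positive
    overlap with the centroid-to-farthest-atom vector; an axis with
    (near-)zero overlap is set by the right-hand rule, and a residual
    left-handed frame is mapped onto (x, y, -z).

    Returns ``(rotation, standardized)`` where ``rotation`` is a proper
    rotation matrix with ``standardized @ rotation.T == coords - centroid``.
    """
    x = np.asarray(coords, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 atoms for an orientation frame")
    c = x.mean(axis=0)
    xc = x - c

    # collinearity check via the rank of the centered coordinates
    svals = np.linalg.svd(xc, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise ValueError("all atoms are collinear; orientation frame undefined")

    moments, vecs = np.linalg.eigh(inertia_tensor(xc))
    axes = vecs.T.copy()  # rows, ordered by ascending moment

    norms = np.linalg.norm(xc, axis=1)
    far = int(np.argmax(np.round(norms / 1e-9)))  # stable under fp jitter
    u = xc[far]

    overlaps = axes @ u
    ambiguous = np.abs(overlaps) <= _SIGN_TOL * max(np.linalg.norm(u), 1.0)
    for i in range(3):
        if not ambiguous[i] and overlaps[i] < 0:
            axes[i] = -axes[i]

    n_amb = int(ambiguous.sum())
    if n_amb == 1:
        # right-hand rule: ambiguous axis completes a right-handed frame
        i = int(np.flatnonzero(ambiguous)[0])
        j, k = (i + 1) % 3, (i + 2) % 3
        axes[i] = np.cross(axes[j], axes[k])
    elif n_amb >= 2:
        # degenerate top: break ties lexicographically on axis components
        for i in np.flatnonzero(ambiguous):
            lead = axes[i][np.flatnonzero(np.abs(axes[i]) > 1e-12)[0]]
            if lead < 0:
                axes[i] = -axes[i]

    flip = np.eye(3)
    if np.linalg.det(axes) < 0:
        flip[2, 2] = -1.0  # left-handed frame -> align with (x, y, -z)

    standardized = xc @ axes.T @ flip
    rotation = axes.T @ flip  # proper: det(axes.T) * det(flip) = +1
    return rotation, standardized


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()


def rotvec_to_matrix(v):
    """Rodrigues formula; differentiable through autodiff tensors."""
    vx, vy, vz = v[0], v[1], v[2]
    theta2 = vx * vx + vy * vy + vz * vz + 1e-300
    theta = ad.sqrt(theta2)
    a = ad.sin(theta) / theta
    b = (1.0 - ad.cos(theta)) / theta2
    # R = I + a K + b K^2 with K = skew(v)
    r00 = 1.0 + b * (-(vy * vy) - vz * vz)
    r01 = a * (-vz) + b * (vx * vy)
    r02 = a * vy + b * (vx * vz)
    r10 = a * vz + b * (vx * vy)
    r11 = 1.0 + b * (-(vx * vx) - vz * vz)
    r12 = a * (-vx) + b * (vy * vz)
    r20 = a * (-vy) + b * (vx * vz)
    r21 = a * vx + b * (vy * vz)
    r22 = 1.0 + b * (-(vx * vx) - vy * vy)
    return ad.stack(
        [
            ad.stack([r00, r01, r02]),
            ad.stack([r10, r11, r12]),
            ad.stack([r20, r21, r22]),
        ]
    )


def triclinic_volume(a, b, c, alpha, beta, gamma) -> float:
    """Closed-form cell volume; angles in degrees."""
    ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
    arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
    if arg <= 0:
        raise ValueError("cell angles give non-positive volume")
    return float(a * b * c * np.sqrt(arg))


def cell_matrix(a, b, c, alpha, beta, gamma):
    """3x3 lattice matrix, rows = cell vectors (Å); angles in degrees.

    Convention: ``v1`` along x, ``v2`` in the xy plane.  Differentiable.
    """
    deg = np.pi / 180.0
    ca, cb, cg = ad.cos(alpha * deg), ad.cos(beta * deg), ad.cos(gamma * deg)
    sg = ad.sin(gamma * deg)
    # validate on detached values
    arg = 1.0 - _val(ca) ** 2 - _val(cb) ** 2 - _val(cg) ** 2 + 2.0 * _val(ca) * _val(cb) * _val(cg)
    if arg <= 0 or _val(sg) <= 0:
        raise ValueError("cell parameters give non-positive volume")
    zero = a * 0.0
    cy = (ca - cb * cg) / sg
    cz2 = 1.0 - cb * cb - cy * cy
    cz = ad.sqrt(cz2)
    v1 = ad.stack([a, zero, zero])
    v2 = ad.stack([b * cg, b * sg, zero])
    v3 = ad.stack([c * cb, c * cy, c * cz])
    return ad.stack([v1, v2, v3])


def _val(x):
    return x.data if ad.is_tensor(x) else np.asarray(x, dtype=float)


def _cross(u, v):
    return ad.stack(
        [
            u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0],
        ]
    )


def inv3(M):
    """Inverse of a 3x3 matrix via the adjugate; differentiable."""
    v1, v2, v3 = M[0], M[1], M[2]
    c23 = _cross(v2, v3)
    c31 = _cross(v3, v1)
    c12 = _cross(v1, v2)
    det = ad.sum(v1 * c23)
    if abs(float(_val(det))) < 1e-12:
        raise ValueError("singular cell matrix")
    # columns of the inverse are the reciprocal vectors
    return ad.transpose(ad.stack([c23, c31, c12])) * (1.0 / det)


def frac_to_cart(frac, M):
    return ad.matmul(frac, M)


def cart_to_frac(cart, M):
    return ad.matmul(cart, inv3(M))


def sorted_distance_multiset(coords: np.ndarray) -> np.ndarray:
    """Sorted intramolecular pair distances (congruence fingerprint)."""
    x = np.asarray(coords, dtype=float)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return np.sort(d[iu])
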