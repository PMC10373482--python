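"""Molecular and molecular-crystal graph construction.

Nodes are atoms; directed edges connect atoms within the cutoff radius
``r_c`` and carry a zeroth-order spherical Bessel radial embedding.  For
crystals, intramolecular edges live inside the canonical conformer and
intermolecular edges run strictly outside-in, from symmetry-image atoms
(label 1) to canonical atoms (label 0).  Periodicity is maintained by
overwriting image node states from their canonical counterparts after
every node update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import autodiff as ad
from .chem_io import MoleculeRecord
from .lattice import SupercellStructure

__all__ = [
    "GraphConfig",
    "CrystalGraph",
    "build_molecule_graph",
    "build_crystal_graph",
    "radial_embedding",
    "periodic_overwrite",
]

INTRA, INTER = 0, 1

_BRUTE_FORCE_LIMIT = 500  # below this, skip the KD-tree


@dataclass(frozen=True)
class GraphConfig:
    """Graph-construction constants."""

    r_c: float = 6.0
    n_basis: int = 32
    inter_edge_mode: str = "final_layer_only"  # or "all_layers"
    N: int = 3

    def __post_init__(self):
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if self.inter_edge_mode not in ("final_layer_only", "all_layers"):
            raise ValueError("unknown inter_edge_mode")


@dataclass
class CrystalGraph:
    """Directed radial graph over atoms (labels 0 and 1 only)."""

    coords: np.ndarray
    labels: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_dist: np.ndarray
    edge_type: np.ndarray  # INTRA or INTER
    embeddings: np.ndarray  # (n_edges, n_basis)
    canonical_indices: np.ndarray
    config: GraphConfig
    symmetry_map: np.ndarray | None = None
    atomic_numbers: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def edges_of_type(self, kind: int):
        mask = self.edge_type == kind
        return self.edge_src[mask], self.edge_dst[mask], mask

    def to_tables(self):
        """Edge-list and node tables as tab-separated text (debug dump)."""
        node_lines = ["index\tlabel\tx\ty\tz"]
        for i, (lab, xyz) in enumerate(zip(self.labels, self.coords)):
            node_lines.append(
                f"{i}\t{lab}\t{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}"
            )
        edge_lines = ["source\ttarget\tdistance\ttype"]
        for s, d, r, t in zip(
            self.edge_src, self.edge_dst, self.edge_dist, self.edge_type
        ):
            kind = "intra" if t == INTRA else "inter"
            edge_lines.append(f"{s}\t{d}\t{r:.6f}\t{kind}")
        return "\n".join(node_lines), "\n".join(edge_lines)


def radial_embedding(d, config: GraphConfig):
    """Zeroth-order spherical Bessel basis of DimeNet form (no envelope).

    Component ``n`` is ``sqrt(2/r_c) * sin(n pi d / r_c) / d`` for
    ``n = 1..n_basis``; every component vanishes at ``d = r_c``.
    Accepts a scalar, an array of distances, or an autodiff tensor.
    """
    vals = d.data if ad.is_tensor(d) else np.asarray(d, dtype=float)
    if (vals <= 0).any() if vals.ndim else vals <= 0:
        raise ValueError("distance must be positive")
    if (vals > config.r_c + 1e-12).any() if vals.ndim else vals > config.r_c + 1e-12:
        raise ValueError("distance exceeds cutoff; edge should not exist")
    n = np.arange(1, config.n_basis + 1)
    scale = np.sqrt(2.0 / config.r_c)
    if ad.is_tensor(d):
        dd = ad.reshape(d, (-1, 1)) if d.ndim else ad.reshape(d, (1, 1))
        arg = ad.mul(dd, n * np.pi / config.r_c)
        out = ad.mul(ad.mul(ad.sin(arg), scale), ad.astensor(1.0) / dd)
        return out
    dd = np.atleast_1d(vals)[:, None]
    out = scale * np.sin(n * np.pi * dd / config.r_c) / dd
    return out[0] if np.isscalar(d) or np.ndim(d) == 0 else out


def _radius_edges(coords_src, coords_dst, r_c, src_index, dst_index):
    """All (src, dst) pairs with 0 < distance <= r_c; exact by contract."""
    n_src, n_dst = len(src_index), len(dst_index)
    if n_src * n_dst <= _BRUTE_FORCE_LIMIT**2:
        d = np.linalg.norm(
            coords_src[:, None, :] - coords_dst[None, :, :], axis=-1
        )
        si, di = np.nonzero((d <= r_c) & (d > 0))
        return src_index[si], dst_index[di], d[si, di]
    tree = cKDTree(coords_dst)
    src_list, dst_list, dist_list = [], [], []
    for k, hits in enumerate(tree.query_ball_point(coords_src, r_c)):
        for h in hits:
            dist = np.linalg.norm(coords_src[k] - coords_dst[h])
            if dist > 0:
                src_list.append(src_index[k])
                dst_list.append(dst_index[h])
                dist_list.append(dist)
    return (
        np.asarray(src_list, dtype=int),
        np.asarray(dst_list, dtype=int),
        np.asarray(dist_list, dtype=float),
    )


def build_molecule_graph(mol: MoleculeRecord, config: GraphConfig = GraphConfig()) -> CrystalGraph:
    """Radial graph over a single conformer: directed edges both ways
    between every atom pair within ``r_c``; no self-edges."""
    if mol.n_atoms < 1:
        raise ValueError("empty molecule")
    idx = np.arange(mol.n_atoms)
    src, dst, dist = _radius_edges(mol.coords, mol.coords, config.r_c, idx, idx)
    emb = (
        radial_embedding(dist, config)
        if len(dist)
        else np.zeros((0, config.n_basis))
    )
    return CrystalGraph(
        coords=mol.coords,
        labels=np.zeros(mol.n_atoms, dtype=int),
        edge_src=src,
        edge_dst=dst,
        edge_dist=dist,
        edge_type=np.full(len(src), INTRA, dtype=int),
        embeddings=emb,
        canonical_indices=idx,
        config=config,
        atomic_numbers=mol.atomic_numbers,
    )


def build_crystal_graph(
    supercell: SupercellStructure, config: GraphConfig = GraphConfig()
) -> CrystalGraph:
    """Crystal graph: intra edges among label-0 atoms, inter edges strictly
    from label-1 sources to label-0 targets, all within ``r_c``."""
    lab = supercell.labels
    canon = np.flatnonzero(lab == 0)
    if len(canon) == 0:
        raise ValueError("supercell has no canonical (label-0) atoms")
    images = np.flatnonzero(lab == 1)

    c_src, c_dst, c_dist = _radius_edges(
        supercell.coords[canon], supercell.coords[canon], config.r_c, canon, canon
    )
    i_src, i_dst, i_dist = _radius_edges(
        supercell.coords[images], supercell.coords[canon], config.r_c, images, canon
    )

    src = np.concatenate([c_src, i_src])
    dst = np.concatenate([c_dst, i_dst])
    dist = np.concatenate([c_dist, i_dist])
    etype = np.concatenate(
        [np.full(len(c_src), INTRA), np.full(len(i_src), INTER)]
    ).astype(int)
    emb = (
        radial_embedding(dist, config)
        if len(dist)
        else np.zeros((0, config.n_basis))
    )
    return CrystalGraph(
        coords=supercell.coords,
        labels=lab,
        edge_src=src,
        edge_dst=dst,
        edge_dist=dist,
        edge_type=etype,
        embeddings=emb,
        canonical_indices=canon,
        config=config,
        symmetry_map=supercell.symmetry_map,
        atomic_numbers=supercell.atomic_numbers,
    )


def periodic_overwrite(node_states, symmetry_map):
    """Copy canonical node states onto all their symmetry images.

    ``symmetry_map[i]`` is the canonical (label-0) atom index for node
    ``i``; after the overwrite every image state equals its canonical
    state bit-for-bit.  Idempotent.  Works on arrays and tensors.
    """
    symmetry_map = np.asarray(symmetry_map, dtype=np.intp)
    n = node_states.shape[0]
    if symmetry_map.shape[0] != n:
        raise ValueError("symmetry map does not cover all nodes")
    if (symmetry_map < 0).any() or (symmetry_map >= n).any():
        raise ValueError("symmetry map references missing nodes")
    return ad.gather(node_states, symmetry_map)
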