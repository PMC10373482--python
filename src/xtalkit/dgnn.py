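"""Graph neural networks for molecular crystals.

Two instantiations of one architecture: a density model predicting the
crystal packing coefficient from a single conformer, and a discriminator
scoring whole crystal structures as real vs. fake.  Node states are
initialized from atom + molecule features (with the atomic number swapped
for a learned embedding), refined by bottlenecked message-passing layers
conditioned on Bessel radial edge embeddings, pooled by a four-way global
aggregation (max / sum / mean / self-attention), and read out through an
MLP with ``n_gc + 1`` layers.

Everything runs on :mod:`xtalkit.autodiff`, so outputs are differentiable
with respect to the weights and — through the differentiable cell
builder — the 12 crystal parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import Tensor
from .chem_io import CrystalEntry, MoleculeRecord
from .crystal_graph import (
    INTER,
    INTRA,
    CrystalGraph,
    GraphConfig,
    build_crystal_graph,
    build_molecule_graph,
    radial_embedding,
)
from .lattice import (
    CrystalParams,
    _place_molecule,
    build_supercell,
    build_unit_cell,
    select_canonical_conformer,
    supercell_encloses_check,
)

__all__ = [
    "ModelConfig",
    "Model",
    "fc_layer",
    "forward_density",
    "forward_discriminator",
    "discriminator_output_from_params",
    "choose_supercell_size",
]

MAX_EMBED_Z = 100

# fixed input scalings keeping raw features O(1) for the first FC layer
_ATOM_SCALE = np.array([7.0, 18.0, 4.0, 2.0, 2.0, 1.0, 1.0])
_MOL_SCALE = np.array(
    [50.0, 500.0, 500.0, 1e4, 1e4, 1e4, 5.0, 5.0, 5.0, 8.0, 8.0, 1.0, 10.0, 1.0, 1.0, 1.0]
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture constants, validated in one place."""

    n_gc: int = 4
    node_width: int = 256
    message_width: int = 128
    edge_embed_width: int = 128
    n_basis: int = 32
    dropout: float = 0.1
    atomic_embedding_dim: int = 32
    head: str = "density"  # or "discriminator"
    inter_edge_mode: str = "final_layer_only"
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_gc", "node_width", "message_width", "edge_embed_width",
                     "n_basis", "atomic_embedding_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.head not in ("density", "discriminator"):
            raise ValueError("head must be 'density' or 'discriminator'")
        if self.inter_edge_mode not in ("final_layer_only", "all_layers"):
            raise ValueError("unknown inter_edge_mode")

    @property
    def out_dim(self) -> int:
        return 1 if self.head == "density" else 2


def fc_layer(x, W, b, slope: float = 0.01):
    """sigma(W x + b) with leaky-ReLU sigma; works on arrays and tensors."""
    Wd = W.data if ad.is_tensor(W) else np.asarray(W)
    xd = x.data if ad.is_tensor(x) else np.asarray(x)
    if xd.shape[-1] != Wd.shape[0]:
        raise ValueError(
            f"width mismatch: input {xd.shape[-1]} vs weight {Wd.shape[0]}"
        )
    return ad.leaky_relu(ad.add(ad.matmul(x, W), b), slope)


def _glorot(rng, n_in, n_out):
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


def _init_fc(params, rng, name, n_in, n_out):
    params[f"{name}.W"] = _glorot(rng, n_in, n_out)
    params[f"{name}.b"] = np.zeros(n_out)


def _init_conv(params, rng, prefix, cfg: ModelConfig):
    _init_fc(params, rng, f"{prefix}.n2m", cfg.node_width, cfg.message_width)
    _init_fc(params, rng, f"{prefix}.e2m", cfg.n_basis, cfg.edge_embed_width)
    _init_fc(params, rng, f"{prefix}.fc1",
             2 * cfg.message_width + cfg.edge_embed_width, cfg.message_width)
    _init_fc(params, rng, f"{prefix}.fc2", cfg.message_width, cfg.node_width)
    params[f"{prefix}.ln.g"] = np.ones(cfg.node_width)
    params[f"{prefix}.ln.b"] = np.zeros(cfg.node_width)


def init_params(cfg: ModelConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    params: dict[str, np.ndarray] = {}
    params["embed"] = rng.normal(
        0.0, 1.0 / np.sqrt(cfg.atomic_embedding_dim),
        size=(MAX_EMBED_Z + 1, cfg.atomic_embedding_dim),
    )
    _init_fc(params, rng, "node_init",
             cfg.atomic_embedding_dim + 7 + 16, cfg.node_width)
    for t in range(cfg.n_gc):
        _init_conv(params, rng, f"conv{t}", cfg)
    if cfg.head == "discriminator" and cfg.inter_edge_mode == "final_layer_only":
        _init_conv(params, rng, "conv_inter", cfg)
    params["agg.query"] = rng.normal(0.0, 1.0 / np.sqrt(cfg.node_width),
                                     size=cfg.node_width)
    _init_fc(params, rng, "agg.fc", 4 * cfg.node_width, cfg.node_width)
    dims = [cfg.node_width + 16] + [cfg.node_width] * cfg.n_gc + [cfg.out_dim]
    for i, (n_in, n_out) in enumerate(zip(dims[:-1], dims[1:])):
        _init_fc(params, rng, f"head{i}", n_in, n_out)
        if i < cfg.n_gc:  # hidden layers carry layer norm
            params[f"head{i}.ln.g"] = np.ones(n_out)
            params[f"head{i}.ln.b"] = np.zeros(n_out)
    return params


# ----------------------------------------------------------------------
# forward-pass building blocks (functional; `tp` maps name -> Tensor)
# ----------------------------------------------------------------------

def _dropout(x, p, train, rng):
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape if not ad.is_tensor(x) else x.data.shape) >= p)
    return ad.mul(x, mask / (1.0 - p))


def init_node_states(tp, atom_features, mol_features, cfg: ModelConfig, slope=None):
    """Initial 256-wide node states.

    The atomic number (first atom-feature column) is replaced by a learned
    embedding and reconcatenated with the remaining atom features and the
    (broadcast) molecule features before the first FC layer.
    """
    atom_features = np.asarray(atom_features, dtype=float)
    z = atom_features[:, 0].astype(int)
    if (z < 1).any() or (z > MAX_EMBED_Z).any():
        raise ValueError("atomic number outside embedding table (1..100)")
    emb = ad.gather(tp["embed"], z)
    rest = atom_features[:, 1:] / _ATOM_SCALE
    molf = np.broadcast_to(
        np.asarray(mol_features, dtype=float) / _MOL_SCALE,
        (len(z), 16),
    ) if np.ndim(mol_features) == 1 else np.asarray(mol_features) / _MOL_SCALE
    x = ad.concat([emb, Tensor(rest), Tensor(np.ascontiguousarray(molf))], axis=1)
    return fc_layer(x, tp["node_init.W"], tp["node_init.b"],
                    slope if slope is not None else cfg.leaky_slope)


def graph_convolution(
    tp, prefix, states, embeddings, edge_src, edge_dst, cfg: ModelConfig,
    train=False, rng=None, residual=True, target_subset=None,
):
    """One message-passing layer.

    Per edge (j -> i): bottleneck both endpoint states to the message
    width, boost the radial embedding likewise, concatenate
    ``(F_i | F_j | E_ij)`` through FC1, sum messages over sources j, pass
    through FC2 back to the node width, add the residual, then layer-norm
    and dropout.  With ``residual=False`` the layer output replaces the
    state (final intermolecular convolution).  ``target_subset`` restricts
    which nodes are updated; others pass through unchanged.
    """
    n_nodes = states.data.shape[0] if ad.is_tensor(states) else states.shape[0]
    edge_src = np.asarray(edge_src, dtype=np.intp)
    edge_dst = np.asarray(edge_dst, dtype=np.intp)
    if len(edge_src) and (edge_src.max() >= n_nodes or edge_dst.max() >= n_nodes):
        raise IndexError("edge references a missing node")
    slope = cfg.leaky_slope
    F = fc_layer(states, tp[f"{prefix}.n2m.W"], tp[f"{prefix}.n2m.b"], slope)
    if len(edge_src):
        E = fc_layer(embeddings, tp[f"{prefix}.e2m.W"], tp[f"{prefix}.e2m.b"], slope)
        cat = ad.concat([ad.gather(F, edge_dst), ad.gather(F, edge_src), E], axis=1)
        msg = fc_layer(cat, tp[f"{prefix}.fc1.W"], tp[f"{prefix}.fc1.b"], slope)
        summed = ad.segment_sum(msg, edge_dst, n_nodes)
    else:  # empty-neighborhood convention: zero message sum
        summed = Tensor(np.zeros((n_nodes, cfg.message_width)))
    update = fc_layer(summed, tp[f"{prefix}.fc2.W"], tp[f"{prefix}.fc2.b"], slope)
    out = ad.add(states, update) if residual else update
    out = ad.layer_norm(out, tp[f"{prefix}.ln.g"], tp[f"{prefix}.ln.b"])
    out = _dropout(out, cfg.dropout, train, rng)
    if target_subset is not None:
        updated = np.zeros((n_nodes, 1))
        updated[np.asarray(target_subset, dtype=np.intp)] = 1.0
        out = ad.add(ad.mul(out, updated), ad.mul(states, 1.0 - updated))
    return out


def final_intermolecular_convolution(tp, states, graph: CrystalGraph,
                                     cfg: ModelConfig, train=False, rng=None):
    """Replace canonical node states by a non-residual convolution whose
    message sources run only over symmetry-image atoms (inter edges).

    Returns ``(states, had_inter_edges)``; with no inter edges the update
    follows the empty-sum convention and the flag is False.
    """
    src, dst, _ = graph.edges_of_type(INTER)
    emb = graph.embeddings[graph.edge_type == INTER]
    out = graph_convolution(
        tp, "conv_inter", states, emb, src, dst, cfg,
        train=train, rng=rng, residual=False,
        target_subset=graph.canonical_indices,
    )
    return out, bool(len(src))


def global_aggregate(tp, states, cfg: ModelConfig, segment_ids=None, n_graphs=1):
    """FC(max | sum | mean | self-attention) pooled over each node set."""
    n_nodes = states.data.shape[0] if ad.is_tensor(states) else states.shape[0]
    if n_nodes == 0:
        raise ValueError("cannot aggregate an empty node set")
    if segment_ids is None:
        segment_ids = np.zeros(n_nodes, dtype=np.intp)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    counts = np.bincount(segment_ids, minlength=n_graphs).astype(float)
    if (counts == 0).any():
        raise ValueError("cannot aggregate an empty node set")

    s_sum = ad.segment_sum(states, segment_ids, n_graphs)
    s_mean = ad.mul(s_sum, (1.0 / counts)[:, None])
    s_max = ad.segment_max(states, segment_ids, n_graphs)

    # single-head dot-product attention with a learned query
    scores = ad.matmul(states, tp["agg.query"]) * (1.0 / np.sqrt(cfg.node_width))
    sd = scores.data if ad.is_tensor(scores) else scores
    smax = np.full(n_graphs, -np.inf)
    np.maximum.at(smax, segment_ids, sd)
    e = ad.exp(ad.add(scores, -smax[segment_ids]))  # shift is detached
    denom = ad.segment_sum(e, segment_ids, n_graphs)
    w = ad.mul(e, ad.gather(ad.astensor(denom) if ad.is_tensor(e) else denom,
                            segment_ids) ** -1.0)
    s_att = ad.segment_sum(ad.mul(states, ad.reshape(w, (-1, 1))),
                           segment_ids, n_graphs)

    cat = ad.concat([s_max, s_sum, s_mean, s_att], axis=1)
    return fc_layer(cat, tp["agg.fc.W"], tp["agg.fc.b"], cfg.leaky_slope)


def output_head(tp, graph_vec, mol_features, cfg: ModelConfig,
                train=False, rng=None):
    """MLP with ``n_gc + 1`` layers over (graph vector | molecule features)."""
    molf = np.atleast_2d(np.asarray(mol_features, dtype=float)) / _MOL_SCALE
    x = ad.concat([graph_vec, Tensor(molf)], axis=1)
    n_layers = cfg.n_gc + 1
    for i in range(n_layers):
        last = i == n_layers - 1
        if last:
            x = ad.add(ad.matmul(x, tp[f"head{i}.W"]), tp[f"head{i}.b"])
        else:
            x = fc_layer(x, tp[f"head{i}.W"], tp[f"head{i}.b"], cfg.leaky_slope)
            x = ad.layer_norm(x, tp[f"head{i}.ln.g"], tp[f"head{i}.ln.b"])
            x = _dropout(x, cfg.dropout, train, rng)
    return x


# ----------------------------------------------------------------------
# the model object
# ----------------------------------------------------------------------

class Model:
    """Parameter container plus forward passes for one task head."""

    def __init__(self, config: ModelConfig, graph_config: GraphConfig | None = None):
        if graph_config is None:
            graph_config = GraphConfig(n_basis=config.n_basis)
        if graph_config.n_basis != config.n_basis:
            raise ValueError("model and graph basis sizes disagree")
        self.config = config
        self.graph_config = graph_config
        self.params = init_params(config)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": asdict(self.config),
                "graph_config": asdict(self.graph_config)}
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "Model":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        model = cls(ModelConfig(**meta["config"]),
                    GraphConfig(**meta["graph_config"]))
        for k in model.params:
            model.params[k] = archive[k]
        return model

    # -- tape helpers ---------------------------------------------------
    def bind(self) -> dict:
        """Fresh Tensor bindings of the weights for one forward/backward."""
        return {k: Tensor(v) for k, v in self.params.items()}

    # -- density --------------------------------------------------------
    def density_forward_batch(self, graphs, mol_features_list,
                              train=False, rng=None, tp=None):
        """Batched conformer forward; returns an (n_graphs, 1) tensor."""
        if tp is None:
            tp = self.bind()
        cfg = self.config
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        atomf = np.concatenate([g_atom_features(g) for g in graphs])
        segids = np.concatenate(
            [np.full(g.n_nodes, i) for i, g in enumerate(graphs)]
        )
        molf_nodes = np.concatenate(
            [np.broadcast_to(np.asarray(m, dtype=float), (g.n_nodes, 16))
             for g, m in zip(graphs, mol_features_list)]
        )
        src = np.concatenate(
            [g.edge_src + offsets[i] for i, g in enumerate(graphs)]
        ) if graphs else np.zeros(0, dtype=int)
        dst = np.concatenate(
            [g.edge_dst + offsets[i] for i, g in enumerate(graphs)]
        ) if graphs else np.zeros(0, dtype=int)
        emb = np.concatenate([g.embeddings for g in graphs]) if graphs else None

        states = init_node_states(tp, atomf, molf_nodes, cfg)
        for t in range(cfg.n_gc):
            states = graph_convolution(tp, f"conv{t}", states, emb, src, dst,
                                       cfg, train=train, rng=rng)
        g_vec = global_aggregate(tp, states, cfg, segids, len(graphs))
        molf = np.stack([np.asarray(m, dtype=float) for m in mol_features_list])
        return output_head(tp, g_vec, molf, cfg, train=train, rng=rng), tp

    def density_forward(self, mol: MoleculeRecord):
        """Packing-coefficient estimate for a single featurized conformer."""
        if self.config.head != "density":
            raise ValueError("model head is not 'density'")
        graph = build_molecule_graph(mol, self.graph_config)
        attach_atom_features(graph, mol)
        out, _ = self.density_forward_batch([graph], [mol.mol_features])
        return float(out.data[0, 0])

    # -- discriminator --------------------------------------------------
    def discriminator_forward_graph(self, graph: CrystalGraph, mol_features,
                                    train=False, rng=None, tp=None,
                                    embeddings_override=None):
        """Forward pass on a built crystal graph; returns (1, 2) logits."""
        if tp is None:
            tp = self.bind()
        cfg = self.config
        emb_all = (embeddings_override if embeddings_override is not None
                   else graph.embeddings)
        intra_mask = graph.edge_type == INTRA
        inter_mask = graph.edge_type == INTER
        emb_intra = _mask_rows(emb_all, intra_mask)
        emb_inter = _mask_rows(emb_all, inter_mask)
        src_a, dst_a = graph.edge_src[intra_mask], graph.edge_dst[intra_mask]
        src_e, dst_e = graph.edge_src[inter_mask], graph.edge_dst[inter_mask]

        atomf = g_atom_features(graph)
        molf_nodes = np.broadcast_to(
            np.asarray(mol_features, dtype=float), (graph.n_nodes, 16)
        )
        states = init_node_states(tp, atomf, molf_nodes, cfg)
        states = periodic_sync(states, graph)

        if cfg.inter_edge_mode == "final_layer_only":
            for t in range(cfg.n_gc):
                states = graph_convolution(
                    tp, f"conv{t}", states, emb_intra, src_a, dst_a, cfg,
                    train=train, rng=rng,
                )
                states = periodic_sync(states, graph)
            states = graph_convolution(
                tp, "conv_inter", states, emb_inter, src_e, dst_e, cfg,
                train=train, rng=rng, residual=False,
                target_subset=graph.canonical_indices,
            )
        else:  # every layer sees intra + inter edges
            src_all = np.concatenate([src_a, src_e])
            dst_all = np.concatenate([dst_a, dst_e])
            emb_both = ad.concat([emb_intra, emb_inter], axis=0)
            for t in range(cfg.n_gc):
                states = graph_convolution(
                    tp, f"conv{t}", states, emb_both, src_all, dst_all, cfg,
                    train=train, rng=rng,
                )
                states = periodic_sync(states, graph)

        canon_states = ad.gather(states, graph.canonical_indices)
        g_vec = global_aggregate(tp, canon_states, cfg)
        molf = np.asarray(mol_features, dtype=float)
        return output_head(tp, g_vec, molf, cfg, train=train, rng=rng), tp

    def discriminator_forward(self, entry: CrystalEntry, N: int | None = None):
        """Logits (real, fake) for a crystal entry."""
        if self.config.head != "discriminator":
            raise ValueError("model head is not 'discriminator'")
        gc = self.graph_config
        if N is None:
            N = gc.N
        if not supercell_encloses_check(entry, N, gc.r_c):
            raise ValueError(
                f"N={N} supercell does not enclose the r_max + r_c sphere; "
                "increase the supercell size N"
            )
        cell = build_supercell(entry, N=N, r_c=gc.r_c)
        graph = build_crystal_graph(cell, gc)
        molf = entry.molecule.mol_features
        if molf is None:
            raise ValueError("featurize the entry's molecule first")
        attach_atom_features(graph, entry.molecule, supercell=cell)
        out, _ = self.discriminator_forward_graph(graph, molf)
        return out.data[0]


def _mask_rows(emb, mask):
    if ad.is_tensor(emb):
        return ad.gather(emb, np.flatnonzero(mask))
    return emb[mask]


def g_atom_features(graph: CrystalGraph) -> np.ndarray:
    """Per-node 8-feature rows for a graph (image atoms inherit canonical)."""
    if getattr(graph, "_atom_features", None) is not None:
        return graph._atom_features
    raise ValueError("graph lacks attached atom features")


def attach_atom_features(graph: CrystalGraph, mol: MoleculeRecord,
                         supercell=None) -> CrystalGraph:
    """Attach per-node atom feature rows to a graph in place."""
    if mol.atom_features is None:
        raise ValueError("molecule is not featurized")
    if supercell is not None:
        rows = mol.atom_features[supercell.atom_in_mol]
    elif graph.symmetry_map is not None:
        canon_pos = np.empty(graph.n_nodes, dtype=int)
        canon_pos[graph.canonical_indices] = np.arange(len(graph.canonical_indices))
        rows = mol.atom_features[canon_pos[graph.symmetry_map]]
    else:
        rows = mol.atom_features
    graph._atom_features = rows
    return graph


def periodic_sync(states, graph: CrystalGraph):
    """Overwrite image node states from their canonical counterparts."""
    if graph.symmetry_map is None:
        return states
    from .crystal_graph import periodic_overwrite

    return periodic_overwrite(states, graph.symmetry_map)


# ----------------------------------------------------------------------
# module-level convenience wrappers
# ----------------------------------------------------------------------

def forward_density(mol: MoleculeRecord, model: Model) -> float:
    graph = build_molecule_graph(mol, model.graph_config)
    attach_atom_features(graph, mol)
    out, _ = model.density_forward_batch([graph], [mol.mol_features])
    return float(out.data[0, 0])


def forward_discriminator(entry: CrystalEntry, model: Model,
                          graph_config: GraphConfig | None = None,
                          N: int | None = None) -> np.ndarray:
    if graph_config is not None and graph_config != model.graph_config:
        model = _with_graph_config(model, graph_config)
    return model.discriminator_forward(entry, N=N)


def _with_graph_config(model: Model, gc: GraphConfig) -> Model:
    clone = Model.__new__(Model)
    clone.config = model.config
    clone.graph_config = gc
    clone.params = model.params
    return clone


def choose_supercell_size(entry: CrystalEntry, r_c: float,
                          start: int = 3, max_n: int = 9) -> int:
    """Smallest odd N whose supercell encloses the r_max + r_c sphere."""
    N = start
    while N <= max_n:
        if supercell_encloses_check(entry, N, r_c):
            return N
        N += 2
    raise ValueError(f"no supercell up to N={max_n} encloses the cutoff sphere")


# ----------------------------------------------------------------------
# differentiable path from the 12 crystal parameters to the model output
# ----------------------------------------------------------------------

def discriminator_output_from_params(
    model: Model,
    params: CrystalParams,
    conformer: MoleculeRecord,
    N: int | None = None,
    output: str = "logit_diff",
):
    """Model output as a differentiable function of the 12 parameters.

    Builds the crystal once in NumPy to freeze the discrete structure
    (wrap shifts, atom labels, edge set), then replays coordinates through
    the autodiff tape.  Returns ``(value, grad12)``.
    """
    if model.config.head != "discriminator":
        raise ValueError("model head is not 'discriminator'")
    gc = model.graph_config
    entry = build_unit_cell(params, conformer)
    if N is None:
        N = choose_supercell_size(entry, gc.r_c, start=gc.N)
    cell = build_supercell(entry, N=N, r_c=gc.r_c)
    graph = build_crystal_graph(cell, gc)
    attach_atom_features(graph, conformer, supercell=cell)

    ops = params.space_group.ops
    std = conformer.coords - conformer.coords.mean(axis=0)
    _, _, wrap_shifts = _place_molecule(params.as_vector(), std, ops)

    vec = Tensor(params.as_vector())
    M, images, _ = _place_molecule(vec, std, ops, wrap_shifts=wrap_shifts)

    # reassemble retained supercell atom coordinates on the tape
    Z = entry.Z
    blocks = []
    retained_rows = []
    row0 = 0
    for img in np.unique(cell.molecule_image_index):
        s_idx, m = divmod(int(img), Z)
        shift = ad.matmul(cell.frac_shifts[s_idx], M)
        block_rows = np.flatnonzero(cell.molecule_image_index == img)
        atoms = cell.atom_in_mol[block_rows]
        blocks.append(ad.add(ad.gather(images[m], atoms), shift))
        retained_rows.append(block_rows)
        row0 += len(block_rows)
    coords_t = ad.concat(blocks, axis=0)
    # blocks follow the supercell's own row order already
    assert np.allclose(coords_t.data, cell.coords, atol=1e-8)

    diff = ad.add(ad.gather(coords_t, graph.edge_src),
                  ad.mul(ad.gather(coords_t, graph.edge_dst), -1.0))
    dist = ad.sqrt(ad.sum(ad.mul(diff, diff), axis=1))
    emb = radial_embedding(dist, gc)

    out, _tp = model.discriminator_forward_graph(
        graph, conformer.mol_features, embeddings_override=emb
    )
    if output == "logit_diff":
        scalar = ad.add(out[0, 0], ad.mul(out[0, 1], -1.0))
    elif output == "real_logit":
        scalar = out[0, 0]
    else:
        raise ValueError("output must be 'logit_diff' or 'real_logit'")
    scalar.backward()
    return float(scalar.data), np.asarray(vec.grad, dtype=float).copy()
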