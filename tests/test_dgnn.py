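"""dgnn: layer contracts, invariances, gradient flow through the builder."""

from dataclasses import replace

import numpy as np
import pytest

from xtalkit import autodiff as ad
from xtalkit.autodiff import Tensor
from xtalkit.chem_io import featurize
from xtalkit.crystal_graph import GraphConfig, build_molecule_graph
from xtalkit.dgnn import (
    Model,
    ModelConfig,
    attach_atom_features,
    choose_supercell_size,
    discriminator_output_from_params,
    fc_layer,
    final_intermolecular_convolution,
    forward_density,
    forward_discriminator,
    global_aggregate,
    graph_convolution,
    init_node_states,
    output_head,
)
from xtalkit.fixtures import FixtureSpec, make_crystal, make_molecule
from xtalkit.lattice import CrystalParams, canonical_conformer_record

from conftest import rigid_rotation


# ----------------------------------------------------------------------
# fc layer
# ----------------------------------------------------------------------

def test_fc_zero_weights():
    x = np.array([1.0, -2.0, 3.0])
    out = fc_layer(x, np.zeros((3, 2)), np.zeros(2))
    np.testing.assert_allclose(out, 0.0)


def test_fc_identity_positive_passthrough():
    x = np.array([1.0, 2.0, 3.0])
    out = fc_layer(x, np.eye(3), np.zeros(3))
    np.testing.assert_allclose(out, x)


def test_fc_leaky_slope():
    out = fc_layer(np.array([-1.0]), np.eye(1), np.zeros(1), slope=0.01)
    assert out[0] == pytest.approx(-0.01)


def test_fc_width_mismatch():
    with pytest.raises(ValueError, match="width mismatch"):
        fc_layer(np.ones(3), np.ones((4, 2)), np.zeros(2))


# ----------------------------------------------------------------------
# node init
# ----------------------------------------------------------------------

def _featurized(spec_seed=41, n=(6, 6)):
    return make_molecule(FixtureSpec(seed=spec_seed, n_atoms_range=n), 0)


def test_init_identical_atoms_identical_states(tiny_density_model):
    mol = _featurized()
    tp = tiny_density_model.bind()
    af = mol.atom_features.copy()
    af[1] = af[0]  # force two atoms to share identical features
    states = init_node_states(tp, af, mol.mol_features, tiny_density_model.config)
    np.testing.assert_allclose(states.data[0], states.data[1], atol=1e-12)


def test_init_output_width(tiny_density_model):
    mol = _featurized()
    tp = tiny_density_model.bind()
    states = init_node_states(tp, mol.atom_features, mol.mol_features,
                              tiny_density_model.config)
    assert states.data.shape == (mol.n_atoms, tiny_density_model.config.node_width)


def test_init_molecule_features_touch_every_node(tiny_density_model):
    mol = _featurized()
    tp = tiny_density_model.bind()
    a = init_node_states(tp, mol.atom_features, mol.mol_features,
                         tiny_density_model.config)
    bumped = mol.mol_features.copy()
    bumped[2] *= 1.7
    b = init_node_states(tp, mol.atom_features, bumped,
                         tiny_density_model.config)
    per_node_change = np.abs(a.data - b.data).max(axis=1)
    assert (per_node_change > 0).all()


def test_init_rejects_unknown_atomic_number(tiny_density_model):
    mol = _featurized()
    tp = tiny_density_model.bind()
    af = mol.atom_features.copy()
    af[0, 0] = 101
    with pytest.raises(ValueError, match="embedding table"):
        init_node_states(tp, af, mol.mol_features, tiny_density_model.config)


# ----------------------------------------------------------------------
# graph convolution
# ----------------------------------------------------------------------

def test_conv_isolated_node_empty_neighborhood(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    states = Tensor(np.random.default_rng(0).normal(size=(3, cfg.node_width)))
    out = graph_convolution(
        tp, "conv0", states,
        np.zeros((0, cfg.n_basis)), np.zeros(0, int), np.zeros(0, int), cfg,
    )
    # residual + normalized transform of a zero message sum, applied per row
    zero_msg = np.zeros((3, cfg.message_width))
    W, b = tp["conv0.fc2.W"].data, tp["conv0.fc2.b"].data
    upd = np.where(zero_msg @ W + b > 0, zero_msg @ W + b,
                   0.01 * (zero_msg @ W + b))
    expected = states.data + upd
    mu = expected.mean(axis=1, keepdims=True)
    sd = np.sqrt(((expected - mu) ** 2).mean(axis=1, keepdims=True) + 1e-5)
    expected = (expected - mu) / sd * tp["conv0.ln.g"].data + tp["conv0.ln.b"].data
    np.testing.assert_allclose(out.data, expected, atol=1e-10)


def test_conv_single_edge_hand_computed():
    cfg = ModelConfig(
        n_gc=1, node_width=2, message_width=2, edge_embed_width=2,
        n_basis=2, atomic_embedding_dim=2, head="density", dropout=0.0, seed=0,
    )
    model = Model(cfg, GraphConfig(r_c=6.0, n_basis=2))
    tp = model.bind()
    # overwrite with unit weights for a by-hand check
    for name in ("conv0.n2m", "conv0.e2m", "conv0.fc1", "conv0.fc2"):
        tp[f"{name}.W"] = Tensor(np.ones_like(tp[f"{name}.W"].data))
        tp[f"{name}.b"] = Tensor(np.zeros_like(tp[f"{name}.b"].data))
    tp["conv0.ln.g"] = Tensor(np.ones(2))
    tp["conv0.ln.b"] = Tensor(np.zeros(2))
    states = Tensor(np.array([[1.0, 2.0], [0.5, 0.5]]))
    emb = np.array([[0.2, 0.3]])
    src, dst = np.array([1]), np.array([0])
    out = graph_convolution(tp, "conv0", states, emb, src, dst, cfg)
    # by hand: F = sigma(sum(x)) per row -> F0=(3,3), F1=(1,1); E=(0.5,0.5)
    # message into node 0: FC1(3,3,1,1,0.5,0.5) = (9,9); FC2 -> (18,18)
    # node 0: state + (18,18) = (19,20) -> LN -> (-1, 1) (gain 1, bias 0)
    row0 = out.data[0]
    np.testing.assert_allclose(row0, [-0.99999, 0.99999], atol=1e-4)
    # node 1 has no in-edges: residual of zero-message transform
    assert out.data.shape == (2, 2)


def test_conv_permutation_equivariance(tiny_density_model):
    mol = _featurized(43, (7, 7))
    cfg = tiny_density_model.config
    gc = tiny_density_model.graph_config
    tp = tiny_density_model.bind()
    g = build_molecule_graph(mol, gc)
    states = init_node_states(tp, mol.atom_features, mol.mol_features, cfg)
    out = graph_convolution(tp, "conv0", states, g.embeddings,
                            g.edge_src, g.edge_dst, cfg)

    perm = np.random.default_rng(1).permutation(mol.n_atoms)
    inv = np.argsort(perm)
    pmol = replace(mol, atomic_numbers=mol.atomic_numbers[perm],
                   coords=mol.coords[perm], atom_features=mol.atom_features[perm],
                   donor_flags=None, acceptor_flags=None)
    pg = build_molecule_graph(pmol, gc)
    pstates = init_node_states(tp, pmol.atom_features, pmol.mol_features, cfg)
    pout = graph_convolution(tp, "conv0", pstates, pg.embeddings,
                             pg.edge_src, pg.edge_dst, cfg)
    np.testing.assert_allclose(pout.data[inv], out.data, atol=1e-9)


def test_conv_dangling_edge_raises(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    states = Tensor(np.zeros((2, cfg.node_width)))
    with pytest.raises(IndexError):
        graph_convolution(tp, "conv0", states, np.zeros((1, cfg.n_basis)),
                          np.array([5]), np.array([0]), cfg)


# ----------------------------------------------------------------------
# final intermolecular convolution
# ----------------------------------------------------------------------

def _crystal_graph_fixture(spec, i, gc):
    from xtalkit.crystal_graph import build_crystal_graph
    from xtalkit.lattice import build_supercell

    _, entry = make_crystal(spec, i)
    conf = featurize(canonical_conformer_record(entry))
    N = choose_supercell_size(entry, gc.r_c)
    cell = build_supercell(entry, N=N, r_c=gc.r_c)
    g = build_crystal_graph(cell, gc)
    attach_atom_features(g, conf, supercell=cell)
    return g, conf


def test_final_inter_conv_matches_non_residual_oracle(spec, tiny_discriminator_model):
    from xtalkit.crystal_graph import INTER

    model = tiny_discriminator_model
    gc = model.graph_config
    g, conf = _crystal_graph_fixture(spec, 1, gc)
    tp = model.bind()
    rng = np.random.default_rng(2)
    states = Tensor(rng.normal(size=(g.n_nodes, model.config.node_width)))

    out, had = final_intermolecular_convolution(tp, states, g, model.config)
    src, dst, mask = g.edges_of_type(INTER)
    oracle = graph_convolution(
        tp, "conv_inter", states, g.embeddings[mask], src, dst, model.config,
        residual=False, target_subset=g.canonical_indices,
    )
    np.testing.assert_allclose(out.data, oracle.data, atol=1e-12)
    assert had == (len(src) > 0)
    # image-node states are never touched
    images = np.flatnonzero(g.labels == 1)
    np.testing.assert_array_equal(out.data[images], states.data[images])


def test_final_inter_conv_empty_flag(tiny_discriminator_model):
    # isolated molecule: zero inter edges -> flag False, empty-sum states
    spec = FixtureSpec(seed=47, n_atoms_range=(5, 5), c_pack_range=(0.0005, 0.001))
    model = tiny_discriminator_model
    g, conf = _crystal_graph_fixture(spec, 0, model.graph_config)
    assert (g.edge_type == 1).sum() == 0
    tp = model.bind()
    states = Tensor(np.random.default_rng(0).normal(size=(g.n_nodes, model.config.node_width)))
    out, had = final_intermolecular_convolution(tp, states, g, model.config)
    assert not had
    assert np.isfinite(out.data).all()


# ----------------------------------------------------------------------
# global aggregation
# ----------------------------------------------------------------------

def test_aggregate_single_node(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    state = np.random.default_rng(0).normal(size=(1, cfg.node_width))
    out = global_aggregate(tp, Tensor(state), cfg)
    # max = sum = mean = SA = the single state
    cat = np.concatenate([state, state, state, state], axis=1)
    W, b = tp["agg.fc.W"].data, tp["agg.fc.b"].data
    pre = cat @ W + b
    expected = np.where(pre > 0, pre, 0.01 * pre)
    np.testing.assert_allclose(out.data, expected, atol=1e-10)


def test_aggregate_duplication_algebra(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    rng = np.random.default_rng(3)
    states = rng.normal(size=(5, cfg.node_width))
    doubled = np.concatenate([states, states])

    def parts(x):
        scores = x @ tp["agg.query"].data / np.sqrt(cfg.node_width)
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        return (
            x.max(axis=0), x.sum(axis=0), x.mean(axis=0), (w[:, None] * x).sum(axis=0)
        )

    m1, s1, mu1, a1 = parts(states)
    m2, s2, mu2, a2 = parts(doubled)
    np.testing.assert_allclose(m2, m1)
    np.testing.assert_allclose(s2, 2 * s1)
    np.testing.assert_allclose(mu2, mu1)
    np.testing.assert_allclose(a2, a1)


def test_aggregate_permutation_invariant(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    rng = np.random.default_rng(4)
    states = rng.normal(size=(6, cfg.node_width))
    out1 = global_aggregate(tp, Tensor(states), cfg)
    out2 = global_aggregate(tp, Tensor(states[rng.permutation(6)]), cfg)
    np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)


def test_aggregate_empty_raises(tiny_density_model):
    cfg = tiny_density_model.config
    tp = tiny_density_model.bind()
    with pytest.raises(ValueError):
        global_aggregate(tp, Tensor(np.zeros((0, cfg.node_width))), cfg)


# ----------------------------------------------------------------------
# output head
# ----------------------------------------------------------------------

def test_head_output_dims(tiny_density_model, tiny_discriminator_model):
    for model, dim in ((tiny_density_model, 1), (tiny_discriminator_model, 2)):
        tp = model.bind()
        g_vec = Tensor(np.zeros((1, model.config.node_width)))
        out = output_head(tp, g_vec, np.zeros(16), model.config)
        assert out.data.shape == (1, dim)


def test_head_layer_count_follows_n_gc():
    cfg = ModelConfig(n_gc=5, node_width=16, message_width=8, edge_embed_width=8,
                      n_basis=4, atomic_embedding_dim=4, head="density", seed=0)
    params = Model(cfg, GraphConfig(r_c=6.0, n_basis=4)).params
    head_layers = {k.split(".")[0] for k in params if k.startswith("head")}
    assert len(head_layers) == 6  # n_gc + 1


def test_head_deterministic_without_dropout(tiny_density_model):
    tp = tiny_density_model.bind()
    g_vec = Tensor(np.random.default_rng(5).normal(size=(1, tiny_density_model.config.node_width)))
    a = output_head(tp, g_vec, np.ones(16), tiny_density_model.config)
    b = output_head(tp, g_vec, np.ones(16), tiny_density_model.config)
    np.testing.assert_array_equal(a.data, b.data)


# ----------------------------------------------------------------------
# full forward passes
# ----------------------------------------------------------------------

def test_density_forward_rigid_motion_and_permutation_invariant(tiny_density_model):
    # invariant descriptors held fixed; only coordinates are transformed
    mol = _featurized(53, (6, 9))
    base = forward_density(mol, tiny_density_model)
    R = rigid_rotation(9)
    moved = replace(mol, coords=mol.coords @ R.T + 3.0)
    assert forward_density(moved, tiny_density_model) == pytest.approx(base, abs=1e-5)
    inverted = replace(mol, coords=-mol.coords)
    assert forward_density(inverted, tiny_density_model) == pytest.approx(base, abs=1e-5)
    perm = np.random.default_rng(2).permutation(mol.n_atoms)
    permuted = replace(mol, coords=mol.coords[perm],
                       atomic_numbers=mol.atomic_numbers[perm],
                       atom_features=mol.atom_features[perm])
    assert forward_density(permuted, tiny_density_model) == pytest.approx(base, abs=1e-5)


def test_density_forward_deterministic(tiny_density_model):
    mol = _featurized(59, (5, 8))
    assert forward_density(mol, tiny_density_model) == forward_density(
        mol, tiny_density_model
    )


def test_discriminator_forward_translation_and_inversion_invariant(
    spec, tiny_discriminator_model
):
    # translation and inversion are lattice-compatible transforms of the
    # explicit cell (the supercell shift set is centrosymmetric)
    _, entry = make_crystal(spec, 2)
    entry = replace(entry, molecule=featurize(entry.molecule))
    base = forward_discriminator(entry, tiny_discriminator_model, N=5)
    t = np.array([1.0, -2.0, 0.5])
    moved = replace(
        entry,
        unit_cell_coords=entry.unit_cell_coords + t,
        molecule=replace(entry.molecule, coords=entry.molecule.coords + t),
    )
    np.testing.assert_allclose(
        forward_discriminator(moved, tiny_discriminator_model, N=5), base, atol=1e-5
    )
    inverted = replace(
        entry,
        unit_cell_coords=-entry.unit_cell_coords,
        molecule=replace(entry.molecule, coords=-entry.molecule.coords),
    )
    # inversion relabels the canonical molecule; let the supercell size adapt
    N_inv = choose_supercell_size(inverted, tiny_discriminator_model.graph_config.r_c)
    np.testing.assert_allclose(
        forward_discriminator(inverted, tiny_discriminator_model, N=N_inv),
        base, atol=1e-5,
    )


def test_discriminator_rotation_invariant_at_graph_level(spec, tiny_discriminator_model):
    # a global rotation acts on lattice and molecules together; apply it to
    # the explicit supercell and push both versions through the network
    from xtalkit.crystal_graph import build_crystal_graph
    from xtalkit.lattice import build_supercell

    model = tiny_discriminator_model
    gc = model.graph_config
    _, entry = make_crystal(spec, 2)
    conf = featurize(canonical_conformer_record(entry))
    cell = build_supercell(entry, N=5, r_c=gc.r_c)
    R = rigid_rotation(10)
    rotated = replace(cell, coords=cell.coords @ R.T + np.array([1.0, 2.0, 3.0]))
    logits = []
    for sc in (cell, rotated):
        g = build_crystal_graph(sc, gc)
        attach_atom_features(g, conf, supercell=sc)
        out, _ = model.discriminator_forward_graph(g, conf.mol_features)
        logits.append(out.data[0])
    np.testing.assert_allclose(logits[1], logits[0], atol=1e-5)


def test_discriminator_reorigin_invariant(spec, tiny_discriminator_model):
    params, entry = make_crystal(spec, 4)
    entry = replace(entry, molecule=featurize(entry.molecule))
    base = forward_discriminator(entry, tiny_discriminator_model, N=5)
    # shift the origin by a full lattice vector: same crystal, relabeled cell
    M = entry.cell_matrix()
    shifted = replace(entry, unit_cell_coords=entry.unit_cell_coords + M[0])
    got = forward_discriminator(shifted, tiny_discriminator_model, N=5)
    np.testing.assert_allclose(got, base, atol=1e-5)


def test_discriminator_enclosure_error_advises_larger_n(tiny_discriminator_model):
    spec = FixtureSpec(seed=61, n_atoms_range=(8, 8), c_pack_range=(0.8, 0.85))
    _, entry = make_crystal(spec, 0)
    entry = replace(entry, molecule=featurize(entry.molecule))
    with pytest.raises(ValueError, match="supercell size N"):
        tiny_discriminator_model.discriminator_forward(entry, N=1)


def test_model_save_load_round_trip(tmp_path, tiny_density_model):
    mol = _featurized(67, (5, 7))
    base = forward_density(mol, tiny_density_model)
    path = tmp_path / "model.npz"
    tiny_density_model.save(path)
    back = Model.load(path)
    assert forward_density(mol, back) == base


# ----------------------------------------------------------------------
# gradient flow through the differentiable builder
# ----------------------------------------------------------------------

@pytest.mark.parametrize("index", [2, 4])  # P21, P212121 fixtures
def test_gradient_matches_finite_differences(index, tiny_discriminator_model):
    spec = FixtureSpec(seed=5, n_atoms_range=(5, 8))
    params, entry = make_crystal(spec, index)
    conf = featurize(canonical_conformer_record(entry))
    model = tiny_discriminator_model
    N = choose_supercell_size(entry, model.graph_config.r_c)
    value, grad = discriminator_output_from_params(model, params, conf, N=N)
    assert np.isfinite(value)
    assert (grad != 0).all()  # nonzero gradient for all 12 parameters
    h = 1e-4
    base = params.as_vector()
    for k in range(12):
        vp, vm = base.copy(), base.copy()
        vp[k] += h
        vm[k] -= h
        f1, _ = discriminator_output_from_params(
            model, CrystalParams.from_vector(vp, params.space_group), conf, N=N
        )
        f0, _ = discriminator_output_from_params(
            model, CrystalParams.from_vector(vm, params.space_group), conf, N=N
        )
        fd = (f1 - f0) / (2 * h)
        assert abs(fd - grad[k]) <= 1e-3 * max(abs(fd), 1e-6), f"param {k}"
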