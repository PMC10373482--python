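"""Shared fixtures: deterministic synthetic molecules, crystals, models."""

from __future__ import annotations

import numpy as np
import pytest

from xtalkit.chem_io import featurize
from xtalkit.crystal_graph import GraphConfig
from xtalkit.dgnn import Model, ModelConfig
from xtalkit.fixtures import FixtureSpec, make_crystal, make_molecule
from xtalkit.lattice import canonical_conformer_record


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=3, n_atoms_range=(5, 9))


@pytest.fixture(scope="session")
def small_molecule(spec):
    return make_molecule(spec, 0)


@pytest.fixture(scope="session")
def crystal_p1(spec):
    return make_crystal(spec, 0, space_group="P1")


@pytest.fixture(scope="session")
def crystal_pminus1(spec):
    return make_crystal(spec, 1, space_group="P-1")


@pytest.fixture(scope="session")
def crystal_p21c(spec):
    return make_crystal(spec, 3, space_group="P21/c")


@pytest.fixture(scope="session")
def tiny_graph_config():
    return GraphConfig(r_c=4.0, n_basis=8)


@pytest.fixture(scope="session")
def tiny_density_model(tiny_graph_config):
    cfg = ModelConfig(
        n_gc=2, node_width=32, message_width=16, edge_embed_width=16,
        n_basis=8, atomic_embedding_dim=8, head="density",
        dropout=0.0, seed=0,
    )
    return Model(cfg, tiny_graph_config)


@pytest.fixture(scope="session")
def tiny_discriminator_model(tiny_graph_config):
    cfg = ModelConfig(
        n_gc=2, node_width=32, message_width=16, edge_embed_width=16,
        n_basis=8, atomic_embedding_dim=8, head="discriminator",
        dropout=0.0, seed=0,
    )
    return Model(cfg, tiny_graph_config)


@pytest.fixture(scope="session")
def featurized_conformer(crystal_pminus1):
    _, entry = crystal_pminus1
    return featurize(canonical_conformer_record(entry))


def rigid_rotation(seed: int = 0) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_matrix()
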