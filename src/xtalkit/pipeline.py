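"""Desk-scale training and evaluation.

Dataset splitting, mixed real/fake batch construction with 50/50
generator alternation, Adam optimization of either model head, best-test-
loss checkpoint selection, and the evaluation analyses (relative MAE,
regression R and slope, score distributions, correlation tables,
quantile filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import scoring
from .autodiff import Tensor
from .chem_io import CrystalEntry, featurize, molecular_volume
from .crystal_graph import GraphConfig, build_crystal_graph, build_molecule_graph
from .dgnn import Model, ModelConfig, attach_atom_features, choose_supercell_size
from .generators import (
    DistortionConfig,
    ParamStats,
    distort_crystal,
    fit_param_gaussian,
    sample_gaussian_crystals,
)
from .lattice import build_supercell, build_unit_cell, canonical_conformer_record, extract_crystal_params

__all__ = [
    "RunConfig",
    "split_dataset",
    "make_discriminator_batch",
    "train_density",
    "train_discriminator",
    "evaluate_density",
    "evaluate_discriminator",
    "Adam",
]


@dataclass
class RunConfig:
    seed: int = 0
    split_fraction: float = 0.8
    batch_size: int = 32
    generator_mix: float = 0.5  # probability a fake comes from the Gaussian generator
    c_dis: float = 0.1
    max_epochs: int = 20
    learning_rate: float = 1e-3
    patience: int = 20  # non-improving epochs before early stop
    lr_decay: bool = True  # cosine decay to 20% over max_epochs

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")
        if not 0.0 <= self.generator_mix <= 1.0:
            raise ValueError("generator mix probability must lie in [0, 1]")


def _lr_scale(config: "RunConfig", epoch: int) -> float:
    if not config.lr_decay or config.max_epochs <= 1:
        return 1.0
    frac = epoch / max(config.max_epochs - 1, 1)
    return 0.2 + 0.8 * 0.5 * (1.0 + np.cos(np.pi * frac))


def split_dataset(entries, config: RunConfig):
    """Seed-deterministic disjoint 80:20 (by default) split."""
    entries = list(entries)
    if len(entries) < 2:
        raise ValueError("need at least 2 entries to split")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(entries))
    n_train = int(round(config.split_fraction * len(entries)))
    n_train = min(max(n_train, 1), len(entries) - 1)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    return [entries[i] for i in train_idx], [entries[i] for i in test_idx]


class Adam:
    """Adaptive-moment optimizer over a parameter dict.

    Supports global-norm gradient clipping and a multiplicative learning-
    rate scale (for schedules).
    """

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 max_grad_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict, lr_scale: float = 1.0) -> None:
        self.t += 1
        if self.max_grad_norm is not None:
            total = np.sqrt(
                sum(float((g**2).sum()) for g in grads.values() if g is not None)
            )
            clip = min(1.0, self.max_grad_norm / max(total, 1e-12))
        else:
            clip = 1.0
        for k, g in grads.items():
            if g is None:
                continue
            g = g * clip
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= lr_scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------
# discriminator batches
# ----------------------------------------------------------------------

@dataclass
class DiscriminatorSample:
    entry: CrystalEntry
    label: int  # 1 real, 0 fake
    source: str  # "real" | "gaussian" | "distorted"


def make_discriminator_batch(
    real_pool, stats: ParamStats, config: RunConfig, seed: int,
    batch_size: int | None = None, max_retries: int = 8,
    r_c: float = 6.0, max_supercell: int = 7,
) -> list[DiscriminatorSample]:
    """Half real entries, half fakes from the two generators.

    Each fake alternates between the Gaussian generator and the distorted-
    crystal generator with probability ``config.generator_mix``; fakes are
    always rebuilt through the unit-cell builder, and a fake whose cell is
    too degenerate to support a graphable supercell (up to
    ``max_supercell``) is resampled within a bounded retry budget.
    Deterministic under ``seed``.
    """
    if not real_pool:
        raise ValueError("empty real pool")
    n = batch_size if batch_size is not None else config.batch_size
    if n % 2:
        raise ValueError("batch size must be even")
    rng = np.random.default_rng(seed)
    half = n // 2
    samples: list[DiscriminatorSample] = []
    picks = rng.integers(0, len(real_pool), size=n)
    for k in range(half):
        samples.append(DiscriminatorSample(real_pool[picks[k]], 1, "real"))
    for k in range(half):
        base = real_pool[picks[half + k]]
        conformer = canonical_conformer_record(base)
        v_mol = conformer.mol_volume
        if v_mol is None:
            v_mol = molecular_volume(conformer)
        for attempt in range(max_retries):
            sub_seed = int(rng.integers(0, 2**62))
            try:
                if rng.random() < config.generator_mix:
                    fake_params = sample_gaussian_crystals(
                        stats, conformer, base.space_group, 1, seed=sub_seed
                    )[0]
                    source = "gaussian"
                else:
                    params = extract_crystal_params(base)
                    fake_params = distort_crystal(
                        params, stats,
                        DistortionConfig(c_dis=config.c_dis, seed=sub_seed),
                        Z=base.Z, v_mol=v_mol,
                    )
                    source = "distorted"
                fake = build_unit_cell(
                    fake_params, conformer,
                    identifier=f"fake-{seed}-{k}-{attempt}",
                )
                choose_supercell_size(fake, r_c, max_n=max_supercell)
                samples.append(DiscriminatorSample(fake, 0, source))
                break
            except (ValueError, np.linalg.LinAlgError):
                continue
        else:
            raise RuntimeError("fake generation failed repeatedly")
    return samples


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def _smoothed_l1_tensor(pred, target):
    d = ad.add(pred, -np.asarray(target, dtype=float))
    absd = ad.sqrt(ad.add(ad.mul(d, d), 1e-24))
    quad = ad.mul(ad.mul(d, d), 0.5)
    lin = ad.add(absd, -0.5)
    mask = (np.abs(d.data) < 1.0).astype(float)
    return ad.mean(ad.add(ad.mul(quad, mask), ad.mul(lin, 1.0 - mask)))


def _cross_entropy_tensor(logits, labels):
    """Mean two-class cross entropy; labels 1 = real (logit column 0)."""
    labels = np.asarray(labels, dtype=int)
    mx = logits.data.max(axis=1, keepdims=True)  # detached shift
    shifted = ad.add(logits, -mx)
    e = ad.exp(shifted)
    lse = ad.log(ad.sum(e, axis=1, keepdims=True))
    logp = ad.add(shifted, ad.mul(lse, -1.0))
    cols = np.where(labels == 1, 0, 1)
    picked = logp[np.arange(len(labels)), cols]
    return ad.mul(ad.mean(picked), -1.0)


# ----------------------------------------------------------------------
# training loops
# ----------------------------------------------------------------------

def _grads_from(tp: dict) -> dict:
    return {k: (t.grad if t.grad is not None else None) for k, t in tp.items()}


@dataclass
class Checkpoint:
    epoch: int
    test_loss: float
    params: dict


@dataclass
class TrainLog:
    train_losses: list = field(default_factory=list)
    test_losses: list = field(default_factory=list)
    best: Checkpoint | None = None

    def to_text(self) -> str:
        lines = ["epoch\ttrain_loss\ttest_loss"]
        for i, (tr, te) in enumerate(zip(self.train_losses, self.test_losses)):
            lines.append(f"{i}\t{tr:.6f}\t{te:.6f}")
        return "\n".join(lines)


def select_best_checkpoint(test_losses) -> int:
    """Index of the checkpoint with the lowest test loss (argmin contract)."""
    losses = np.asarray(list(test_losses), dtype=float)
    if len(losses) == 0:
        raise ValueError("no epochs logged")
    return int(np.argmin(losses))


def _prep_density(dataset, graph_config: GraphConfig):
    graphs, molfs, labels = [], [], []
    for mol, label in dataset:
        if mol.mol_features is None:
            mol = featurize(mol)
        g = build_molecule_graph(mol, graph_config)
        attach_atom_features(g, mol)
        graphs.append(g)
        molfs.append(mol.mol_features)
        labels.append(label)
    return graphs, molfs, np.asarray(labels, dtype=float)


def train_density(model: Model, dataset, config: RunConfig) -> TrainLog:
    """Minimize the smoothed-L1 packing-coefficient error; keep the best
    test-loss checkpoint.  Fully reproducible under ``config.seed``."""
    train_set, test_set = split_dataset(dataset, config)
    g_tr, m_tr, y_tr = _prep_density(train_set, model.graph_config)
    g_te, m_te, y_te = _prep_density(test_set, model.graph_config)
    opt = Adam(model.params, lr=config.learning_rate)
    log = TrainLog()
    rng = np.random.default_rng(config.seed + 1)
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(g_tr))
        ep_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            out, tp = model.density_forward_batch(
                [g_tr[i] for i in idx], [m_tr[i] for i in idx],
                train=True, rng=rng,
            )
            loss = _smoothed_l1_tensor(
                ad.reshape(out, (-1,)), y_tr[idx]
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step(_grads_from(tp), lr_scale=_lr_scale(config, epoch))
            ep_losses.append(float(loss.data))
        te = _density_test_loss(model, g_te, m_te, y_te)
        log.train_losses.append(float(np.mean(ep_losses)))
        log.test_losses.append(te)
        if log.best is None or te < log.best.test_loss:
            log.best = Checkpoint(
                epoch, te, {k: v.copy() for k, v in model.params.items()}
            )
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.params.update(log.best.params)
    return log


def _density_test_loss(model, graphs, molfs, labels, chunk: int = 256) -> float:
    preds = density_predictions(model, graphs, molfs, chunk)
    return float(np.mean(scoring.smoothed_l1(preds, labels)))


def density_predictions(model, graphs, molfs, chunk: int = 256) -> np.ndarray:
    preds = []
    for lo in range(0, len(graphs), chunk):
        out, _ = model.density_forward_batch(
            graphs[lo : lo + chunk], molfs[lo : lo + chunk]
        )
        preds.append(out.data[:, 0])
    return np.concatenate(preds)


def _prep_discriminator(samples, graph_config: GraphConfig):
    graphs, molfs, labels = [], [], []
    for s in samples:
        entry = s.entry
        if entry.molecule.mol_features is None:
            entry = replace(entry, molecule=featurize(entry.molecule))
        N = choose_supercell_size(entry, graph_config.r_c, start=graph_config.N)
        cell = build_supercell(entry, N=N, r_c=graph_config.r_c)
        g = build_crystal_graph(cell, graph_config)
        attach_atom_features(g, entry.molecule, supercell=cell)
        graphs.append(g)
        molfs.append(entry.molecule.mol_features)
        labels.append(s.label)
    return graphs, molfs, np.asarray(labels, dtype=int)


def train_discriminator(model: Model, real_entries, config: RunConfig,
                        n_batches_per_epoch: int = 8) -> TrainLog:
    """Cross-entropy training on equal real/fake batches.

    Real samples come from the provided pool; fakes are drawn per batch
    from the Gaussian and distortion generators (50/50 alternation by
    default), rebuilt through the cell builder.
    """
    train_pool, test_pool = split_dataset(real_entries, config)
    stats = fit_param_gaussian(
        [(extract_crystal_params(e), e.Z,
          e.molecule.mol_volume or molecular_volume(e.molecule))
         for e in train_pool]
    )
    test_batch = make_discriminator_batch(
        test_pool, stats, config, seed=config.seed + 999,
        batch_size=2 * (len(test_pool) // 2) or 2,
    )
    g_te, m_te, y_te = _prep_discriminator(test_batch, model.graph_config)

    opt = Adam(model.params, lr=config.learning_rate)
    log = TrainLog()
    rng = np.random.default_rng(config.seed + 2)
    stall = 0
    for epoch in range(config.max_epochs):
        ep_losses = []
        for b in range(n_batches_per_epoch):
            batch = make_discriminator_batch(
                train_pool, stats, config,
                seed=int(rng.integers(0, 2**62)),
            )
            graphs, molfs, labels = _prep_discriminator(batch, model.graph_config)
            tp = model.bind()
            logits = []
            for g, mf in zip(graphs, molfs):
                out, _ = model.discriminator_forward_graph(
                    g, mf, train=True, rng=rng, tp=tp
                )
                logits.append(out)
            logits = ad.concat(logits, axis=0)
            loss = _cross_entropy_tensor(logits, labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"divergent training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step(_grads_from(tp), lr_scale=_lr_scale(config, epoch))
            ep_losses.append(float(loss.data))
        te = _discriminator_test_loss(model, g_te, m_te, y_te)
        log.train_losses.append(float(np.mean(ep_losses)))
        log.test_losses.append(te)
        if log.best is None or te < log.best.test_loss:
            log.best = Checkpoint(
                epoch, te, {k: v.copy() for k, v in model.params.items()}
            )
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.params.update(log.best.params)
    return log


def discriminator_logits(model, graphs, molfs) -> np.ndarray:
    rows = []
    for g, mf in zip(graphs, molfs):
        out, _ = model.discriminator_forward_graph(g, mf)
        rows.append(out.data[0])
    return np.stack(rows)


def _discriminator_test_loss(model, graphs, molfs, labels) -> float:
    logits = discriminator_logits(model, graphs, molfs)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    cols = np.where(np.asarray(labels) == 1, 0, 1)
    return float(-logp[np.arange(len(labels)), cols].mean())


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def regression_metrics(pred, target) -> dict:
    """Relative MAE (as % of the mean target), error std, Pearson R, and
    least-squares slope of prediction vs target."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(pred) == 0:
        raise ValueError("empty test set")
    err = pred - target
    mae_pct = 100.0 * np.abs(err).mean() / np.abs(target.mean())
    r = float(np.corrcoef(pred, target)[0, 1]) if target.std() > 0 and pred.std() > 0 else 0.0
    slope = (
        float(np.cov(pred, target, ddof=0)[0, 1] / np.var(target))
        if target.std() > 0
        else 0.0
    )
    return {
        "relative_mae_pct": float(mae_pct),
        "mae_sigma": float(np.abs(err).std()),
        "regression_R": r,
        "regression_slope": slope,
    }


def evaluate_density(model: Model, dataset, masses=None) -> dict:
    """Density-head metrics on c_pack and on the derived mass density.

    Relative MAE is identical between the two targets (density is a
    per-molecule linear rescale of c_pack) while R generally differs.
    """
    graphs, molfs, labels = _prep_density(dataset, model.graph_config)
    preds = density_predictions(model, graphs, molfs)
    out = {"c_pack": regression_metrics(preds, labels)}
    if masses is not None:
        masses = np.asarray(masses, dtype=float)
        out["density"] = regression_metrics(preds * masses, labels * masses)
    return out


_MOL_FEATURE_NAMES = (
    "n_atoms", "mass", "volume", "inertia_1", "inertia_2", "inertia_3",
    "radius_of_gyration", "n_rings", "n_rotatable_bonds", "n_donors",
    "n_acceptors", "planarity", "r_max", "frac_carbon", "frac_n_o",
    "frac_other",
)


def evaluate_discriminator(model: Model, samples, q: float = 0.05) -> dict:
    """Score distributions per class, a score-vs-feature correlation table,
    and the quantile-filter fraction."""
    graphs, molfs, labels = _prep_discriminator(samples, model.graph_config)
    logits = discriminator_logits(model, graphs, molfs)
    p_real = scoring.softmax_pair(logits)
    scores = scoring.stretch_score(p_real)
    labels = np.asarray(labels)
    real_scores = scores[labels == 1]
    fake_scores = scores[labels == 0]
    feature_matrix = np.stack(molfs)
    result = {
        "real_scores": real_scores,
        "fake_scores": fake_scores,
        "auc": _auc(real_scores, fake_scores),
        "correlations": scoring.pearson_feature_correlations(
            scores,
            {name: feature_matrix[:, k]
             for k, name in enumerate(_MOL_FEATURE_NAMES)},
        ),
    }
    if len(real_scores) and len(fake_scores):
        result["fake_fraction_below_quantile"] = scoring.quantile_filter(
            real_scores, fake_scores, q
        )
    return result


def _auc(pos, neg) -> float:
    """Rank-based AUC (probability a real sample outscores a fake one)."""
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    both = np.concatenate([pos, neg])
    ranks = both.argsort().argsort() + 1
    r_pos = ranks[: len(pos)].sum()
    return float(
        (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    )
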