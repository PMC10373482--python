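# xtalkit

Molecular-crystal machine-learning toolkit: a 12-parameter crystal
representation with a deterministic (and differentiable) unit-cell /
supercell builder, synthetic "fake crystal" generators, a periodic
molecular-crystal graph convolution, and two graph neural networks —
one predicting the crystal packing coefficient from a single conformer,
one scoring whole crystal structures as real vs. fake — plus the
associated score functions (vdW contact score, stretched discriminator
score) and desk-scale training/evaluation pipelines.

Everything runs offline on NumPy/SciPy: the networks (and the cell
builder) are written against a small reverse-mode autodiff engine
(`xtalkit.autodiff`), so model outputs are differentiable end-to-end with
respect to both the weights and the 12 crystal parameters.

## Layout

| module | contents |
| --- | --- |
| `xtalkit.chem_io` | molecule/crystal records, CIF + XYZ I/O, hydrogen stripping, 8-dim atom / 16-dim molecule featurization, filter cascade, packing coefficient |
| `xtalkit.lattice` | `CrystalParams` (a,b,c,α,β,γ, fractional centroid, rotation-vector orientation), canonical-conformer selection, standardized inertial orientation, parameter extraction, unit-cell and N×N×N supercell builders |
| `xtalkit.generators` | reduced-length parameter space, multivariate-Gaussian crystal sampler, distorted-crystal generator (`c_dis`) |
| `xtalkit.crystal_graph` | radial graphs (intra + outside-in intermolecular edges), zeroth-order spherical Bessel edge embeddings, periodic feature overwrite |
| `xtalkit.dgnn` | the GNN architecture (bottlenecked message passing, four-way global aggregation, MLP head) with density and discriminator instantiations |
| `xtalkit.scoring` | smoothed-L1, softmax + stretched score, vdW overlap score, Pearson feature correlations, quantile filtering, size normalization |
| `xtalkit.pipeline` | splits, mixed real/fake batches, Adam training loops with best-test-loss checkpointing, evaluation metrics |
| `xtalkit.fixtures` | deterministic synthetic molecules, crystals (with ground-truth parameters), vdW-respecting "pristine" crystals, planted-label density datasets |

## CLI

```bash
xtalkit fixtures-make --n 20 --seed 0 --out scratch/cifs
xtalkit generate --mode gaussian --n 10 --seed 0 --out scratch/fakes
xtalkit generate --mode distort --c-dis 0.1 --n 10 --seed 0 --out scratch/fakes
xtalkit train --task density --seed 0 --ckpt scratch/density.npz
xtalkit evaluate --ckpt scratch/density.npz --seed 1
xtalkit train --task discriminator --seed 0 --n-samples 60 --ckpt scratch/disc.npz
xtalkit score --input scratch/cifs --model scratch/disc.npz
```

`score` reads any directory of small-molecule CIFs (Z′ = 1), strips
hydrogens, featurizes, and prints per-structure p_real, stretched score,
vdW score, and the size-normalized score.

## Notes

- Space groups: bundled general-position tables for P1, P-1, P2₁, P2₁/c,
  P2₁2₁2₁, C2/c, Pbca, Pna2₁; arbitrary operator lists are accepted from
  CIF symmetry loops.
- Crystals are Z′ = 1 with rigid conformers; cells are parametrized by the
  12-vector plus the space-group choice, and `extract ∘ build` is the
  identity to 1e-5 across all bundled groups (tested on 500 fixtures).
- The periodic convolution on an N=3 supercell with feature overwrite
  matches an explicit N=5 convolution restricted to the central molecule
  to machine precision (the padding-style periodicity contract).
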