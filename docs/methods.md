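# Methods

## Volumetric representation

Molecules are sampled on a cubic lattice centered at the origin; the voxel
center of index `i` along an axis sits at `(i − (n−1)/2)·h`. The reference
scale is `n = 64`, `h = 0.5 Å` (a 32 Å box); development and tests run at
`n = 16` with the same step, which holds molecules up to roughly five heavy
atoms with a safety margin.

**Electron density.** The built-in density is promolecular: one isotropic
normalized Gaussian per atom, integrating exactly to the element's electron
count. The width is set so the Gaussian standard deviation equals the
element's covalent radius (`α = 1/(2 r_cov²)`; radii H 0.31, C 0.76, N 0.71,
O 0.66, F 0.57 Å). This reproduces qualitative molecular shape — heavier
atoms are taller, wider peaks — without any quantum chemistry; a quantum
backend can be swapped in as a callable `(molecule, spec) → grid`. Midpoint
sampling of the sharpest Gaussian (hydrogen, σ = 0.31 Å) at h = 0.5 Å incurs
an aliasing error well below 1%, which is why the grid integral conserves
the electron count to the 2% tolerance asserted in the tests.

**Electrostatic potential.** A softened Coulomb sum over per-atom partial
charges, `V(r) = Σ q_a/√(|r−r_a|² + ε²)`, with `ε = 0.5 Å` (one voxel) to
keep the field finite at the nuclei. Units are proportional e/Å. Default
charges are Gasteiger (electronegativity equalization) assigned through
RDKit when a SMILES is available; otherwise charges must be supplied.
`dilate_sparse` supports the alternative path where ESP arrives as sparse
point samples: every voxel within a configurable radius (default 2 voxels)
of a source takes its nearest source's value, ties resolved toward the
smallest point index.

## Neural models

No deep-learning framework is a dependency: the models run on `edgen.nn`, a
compact reverse-mode autodiff engine over numpy arrays (conv3d/conv2d by
kernel-tap matmuls, attention, layer norm, Adam). Dtypes follow the inputs,
so training runs in float32 while gradient checks run in float64.

**Density VAE.** Encoder: stride-2 kernel-3 conv stack (channels 8/16/32 at
test scale) to a dense `(µ, log σ²)`; decoder mirrors it with
nearest-neighbour upsampling followed by stride-1 convolutions (chosen over
transposed convolutions to avoid checkerboard artifacts at small grid
sizes) and a softplus head. Densities span orders of magnitude, so the
model works on `y = log(1 + ρ/ρ₀)` with `ρ₀ = 0.1 e/Å³`; the softplus output
maps back through `ρ = ρ₀(e^y − 1) ≥ 0`, so decoded densities are
non-negative by construction. Loss: voxelwise squared error on `y` plus
`β·KL`, `β = 10⁻⁴` annealed linearly over the first tenth of the steps.
Overfitting 16 fixture grids to voxelwise Pearson r ≥ 0.95 takes ~400
epochs at learning rate 2·10⁻³ (about a minute on one CPU).

**ESP net.** A fully convolutional residual stack (kernel 3, width 12,
two two-conv residual blocks at test scale) mapping transformed density to
signed potential. The input transform is `t(ρ) = log(tanh ρ + ε_t)` with
`ε_t = 10⁻⁴` added inside the log so the transform is defined at empty
voxels. Internally the model rescales `t` so empty space maps to 0 and
saturation to ~1, and its output head works in units of the training-target
standard deviation; both constants are stored in the checkpoint, so
predictions stay in physical units. Because tanh saturates near nuclear
peaks, element identity is encoded only weakly after the transform; dense
Gasteiger-charged multi-element targets therefore train to moderate
correlation, and the dedicated training set for this model is the
idealized-diatomic *dipole fixture* family (a small and a large peak with
opposite charges), on which the density unambiguously determines the sign
pattern and the overfit reaches r ≥ 0.9. Being fully convolutional, the
net accepts any cubic grid at least as large as its receptive field and is
translation-equivariant in its interior.

**Volume→SMILES transformer.** Standard pre-LN encoder–decoder (test scale:
d_model 64, 2 heads, 2 blocks, FFN 128). The molecule embedding flattens a
(n,n,n,C) volume into an (n, d_model) sequence by one of two strategies:
*squeeze* (filters-1 3D conv, drop the unit channel, filters-1 2D conv over
the remaining axes, linear projection to d_model) or *strided* (repeated
3D convs with strides (1,2,2) and d_model filters until the two trailing
spatial axes reach size 1 and are dropped). Learned positional embeddings
are added on both sides. Training is teacher-forced cross-entropy on
canonicalized, character-tokenized SMILES (bracket atoms are single
tokens; PAD/START/END/UNK specials; PAD is index 0 and excluded from the
loss). Greedy decoding is deterministic; sampling draws each token from
`softmax(logits/T)` and converges to greedy as `T → 0`. Disabling
cross-attention turns the decoder into a pure SMILES language model. Both
embedding strategies reach 100% sequence accuracy on the 32-pair overfit
corpus (within ~80–120 epochs).

## Guest optimization

Fitness functions over a latent `z`, with `ρ_g = decode(z)` and
`V_g = esp_net(ρ_g)`:

* size `S = Σ ρ_g` (maximize);
* overlap `O = Σ ρ_h ρ_g` (minimize);
* electrostatics `E = Σ V_h V_g` (minimize — the sign convention resolves
  to minimizing the signed product, i.e. maximizing opposite-sign
  complementarity; a config switch flips it).

The combined objective `J = λ·O/Σρ_h + (1−λ)·E/Σ|V_h|` normalizes both
terms by host magnitudes so λ is unit-free. Optimization is plain gradient
descent with a fixed step; gradients flow by autodiff through the decoder
(and the ESP net when λ < 1). Stage 1 ascends S only while some guest has
zero overlap (automatic trigger, overridable). Stage 2 descends J and stops
when the change of the population-mean J over a trailing 20-iteration
window falls below `10⁻³·|J|` at stage-2 start — referencing the *initial*
objective scale makes the rule terminate both on flat plateaus and on decay
toward zero, where a change relative to the current value would never
trigger.

At desk scale the demonstration host is analytic: a hollow Gaussian shell
(cavity explicitly zeroed) with a balanced ± pair of softened-Coulomb
charge rings at the cavity mouths, mimicking the dipolar carbonyl portals
of a cucurbituril; real hosts enter as XYZ+charges or cube files. The
demonstration run uses λ = 1 (pure steric fit), learning rate 50 on the
normalized objective, a 16-guest standard-normal initial population, and a
400-iteration cap: with an overfit toy decoder whose output magnitude is
unbounded, any λ < 1 lets the electrostatic term decrease without bound
(it is linear in the guest field) and the plateau rule then never fires;
at full scale a generator constrained to realistic molecules bounds that
term naturally. The electrostatic trace is still computed and reported
every iteration. Final volumes are decorated with their FCN-predicted ESP,
translated greedily, deduplicated by canonical SMILES, validity-flagged
(invalid strings are retained in the report, flagged) and ranked by J.

## Synthetic data

The fixture library enumerates four families — linear alkanes, primary and
secondary amines, ethers, and small (hetero)cycles — up to nine heavy atoms
of C/N/O/F, with 3D geometry from seeded ETKDG distance-geometry embedding
plus a short MMFF relaxation and Gasteiger charges. It emulates the scale
and composition of QM9-like corpora but not their conformational diversity,
electronic structure, or size distribution: passing overfit tests shows the
models and the optimization machinery function end-to-end, not that a
desk-scale model generalizes across chemical space. Sequence-accuracy
figures on this corpus are memorization checks by design; headline
generalization accuracies require full-scale training on a real corpus and
are out of scope here. The optional `qm9_ingest` path reads a local
QM9-format directory.

## Numerical choices and limitations

* Gaussian evaluation is cut off at 8σ; densities below that are exactly 0.
* Cube files are written with negative voxel counts marking Å units;
  readers accept Bohr (positive counts) and convert.
* Tokenizer ties and UNK policy: strict (error) for training corpora,
  permissive (UNK) when scoring generated text.
* Determinism: every stochastic step (init, shuffling, sampling,
  reparameterization) takes an explicit seed; two runs with one seed on one
  machine reproduce losses, traces and ranked lists bit-identically.
  Bit-level equality across BLAS builds is not guaranteed.
* The promolecular density ignores bonding charge redistribution, and
  Gasteiger charges are crude; both are adequate for shape/sign structure
  at desk scale, not for quantitative electrostatics.
* `similarity_profile` is O(n²) in set size; benchmark sets beyond ~10⁴
  molecules should be subsampled.
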