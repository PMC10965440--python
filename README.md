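# edgen

**Electron-density generative pipeline for host–guest binder discovery.**

`edgen` is for supramolecular and cheminformatics researchers who want to
search for guest molecules that fit a host's cavity using only the host's
structure. Molecules are represented as voxelized **electron densities (ED)**
decorated with **electrostatic potentials (ESP)**; a volumetric variational
autoencoder models this chemical space; candidate guests are found by
**gradient descent in the VAE latent space** against shape/charge
complementarity objectives; and the optimized 3D volumes are read out as
SMILES strings by an encoder–decoder **transformer**.

## The method

A molecule with atoms at positions `r_a` is sampled onto a centered cubic
grid (default 64 voxels per side, 0.5 Å step) as a promolecular density

    ρ(r) = Σ_a Z_a (α_a/π)^{3/2} exp(−α_a |r − r_a|²),

where `Z_a` is the electron count and the Gaussian width is matched to the
covalent radius, and a softened Coulomb potential over partial charges `q_a`

    V(r) = Σ_a q_a / sqrt(|r − r_a|² + ε²),   ε = 0.5 Å.

Any quantum-chemistry backend can replace either field through a plug-in
callable. Three models operate on these volumes:

* **density VAE** — 3D conv encoder to a latent Gaussian `(µ, σ)`, decoder
  back to a non-negative density (the *molecule generator*);
* **ESP net** — a fully convolutional network predicting `V` from `ρ`
  (inputs pass through `log(tanh(ρ) + ε_t)`), so electrostatics are
  available for decoded, atom-less guests;
* **vol2smiles transformer** — a molecule-embedding layer flattens the 3D
  volume into a 2D attention sequence (two strategies: `squeeze` and
  `strided`), and a standard encoder–decoder transformer emits SMILES
  tokens; the decoder alone acts as a GPT-style SMILES language model.

Guests for a host `(ρ_h, V_h)` are optimized from a random latent
population by plain gradient descent on

    J(z) = λ · Σ ρ_h ρ_g(z) / Σ ρ_h  +  (1−λ) · Σ V_h V_g(z) / Σ |V_h|,

with an optional first stage that grows guest size `S = Σ ρ_g` until every
guest overlaps the host. Iteration stops when the population-mean `J`
plateaus; final volumes are translated to SMILES, deduplicated,
validity-checked and ranked by `J`.

## Worked example

```python
import numpy as np
from edgen.voxelize import GridSpec, DensityGrid
from edgen.fixtures import (FixtureSpec, toy_molecule_library,
                            make_training_pairs, dipole_pairs, toy_host)
from edgen.density_vae import VaeTrainConfig, train_vae
from edgen.esp_net import EspTrainConfig, train_esp_net
from edgen.vol2smiles import XformerConfig, train_translator
from edgen.guest_optimizer import OptimizerConfig, optimize_guests

spec = GridSpec(n_voxels=16, step=0.5)              # desk-scale grid
mols = toy_molecule_library(FixtureSpec(family="all", size_range=(1, 5),
                                        count=32, seed=0, grid=spec))
pairs, _ = make_training_pairs(mols, spec, decorated=True)
grids = [DensityGrid(spec=spec, values=p[0][..., 0].astype(float))
         for p in pairs[:16]]

vae = train_vae(grids, VaeTrainConfig(epochs=400, lr=2e-3, beta=1e-4, seed=0))
esp = train_esp_net(dipole_pairs(8, spec, seed=0),
                    EspTrainConfig(epochs=200, lr=3e-3, width=12, depth=6))
xf = train_translator(pairs, XformerConfig(strategy="strided", epochs=80))

host = toy_host("hollow_shell", spec)               # analytic container host
cfg = OptimizerConfig(population=16, learning_rate=50.0, max_iter=400,
                      lam=1.0, seed=1)
results, trace = optimize_guests(host, vae, esp, xf, cfg)

o = np.median(trace.overlap, axis=1)
print(f"iterations {trace.n_iter}  plateaued {trace.plateaued}")
print(f"median overlap {o[0]:.3f} -> {o[-1]:.5f}")
print("top guest:", results[0].smiles, "valid:", results[0].valid)
```

Output (one CPU, a few minutes):

```
iterations 79  plateaued True
median overlap 0.950 -> 0.00349
top guest: C valid: True
```

The overlap between host and guest densities collapses by ~99.6% before the
plateau rule stops the descent; the shrunken optimized guests translate to
the smallest library molecule (methane), all passing chemical-validity
checks. At full scale (64³ grids, a QM9-trained generator) the same loop
ranks realistic candidate guests.

There is also a CLI mirroring the pipeline stages:

```bash
edgen fixtures --count 32 --grid 16 --seed 0 --out pairs.h5
edgen train-vae --dataset pairs.h5 --out vae.ckpt
edgen optimize --host-ed host_ed.cube --host-esp host_esp.cube \
      --vae vae.ckpt --esp-model esp.ckpt --translator xf.ckpt
```

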