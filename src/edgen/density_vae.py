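"""Variational autoencoder over voxelized electron densities.

The VAE is the molecule generator: the encoder maps an ED grid to the mean
and standard deviation of a diagonal-Gaussian latent, and the decoder maps
any latent vector back to a non-negative density grid.  Densities span
orders of magnitude, so the model works on log-compressed values
``y = log(1 + rho / rho0)``; the decoder ends in a softplus, which keeps the
decompressed density ``rho = rho0 * (exp(y) - 1)`` non-negative.

Loss: voxelwise squared error on the compressed field plus ``beta *
KL(N(mu, sigma) || N(0, I))``, with ``beta`` annealed linearly over the
first tenth of the training steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .voxelize import DensityGrid, GridSpec

__all__ = [
    "LatentState",
    "VaeModel",
    "compress_density",
    "decompress_density",
    "encode",
    "decode",
    "train_vae",
    "sample_prior",
]

RHO0 = 0.1  # e/A^3; density scale of the log compression


def compress_density(rho: np.ndarray, rho0: float = RHO0) -> np.ndarray:
    return np.log1p(np.asarray(rho) / rho0)


def decompress_density(y: np.ndarray, rho0: float = RHO0) -> np.ndarray:
    return rho0 * np.expm1(np.asarray(y))


@dataclass
class LatentState:
    """Encoder output: posterior mean/scale and one reparameterized sample."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).ravel()
        self.sigma = np.asarray(self.sigma, dtype=np.float64).ravel()
        self.z = np.asarray(self.z, dtype=np.float64).ravel()
        if not (self.mu.shape == self.sigma.shape == self.z.shape):
            raise ValueError("mu, sigma, z must share the latent dimension")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite latent sample")


class VaeModel(nn.Module):
    """Mirrored 3D conv encoder / upsample-conv decoder with a dense latent."""

    def __init__(self, spec: GridSpec, latent_dim: int = 32,
                 channels: tuple = (8, 16, 32), rho0: float = RHO0, seed: int = 0):
        rng = np.random.default_rng(seed)
        n = spec.n_voxels
        stages = len(channels)
        if n % (2 ** stages) != 0:
            raise ValueError(f"n_voxels {n} not divisible by 2^{stages}")
        self.spec = spec
        self.latent_dim = int(latent_dim)
        self.channels = tuple(channels)
        self.rho0 = rho0
        self.meta: dict = {"seed": seed, "epochs": 0, "loss_curve": []}
        self.enc_convs = []
        cin = 1
        for c in channels:
            self.enc_convs.append(nn.Conv3d(cin, c, k=3, rng=rng, stride=(2, 2, 2)))
            cin = c
        self.base = n // (2 ** stages)
        flat = channels[-1] * self.base ** 3
        self.fc_mu = nn.Linear(flat, latent_dim, rng)
        self.fc_logvar = nn.Linear(flat, latent_dim, rng)
        self.fc_dec = nn.Linear(latent_dim, flat, rng)
        self.dec_convs = []
        rev = list(channels[::-1])
        for cout in rev[1:] + [rev[-1]]:
            self.dec_convs.append(nn.Conv3d(cin, cout, k=3, rng=rng))
            cin = cout
        self.dec_out = nn.Conv3d(cin, 1, k=3, rng=rng)

    # forward pieces ---------------------------------------------------------
    def encode_tensors(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """x: (B, n, n, n, 1) compressed densities -> (mu, logvar)."""
        h = x
        for conv in self.enc_convs:
            h = conv(h).relu()
        h = h.reshape(h.shape[0], -1)
        return self.fc_mu(h), self.fc_logvar(h)

    def decode_tensor(self, z: nn.Tensor) -> nn.Tensor:
        """z: (B, latent_dim) -> (B, n, n, n, 1) compressed densities (>= 0)."""
        h = self.fc_dec(z).relu()
        c = self.channels[-1]
        h = h.reshape(h.shape[0], self.base, self.base, self.base, c)
        for conv in self.dec_convs:
            h = nn.upsample3d(h, 2)
            h = conv(h).relu()
        return self.dec_out(h).softplus()

    def descriptor(self) -> dict:
        return {"kind": "density_vae", "n_voxels": self.spec.n_voxels,
                "step": self.spec.step, "latent_dim": self.latent_dim,
                "channels": list(self.channels), "rho0": self.rho0}


def _grid_values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, DensityGrid) else np.asarray(grid)


def encode(grid, model: VaeModel, seed: int = 0) -> LatentState:
    """Encode a density grid; ``z`` is sampled as mu + sigma * N(0, I) with ``seed``."""
    vals = _grid_values(grid)
    n = model.spec.n_voxels
    if vals.shape != (n, n, n):
        raise ValueError(f"grid shape {vals.shape} does not match model ({n},{n},{n})")
    x = nn.Tensor(compress_density(vals, model.rho0)[None, ..., None].astype(np.float32))
    mu_t, logvar_t = model.encode_tensors(x)
    mu = mu_t.data[0].astype(np.float64)
    sigma = np.exp(0.5 * logvar_t.data[0].astype(np.float64))
    eps = np.random.default_rng(seed).standard_normal(model.latent_dim)
    return LatentState(mu=mu, sigma=sigma, z=mu + sigma * eps)


def decode(z: np.ndarray, model: VaeModel) -> DensityGrid:
    """Decode a latent vector into a non-negative density grid (deterministic)."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.shape[0] != model.latent_dim:
        raise ValueError(f"latent dim {z.shape[0]} != model latent_dim {model.latent_dim}")
    zt = nn.Tensor(z[None].astype(np.float32))
    y = model.decode_tensor(zt).data[0, ..., 0]
    return DensityGrid(spec=model.spec,
                       values=decompress_density(y.astype(np.float64), model.rho0))


@dataclass
class VaeTrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-3
    beta: float = 1e-3
    latent_dim: int = 32
    channels: tuple = (8, 16, 32)
    seed: int = 0


def train_vae(dataset, config: VaeTrainConfig | None = None,
              model: VaeModel | None = None) -> VaeModel:
    """Fit the VAE on a list of density grids (all sharing one GridSpec).

    Returns the trained model with ``meta['loss_curve']`` holding the
    per-epoch mean loss (reconstruction + beta * KL).
    """
    config = config or VaeTrainConfig()
    grids = [_grid_values(g) for g in dataset]
    if len(grids) == 0:
        raise ValueError("empty training dataset")
    spec = dataset[0].spec if isinstance(dataset[0], DensityGrid) else None
    if spec is None:
        n = grids[0].shape[0]
        spec = GridSpec(n_voxels=n, step=0.5)
    if model is None:
        model = VaeModel(spec, latent_dim=config.latent_dim,
                         channels=config.channels, seed=config.seed)
    x_all = np.stack([compress_density(g, model.rho0) for g in grids])[..., None]
    x_all = x_all.astype(np.float32)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    n_data = x_all.shape[0]
    steps_per_epoch = max(1, (n_data + config.batch_size - 1) // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    warm = max(1, total_steps // 10)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n_data)
        losses = []
        kls = []
        for b0 in range(0, n_data, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            x = nn.Tensor(x_all[idx])
            mu, logvar = model.encode_tensors(x)
            eps = nn.Tensor(rng.standard_normal(mu.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
            y = model.decode_tensor(z)
            diff = y - x
            rec = (diff * diff).sum() * (1.0 / len(idx))
            kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum() * (1.0 / len(idx))
            beta = config.beta * min(1.0, step / warm)
            loss = rec + kl * beta
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            kls.append(kl.item() * beta)
            step += 1
        model.meta["loss_curve"].append(float(np.mean(losses)))
        model.meta["kl_curve"] = model.meta.get("kl_curve", []) + [float(np.mean(kls))]
    model.meta["epochs"] += config.epochs
    model.meta["seed"] = config.seed
    return model


def load_vae_model(path) -> VaeModel:
    """Rebuild a VaeModel from a checkpoint archive written by ``model.save``."""
    import json
    import zipfile

    with zipfile.ZipFile(path) as zf:
        d = json.loads(zf.read("architecture.json"))
    model = VaeModel(GridSpec(n_voxels=d["n_voxels"], step=d["step"]),
                     latent_dim=d["latent_dim"], channels=tuple(d["channels"]),
                     rho0=d["rho0"])
    model.load_weights(path)
    model.meta["epochs"] = d.get("epochs", 1)
    return model


def sample_prior(n: int, latent_dim: int, dist: str = "normal",
                 bounds: float = 1.0, seed: int = 0) -> np.ndarray:
    """Draw ``n`` latent vectors: ``normal`` N(0,1) or ``uniform`` U(-bounds, bounds)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist == "normal":
        return rng.standard_normal((n, latent_dim))
    if dist == "uniform":
        if not np.isfinite(bounds) or bounds <= 0:
            raise ValueError(f"invalid uniform bounds {bounds}")
        return rng.uniform(-bounds, bounds, size=(n, latent_dim))
    raise ValueError(f"unknown prior distribution {dist!r}")
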