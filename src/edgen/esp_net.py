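"""Fully convolutional network predicting ESP grids from ED grids.

The optimizer needs electrostatics for decoded (virtual) guests that have no
atoms, so a small FCN learns the map from electron density to electrostatic
potential on voxelized training pairs.  The input density is first squashed
elementwise with ``t(x) = log(tanh(x) + eps_t)``, which compresses the
orders-of-magnitude dynamic range of the density while staying defined at
zero; the network itself is a stack of same-size kernel-3 3D convolutions
with residual connections and a linear (signed) output.  Being fully
convolutional, it accepts any cubic grid at least as large as its receptive
field and is translation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .voxelize import DensityGrid, ESPGrid, GridSpec

__all__ = [
    "EspModel",
    "ed_input_transform",
    "predict_esp",
    "train_esp_net",
    "EspTrainConfig",
]

EPS_T = 1e-4  # offset inside the log so t(0) is finite


def ed_input_transform(grid: np.ndarray, eps_t: float = EPS_T) -> np.ndarray:
    """Elementwise ``log(tanh(x) + eps_t)`` for non-negative densities.

    Monotone increasing, with ``t(0) = log(eps_t)`` and a ``log(1 + eps_t)``
    asymptote as the density saturates tanh.
    """
    x = np.asarray(grid, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("ed_input_transform expects a non-negative density grid")
    return np.log(np.tanh(x) + eps_t)


class _ResBlock(nn.Module):
    def __init__(self, width: int, rng):
        self.c1 = nn.Conv3d(width, width, k=3, rng=rng)
        self.c2 = nn.Conv3d(width, width, k=3, rng=rng)

    def __call__(self, h: nn.Tensor) -> nn.Tensor:
        return h + self.c2(self.c1(h).relu())


class EspModel(nn.Module):
    """Residual same-size conv stack: (B, n, n, n, 1) -> (B, n, n, n, 1).

    Internally the transformed density is rescaled so the empty-space value
    ``log(eps_t)`` maps to 0 and tanh saturation maps to ~1, and the output
    head works in units of ``out_scale`` (the training-target standard
    deviation); both are fixed, stored constants, so predictions are in the
    physical ESP units of the training pairs.
    """

    def __init__(self, spec: GridSpec, width: int = 8, depth: int = 4,
                 eps_t: float = EPS_T, out_scale: float = 1.0, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.width = int(width)
        self.depth = int(depth)
        self.eps_t = eps_t
        self.out_scale = float(out_scale)
        self.meta: dict = {"seed": seed, "epochs": 0, "loss_curve": []}
        self.conv_in = nn.Conv3d(1, width, k=3, rng=rng)
        n_blocks = max(1, (depth - 2) // 2)
        self.blocks = [_ResBlock(width, rng) for _ in range(n_blocks)]
        self.conv_out = nn.Conv3d(width, 1, k=3, rng=rng)

    @property
    def receptive_field(self) -> int:
        return 1 + 2 * (2 + 2 * len(self.blocks))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """x holds ``ed_input_transform`` values; returns ESP in physical units."""
        t0 = float(np.log(self.eps_t))
        h = x * (-1.0 / t0) + 1.0  # log(eps_t) -> 0, saturation -> ~1
        h = self.conv_in(h).relu()
        for blk in self.blocks:      # two-conv residual blocks
            h = blk(h)
        return self.conv_out(h) * self.out_scale

    def descriptor(self) -> dict:
        return {"kind": "esp_net", "n_voxels": self.spec.n_voxels,
                "step": self.spec.step, "width": self.width,
                "depth": self.depth, "eps_t": self.eps_t,
                "out_scale": self.out_scale}


def predict_esp(ed_grid, model: EspModel) -> ESPGrid:
    """Predict the signed ESP grid for a density grid (deterministic)."""
    vals = ed_grid.values if isinstance(ed_grid, DensityGrid) else np.asarray(ed_grid)
    if vals.ndim != 3 or len(set(vals.shape)) != 1:
        raise ValueError(f"expected a cubic 3D grid, got shape {vals.shape}")
    if vals.shape[0] < model.receptive_field:
        raise ValueError(f"grid side {vals.shape[0]} smaller than the receptive "
                         f"field {model.receptive_field}")
    x = nn.Tensor(ed_input_transform(vals, model.eps_t)[None, ..., None].astype(np.float32))
    out = model.forward(x).data[0, ..., 0].astype(np.float64)
    spec = ed_grid.spec if isinstance(ed_grid, DensityGrid) else \
        GridSpec(n_voxels=vals.shape[0], step=model.spec.step)
    return ESPGrid(spec=spec, values=out)


def load_esp_model(path) -> EspModel:
    """Rebuild an EspModel from a checkpoint archive written by ``model.save``."""
    import json
    import zipfile

    with zipfile.ZipFile(path) as zf:
        d = json.loads(zf.read("architecture.json"))
    model = EspModel(GridSpec(n_voxels=d["n_voxels"], step=d["step"]),
                     width=d["width"], depth=d["depth"], eps_t=d["eps_t"],
                     out_scale=d.get("out_scale", 1.0))
    model.load_weights(path)
    return model


@dataclass
class EspTrainConfig:
    epochs: int = 200
    batch_size: int = 4
    lr: float = 1e-3
    width: int = 8
    depth: int = 4
    seed: int = 0


def train_esp_net(pairs, config: EspTrainConfig | None = None,
                  model: EspModel | None = None) -> EspModel:
    """Fit the FCN on (ED grid, ESP grid) pairs by voxelwise mean squared error."""
    config = config or EspTrainConfig()
    if len(pairs) == 0:
        raise ValueError("empty training dataset")
    eds, esps = [], []
    spec = None
    for ed, esp in pairs:
        ev = ed.values if isinstance(ed, DensityGrid) else np.asarray(ed)
        pv = esp.values if isinstance(esp, ESPGrid) else np.asarray(esp)
        if spec is None and isinstance(ed, DensityGrid):
            spec = ed.spec
        eds.append(ev)
        esps.append(pv)
    if spec is None:
        spec = GridSpec(n_voxels=eds[0].shape[0], step=0.5)
    if model is None:
        scale = float(np.std(np.stack(esps))) or 1.0
        model = EspModel(spec, width=config.width, depth=config.depth,
                         out_scale=scale, seed=config.seed)
    x_all = np.stack([ed_input_transform(e, model.eps_t) for e in eds])[..., None]
    x_all = x_all.astype(np.float32)
    y_all = np.stack(esps)[..., None].astype(np.float32)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    n_data = x_all.shape[0]
    for epoch in range(config.epochs):
        # cosine decay to a tenth of the initial rate
        opt.lr = config.lr * (0.55 + 0.45 * np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(n_data)
        losses = []
        for b0 in range(0, n_data, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            x = nn.Tensor(x_all[idx])
            y = nn.Tensor(y_all[idx])
            pred = model.forward(x)
            diff = pred - y
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.meta["loss_curve"].append(float(np.mean(losses)))
    model.meta["epochs"] += config.epochs
    return model
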