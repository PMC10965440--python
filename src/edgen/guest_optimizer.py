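"""Latent-space gradient-descent optimization of guests for a target host.

Given a host's electron-density and electrostatic-potential grids, a
population of latent vectors is pushed through the VAE decoder and scored by
three differentiable fitness functions:

* size       ``S = sum_voxels rho_guest``             (maximize),
* overlap    ``O = sum_voxels rho_host * rho_guest``  (minimize),
* charge     ``E = sum_voxels V_host * V_guest``      (minimize; opposite-sign
  alignment of the potentials drives E negative).

Stage 1 grows the guests by gradient ascent on S until every guest overlaps
the host (skipped when the initial population already does).  Stage 2
descends the combined objective ``J = lam * O/sum(rho_host) +
(1 - lam) * E/sum(|V_host|)`` until the population-mean J plateaus.  Final
volumes are translated to SMILES by the transformer and ranked by J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .density_vae import VaeModel, decode, sample_prior
from .esp_net import EspModel
from .smiles_codec import is_valid, canonicalize
from .voxelize import DensityGrid, ESPGrid

__all__ = [
    "OptimizerConfig",
    "FitnessTrace",
    "GuestResult",
    "IdentityDecoder",
    "fitness_size",
    "fitness_overlap",
    "fitness_electrostatic",
    "combined_objective",
    "gradient_step",
    "optimize_guests",
]


@dataclass
class OptimizerConfig:
    population: int = 16
    learning_rate: float = 0.05
    max_iter: int = 500
    lam: float = 0.5                 # overlap vs electrostatics ratio in J
    stage1_max_iter: int = 100
    plateau_tol: float = 1e-3
    plateau_window: int = 20
    init_dist: str = "normal"
    init_bounds: float = 1.0
    momentum: float = 0.0            # 0 = plain gradient descent
    seed: int = 0
    force_stage1: bool | None = None  # None = automatic trigger
    flip_electrostatic_sign: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.plateau_window < 2:
            raise ValueError("plateau window must be >= 2")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class FitnessTrace:
    """Per-iteration, per-guest fitness history."""

    size: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    overlap: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    electro: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    combined: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    stage: list = field(default_factory=list)
    plateaued: bool = False

    def append(self, stage: int, s, o, e, j) -> None:
        row = lambda cur, v: np.vstack([cur, np.asarray(v)[None]]) if cur.size else np.asarray(v)[None]
        self.size = row(self.size, s)
        self.overlap = row(self.overlap, o)
        self.electro = row(self.electro, e)
        self.combined = row(self.combined, j)
        self.stage.append(stage)

    @property
    def n_iter(self) -> int:
        return len(self.stage)

    def to_frame(self):
        import pandas as pd

        rows = []
        for it in range(self.n_iter):
            for g in range(self.size.shape[1]):
                rows.append({"iteration": it, "stage": self.stage[it], "guest": g,
                             "size": self.size[it, g], "overlap": self.overlap[it, g],
                             "electrostatic": self.electro[it, g],
                             "combined": self.combined[it, g]})
        return pd.DataFrame(rows)


@dataclass
class GuestResult:
    rank: int
    guest: int
    smiles: str
    valid: bool
    reason: str
    duplicate_of: int | None
    size: float
    overlap: float
    electro: float
    combined: float
    status: str = "ok"


class IdentityDecoder:
    """Analytic harness: the latent vector *is* the flattened grid.

    Gives fitness functions and their gradients in closed form, for
    gradient-checking the autodiff path independent of any trained model.
    """

    def __init__(self, n: int = 8, step: float = 0.5):
        from .voxelize import GridSpec

        self.spec = GridSpec(n_voxels=n, step=step)
        self.latent_dim = n ** 3

    def decode_density_tensor(self, z: nn.Tensor) -> nn.Tensor:
        n = self.spec.n_voxels
        return z.reshape(z.shape[0], n, n, n)


def _decode_density(decoder, zt: nn.Tensor) -> nn.Tensor:
    """(B, latent) -> (B, n, n, n) guest density, differentiable."""
    if hasattr(decoder, "decode_density_tensor"):
        return decoder.decode_density_tensor(zt)
    if isinstance(decoder, VaeModel):
        y = decoder.decode_tensor(zt)  # compressed, (B,n,n,n,1)
        rho = (y.exp() - 1.0) * decoder.rho0
        n = decoder.spec.n_voxels
        return rho.reshape(zt.shape[0], n, n, n)
    raise TypeError(f"unsupported decoder {type(decoder).__name__}")


def _guest_esp_tensor(decoder, zt: nn.Tensor, esp_model) -> nn.Tensor:
    rho = _decode_density(decoder, zt)
    if esp_model is None:
        # harness mode: the decoded grid itself is taken as the guest ESP
        return rho
    if not isinstance(esp_model, EspModel):
        raise TypeError(f"unsupported ESP model {type(esp_model).__name__}")
    t = (rho.tanh() + esp_model.eps_t).log()  # differentiable input transform
    B = zt.shape[0]
    n = rho.shape[1]
    return esp_model.forward(t.reshape(B, n, n, n, 1)).reshape(B, n, n, n)


def _as_tensor_z(z) -> nn.Tensor:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[None]
    return nn.Tensor(z, requires_grad=True)


def _check_specs(decoder, grid) -> None:
    if grid is not None and hasattr(decoder, "spec") and grid.spec != decoder.spec:
        raise ValueError(f"grid spec {grid.spec} does not match decoder {decoder.spec}")


# ---------------------------------------------------------------------------
# fitness functions (scalar values; per-guest rows when z is a matrix)


def fitness_size(z, vae) -> float | np.ndarray:
    """S = sum of the decoded electron density over all voxels."""
    zt = nn.Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
    s = _decode_density(vae, zt).sum(axis=(1, 2, 3)).data
    return float(s[0]) if np.asarray(z).ndim == 1 else s


def fitness_overlap(z, vae, host_ed) -> float | np.ndarray:
    """O = sum of host-density * guest-density over all voxels (minimize)."""
    _check_specs(vae, host_ed if isinstance(host_ed, DensityGrid) else None)
    hv = host_ed.values if isinstance(host_ed, DensityGrid) else np.asarray(host_ed)
    zt = nn.Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
    rho = _decode_density(vae, zt).data
    o = (rho * hv[None]).sum(axis=(1, 2, 3))
    return float(o[0]) if np.asarray(z).ndim == 1 else o


def fitness_electrostatic(z, vae, esp_model, host_esp) -> float | np.ndarray:
    """E = sum of host-ESP * guest-ESP over all voxels (minimize)."""
    _check_specs(vae, host_esp if isinstance(host_esp, ESPGrid) else None)
    hv = host_esp.values if isinstance(host_esp, ESPGrid) else np.asarray(host_esp)
    zt = nn.Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
    gv = _guest_esp_tensor(vae, zt, esp_model).data
    e = (gv * hv[None]).sum(axis=(1, 2, 3))
    return float(e[0]) if np.asarray(z).ndim == 1 else e


def combined_objective(z, lam: float, vae, esp_model, host) -> float | np.ndarray:
    """J = lam * O / sum(rho_host) + (1 - lam) * E / sum(|V_host|) (minimize)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    host_ed, host_esp = host
    o = fitness_overlap(z, vae, host_ed)
    e = fitness_electrostatic(z, vae, esp_model, host_esp)
    hv = host_ed.values if isinstance(host_ed, DensityGrid) else np.asarray(host_ed)
    pv = host_esp.values if isinstance(host_esp, ESPGrid) else np.asarray(host_esp)
    o_scale = hv.sum()
    e_scale = np.abs(pv).sum()
    return lam * o / (o_scale if o_scale else 1.0) + \
        (1.0 - lam) * e / (e_scale if e_scale else 1.0)


def gradient_step(z, objective, eta: float, direction: str = "minimize"):
    """One plain gradient step on ``objective`` (a callable Tensor -> Tensor).

    ``z' = z - eta * grad`` for ``minimize``, ``z' = z + eta * grad`` for
    ``maximize``.  Gradients come from reverse-mode autodiff through the
    decoder (and the ESP net when the objective uses it).  A non-finite
    gradient raises ``FloatingPointError``.
    """
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"direction must be minimize or maximize, got {direction!r}")
    single = np.asarray(z).ndim == 1
    zt = _as_tensor_z(z)
    val = objective(zt)
    if val.data.size != 1:
        val = val.sum()
    val.backward()
    g = zt.grad
    if g is None or not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient")
    sign = -1.0 if direction == "minimize" else 1.0
    out = zt.data + sign * eta * g
    return out[0] if single else out


# ---------------------------------------------------------------------------
# the full pipeline


def optimize_guests(host, vae, esp_model, translator, cfg: OptimizerConfig | None = None
                    ) -> tuple[list[GuestResult], FitnessTrace]:
    """Run the two-stage latent optimization against a host and read out SMILES.

    ``host`` is a ``(DensityGrid, ESPGrid)`` pair on the decoder's GridSpec.
    Returns guests ranked by the combined objective J (duplicates and
    invalid translations flagged, not dropped) plus the full fitness trace.
    """
    cfg = cfg or OptimizerConfig()
    host_ed, host_esp = host
    _check_specs(vae, host_ed if isinstance(host_ed, DensityGrid) else None)
    _check_specs(vae, host_esp if isinstance(host_esp, ESPGrid) else None)
    if isinstance(vae, VaeModel) and not vae.meta.get("epochs"):
        raise ValueError("VAE decoder is untrained")
    hv = host_ed.values if isinstance(host_ed, DensityGrid) else np.asarray(host_ed)
    pv = host_esp.values if isinstance(host_esp, ESPGrid) else np.asarray(host_esp)
    sign_e = -1.0 if cfg.flip_electrostatic_sign else 1.0
    o_scale = hv.sum() or 1.0
    e_scale = np.abs(pv).sum() or 1.0

    zs = sample_prior(cfg.population, vae.latent_dim, dist=cfg.init_dist,
                      bounds=cfg.init_bounds, seed=cfg.seed)
    trace = FitnessTrace()
    active = np.ones(cfg.population, dtype=bool)
    status = ["ok"] * cfg.population

    def forward_scores(with_grad: bool):
        """One decoder (+ ESP net) pass giving S, O, E, J per guest as Tensors."""
        zt = nn.Tensor(zs, requires_grad=with_grad)
        rho = _decode_density(vae, zt)
        s = rho.sum(axis=(1, 2, 3))
        o = (rho * nn.Tensor(hv[None])).sum(axis=(1, 2, 3))
        if esp_model is None:
            gv = rho
        else:
            rho_e = rho if cfg.lam < 1.0 else nn.Tensor(rho.data)
            t = (rho_e.tanh() + esp_model.eps_t).log()
            n = rho.shape[1]
            gv = esp_model.forward(t.reshape(zt.shape[0], n, n, n, 1)
                                   ).reshape(zt.shape[0], n, n, n)
        e = (gv * nn.Tensor(pv[None])).sum(axis=(1, 2, 3)) * sign_e
        j = o * (cfg.lam / o_scale) + e * ((1.0 - cfg.lam) / e_scale)
        return zt, s, o, e, j

    velocity = np.zeros_like(zs)

    def step_from(zt: nn.Tensor, objective_sum: nn.Tensor, direction: str) -> None:
        """Gradient step on the already-built graph; frozen guests keep their z."""
        nonlocal zs, velocity
        objective_sum.backward()
        g = zt.grad
        if g is None or not np.all(np.isfinite(g)):
            bad = ~np.all(np.isfinite(g), axis=1) if g is not None \
                else np.ones(cfg.population, dtype=bool)
            for gi in np.nonzero(bad)[0]:
                if active[gi]:
                    active[gi] = False
                    status[gi] = "aborted: non-finite gradient"
            g = np.where(np.isfinite(g), g, 0.0) if g is not None else np.zeros_like(zs)
        sign = -1.0 if direction == "minimize" else 1.0
        velocity = cfg.momentum * velocity + (sign * cfg.learning_rate) * g
        zs = zs + velocity * active[:, None]

    # stage 1 — size growth until every guest overlaps the host
    zt, s, o, e, j = forward_scores(with_grad=True)
    trace.append(1, s.data, o.data, e.data, j.data)
    run_stage1 = cfg.force_stage1 if cfg.force_stage1 is not None \
        else bool(np.any(o.data <= 0))
    it1 = 0
    while run_stage1 and np.any(o.data[active] <= 0) and it1 < cfg.stage1_max_iter:
        step_from(zt, s.sum(), "maximize")
        zt, s, o, e, j = forward_scores(with_grad=True)
        trace.append(1, s.data, o.data, e.data, j.data)
        it1 += 1

    # stage 2 — combined objective descent with plateau stopping: the change
    # of the population-mean J over a trailing window must fall below
    # tol * |J at stage-2 start| (so decay-to-zero also terminates)
    mean_j: list[float] = [float(np.mean(j.data))]
    j_ref = abs(mean_j[0]) + 1e-12
    plateaued = False
    for _ in range(cfg.max_iter):
        step_from(zt, j.sum(), "minimize")
        zt, s, o, e, j = forward_scores(with_grad=True)
        trace.append(2, s.data, o.data, e.data, j.data)
        mean_j.append(float(np.mean(j.data)))
        w = cfg.plateau_window
        if len(mean_j) > w:
            window = mean_j[-w:]
            if (max(window) - min(window)) / j_ref < cfg.plateau_tol:
                plateaued = True
                break
    trace.plateaued = plateaued

    # read out: translate, flag validity and duplicates, rank by J
    from .vol2smiles import translate as _translate

    _, s_t, o_t, e_t, j_t = forward_scores(with_grad=False)
    s, o, e, j = s_t.data, o_t.data, e_t.data, j_t.data
    smiles = []
    for g in range(cfg.population):
        if translator is None or not isinstance(vae, VaeModel):
            smiles.append("")
            continue
        vol = decode(zs[g], vae)
        if translator.in_channels == 2:
            # decorate the decoded guest with its FCN-predicted potential
            from .esp_net import predict_esp

            gv = predict_esp(vol, esp_model).values
            arr = np.stack([vol.values, gv], axis=-1)
        else:
            arr = vol.values
        smiles.append(_translate(arr, translator))
    order = np.argsort(j, kind="stable")
    results: list[GuestResult] = []
    seen: dict[str, int] = {}
    for rank, g in enumerate(order):
        smi = smiles[g]
        ok, reason = is_valid(smi) if smi else (False, "no translator")
        canon = canonicalize(smi) if ok else None
        dup = seen.get(canon) if canon is not None else None
        if canon is not None and canon not in seen:
            seen[canon] = int(g)
        results.append(GuestResult(
            rank=rank, guest=int(g), smiles=smi, valid=ok, reason=reason,
            duplicate_of=dup, size=float(s[g]), overlap=float(o[g]),
            electro=float(e[g]), combined=float(j[g]), status=status[g]))
    return results, trace
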