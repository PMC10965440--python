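"""Fitness oracles, gradient correctness, combined objective, pipeline rules."""

import numpy as np
import pytest

from edgen import nn
from edgen.guest_optimizer import (IdentityDecoder, OptimizerConfig,
                                   combined_objective, fitness_electrostatic,
                                   fitness_overlap, fitness_size, gradient_step,
                                   optimize_guests)
from edgen.voxelize import DensityGrid, ESPGrid


def brute_force_sum(grid):
    total = 0.0
    n = grid.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                total += grid[i, j, k]
    return total


def brute_force_product_sum(a, b):
    total = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                total += a[i, j, k] * b[i, j, k]
    return total


class TestFitnessOracles:
    def test_size_equals_sum_of_latent_for_identity_decoder(self):
        dec = IdentityDecoder(n=8)
        z = np.random.default_rng(0).uniform(0, 1, 512)
        assert fitness_size(z, dec) == pytest.approx(z.sum(), rel=1e-9)

    def test_size_matches_triple_loop(self):
        dec = IdentityDecoder(n=8)
        z = np.random.default_rng(1).uniform(0, 1, 512)
        s = fitness_size(z, dec)
        assert s == pytest.approx(brute_force_sum(z.reshape(8, 8, 8)), rel=1e-9)

    def test_overlap_disjoint_supports_is_zero(self):
        dec = IdentityDecoder(n=8)
        z = np.zeros(512)
        z[:256] = 1.0  # guest occupies lower half
        host = np.zeros((8, 8, 8))
        host[4:] = 1.0  # host occupies upper half
        assert fitness_overlap(z, dec, host) == 0.0

    def test_overlap_indicator_closed_form(self):
        dec = IdentityDecoder(n=8)
        ind = np.zeros((8, 8, 8))
        ind[2:4, 2:4, 2:4] = 1.0  # k = 8 voxels
        assert fitness_overlap(ind.ravel(), dec, ind) == pytest.approx(8.0)

    def test_overlap_matches_triple_loop_random(self):
        rng = np.random.default_rng(2)
        dec = IdentityDecoder(n=8)
        z = rng.uniform(0, 1, 512)
        host = rng.uniform(0, 1, (8, 8, 8))
        assert fitness_overlap(z, dec, host) == pytest.approx(
            brute_force_product_sum(z.reshape(8, 8, 8), host), rel=1e-9)

    def test_electrostatic_perfect_complement(self):
        dec = IdentityDecoder(n=8)
        rng = np.random.default_rng(3)
        host_esp = rng.standard_normal((8, 8, 8))
        z = (-host_esp).ravel()  # guest ESP = -host ESP (esp_model None harness)
        e = fitness_electrostatic(z, dec, None, host_esp)
        assert e == pytest.approx(-(host_esp ** 2).sum(), rel=1e-9)
        assert e < 0

    def test_electrostatic_zero_guest(self):
        dec = IdentityDecoder(n=8)
        assert fitness_electrostatic(np.zeros(512), dec, None,
                                     np.ones((8, 8, 8))) == 0.0

    def test_electrostatic_matches_triple_loop_random(self):
        rng = np.random.default_rng(4)
        dec = IdentityDecoder(n=8)
        z = rng.standard_normal(512)
        host_esp = rng.standard_normal((8, 8, 8))
        assert fitness_electrostatic(z, dec, None, host_esp) == pytest.approx(
            brute_force_product_sum(z.reshape(8, 8, 8), host_esp), rel=1e-9)


class TestCombinedObjective:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.dec = IdentityDecoder(n=8)
        self.z = rng.uniform(0, 1, 512)
        self.host = (rng.uniform(0, 1, (8, 8, 8)), rng.standard_normal((8, 8, 8)))

    def test_lambda_one_ignores_electrostatics(self):
        j1 = combined_objective(self.z, 1.0, self.dec, None, self.host)
        perturbed = (self.host[0], self.host[1] * 10.0)
        j2 = combined_objective(self.z, 1.0, self.dec, None, perturbed)
        # E normalization changes but the lam=1 objective only weights overlap
        assert j1 == pytest.approx(j2)

    def test_lambda_zero_ignores_overlap(self):
        j1 = combined_objective(self.z, 0.0, self.dec, None, self.host)
        perturbed = (self.host[0] * 10.0, self.host[1])
        j2 = combined_objective(self.z, 0.0, self.dec, None, perturbed)
        assert j1 == pytest.approx(j2)

    def test_linear_in_lambda(self):
        j = [combined_objective(self.z, lam, self.dec, None, self.host)
             for lam in (0.0, 0.5, 1.0)]
        assert j[1] == pytest.approx(0.5 * (j[0] + j[2]), rel=1e-9)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lam"):
            combined_objective(self.z, 1.5, self.dec, None, self.host)


class TestGradientStep:
    def test_eta_zero_identity(self):
        z = np.random.default_rng(6).standard_normal(20)
        z2 = gradient_step(z, lambda zt: (zt * zt).sum(), eta=0.0)
        np.testing.assert_array_equal(z, z2)

    def test_quadratic_harness_converges_to_optimum(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(16)
        z = rng.standard_normal(16)
        objective = lambda zt: -((zt - nn.Tensor(a)) ** 2).sum()  # maximize
        for _ in range(500):
            z = gradient_step(z, objective, eta=0.1, direction="maximize")
            if np.linalg.norm(z - a) < 1e-3:
                break
        assert np.linalg.norm(z - a) < 1e-3

    def test_autodiff_matches_finite_differences_through_identity_decoder(self):
        rng = np.random.default_rng(8)
        dec = IdentityDecoder(n=4)
        host = rng.uniform(0, 1, (4, 4, 4))
        z0 = rng.uniform(0.1, 1, 64)

        def objective(zt):
            from edgen.guest_optimizer import _decode_density
            rho = _decode_density(dec, zt)
            return (rho * nn.Tensor(host[None])).sum()

        zt = nn.Tensor(z0[None], requires_grad=True)
        objective(zt).backward()
        grad = zt.grad[0]
        eps = 1e-6
        for idx in rng.integers(0, 64, 10):
            zp, zm = z0.copy(), z0.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (objective(nn.Tensor(zp[None])).item()
                  - objective(nn.Tensor(zm[None])).item()) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_single_objective_descent_monotone_small_eta(self):
        rng = np.random.default_rng(9)
        dec = IdentityDecoder(n=4)
        host = rng.uniform(0, 1, (4, 4, 4))
        z = rng.uniform(0.5, 1.5, 64)
        prev = fitness_overlap(z, dec, host)
        for _ in range(50):
            z = gradient_step(
                z, lambda zt: (dec.decode_density_tensor(zt)
                               * nn.Tensor(host[None])).sum(),
                eta=0.01, direction="minimize")
            cur = fitness_overlap(z, dec, host)
            assert cur <= prev + 1e-12
            prev = cur

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            gradient_step(np.zeros(4), lambda zt: zt.sum(), 0.1, "sideways")

    def test_nonfinite_gradient_raises(self):
        z = np.zeros(4)
        with pytest.raises(FloatingPointError):
            gradient_step(z, lambda zt: (zt ** 0.5).sum(), 0.1)


class TestPipelineRules:
    def test_untrained_vae_rejected(self, host16):
        from edgen.density_vae import VaeModel
        from edgen.voxelize import GridSpec

        fresh = VaeModel(GridSpec(16, 0.5), latent_dim=8, channels=(4, 8), seed=0)
        with pytest.raises(ValueError, match="untrained"):
            optimize_guests(host16, fresh, None, None, OptimizerConfig())

    def test_spec_mismatch_rejected(self, trained_vae):
        from edgen.voxelize import GridSpec

        bad = GridSpec(n_voxels=8, step=0.5)
        host = (DensityGrid(spec=bad, values=np.zeros((8,) * 3)),
                ESPGrid(spec=bad, values=np.zeros((8,) * 3)))
        with pytest.raises(ValueError, match="spec"):
            optimize_guests(host, trained_vae, None, None, OptimizerConfig())

    @pytest.mark.parametrize("kw", [
        {"learning_rate": 0.0}, {"lam": -0.1}, {"plateau_window": 1},
    ])
    def test_config_invariants(self, kw):
        with pytest.raises(ValueError):
            OptimizerConfig(**kw)

    def test_stage1_triggered_when_no_initial_overlap(self):
        # a decoder whose initial guests are empty must grow through stage 1
        dec = IdentityDecoder(n=4)
        dec.meta = {"epochs": 1}
        host_vals = np.ones((4, 4, 4))
        host = (DensityGrid(spec=dec.spec, values=host_vals),
                ESPGrid(spec=dec.spec, values=np.zeros((4, 4, 4))))
        cfg = OptimizerConfig(population=4, learning_rate=0.1, max_iter=5,
                              stage1_max_iter=10, lam=1.0, seed=0,
                              init_dist="uniform", init_bounds=1e-12)
        _, trace = optimize_guests(host, dec, None, None, cfg)
        assert trace.stage.count(1) > 1  # stage-1 iterations actually ran
        last_stage1 = max(i for i, s in enumerate(trace.stage) if s == 1)
        assert np.all(trace.overlap[last_stage1] > 0)

    def test_plateau_rule_satisfied_at_termination(self, optimization_run):
        trace = optimization_run["trace"]
        cfg = optimization_run["cfg"]
        assert trace.plateaued
        last_stage1 = max(i for i, s in enumerate(trace.stage) if s == 1)
        stage2 = [i for i, s in enumerate(trace.stage) if s == 2]
        mean_j = trace.combined[stage2].mean(axis=1)
        window = mean_j[-cfg.plateau_window:]
        ref = abs(trace.combined[last_stage1].mean()) + 1e-12
        assert (window.max() - window.min()) / ref < cfg.plateau_tol
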