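"""Noise schedules, forward/reverse processes, losses, size sampling."""

import numpy as np
import pytest

from keydiff.autodiff import Tensor
from keydiff.core import AtomCloud, LIGAND_VOCAB
from keydiff.diffusion import (
    DiffusionState,
    NoisePrediction,
    NoiseSchedule,
    denoising_loss,
    diffuse_values,
    forward_diffuse,
    make_schedule,
    reverse_step,
    sample_ligand_size,
)


def schedule_with_alpha(alpha_mid: float) -> NoiseSchedule:
    """T=2 schedule whose middle step has exactly the requested α."""
    alpha = np.array([1.0, alpha_mid, 1e-4])
    return NoiseSchedule(alpha=alpha, sigma=np.sqrt(1 - alpha**2))


class TestSchedule:
    @pytest.mark.parametrize("kind", ["polynomial", "cosine"])
    @pytest.mark.parametrize("T", [1, 10, 1000])
    def test_variance_preserving_and_endpoints(self, kind, T):
        s = make_schedule(T, kind)
        assert np.abs(s.alpha**2 + s.sigma**2 - 1).max() < 1e-9
        assert s.alpha[0] >= 0.999
        assert s.alpha[-1] <= 1e-3
        assert np.all(np.diff(s.alpha) <= 0)

    def test_polynomial_alpha_strictly_decreasing(self):
        s = make_schedule(1000, "polynomial")
        assert np.all(np.diff(s.alpha) < 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(10, "linear-ish")

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):  # not variance preserving
            NoiseSchedule(alpha=np.array([1.0, 0.5, 0.0]), sigma=np.array([0.0, 0.5, 1.0]))
        with pytest.raises(ValueError):  # increasing α
            a = np.array([0.9995, 0.5, 0.7, 1e-4])
            NoiseSchedule(alpha=a, sigma=np.sqrt(1 - a**2))


class TestForward:
    def test_no_noise_endpoint_returns_input(self, rng):
        s = schedule_with_alpha(0.6)
        x0 = rng.normal(size=(5, 3))
        xt, _ = diffuse_values(x0, 0, s, rng)
        assert np.allclose(xt, s.alpha[0] * x0)

    def test_pure_noise_endpoint_is_epsilon(self, rng):
        alpha = np.array([np.sqrt(1 - 1e-9), 0.5, 0.0])
        s = NoiseSchedule(alpha=alpha, sigma=np.sqrt(1 - alpha**2))
        xt, eps = diffuse_values(np.ones((4, 3)), 2, s, rng)
        assert np.allclose(xt, eps)

    def test_scalar_probe_matches_gaussian_moments(self):
        """x0=1 at α=0.6: 20,000 draws match mean 0.6 / variance 0.64 within 3 SE."""
        rng = np.random.default_rng(777)
        s = schedule_with_alpha(0.6)
        draws, _ = diffuse_values(np.ones(20_000), 1, s, rng)
        n = draws.size
        se_mean = 0.8 / np.sqrt(n)
        assert abs(draws.mean() - 0.6) < 3 * se_mean
        se_var = 0.64 * np.sqrt(2.0 / (n - 1))
        assert abs(draws.var() - 0.64) < 3 * se_var

    def test_forward_diffuse_cloud_shapes_and_noise_return(self, toy_complex, rng):
        s = make_schedule(50)
        z, eps = forward_diffuse(toy_complex.ligand, 25, s, rng)
        assert z.positions.shape == toy_complex.ligand.positions.shape
        assert np.allclose(
            z.positions,
            s.alpha[25] * toy_complex.ligand.positions + s.sigma[25] * eps.eps_x,
        )


class TestLoss:
    def test_exact_match_gives_zero(self, rng):
        e = NoisePrediction(rng.normal(size=(3, 3)), rng.normal(size=(3, 4)))
        assert denoising_loss(e, e) == 0.0

    def test_single_node_positions_mean_convention(self):
        e = NoisePrediction(np.array([[1.0, 2.0, 2.0]]))
        z = NoisePrediction(np.zeros((1, 3)))
        assert denoising_loss(e, z) == pytest.approx(3.0)

    def test_matches_direct_formula(self, rng):
        a = NoisePrediction(rng.normal(size=(6, 3)), rng.normal(size=(6, 4)))
        b = NoisePrediction(rng.normal(size=(6, 3)), rng.normal(size=(6, 4)))
        expected = (
            np.sum((a.eps_x - b.eps_x) ** 2) + np.sum((a.eps_s - b.eps_s) ** 2)
        ) / (6 * 7)
        assert denoising_loss(a, b) == pytest.approx(expected)

    def test_returns_tensor_when_inputs_carry_tape(self, rng):
        pred = NoisePrediction(Tensor(rng.normal(size=(2, 3)), requires_grad=True))
        target = NoisePrediction(rng.normal(size=(2, 3)))
        out = denoising_loss(target, pred)
        assert isinstance(out, Tensor)
        out.backward()
        assert pred.eps_x.grad is not None


class TestReverse:
    def test_posterior_moments_with_zero_noise_prediction(self):
        """ε̂ ≡ 0 oracle: empirical mean/variance of z_{t−1} match the
        closed-form Gaussian posterior within 3 SE over 10,000 draws."""
        rng = np.random.default_rng(321)
        s = make_schedule(10)
        t = 5
        zt = DiffusionState(np.array([[0.7, -0.3, 0.2]]), np.zeros((1, 1)), t)
        eh = NoisePrediction(np.zeros((1, 3)), np.zeros((1, 1)))
        draws = np.array(
            [reverse_step(zt, eh, s, rng).positions[0] for _ in range(10_000)]
        )
        a_ts = s.alpha[t] / s.alpha[t - 1]
        var_ts = s.sigma[t] ** 2 - a_ts**2 * s.sigma[t - 1] ** 2
        mean = zt.positions[0] / a_ts
        var = var_ts * s.sigma[t - 1] ** 2 / s.sigma[t] ** 2
        n = draws.shape[0]
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * np.sqrt(var / n))
        assert np.all(np.abs(draws.var(axis=0) - var) < 3 * var * np.sqrt(2 / (n - 1)))

    def test_final_step_is_deterministic(self, rng):
        s = make_schedule(10)
        zt = DiffusionState(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)), 1)
        eh = NoisePrediction(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))
        out1 = reverse_step(zt, eh, s, np.random.default_rng(1))
        out2 = reverse_step(zt, eh, s, np.random.default_rng(2))
        assert np.array_equal(out1.positions, out2.positions)
        assert out1.t == 0

    def test_perfect_epsilon_chain_recovers_clean_state(self):
        """Chaining all reverse steps with the oracle ε̂ implied by the true
        z_0 recovers z_0 within accumulated float tolerance."""
        rng = np.random.default_rng(9)
        s = make_schedule(150)
        x0 = np.array([[0.8, -1.2, 0.4]])
        s0 = np.array([[1.0, 0.0, 0.0, 0.0]])
        z = DiffusionState(rng.standard_normal((1, 3)), rng.standard_normal((1, 4)), 150)
        for t in range(150, 0, -1):
            ex = (z.positions - s.alpha[t] * x0) / s.sigma[t]
            es = (z.features - s.alpha[t] * s0) / s.sigma[t]
            z = reverse_step(z, NoisePrediction(ex, es), s, rng)
        assert np.abs(z.positions - x0).max() < 1e-3
        assert np.abs(z.features - s0).max() < 1e-3

    def test_rejects_t_zero(self, rng):
        s = make_schedule(5)
        with pytest.raises(ValueError):
            reverse_step(
                DiffusionState(np.zeros((1, 3)), np.zeros((1, 2)), 0),
                NoisePrediction(np.zeros((1, 3)), np.zeros((1, 2))),
                s,
                rng,
            )


class TestSizeSampler:
    def test_degenerate_histogram_is_constant(self, rng):
        assert all(sample_ligand_size(60, {8: 1.0}, rng) == 8 for _ in range(20))

    def test_two_bin_frequencies(self):
        rng = np.random.default_rng(5)
        draws = np.array([sample_ligand_size(60, {5: 0.5, 10: 0.5}, rng) for _ in range(10_000)])
        assert abs(np.mean(draws == 5) - 0.5) < 0.02
        assert abs(np.mean(draws == 10) - 0.5) < 0.02

    def test_pocket_size_conditioning_and_floor(self, rng):
        bins = [(0, 50, {4: 1.0}), (50, 1000, {12: 1.0})]
        assert sample_ligand_size(30, bins, rng) == 4
        assert sample_ligand_size(400, bins, rng) == 12
        assert sample_ligand_size(10, {0: 1.0}, rng) == 1  # floored at one atom

    def test_empty_histogram_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_ligand_size(10, {}, rng)
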