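import numpy as np
import pytest
import scipy.fft as fft

import holopnp as hp
from holopnp import generator as gen
from holopnp.autodiff import Tensor
from holopnp.generator import GeneratorSpec
from holopnp.pnp import (ADMMConfig, check_convergence, hologram_fidelity,
                         initialize, loss, make_prior, reconstruct,
                         update_multiplier, update_object, update_theta)

from conftest import hologram_of
from oracles import scalar_multiplier_updates, scalar_object_updates


@pytest.fixture(scope="module")
def small_setup():
    ph = hp.make_cell_phantom(32, 1.67, 1.0, seed=2)
    holo = hologram_of(ph)
    return ph, holo


class TestMakePrior:
    def test_none_mode_disables_prior(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "none", 1, 1.0)
        assert prior.alpha_disabled
        assert np.all(prior.phi_tau == 0.0)

    def test_upsample_shapes(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "bicubic", 2, 1.0)
        assert prior.phi_tau.shape == (64, 64)
        assert prior.I_tau.shape == (64, 64)
        assert prior.pitch == pytest.approx(holo.pitch / 2)

    def test_constant_prior_amplitude(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "tv", 1, 1.0)
        amps = np.abs(prior.u_tau)
        np.testing.assert_allclose(amps, amps.flat[0], rtol=1e-12)

    def test_file_mode_shape_mismatch_rejected(self, small_setup):
        _, holo = small_setup
        with pytest.raises(ValueError, match="shape"):
            make_prior(holo, "file", 2, 1.0, prior_phase=np.zeros((32, 32)))

    def test_file_mode_requires_phase(self, small_setup):
        _, holo = small_setup
        with pytest.raises(ValueError, match="requires"):
            make_prior(holo, "file", 1, 1.0)


class TestInitialize:
    def test_multiplier_zero_and_epoch_zero(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "none", 1, 1.0)
        state = initialize(holo, prior, GeneratorSpec(seed=0), ADMMConfig())
        assert np.all(state.t == 0.0)
        assert state.k == 0

    def test_same_seed_identical_initial_loss(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "tv", 1, 1.0)
        vals = []
        for _ in range(2):
            state = initialize(holo, prior, GeneratorSpec(seed=3), ADMMConfig())
            _, breakdown = loss(state.params, state.uo, state.t, prior,
                                ADMMConfig(), state.gen_spec, state.kernel)
            vals.append(breakdown["total"])
        assert vals[0] == vals[1]


class TestFidelityNode:
    def test_single_pixel_closed_form(self):
        # 8x8 constant field, unit-modulus kernel: |U|^2 == |u|^2
        u = np.full((8, 8), 1.3 - 0.4j)
        I = np.full((8, 8), 0.9)
        kernel = np.exp(1j * 0.7) * np.ones((8, 8))
        x = Tensor(np.stack([u.real, u.imag]), requires_grad=True)
        out = hologram_fidelity(x, I, kernel)
        expected = 0.5 * 64 * ((1.3**2 + 0.4**2) - 0.9) ** 2
        assert float(out.data) == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        I = rng.random((8, 8)) + 0.5
        fy = fft.fftfreq(8)[:, None]
        fx = fft.fftfreq(8)[None, :]
        kernel = np.exp(1j * 2 * np.pi * 30 * np.sqrt(
            np.clip(1 - 0.3**2 * (fx**2 + fy**2), 0, None)))
        x = Tensor(np.stack([u.real, u.imag]), requires_grad=True)
        hologram_fidelity(x, I, kernel).backward()
        for idx in [(0, 2, 3), (1, 5, 7), (0, 0, 0)]:
            eps = 1e-6
            x.data[idx] += eps
            fp = float(hologram_fidelity(Tensor(x.data), I, kernel).data)
            x.data[idx] -= 2 * eps
            fm = float(hologram_fidelity(Tensor(x.data), I, kernel).data)
            x.data[idx] += eps
            assert x.grad[idx] == pytest.approx((fp - fm) / (2 * eps),
                                                rel=1e-5, abs=1e-7)


class TestLossBreakdown:
    def test_terms_match_independent_recomputation(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "tv", 1, 1.0)
        config = ADMMConfig(alpha=0.7, beta=0.9)
        spec = GeneratorSpec(depth=2, base_channels=4, seed=1)
        state = initialize(holo, prior, spec, config)
        state.t = 0.1 * (state.uo - state.uo.mean())
        total, br = loss(state.params, state.uo, state.t, prior, config,
                         spec, state.kernel)
        R2 = gen.generate(state.params, spec,
                          np.stack([state.uo.real, state.uo.imag]).astype(np.float32))
        R = R2[0].astype(np.float64) + 1j * R2[1].astype(np.float64)
        U = fft.ifft2(fft.fft2(R) * state.kernel)
        fid = 0.5 * np.sum((np.abs(U) ** 2 - prior.I_tau) ** 2)
        prox = 0.5 * config.beta * np.sum(np.abs(state.uo - R - state.t) ** 2)
        pri = 0.5 * config.alpha * np.real(np.vdot(state.uo, state.uo - prior.u_tau))
        assert br["fidelity"] == pytest.approx(fid, rel=1e-6)
        assert br["proximity"] == pytest.approx(prox, rel=1e-5)
        assert br["prior"] == pytest.approx(pri, rel=1e-12)
        assert float(total.data) == pytest.approx(fid + prox + pri, rel=1e-5)

    def test_alpha_beta_zero_reduces_to_data_fidelity(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "none", 1, 1.0)
        config = ADMMConfig(alpha=0.0, beta=1e-300)
        spec = GeneratorSpec(depth=2, base_channels=4, seed=1)
        state = initialize(holo, prior, spec, config)
        _, br = loss(state.params, state.uo, state.t, prior, config, spec,
                     state.kernel)
        assert br["prior"] == 0.0
        assert br["proximity"] == pytest.approx(0.0, abs=1e-250)


class TestObjectUpdate:
    def _state(self, uo, R, t):
        state = hp.ADMMState(uo=np.array(uo, complex).reshape(1, 1),
                             t=np.array(t, complex).reshape(1, 1),
                             params={}, gen_spec=GeneratorSpec(),
                             kernel=np.ones((1, 1), complex))
        state.R = np.array(R, complex).reshape(1, 1)
        return state

    def test_zero_weights_leave_object_unchanged(self):
        prior = hp.PriorBundle(np.zeros((1, 1)), np.ones((1, 1)),
                               np.ones((1, 1), complex), "none", 1, 1.67,
                               627.0, 1.0, alpha_disabled=True)
        state = self._state(2 + 1j, 0.3, 0.0)
        update_object(state, prior, ADMMConfig(alpha=0.4, beta=0.0, c=0.1))
        assert state.uo[0, 0] == 2 + 1j

    def test_geometric_convergence_to_prior_object(self):
        """beta = 0: uo converges to u_tau geometrically with ratio 1 - c*alpha."""
        u_tau = 0.8 + 0.2j
        prior = hp.PriorBundle(np.zeros((1, 1)), np.ones((1, 1)),
                               np.full((1, 1), u_tau), "file", 1, 1.67,
                               627.0, 1.0)
        alpha, c = 0.5, 0.3
        config = ADMMConfig(alpha=alpha, beta=0.0, c=c)
        state = self._state(2 - 1j, 0.0, 0.0)
        expected = scalar_object_updates(2 - 1j, u_tau, 0.0, 0.0, alpha, 0.0,
                                         c, 40)
        for m in range(40):
            update_object(state, prior, config)
            assert state.uo[0, 0] == pytest.approx(expected[m], rel=1e-12)
        ratio = abs(state.uo[0, 0] - u_tau) / abs((2 - 1j) - u_tau)
        assert ratio == pytest.approx((1 - c * alpha) ** 40, rel=1e-9)

    def test_fixed_point_is_stationary(self):
        u_tau = 1.1 + 0.1j
        prior = hp.PriorBundle(np.zeros((1, 1)), np.ones((1, 1)),
                               np.full((1, 1), u_tau), "file", 1, 1.67,
                               627.0, 1.0)
        t = 0.25 + 0.0j
        state = self._state(u_tau, u_tau - t, t)   # uo = u_tau = R + t
        update_object(state, prior, ADMMConfig(alpha=0.4, beta=0.6, c=1.0))
        assert state.uo[0, 0] == pytest.approx(u_tau, rel=1e-12)

    def test_oversized_step_flagged(self):
        prior = hp.PriorBundle(np.zeros((1, 1)), np.ones((1, 1)),
                               np.full((1, 1), 100.0 + 0j), "file", 1, 1.67,
                               627.0, 1.0)
        state = self._state(0.01, 0.0, 0.0)
        update_object(state, prior, ADMMConfig(alpha=1.0, beta=0.0, c=1.0))
        assert any("step larger" in f for f in state.flags)


class TestMultiplierUpdate:
    def _state(self, uo, R, t):
        state = hp.ADMMState(uo=np.array(uo, complex).reshape(1, 1),
                             t=np.array(t, complex).reshape(1, 1),
                             params={}, gen_spec=GeneratorSpec(),
                             kernel=np.ones((1, 1), complex))
        state.R = np.array(R, complex).reshape(1, 1)
        return state

    def test_zero_residual_leaves_multiplier(self):
        state = self._state(1.5 + 0.5j, 1.5 + 0.5j, 0.7)
        update_multiplier(state, ADMMConfig())
        assert state.t[0, 0] == 0.7

    def test_hand_iterated_updates_match(self):
        for sign in ["residual", "sum"]:
            config = ADMMConfig(multiplier_sign=sign, multiplier_step=0.3)
            state = self._state(1.2 - 0.3j, 0.4 + 0.1j, 0.0)
            expected = scalar_multiplier_updates(0.0, 1.2 - 0.3j, 0.4 + 0.1j,
                                                 0.3, 2, sign)
            update_multiplier(state, config)
            assert state.t[0, 0] == pytest.approx(expected[0], rel=1e-12)
            update_multiplier(state, config)
            assert state.t[0, 0] == pytest.approx(expected[1], rel=1e-12)


class TestThetaUpdate:
    def test_zero_inner_steps_leave_parameters(self, small_setup):
        _, holo = small_setup
        prior = make_prior(holo, "tv", 1, 1.0)
        config = ADMMConfig(inner_theta_steps=0)
        state = initialize(holo, prior, GeneratorSpec(depth=2, base_channels=4,
                                                      seed=2), config)
        before = gen.param_checksum(state.params)
        update_theta(state, prior, config)
        assert gen.param_checksum(state.params) == before
        assert state.R is not None

    def test_pure_dip_objective_mostly_decreases(self, small_setup):
        """mode none + beta ~ 0: plain physics-loss training; the objective
        decreases in at least 90% of epochs on noiseless input."""
        _, holo = small_setup
        prior = make_prior(holo, "none", 1, 1.0)
        config = ADMMConfig(alpha=0.0, beta=1e-12, theta_lr=5e-4, seed=0)
        state = initialize(holo, prior, GeneratorSpec(seed=0), config)
        from holopnp.autodiff import Adam
        opt = Adam(list(state.params.values()), lr=config.theta_lr)
        vals = [update_theta(state, prior, config, opt) for _ in range(50)]
        decreases = sum(b <= a for a, b in zip(vals, vals[1:]))
        assert decreases >= 0.9 * (len(vals) - 1)


class TestConvergenceRule:
    def test_printed_rule_arithmetic(self):
        assert check_convergence((1e-4, 2e-4, 3e-4), tol=1e-3)
        assert not check_convergence((1e-3, 0.0, 0.0), tol=1e-3)

    def test_normalization_by_pixel_count(self):
        assert check_convergence((1.0, 2.0, 3.0), tol=1e-3, n=10000)


class TestReconstruct:
    def test_smoke_outputs_and_determinism(self, small_setup):
        ph, holo = small_setup
        config = ADMMConfig(max_epochs=8, tol=1e-12, seed=0, avg_tail=4)
        a = reconstruct(holo, "dip-red", config=config, z=1.0)
        b = reconstruct(holo, "dip-red", config=config, z=1.0)
        assert np.array_equal(a["phase"], b["phase"])
        assert np.all(np.isfinite(a["phase"]))
        assert a["diagnostics"]["stop_reason"] in ("tolerance", "max_epochs")
        assert len(a["diagnostics"]["loss_history"]) == a["diagnostics"]["epochs"]

    def test_invalid_mode_rejected(self, small_setup):
        _, holo = small_setup
        with pytest.raises(ValueError, match="mode"):
            reconstruct(holo, "gan", z=1.0)

    def test_upsampled_output_shape(self, small_setup):
        _, holo = small_setup
        res = reconstruct(holo, "dip-red",
                          config=ADMMConfig(max_epochs=3, seed=0, avg_tail=2),
                          z=1.0, upsample_factor=2)
        assert res["phase"].shape == (64, 64)

    def test_prior_improves_reconstruction_fidelity(self):
        """SSIM against ground truth orders hybrid (true-phase file prior)
        above dip above the classic reconstruction on noiseless phantoms."""
        from holopnp.classic import backpropagate, extract_amp_phase
        ss = {"asm": [], "dip": [], "hybrid": []}
        for seed in [0, 1, 2]:
            ph = hp.make_cell_phantom(64, 1.67, 2.0, seed=seed)
            holo = hologram_of(ph)
            classic = extract_amp_phase(backpropagate(holo, 1.0))["phase"]
            ss["asm"].append(hp.ssim(classic, ph.phase))
            res = reconstruct(holo, "dip",
                              config=ADMMConfig(c=1 / 0.6, theta_lr=2e-3,
                                                max_epochs=40, tol=1e-9,
                                                seed=0, avg_tail=15), z=1.0)
            ss["dip"].append(hp.ssim(res["phase"], ph.phase))
            res = reconstruct(holo, "hybrid",
                              config=ADMMConfig(alpha=1.2, c=1 / 1.8,
                                                theta_lr=2e-3, max_epochs=60,
                                                tol=1e-9, seed=0, avg_tail=20),
                              prior_phase=ph.phase, z=1.0)
            ss["hybrid"].append(hp.ssim(res["phase"], ph.phase))
        assert np.mean(ss["hybrid"]) > np.mean(ss["dip"]) > np.mean(ss["asm"])

    def test_twin_image_suppression_vs_classic(self):
        """Background phase variance of the prior-driven reconstruction is
        below the classic single-propagation reconstruction on noiseless
        phantoms."""
        from holopnp.classic import backpropagate, extract_amp_phase
        for seed in [0, 1]:
            ph = hp.make_cell_phantom(64, 1.67, 2.0, seed=seed)
            holo = hologram_of(ph)
            classic = extract_amp_phase(backpropagate(holo, 1.0))["phase"]
            res = reconstruct(holo, "hybrid",
                              config=ADMMConfig(alpha=1.2, c=1 / 1.8,
                                                theta_lr=2e-3, max_epochs=60,
                                                tol=1e-9, seed=0, avg_tail=20),
                              prior_phase=hp.degrade_phase_prior(ph.phase, 1, 1.0),
                              z=1.0)
            bg = ph.phase < 0.05 * ph.phase.max()
            assert res["phase"][bg].var() < classic[bg].var()
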