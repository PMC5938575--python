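import numpy as np
import pytest

from nichesync.free_energy import laplace_free_energy
from nichesync.generalized_coords import GeneralizedState
from nichesync.generative_model import (DIM_MU, BirdsongEnergy, Expectations,
                                        birdsong_model, error_precisions,
                                        cause_prior_precisions,
                                        generalized_from_flow, lorenz_flow,
                                        model_flow, prediction_errors,
                                        predict_sensory, simulate_generative,
                                        simulate_lorenz, song_observation)

CLASSIC = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "tau": 1.0}


class TestLorenzFlow:
    def test_origin_is_fixed_point(self):
        np.testing.assert_array_equal(lorenz_flow(np.zeros(3), CLASSIC),
                                      np.zeros(3))

    def test_hand_evaluated_point(self):
        out = lorenz_flow(np.array([1.0, 1.0, 1.0]), CLASSIC)
        np.testing.assert_allclose(out, [0.0, 26.0, -5.0 / 3.0], rtol=1e-12)

    def test_nontrivial_fixed_point(self):
        c = np.sqrt(CLASSIC["beta"] * (CLASSIC["rho"] - 1))
        out = lorenz_flow(np.array([c, c, CLASSIC["rho"] - 1]), CLASSIC)
        np.testing.assert_allclose(out, np.zeros(3), atol=1e-12)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            lorenz_flow(np.ones(3), dict(CLASSIC, rho=np.inf))

    def test_tau_scales_flow(self):
        x = np.array([2.0, -1.0, 15.0])
        f1 = lorenz_flow(x, CLASSIC)
        f2 = lorenz_flow(x, dict(CLASSIC, tau=2.0))
        np.testing.assert_allclose(f2, f1 / 2.0, rtol=1e-12)


class TestModelFlow:
    def test_zero_output_map_decouples_levels(self, model):
        """With the cause map severed, the song level runs at its default
        rho regardless of the top level's state."""
        import dataclasses
        top = dataclasses.replace(model.top, output_map=np.zeros(3))
        decoupled = dataclasses.replace(model, levels=(top, model.bottom))
        rng = np.random.default_rng(0)
        hidden = {
            "top": GeneralizedState(rng.normal(size=(3, 5)), 1.0),
            "bottom": GeneralizedState(rng.normal(size=(3, 5)), 1.0),
        }
        flows = model_flow(decoupled, hidden, {"rho_base": 24.0})
        single = lorenz_flow(hidden["bottom"].values[:, 0],
                             dict(decoupled.bottom.flow_params, rho=24.0))
        np.testing.assert_allclose(flows["bottom"][:, 0], single, rtol=1e-12)

    def test_frozen_top_reproduces_single_level_run(self, model):
        """Top level at its fixed point -> the song level is a plain Lorenz
        run at the implied constant rho."""
        p = model.top.flow_params
        c = np.sqrt(p["beta"] * (p["rho"] - 1))
        x_top0 = np.array([c, c, p["rho"] - 1])  # analytic fixed point
        x_b0 = np.array([2.0, 3.0, 20.0])
        theta = 24.0
        n, dt = 256, 1 / 256
        two = simulate_generative(model, x_top0, x_b0, theta, n, dt)
        v = float(model.top.output_map @ x_top0)
        one = simulate_lorenz(dict(model.bottom.flow_params, rho=theta + v),
                              x_b0, n, dt)
        np.testing.assert_allclose(two["bottom"], one, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(two["top"], np.tile(x_top0, (n + 1, 1)),
                                   atol=1e-9)

    def test_doubling_top_tau_halves_its_flow(self, model):
        import dataclasses
        rng = np.random.default_rng(1)
        hidden = {
            "top": GeneralizedState(rng.normal(size=(3, 5)), 1.0),
            "bottom": GeneralizedState(rng.normal(size=(3, 5)), 1.0),
        }
        slow_top = dataclasses.replace(
            model.top, flow_params=dict(model.top.flow_params,
                                        tau=2 * model.top.flow_params["tau"]))
        slowed = dataclasses.replace(model, levels=(slow_top, model.bottom))
        f = model_flow(model, hidden, {"rho_base": 24.0})
        g = model_flow(slowed, hidden, {"rho_base": 24.0})
        np.testing.assert_allclose(g["top"], f["top"] / 2.0, rtol=1e-12)


class TestSongObservation:
    def test_frequency_midpoint_exact(self, model):
        song = model.song
        _, freq = song_observation(np.array([0.0, 0.0, song.x3_ref]), song)
        assert freq == song.f_mid

    def test_silence_limit(self, model):
        amp, _ = song_observation(np.array([0.0, -1e3, 0.0]), model.song)
        assert amp < 1e-12

    def test_frequency_bounded_over_trajectory(self, model):
        """Every sample of a generated song stays inside the 2-5 kHz band."""
        run = simulate_generative(model, np.array([1.0, 2.0, 25.0]),
                                  np.array([2.0, 3.0, 24.0]), 24.0, 2048,
                                  1 / 256)
        freq = run["song"][:, 1]
        assert np.all(freq > model.song.f_lo) and np.all(freq < model.song.f_hi)
        assert np.all(run["song"][:, 0] >= 0)


class TestPredictionErrors:
    def test_noise_free_self_consistency(self, tick_model):
        """Expectations generated by the model's own flow, observing their
        own output, have vanishing errors in every channel and order."""
        exp = generalized_from_flow(tick_model, np.array([2.0, 3.0, 25.0]),
                                    np.array([1.0, 2.0, 20.0]), 24.0, 1.0)
        sens = predict_sensory(tick_model, exp)
        errs = prediction_errors(tick_model, exp, {"rho_base": 24.0}, sens)
        for key, eps in errs.items():
            assert np.max(np.abs(eps)) < 1e-6, key

    def test_sensory_offset_locality(self, tick_model):
        """A +delta offset on the amplitude channel moves exactly that
        channel of eps_z1 and nothing else."""
        exp = generalized_from_flow(tick_model, np.array([2.0, 3.0, 25.0]),
                                    np.array([1.0, 2.0, 20.0]), 24.0, 1.0)
        sens = predict_sensory(tick_model, exp)
        base = prediction_errors(tick_model, exp, {"rho_base": 24.0}, sens)
        delta = 0.37
        shifted = sens.values.copy()
        shifted[0, 0] += delta
        off = prediction_errors(tick_model, exp, {"rho_base": 24.0},
                                GeneralizedState(shifted, sens.dt))
        assert abs((off["z1"] - base["z1"])[0, 0] - delta) < 1e-12
        assert np.max(np.abs(off["z1"][1])) < 1e-12 + np.max(np.abs(base["z1"][1]))
        for key in ("z2", "w1", "w2"):
            np.testing.assert_array_equal(off[key], base[key])

    def test_matches_naive_evaluator(self, tick_model):
        """Straight-line re-implementation of the error equations."""
        rng = np.random.default_rng(7)
        exp = Expectations.from_flat(rng.normal(scale=2.0, size=DIM_MU), 1.0)
        sens = GeneralizedState(rng.normal(size=(2, 5)), 1.0)
        theta = 25.0
        errs = prediction_errors(tick_model, exp, {"rho_base": theta}, sens)

        m = tick_model
        xb, xt = exp.x_bottom.values, exp.x_top.values
        v = exp.cause.values[0]
        # sensory prediction, first-order closure
        a0, a1 = m.song.a0, m.song.a1
        z = a0 + a1 * xb[1, 0]
        amp0 = np.log1p(np.exp(z)) if z < 30 else z
        damp = a1 / (1 + np.exp(-z))
        u = m.song.f_gain * (xb[2, 0] - m.song.x3_ref) / m.song.f_band
        fr0 = m.song.f_mid + m.song.f_band * np.tanh(u)
        dfr = m.song.f_gain * (1 - np.tanh(u) ** 2)
        pred = np.zeros((2, 5))
        pred[0, 0], pred[1, 0] = amp0, fr0
        pred[0, 1:] = damp * xb[1, 1:]
        pred[1, 1:] = dfr * xb[2, 1:]
        np.testing.assert_allclose(errs["z1"], sens.values - pred, rtol=1e-9)
        # cause error
        w = m.top.output_map
        np.testing.assert_allclose(errs["z2"], v - w @ xt[:, :3], rtol=1e-9)
        # song-level flow error, order 0
        pb = dict(m.bottom.flow_params, rho=theta + v[0])
        f0 = lorenz_flow(xb[:, 0], pb)
        np.testing.assert_allclose(errs["w1"][:, 0], xb[:, 1] - f0, rtol=1e-9)

    def test_generated_songs_sensitive_to_initial_conditions(self, model):
        """Two song-level runs 1e-6 apart diverge beyond unit distance
        within 4 s on a verified chaotic stretch of the attractor."""
        params = dict(model.bottom.flow_params, rho=28.0)
        rng = np.random.default_rng(3)
        x0 = simulate_lorenz(params, rng.uniform(-8, 8, 3), 512, 1 / 256)[-1]
        t1 = simulate_lorenz(params, x0, 1024, 1 / 256)
        t2 = simulate_lorenz(params, x0 + np.array([1e-6, 0, 0]), 1024, 1 / 256)
        dist = np.sqrt(np.sum((t1 - t2) ** 2, axis=1))
        assert dist.max() > 1.0


class TestBirdsongEnergy:
    def test_fused_energy_matches_reference_path(self, model, tick_model):
        """Dual route: the vectorized energy equals prediction_errors +
        laplace_free_energy (+ the cause shrinkage prior) exactly."""
        rng = np.random.default_rng(0)
        exp = generalized_from_flow(tick_model, np.array([2.0, 3.0, 25.0]),
                                    np.array([1.0, 2.0, 20.0]), 24.0, 1.0)
        sens = predict_sensory(tick_model, exp)
        mu = exp.to_flat() + rng.normal(0, 0.3, DIM_MU)
        theta = 24.5
        energy = BirdsongEnergy(model)
        F_fast = float(energy.F_batch(mu[None, :], sens.values, theta)[0])

        errs = prediction_errors(tick_model, Expectations.from_flat(mu, 1.0),
                                 {"rho_base": theta}, sens)
        rep = laplace_free_energy(errs, error_precisions(tick_model),
                                  param_deviation=(theta - 24.0, np.exp(8.0)))
        wvp = cause_prior_precisions(tick_model)
        v = Expectations.from_flat(mu, 1.0).cause.values[0]
        vprior = (0.5 * float(np.sum(wvp * v**2))
                  - 0.5 * float(np.sum(np.log(wvp) - np.log(2 * np.pi))))
        assert abs(F_fast - (rep.F + vprior)) < 1e-9 * max(1, abs(F_fast))

    def test_gain_scales_only_sensory_terms(self, model, tick_model):
        rng = np.random.default_rng(1)
        mu = rng.normal(scale=2.0, size=DIM_MU)
        s = rng.normal(size=(2, 5))
        energy = BirdsongEnergy(model)
        r1 = energy.report(mu, s, 24.0, gain=1.0)
        r2 = energy.report(mu, s, 24.0, gain=0.5)
        assert r1.complexity == pytest.approx(r2.complexity, rel=1e-12)
        assert r1.accuracy != r2.accuracy

    def test_fd_gradient_consistent_with_energy(self, model):
        rng = np.random.default_rng(5)
        mu = rng.normal(scale=1.0, size=DIM_MU)
        s = rng.normal(size=(2, 5))
        energy = BirdsongEnergy(model)
        F0, g, gth, cth = energy.grads(mu, s, 24.0)
        direction = rng.normal(size=DIM_MU)
        direction /= np.linalg.norm(direction)
        h = 1e-6
        Fp = float(energy.F_batch((mu + h * direction)[None], s, 24.0)[0])
        Fm = float(energy.F_batch((mu - h * direction)[None], s, 24.0)[0])
        assert abs((Fp - Fm) / (2 * h) - g @ direction) < 1e-3 * max(
            1.0, abs(g @ direction))
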