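"""Filter-core tests: sigma points, predict/update, linear-Gaussian oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroassim.errors import ConfigError
from neuroassim.simulate import TraceRecord
from neuroassim.ukf import (AugmentedStateSpec, GaussianBelief, NoiseSpec,
                            augment, condition_covariance, default_process_noise,
                            measurement_update, predict, run_filter, sigma_points)


def random_psd(rng, d, scale=1.0):
    a = rng.normal(size=(d, d))
    return scale * (a @ a.T + 0.1 * np.eye(d))


def kalman_filter(ys, A, H, Q, R, m0, P0):
    """Independent closed-form Kalman recursion (predict + scalar update)."""
    A, Q, P0 = (np.atleast_2d(x) for x in (A, Q, P0))
    H = np.atleast_2d(H)
    m = np.atleast_1d(np.asarray(m0, float)).copy()
    P = P0.copy()
    means, covs, gains = [], [], []
    for y in ys:
        m = A @ m
        P = A @ P @ A.T + Q
        S = float((H @ P @ H.T).item()) + R
        K = (P @ H.T / S).ravel()
        m = m + K * (y - float((H @ m).item()))
        P = P - np.outer(K, K) * S
        means.append(m.copy())
        covs.append(P.copy())
        gains.append(K.copy())
    return np.array(means), np.array(covs), np.array(gains)


class _LinearSpec:
    """Minimal stand-in spec: linear dynamics x -> Ax, observe component 0."""

    def __init__(self, A):
        self.A = np.atleast_2d(A)
        self.dim = self.A.shape[0]
        self.labels = tuple(f"x{i}" for i in range(self.dim))

    def make_transition(self, t0):
        return lambda pts: pts @ self.A.T

    def observe(self, pts):
        return pts[..., 0]

    def clamp_mean(self, m):
        return m


def _run_filter_linear(spec, rec, Q, R, m0, P0):
    """Drive the generic predict/measurement_update pair over a record."""
    belief = GaussianBelief(np.atleast_1d(np.asarray(m0, float)),
                            np.atleast_2d(P0), spec.labels)
    Q = np.atleast_2d(Q)
    means, covs = [], []
    for y in rec.v:
        prior, prop = predict(belief, spec.make_transition(0.0), Q)
        belief, gain, ypred = measurement_update(prior, prop, spec.observe,
                                                 rec.noise_sd ** 2, float(y))
        means.append(belief.mean.copy())
        covs.append(belief.cov.copy())
    return np.array(means), np.array(covs)


class TestSigmaPoints:
    def test_scalar_case(self):
        s = sigma_points(GaussianBelief(np.zeros(1), np.eye(1)))
        assert sorted(s.points.ravel().tolist()) == [-1.0, 1.0]

    def test_mean_exact(self, rng):
        for d in (2, 5, 11):
            mean = rng.normal(size=d)
            s = sigma_points(GaussianBelief(mean, random_psd(rng, d)))
            np.testing.assert_allclose(s.mean(), mean, atol=1e-10)

    @pytest.mark.parametrize("d", [3, 10, 30])
    def test_covariance_moment_matching(self, d, rng):
        P = random_psd(rng, d)
        s = sigma_points(GaussianBelief(np.zeros(d), P))
        rel = np.linalg.norm(s.cov() - P) / np.linalg.norm(P)
        assert rel < 1e-8


class TestConditionCovariance:
    def test_idempotent_on_valid(self, rng):
        P = random_psd(rng, 4)
        np.testing.assert_allclose(condition_covariance(P), P, atol=1e-15)

    def test_eigenvalue_floor(self):
        P = np.diag([1.0, -1e-14])
        out = condition_covariance(P, jitter=1e-10)
        w = np.linalg.eigvalsh(out)
        assert w.min() >= 1e-10 * np.trace(out) / 2 * 0.99

    def test_symmetrizes(self):
        P = np.array([[1.0, 0.3], [0.1, 1.0]])
        out = condition_covariance(P)
        np.testing.assert_allclose(out, out.T, atol=0)
        assert out[0, 1] == pytest.approx(0.2)


class TestPredictUpdate:
    def test_identity_transition_no_noise(self, rng):
        bel = GaussianBelief(rng.normal(size=3), random_psd(rng, 3))
        prior, _ = predict(bel, lambda p: p, np.zeros((3, 3)))
        np.testing.assert_allclose(prior.mean, bel.mean, atol=1e-10)
        np.testing.assert_allclose(prior.cov, bel.cov, atol=1e-8)

    def test_linear_transition_oracle(self, rng):
        A = np.array([[0.9, 0.2], [-0.1, 0.95]])
        Q = 0.01 * np.eye(2)
        bel = GaussianBelief(rng.normal(size=2), random_psd(rng, 2))
        prior, _ = predict(bel, lambda p: p @ A.T, Q)
        np.testing.assert_allclose(prior.mean, A @ bel.mean, atol=1e-8)
        np.testing.assert_allclose(prior.cov, A @ bel.cov @ A.T + Q, atol=1e-8)

    def test_parameter_components_trivial_dynamics(self, rng):
        """Components the transition does not touch come back bit-identical."""
        bel = GaussianBelief(rng.normal(size=3), random_psd(rng, 3))

        def transition(pts):
            before = pts[:, 2].copy()
            pts[:, 0] *= 0.9
            assert np.array_equal(pts[:, 2], before)
            return pts

        prior, prop = predict(bel, transition, np.zeros((3, 3)))
        sig = sigma_points(GaussianBelief(bel.mean, bel.cov))
        np.testing.assert_array_equal(prop.points[:, 2], sig.points[:, 2])

    def test_uninformative_observation(self, rng):
        bel = GaussianBelief(rng.normal(size=2), random_psd(rng, 2))
        prior, prop = predict(bel, lambda p: p, np.zeros((2, 2)))
        post, gain, _ = measurement_update(prior, prop, lambda p: p[..., 0],
                                           1e12, 5.0)
        np.testing.assert_allclose(gain, 0.0, atol=1e-10)
        np.testing.assert_allclose(post.mean, prior.mean, atol=1e-8)

    def test_scalar_gain_closed_form(self):
        P = np.array([[2.0]])
        bel = GaussianBelief(np.array([1.0]), P)
        prior, prop = predict(bel, lambda p: p, np.zeros((1, 1)))
        R = 0.5
        post, gain, _ = measurement_update(prior, prop, lambda p: p[..., 0],
                                           R, 3.0)
        assert gain[0] == pytest.approx(2.0 / 2.5, abs=1e-10)

    def test_informative_observation_pins_component(self, rng):
        bel = GaussianBelief(np.array([0.0, 1.0]), np.eye(2))
        prior, prop = predict(bel, lambda p: p, np.zeros((2, 2)))
        post, _, _ = measurement_update(prior, prop, lambda p: p[..., 0],
                                        1e-8, 0.7)
        assert post.mean[0] == pytest.approx(0.7, abs=3e-4)


class TestLinearGaussianEquivalence:
    def test_scalar_system(self, rng):
        A, Q, R = 0.95, 0.1, 0.25
        ys = rng.normal(size=100)
        m_kf, P_kf, _ = kalman_filter(ys, A, 1.0, Q, R, 0.0, 1.0)
        spec = _LinearSpec(A)
        rec = TraceRecord(time=0.1 * np.arange(100), v=ys, noise_sd=np.sqrt(R))
        m_ukf, P_ukf = _run_filter_linear(spec, rec, Q, R, [0.0], [[1.0]])
        np.testing.assert_allclose(m_ukf.ravel(), m_kf.ravel(), atol=1e-8)
        np.testing.assert_allclose(P_ukf.ravel(), P_kf.ravel(), atol=1e-8)

    def test_two_dimensional_system(self, rng):
        A = np.array([[0.95, 0.1], [-0.05, 0.9]])
        Q = np.diag([0.05, 0.02])
        R = 0.3
        ys = rng.normal(size=100)
        m_kf, P_kf, _ = kalman_filter(ys, A, [1.0, 0.0], Q, R,
                                      [0.0, 0.0], np.eye(2))
        spec = _LinearSpec(A)
        rec = TraceRecord(time=0.1 * np.arange(100), v=ys, noise_sd=np.sqrt(R))
        m_ukf, P_ukf = _run_filter_linear(spec, rec, Q, R, [0.0, 0.0], np.eye(2))
        np.testing.assert_allclose(m_ukf, m_kf, atol=1e-8)
        np.testing.assert_allclose(P_ukf, P_kf, atol=1e-8)

    def test_innovation_whiteness(self, rng):
        """On a matched linear benchmark the innovations are white."""
        A, Q, R = 0.9, 0.2, 0.5
        n = 1000
        x = 0.0
        ys = np.empty(n)
        for i in range(n):
            x = A * x + rng.normal(0, np.sqrt(Q))
            ys[i] = x + rng.normal(0, np.sqrt(R))
        m_kf, P_kf, gains = kalman_filter(ys, A, 1.0, Q, R, 0.0, 1.0)
        pred = A * np.concatenate([[0.0], m_kf[:-1, 0]])
        innov = ys - pred
        r1 = np.corrcoef(innov[:-1], innov[1:])[0, 1]
        assert abs(r1) < 0.1


class TestAugmentedSpec:
    def test_no_parameters(self):
        spec = augment("pc_full")
        assert spec.dim == 7
        assert spec.tracked_parameters == ()

    def test_three_microenv_parameters(self):
        spec = augment("pc_full", tracked_parameters=("epsilon", "G_glia",
                                                      "K_bath"))
        assert spec.dim == 10

    def test_log_roundtrip(self):
        spec = augment("pc_full", tracked_parameters=("G_glia",))
        x = spec.assemble({c: 0.5 for c in spec.dynamic_labels},
                          {"G_glia": 37.5})
        states, params = spec.disassemble(x)
        assert params["G_glia"] == pytest.approx(37.5, rel=1e-12)

    def test_assemble_disassemble_identity(self, rng):
        spec = augment("pc_full", tracked_parameters=("epsilon", "K_bath"),
                       transforms={"K_bath": "identity"})
        sv = {c: float(v) for c, v in zip(spec.dynamic_labels,
                                          rng.uniform(0.1, 1, 7))}
        pv = {"epsilon": 1.3, "K_bath": 4.0}
        x = spec.assemble(sv, pv)
        sv2, pv2 = spec.disassemble(x)
        for k in sv:
            assert sv2[k] == pytest.approx(sv[k], rel=1e-14)
        for k in pv:
            assert pv2[k] == pytest.approx(pv[k], rel=1e-12)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError):
            augment("pc_full", tracked_parameters=("not_a_param",))

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            augment("bogus_model")

    def test_fixed_ion_spec_drops_concentrations(self):
        spec = augment("pc_fixed_ions", pinned_ions=(4.0, 18.0))
        assert "K_o" not in spec.dynamic_labels
        assert spec.dim == 5


class TestRunFilterNonlinear:
    def test_self_consistency_from_true_state(self, spiking_fixture):
        """Noise-free observations from the true initial state stay locked."""
        traj, _ = spiking_fixture
        from neuroassim.simulate import StimulusProtocol, make_observations
        rec = make_observations(traj, 0.1, 0.0, seed=0)
        proto = StimulusProtocol.from_pA(100.0, 200.0, 1000.0)
        spec = augment("pc_full", protocol=proto)
        m0 = traj.states[0].copy()
        P0 = np.diag([1e-4, 1e-6, 1e-6, 1e-6, 1e-8, 1e-4, 1e-4])
        q = default_process_noise(spec)
        R = 0.01
        res = run_filter(spec, rec, NoiseSpec(Q=q, R=R),
                         GaussianBelief(m0, P0))
        err = res["V"] - traj["V"][:len(res.time)]
        assert np.sqrt(np.mean(err ** 2)) < 10 * np.sqrt(R)

    def test_dimension_mismatch_rejected(self, spiking_fixture):
        traj, rec = spiking_fixture
        spec = augment("pc_full")
        with pytest.raises(ConfigError):
            run_filter(spec, rec, NoiseSpec(Q=np.ones(7), R=0.25),
                       GaussianBelief(np.zeros(3), np.eye(3)))


class TestPosteriorCovariancePSD:
    def test_acceptance_run_covariances_psd(self, microenv_report):
        sd = microenv_report.result.marginal_sd
        assert np.all(np.isfinite(sd))
        assert np.all(sd >= 0)
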