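"""Reservoir construction, state updates, ridge readout: oracle checks.

The state-update oracle is an independently coded per-element loop; the
ridge oracle is the explicit normal-equation formula.  Both stay free of the
vectorised implementation paths they check.
"""

import numpy as np
import pytest

from parnet.esn import (ESNClassifier, ReadoutWeights, ReservoirConfig,
                        esn_classify, esn_states, esn_states_batch, esn_step,
                        fit_ridge_readout, init_reservoir)


def loop_oracle(params, config, sequence):
    """Scalar-arithmetic reimplementation of the reservoir recurrence."""
    N = config.n_units
    L, M = sequence.shape
    h = [0.0] * N
    H = np.empty((L, N + 1))
    for t in range(L):
        xa = [1.0] + [float(v) for v in sequence[t]]
        new = []
        for i in range(N):
            a = 0.0
            for j in range(M + 1):
                a += params.W_in[i, j] * xa[j]
            for j in range(N):
                a += params.W[i, j] * h[j]
            phi = np.tanh(config.alpha * a)
            new.append(((1.0 - config.decay) * h[i] + config.decay * phi)
                       / (1.0 + config.epsilon))
        h = new
        H[t, 0] = 1.0
        H[t, 1:] = h
    return H


class TestInitReservoir:
    def test_spectral_radius_is_exact(self):
        cfg = ReservoirConfig(n_units=32, input_dim=5, spectral_radius=0.9,
                              seed=1)
        p = init_reservoir(cfg)
        rho = np.max(np.abs(np.linalg.eigvals(p.W)))
        assert abs(rho - 0.9) < 1e-8

    def test_same_seed_is_bit_identical(self):
        cfg = ReservoirConfig(n_units=16, input_dim=3, seed=9)
        a, b = init_reservoir(cfg), init_reservoir(cfg)
        np.testing.assert_array_equal(a.W_in, b.W_in)
        np.testing.assert_array_equal(a.W, b.W)

    def test_shapes_fold_bias_into_input(self):
        cfg = ReservoirConfig(n_units=32, input_dim=50, seed=0)
        p = init_reservoir(cfg)
        assert p.W_in.shape == (32, 51)
        assert p.W.shape == (32, 32)
        assert not p.W_back.any()

    def test_input_scaling_bounds_entries(self):
        cfg = ReservoirConfig(n_units=8, input_dim=4, input_scaling=0.25,
                              seed=2)
        p = init_reservoir(cfg)
        assert np.abs(p.W_in).max() <= 0.25

    @pytest.mark.parametrize("bad", [
        dict(decay=0.0), dict(decay=1.5), dict(spectral_radius=-1.0),
        dict(n_units=0), dict(alpha=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            ReservoirConfig(n_units=bad.get("n_units", 8), input_dim=2, **{
                k: v for k, v in bad.items() if k != "n_units"})


class TestEsnStep:
    def test_zero_state_zero_input_zero_bias_stays_zero(self):
        cfg = ReservoirConfig(n_units=4, input_dim=2, decay=0.7, seed=0)
        p = init_reservoir(cfg)
        p.W_in[:, 0] = 0.0  # zero bias column
        h = esn_step(p, cfg, np.zeros(4), np.zeros(2))
        np.testing.assert_array_equal(h, 0.0)

    def test_two_unit_closed_form(self):
        cfg = ReservoirConfig(n_units=2, input_dim=1, decay=1.0, alpha=1.0,
                              seed=0)
        p = init_reservoir(cfg)
        p.W_in = np.array([[0.0, 0.5], [0.0, -0.5]])
        p.W = np.zeros((2, 2))
        h = esn_step(p, cfg, np.zeros(2), np.array([1.0]))
        np.testing.assert_allclose(h, [np.tanh(0.5), np.tanh(-0.5)])

    def test_states_bounded_by_unit_interval(self, rng):
        cfg = ReservoirConfig(n_units=8, input_dim=3, seed=3)
        p = init_reservoir(cfg)
        h = np.zeros(8)
        for t in range(50):
            h = esn_step(p, cfg, h, rng.normal(size=3) * 10)
        assert np.all(np.abs(h) < 1.0)

    def test_non_finite_input_is_rejected(self):
        cfg = ReservoirConfig(n_units=2, input_dim=1, seed=0)
        p = init_reservoir(cfg)
        with pytest.raises(ValueError, match="non-finite"):
            esn_step(p, cfg, np.zeros(2), np.array([np.nan]))


class TestEsnStates:
    def test_zero_sequence_zero_bias_gives_ones_column(self):
        cfg = ReservoirConfig(n_units=3, input_dim=2, seed=1)
        p = init_reservoir(cfg)
        p.W_in[:, 0] = 0.0
        H = esn_states(p, cfg, np.zeros((10, 2)))
        np.testing.assert_array_equal(H[:, 0], 1.0)
        np.testing.assert_array_equal(H[:, 1:], 0.0)

    def test_shape_contract(self, rng):
        cfg = ReservoirConfig(n_units=32, input_dim=50, seed=2)
        p = init_reservoir(cfg)
        H = esn_states(p, cfg, rng.normal(size=(30, 50)))
        assert H.shape == (30, 33)
        np.testing.assert_array_equal(H[:, 0], 1.0)

    @pytest.mark.parametrize("decay,alpha,eps", [
        (1.0, 1.0, 0.0), (0.5, 1.3, 0.0), (0.8, 0.7, 0.05)])
    def test_matches_per_element_loop_oracle(self, rng, decay, alpha, eps):
        for trial in range(10):
            N = int(rng.integers(1, 9))
            L = int(rng.integers(1, 31))
            M = int(rng.integers(1, 6))
            cfg = ReservoirConfig(n_units=N, input_dim=M, decay=decay,
                                  alpha=alpha, epsilon=eps,
                                  seed=int(rng.integers(0, 1000)))
            p = init_reservoir(cfg)
            seq = rng.normal(size=(L, M))
            np.testing.assert_allclose(esn_states(p, cfg, seq),
                                       loop_oracle(p, cfg, seq), atol=1e-10)

    def test_batch_agrees_with_single(self, rng):
        cfg = ReservoirConfig(n_units=6, input_dim=4, seed=7)
        p = init_reservoir(cfg)
        X = rng.normal(size=(5, 12, 4))
        Hb = esn_states_batch(p, cfg, X)
        for i in range(5):
            np.testing.assert_allclose(Hb[i], esn_states(p, cfg, X[i]),
                                       atol=1e-12)

    def test_echo_state_property(self, rng):
        """Two random initial states driven by one input converge."""
        cfg = ReservoirConfig(n_units=32, input_dim=3, spectral_radius=0.95,
                              seed=4)
        p = init_reservoir(cfg)
        seq = rng.normal(size=(500, 3))
        h0a = rng.normal(size=32)
        h0a /= np.linalg.norm(h0a)
        Ha = esn_states(p, cfg, seq, h0=h0a)
        Hb = esn_states(p, cfg, seq, h0=np.zeros(32))
        dist = np.linalg.norm(Ha[:, 1:] - Hb[:, 1:], axis=1)
        assert dist[-1] < 1e-3
        assert np.all(np.diff(dist[10:]) <= 1e-12)


class TestRidgeReadout:
    def test_zero_targets_give_zero_weights(self, rng):
        H = rng.normal(size=(10, 4))
        W = fit_ridge_readout(H, np.zeros((10, 2)), beta=0.5).W_out
        np.testing.assert_allclose(W, 0.0, atol=1e-12)

    def test_orthonormal_columns_collapse_to_projection(self):
        H, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(10, 4)))
        y = np.random.default_rng(1).normal(size=(10, 2))
        W = fit_ridge_readout(H, y, beta=0.0).W_out
        np.testing.assert_allclose(W, H.T @ y, atol=1e-10)

    def test_matches_explicit_normal_equation_oracle(self, rng):
        for _ in range(20):
            H = rng.normal(size=(20, 4))
            y = rng.normal(size=(20, 2))
            beta = float(rng.uniform(0.01, 2.0))
            W = fit_ridge_readout(H, y, beta).W_out
            expl = np.linalg.inv(H.T @ H + beta * np.eye(4)) @ H.T @ y
            np.testing.assert_allclose(W, expl, atol=1e-8)

    def test_perturbation_never_improves_objective(self, rng):
        def objective(H, W, y, beta):
            return 0.5 * np.sum((H @ W - y) ** 2) + beta / 2 * np.sum(W ** 2)

        for _ in range(20):
            H = rng.normal(size=(15, 5))
            y = rng.normal(size=(15, 2))
            beta = 0.3
            W = fit_ridge_readout(H, y, beta).W_out
            base = objective(H, W, y, beta)
            for _ in range(5):
                delta = rng.normal(size=W.shape)
                delta *= 1e-3 / np.linalg.norm(delta)
                assert objective(H, W + delta, y, beta) >= base

    def test_rank_deficient_without_ridge_is_diagnosed(self):
        H = np.ones((6, 3))
        with pytest.raises(np.linalg.LinAlgError, match="beta > 0"):
            fit_ridge_readout(H, np.ones((6, 1)), beta=0.0)


class TestClassify:
    def test_zero_readout_ties_break_to_class_zero(self, rng):
        cfg = ReservoirConfig(n_units=4, input_dim=2, seed=0)
        p = init_reservoir(cfg)
        readout = ReadoutWeights(np.zeros((5, 3)), beta=1.0)
        scores = esn_classify(p, cfg, readout, rng.normal(size=(8, 2)))
        np.testing.assert_array_equal(scores, 0.0)
        assert int(np.argmax(scores)) == 0

    def test_readout_shape_mismatch_is_rejected(self, rng):
        cfg = ReservoirConfig(n_units=4, input_dim=2, seed=0)
        p = init_reservoir(cfg)
        readout = ReadoutWeights(np.zeros((9, 3)), beta=1.0)
        with pytest.raises(ValueError, match="state width"):
            esn_classify(p, cfg, readout, rng.normal(size=(8, 2)))

    def test_identical_sequences_get_identical_scores(self, rng):
        cfg = ReservoirConfig(n_units=6, input_dim=3, seed=1)
        p = init_reservoir(cfg)
        readout = ReadoutWeights(rng.normal(size=(7, 2)), beta=1.0)
        seq = rng.normal(size=(12, 3))
        s1 = esn_classify(p, cfg, readout, seq)
        s2 = esn_classify(p, cfg, readout, seq.copy())
        np.testing.assert_array_equal(s1, s2)

    def test_standalone_pipeline_separates_temporal_classes(self, temporal_pair):
        """Coordination-order classes are learned by the ridge pipeline."""
        from parnet.io_skeleton import make_windows, normalize_windows

        table, _ = temporal_pair
        ws = make_windows(table, 30)
        ws, _ = normalize_windows(ws, "zscore")
        clf = ESNClassifier(ReservoirConfig(n_units=32, input_dim=50, seed=5),
                            beta=1.0)
        clf.fit(ws.data, ws.labels)
        assert clf.score(ws.data, ws.labels) >= 0.95
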