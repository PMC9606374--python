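"""Bayesian-evidence network: forward pass, cost, training, evidence."""

import numpy as np
import pytest

from woundtherm import bnn


def separable_data(rng, n_per=20, gap=2.0):
    x1 = rng.normal(size=(n_per, 3)) + np.array([gap, 0, 0])
    x0 = rng.normal(size=(n_per, 3)) - np.array([gap, 0, 0])
    X = np.vstack([x1, x0])
    t = np.r_[np.ones(n_per), np.zeros(n_per)]
    return X, t


class TestInitForward:
    def test_deterministic_init(self):
        a = bnn.init_network(4, seed=1)
        b = bnn.init_network(4, seed=1)
        assert np.array_equal(a.pack(), b.pack())

    @pytest.mark.parametrize("h,expected", [(1, 6), (4, 21), (9, 46)])
    def test_parameter_count(self, h, expected):
        assert bnn.init_network(h, 0).n_params == expected

    def test_zero_weights_output_half(self):
        m = bnn.init_network(3, 0).with_params(np.zeros(16))
        assert bnn.forward(m, np.array([0.3, -2.0, 5.0])) == pytest.approx(0.5)

    def test_large_output_bias_saturates(self):
        m = bnn.init_network(2, 0)
        w = m.pack()
        w[-1] = 50.0
        w[:-1] = 0.0
        assert bnn.forward(m.with_params(w), np.zeros(3)) == pytest.approx(1.0)

    def test_forward_matches_loop_oracle(self, rng):
        m = bnn.init_network(5, seed=2)
        x = rng.normal(size=3)
        # explicit loops
        hid = [np.tanh(sum(m.w1[k, j] * x[j] for j in range(3)) + m.b1[k])
               for k in range(5)]
        a = sum(m.w2[k] * hid[k] for k in range(5)) + m.b2
        expected = 1.0 / (1.0 + np.exp(-a))
        assert bnn.forward(m, x) == pytest.approx(expected)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            bnn.init_network(0, 1)


class TestCost:
    def test_zero_weights_balanced_labels(self):
        m = bnn.init_network(2, 0).with_params(np.zeros(11))
        X = np.zeros((4, 3))
        t = np.array([0.0, 1.0, 0.0, 1.0])
        M, G, E_W = bnn.cost(m, X, t, alpha=0.7)
        assert G == pytest.approx(4 * np.log(2))
        assert E_W == 0.0
        assert M == pytest.approx(G)

    def test_confident_correct_predictions_low_G(self, rng):
        X, t = separable_data(rng, gap=4.0)
        m = bnn.train(bnn.init_network(2, 3), X, t, alpha0=0.01,
                      reestimate_alpha=False)
        _, G, _ = bnn.cost(m, X, t)
        assert G < 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(1, 6))
        m = bnn.init_network(h, seed + 100)
        X = rng.normal(size=(10, 3))
        t = rng.integers(0, 2, 10).astype(float)
        alpha = float(rng.uniform(0.01, 1.0))
        g = bnn.cost_gradient(m, X, t, alpha)
        w0 = m.pack()
        eps = 1e-6
        for i in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += eps
            wm[i] -= eps
            num = (bnn.cost(m.with_params(wp), X, t, alpha)[0]
                   - bnn.cost(m.with_params(wm), X, t, alpha)[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestTrain:
    def test_separable_data_high_accuracy(self, rng):
        X, t = separable_data(rng)
        m = bnn.train(bnn.init_network(2, 5), X, t)
        labels, _ = bnn.predict(m, X)
        acc = np.mean((labels == "unhealed") == (t == 1))
        assert acc >= 0.95

    def test_huge_fixed_alpha_shrinks_weights(self, rng):
        X, t = separable_data(rng)
        m = bnn.train(bnn.init_network(2, 5), X, t, alpha0=1e6,
                      reestimate_alpha=False)
        assert np.abs(m.pack()).max() < 1e-2
        y = bnn.forward(m, X)
        assert np.abs(y - 0.5).max() < 0.05

    def test_shrinkage_monotone_in_fixed_alpha(self, rng):
        X, t = separable_data(rng)
        ews = []
        for alpha in [1e-2, 1e-1, 1e0, 1e1, 1e2]:
            m = bnn.train(bnn.init_network(2, 9), X, t, alpha0=alpha,
                          reestimate_alpha=False)
            ews.append(bnn.cost(m, X, t)[2])
        assert all(b <= a + 1e-9 for a, b in zip(ews, ews[1:]))

    def test_training_deterministic(self, rng):
        X, t = separable_data(rng)
        a = bnn.train(bnn.init_network(3, 7), X, t)
        b = bnn.train(bnn.init_network(3, 7), X, t)
        assert np.array_equal(a.pack(), b.pack())
        assert a.alpha == b.alpha


class TestEvidence:
    def test_finite_evidence_and_small_gamma_under_strong_prior(self):
        m = bnn.init_network(1, 0).with_params(np.zeros(6))
        m.trained = True
        X = np.zeros((6, 3))
        t = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        ev = bnn.log_evidence(m, X, t, alpha=1e6)
        assert np.isfinite(ev.log_evidence)
        assert ev.gamma == pytest.approx(0.0, abs=1e-3)

    def test_gamma_within_parameter_count(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(20, 3))
            t = r.integers(0, 2, 20).astype(float)
            m = bnn.train(bnn.init_network(3, seed), X, t)
            ev = bnn.log_evidence(m, X, t)
            assert 0.0 <= ev.gamma <= m.n_params

    def test_symmetry_factor_flag(self, rng):
        import math

        X, t = separable_data(rng, n_per=10)
        m = bnn.train(bnn.init_network(3, 1), X, t)
        base = bnn.log_evidence(m, X, t).log_evidence
        sym = bnn.log_evidence(m, X, t, include_symmetry=True).log_evidence
        assert sym == pytest.approx(base + math.log(math.factorial(3)) +
                                    3 * math.log(2))


class TestSelection:
    def test_argmax_and_tiebreak(self, rng):
        X, t = separable_data(rng, n_per=12)
        h, model, results = bnn.select_architecture(
            X, t, h_range=range(1, 4), restarts=2, seed=0)
        evs = {r.h: r.log_evidence for r in results}
        assert h == max(evs, key=lambda k: (evs[k], -k))
        assert model.trained and model.h == h

    def test_selected_model_accurate_on_separable_scores(self, rng):
        X, t = separable_data(rng)
        _, model, _ = bnn.select_architecture(
            X, t, h_range=range(1, 4), restarts=2, seed=1)
        labels, _ = bnn.predict(model, X)
        assert np.mean((labels == "unhealed") == (t == 1)) >= 0.95

    def test_selection_deterministic(self, rng):
        X, t = separable_data(rng, n_per=10)
        r1 = bnn.select_architecture(X, t, h_range=range(1, 3), restarts=2, seed=4)
        r2 = bnn.select_architecture(X, t, h_range=range(1, 3), restarts=2, seed=4)
        assert r1[0] == r2[0]
        assert np.array_equal(r1[1].pack(), r2[1].pack())

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            bnn.select_architecture(X, np.ones(10), restarts=1, seed=0)


class TestPredict:
    def test_threshold_extremes(self, rng):
        X, t = separable_data(rng, n_per=5)
        m = bnn.train(bnn.init_network(2, 2), X, t)
        lab0, _ = bnn.predict(m, X, threshold=0.0)
        assert (lab0 == "unhealed").all()
        lab1, probs = bnn.predict(m, X, threshold=1.0)
        assert ((lab1 == "unhealed") == (probs >= 1.0)).all()

    def test_probabilities_match_forward(self, rng):
        X, t = separable_data(rng, n_per=5)
        m = bnn.train(bnn.init_network(2, 2), X, t)
        _, probs = bnn.predict(m, X)
        assert np.allclose(probs, bnn.forward(m, X))

    def test_untrained_model_rejected(self, rng):
        with pytest.raises(ValueError):
            bnn.predict(bnn.init_network(2, 0), rng.normal(size=(3, 3)))

    def test_json_round_trip(self, rng, tmp_path):
        X, t = separable_data(rng, n_per=5)
        m = bnn.train(bnn.init_network(2, 2), X, t)
        m.to_json(tmp_path / "net.json")
        back = bnn.BNNModel.from_json(tmp_path / "net.json")
        assert np.array_equal(back.pack(), m.pack())
        assert back.alpha == m.alpha and back.trained
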