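import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_cca
from dcsae.model import (
    DcsaeConfig,
    Mlp,
    TwoViewBatch,
    cca_layer,
    dcsae_loss,
    kl_sparsity,
    kl_sparsity_grad,
    make_views,
    predict,
    train_dcsae,
)


class TestCcaLayer:
    def test_identical_views_fully_correlated(self, rng):
        h = rng.normal(size=(25, 4))
        corr, _, _ = cca_layer(h, h.copy(), 1e-12, 1e-12, 4)
        assert corr == pytest.approx(4.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generalized_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h1, h2 = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        corr, u, v = cca_layer(h1, h2, 1e-9, 1e-9, 3)
        oracle_corr, _ = oracle_cca(h1, h2, 1e-9, 3)
        assert corr == pytest.approx(oracle_corr, abs=1e-8)

    def test_whitening_constraints(self, rng):
        h1, h2 = rng.normal(size=(50, 4)), rng.normal(size=(50, 5))
        r = 1e-4
        _, u, v = cca_layer(h1, h2, r, r, 3)
        n = 50
        for h, w in ((h1, u), (h2, v)):
            hc = h - h.mean(axis=0)
            sigma = hc.T @ hc / n + r * np.eye(h.shape[1])
            assert np.abs(w.T @ sigma @ w - np.eye(3)).max() < 1e-6

    def test_independent_views_near_zero(self):
        rng = np.random.default_rng(0)
        h1 = rng.normal(size=(100_000, 2))
        h2 = rng.normal(size=(100_000, 2))
        corr, _, _ = cca_layer(h1, h2, 1e-9, 1e-9, 1)
        assert abs(corr) < 0.02

    def test_affine_invariance_of_one_view(self, rng):
        h1, h2 = rng.normal(size=(40, 3)), rng.normal(size=(40, 3))
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
        corr0, _, _ = cca_layer(h1, h2, 1e-12, 1e-12, 3)
        corr1, _, _ = cca_layer(h1 @ a + 5.0, h2, 1e-12, 1e-12, 3)
        assert corr0 == pytest.approx(corr1, abs=1e-8)

    def test_rank_error_when_too_few_samples(self, rng):
        h = rng.normal(size=(3, 4))
        with pytest.raises(ValueError):
            cca_layer(h, h, 1e-6, 1e-6, 3)

    def test_gradient_matches_finite_differences(self, rng):
        h1, h2 = rng.normal(size=(15, 3)), rng.normal(size=(15, 2))
        r = 1e-6
        _, _, _, g1, g2 = cca_layer(h1, h2, r, r, 2, with_grad=True)
        eps = 1e-6
        for h, g, other, first in ((h1, g1, h2, True), (h2, g2, h1, False)):
            fd = np.zeros_like(h)
            for i in range(h.shape[0]):
                for j in range(h.shape[1]):
                    hp, hm = h.copy(), h.copy()
                    hp[i, j] += eps
                    hm[i, j] -= eps
                    args_p = (hp, other) if first else (other, hp)
                    args_m = (hm, other) if first else (other, hm)
                    cp, _, _ = cca_layer(*args_p, r, r, 2)
                    cm, _, _ = cca_layer(*args_m, r, r, 2)
                    fd[i, j] = (cp - cm) / (2 * eps)
            assert np.abs(fd - g).max() < 1e-6


class TestKlSparsity:
    def test_zero_at_target(self):
        assert kl_sparsity(0.05, np.full(7, 0.05)) == 0.0

    def test_hand_computed_value(self):
        expected = 0.05 * math.log(0.1) + 0.95 * math.log(0.95 / 0.5)
        assert kl_sparsity(0.05, np.array([0.5])) == pytest.approx(expected, abs=1e-10)

    @given(
        st.floats(0.01, 0.99),
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_non_negative(self, target, acts):
        assert kl_sparsity(target, np.array(acts)) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        acts = rng.uniform(0.1, 0.9, size=(12, 4))
        g = kl_sparsity_grad(0.05, acts)
        eps = 1e-7
        for i in (0, 5):
            for j in range(4):
                ap, am = acts.copy(), acts.copy()
                ap[i, j] += eps
                am[i, j] -= eps
                fd = (
                    kl_sparsity(0.05, ap.mean(axis=0))
                    - kl_sparsity(0.05, am.mean(axis=0))
                ) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, abs=1e-6)


def linear_cfg(**kw):
    base = dict(
        hidden_sizes_f=(4,), hidden_sizes_g=(4,), canonical_dims=2,
        recon_weight=0.0, sparsity_weight_f=0.0, sparsity_weight_g=0.0,
        dropout_rate=0.0, activation="linear", epochs=50, learning_rate=0.01,
        reg_x=1e-6, reg_y=1e-6, rng_seed=0,
    )
    base.update(kw)
    return DcsaeConfig(**base)


def correlated_views(n=500, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 2))
    x = np.hstack([z + 0.3 * rng.normal(size=(n, 2)), rng.normal(size=(n, 2))])
    y = np.hstack([z + 0.3 * rng.normal(size=(n, 2)), rng.normal(size=(n, 2))])
    return x, y


class TestDcsaeLoss:
    def setup_method(self):
        x, y = correlated_views(n=60)
        self.batch = TwoViewBatch(x, y)

    def test_zero_weights_leave_negative_correlation(self):
        cfg = linear_cfg(epochs=1)
        model = train_dcsae(self.batch, cfg)
        total, comps = dcsae_loss(self.batch, model, cfg)
        assert total == pytest.approx(-comps["correlation"])

    def test_doubling_recon_weight_doubles_its_share(self):
        cfg1 = linear_cfg(epochs=1, recon_weight=1.0)
        model = train_dcsae(self.batch, cfg1)
        t1, c1 = dcsae_loss(self.batch, model, cfg1)
        cfg2 = linear_cfg(epochs=1, recon_weight=2.0)
        t2, c2 = dcsae_loss(self.batch, model, cfg2)
        assert c1["reconstruction_x"] == c2["reconstruction_x"]
        recon1 = c1["reconstruction_x"] + c1["reconstruction_y"]
        assert t2 - t1 == pytest.approx(recon1)


class TestTrainDcsae:
    def test_linear_reduction_recovers_classical_cca(self):
        x, y = correlated_views()
        model = train_dcsae(TwoViewBatch(x, y), linear_cfg())
        oracle_corr, _ = oracle_cca(x, y, 1e-6, 2)
        h1 = model.encoder_f.forward(x)
        h2 = model.encoder_g.forward(y)
        corr, _, _ = cca_layer(h1, h2, 1e-6, 1e-6, 2)
        assert corr == pytest.approx(oracle_corr, abs=0.02)

    def test_linear_reduction_projection_span(self):
        x, y = correlated_views()
        model = train_dcsae(TwoViewBatch(x, y), linear_cfg())
        _, u_oracle = oracle_cca(x, y, 1e-6, 2)
        z_model = model.embed(x)
        z_oracle = (x - x.mean(axis=0)) @ u_oracle
        q1, _ = np.linalg.qr(z_model - z_model.mean(axis=0))
        q2, _ = np.linalg.qr(z_oracle)
        cosines = np.linalg.svd(q1.T @ q2, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
        assert angles.max() < 5.0

    def test_fixed_seed_reproduces_training_log(self, small_table):
        norm, _ = small_table
        cfg = DcsaeConfig(epochs=5, rng_seed=3)
        logs = []
        for _ in range(2):
            m = train_dcsae(make_views(norm.values, norm.labels), cfg)
            logs.append([e["total"] for e in m.training_log])
        assert logs[0] == logs[1]

    def test_descent_on_linear_full_batch(self):
        x, y = correlated_views(n=200, seed=1)
        cfg = linear_cfg(learning_rate=1e-3, epochs=30)
        model = train_dcsae(TwoViewBatch(x, y), cfg)
        totals = [e["total"] for e in model.training_log]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_sparsity_weight_shrinks_activation_gap(self, small_table):
        norm, _ = small_table
        gaps = []
        for w in (0.0, 0.1, 1.0):
            cfg = DcsaeConfig(
                epochs=30, dropout_rate=0.0, recon_weight=0.0,
                sparsity_weight_f=w, sparsity_weight_g=w, rng_seed=0,
            )
            m = train_dcsae(make_views(norm.values, norm.labels), cfg)
            h = m.encoder_f.forward(norm.values)
            gaps.append(abs(h.mean() - cfg.sparsity_target_f))
        assert gaps[0] > gaps[1] > gaps[2]


class TestPredict:
    def test_separable_data_high_training_accuracy(self, easy_table):
        norm, _ = easy_table
        cfg = DcsaeConfig(dropout_rate=0.0, rng_seed=0)
        model = train_dcsae(make_views(norm.values, norm.labels), cfg)
        pred, scores = predict(model, norm.values)
        assert (pred == norm.labels).mean() >= 0.95
        assert scores.shape == (norm.n_samples, 2)

    def test_point_on_centroid_gets_its_class(self, small_table):
        norm, _ = small_table
        cfg = DcsaeConfig(epochs=5, rng_seed=0)
        model = train_dcsae(make_views(norm.values, norm.labels), cfg)
        # synthesize inputs whose projection is exactly each centroid
        z = model.embed(norm.values)
        for k, centroid in enumerate(model.class_centroids):
            i = int(np.linalg.norm(z - centroid, axis=1).argmin())
            pred, _ = predict(model, norm.values[i : i + 1])
            assert pred[0] == model.class_labels[
                int(np.linalg.norm(model.class_centroids - z[i], axis=1).argmin())
            ]

    def test_equidistant_tie_goes_to_lower_class(self, small_table):
        norm, _ = small_table
        cfg = DcsaeConfig(epochs=5, rng_seed=0)
        model = train_dcsae(make_views(norm.values, norm.labels), cfg)
        model.class_centroids = np.array([[1.0, 0.0], [-1.0, 0.0]])[:, : model.n_components]
        # a point projecting to the origin is equidistant; fabricate directly
        dists = np.linalg.norm(
            np.zeros((1, 1, model.class_centroids.shape[1]))
            - model.class_centroids[None], axis=2
        )
        assert dists.argmin(axis=1)[0] == 0  # argmin takes the first minimum

    def test_untrained_model_raises(self):
        rng = np.random.default_rng(0)
        from dcsae.model import DcsaeModel

        net = Mlp((2, 2), ("linear",), rng)
        model = DcsaeModel(net, net, net, net, DcsaeConfig(), 1)
        with pytest.raises(RuntimeError):
            predict(model, np.zeros((1, 2)))


def test_make_views_one_hot_and_split(rng):
    values = rng.normal(size=(6, 4))
    labels = np.array([0, 1, 2, 0, 1, 2])
    b = make_views(values, labels, "labels")
    assert b.view_y.shape == (6, 3)
    assert np.array_equal(b.view_y.sum(axis=1), np.ones(6))
    s = make_views(values, labels, "split")
    assert s.view_x.shape == (6, 2) and s.view_y.shape == (6, 2)
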