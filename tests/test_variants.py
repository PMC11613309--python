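"""Networks, losses and the hybrid variants: loss algebra, MLP forward
against plain matrix arithmetic, the embedding composition and the
per-variant prediction contract."""

import numpy as np
import pytest

from pinneco import autodiff as ad
from pinneco import flux, variants
from pinneco.nn import MLP, MLPSpec
from pinneco.variants import (
    LossSpec,
    Standardizer,
    build_variant,
    covariate_features,
    embedding_forward,
    loss_embedding,
    loss_mse,
    loss_parallel,
    loss_regularised,
)


class TestLossAlgebra:
    y = np.array([1.0, 2.0, 0.5])

    def test_parallel_reduces_to_mse_when_pm_is_zero(self):
        y_nn = np.array([0.4, 1.1, 0.2])
        assert loss_parallel(self.y, y_nn, np.zeros(3)) == loss_mse(self.y, y_nn)

    def test_parallel_zero_when_network_fits_residual_exactly(self):
        y_phy = np.array([0.7, 1.5, 0.1])
        assert loss_parallel(self.y, self.y - y_phy, y_phy) == 0.0

    def test_parallel_hand_value(self):
        # y=(1,2), y_nn=(0,0), y_phy=(1,1): ((0)^2 + (1)^2)/2 = 0.5
        assert loss_parallel([1.0, 2.0], [0.0, 0.0], [1.0, 1.0]) == pytest.approx(0.5)

    def test_regularised_at_lambda_zero_is_plain_mse(self):
        y_nn = np.array([0.4, 1.1, 0.2])
        y_phy = np.array([9.0, 9.0, 9.0])
        assert loss_regularised(self.y, y_nn, y_phy, 0.0) == loss_mse(self.y, y_nn)

    def test_regularised_vanishes_when_all_three_agree(self):
        for lam in (0.0, 0.3, 1.0):
            assert loss_regularised(self.y, self.y, self.y, lam) == 0.0

    def test_regularised_hand_value(self):
        # y=(1,1), y_nn=(0,0), y_phy=(2,2), lam=0.5: 1 + 0.5*4 = 3
        assert loss_regularised([1.0, 1.0], [0.0, 0.0], [2.0, 2.0], 0.5) == pytest.approx(3.0)

    def test_embedding_at_lambda_zero_is_bias_net_mse(self):
        y_nn = np.array([0.4, 1.1, 0.2])
        assert loss_embedding(self.y, y_nn, np.full(3, 7.0), 0.0) == loss_mse(self.y, y_nn)

    def test_embedding_hand_value(self):
        # y=(2,), y_nn=(1,), y_phy=(0,), lam=1: 1 + 4 = 5
        assert loss_embedding([2.0], [1.0], [0.0], 1.0) == pytest.approx(5.0)

    def test_losses_nonnegative_and_zero_only_at_coincidence(self, rng):
        y = rng.normal(size=20)
        y_nn = rng.normal(size=20)
        y_phy = rng.normal(size=20)
        assert loss_parallel(y, y_nn, y_phy) > 0
        assert loss_regularised(y, y_nn, y_phy, 0.7) > 0
        assert loss_embedding(y, y_nn, y_phy, 0.7) > 0
        half = 0.5 * y  # y - 0.5y + 0.5y is exact in binary floats
        assert loss_parallel(y, y - half, half) == 0.0
        assert loss_regularised(y, y, y, 1.0) == 0.0

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            loss_regularised(self.y, self.y, self.y, 1.5)
        with pytest.raises(ValueError, match="lambda"):
            LossSpec("regularised", -0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            loss_parallel(np.ones(3), np.ones(4), np.ones(3))


class TestMLPForward:
    def test_identity_configuration_passes_input_through(self):
        net = MLP(MLPSpec(3, (), 3, "identity"), rng=np.random.default_rng(0))
        net.weights[0].value = np.eye(3)
        net.biases[0].value = np.zeros(3)
        x = np.array([[1.0, -2.0, 0.5]])
        np.testing.assert_array_equal(ad.value_of(net(x)), x)

    def test_zero_weights_give_constant_bias_output(self):
        net = MLP(MLPSpec(4, (8,), 2, "tanh"), rng=np.random.default_rng(0))
        for w in net.weights:
            w.value[:] = 0.0
        net.biases[-1].value = np.array([3.0, -1.0])
        out = ad.value_of(net(np.random.default_rng(1).normal(size=(5, 4))))
        np.testing.assert_allclose(out, np.tile([3.0, -1.0], (5, 1)))

    def test_random_spec_matches_matrix_arithmetic(self, rng):
        net = MLP(MLPSpec(4, (6, 5), 2, "tanh"), rng=rng)
        x = rng.normal(size=(7, 4))
        h = np.tanh(x @ net.weights[0].value + net.biases[0].value)
        h = np.tanh(h @ net.weights[1].value + net.biases[1].value)
        expected = h @ net.weights[2].value + net.biases[2].value
        np.testing.assert_allclose(ad.value_of(net(x)), expected, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        net = MLP(MLPSpec(4, (6,), 1), rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="features"):
            net(np.ones((3, 5)))

    def test_state_dict_roundtrip(self):
        net = MLP(MLPSpec(3, (5,), 2, "relu"), rng=np.random.default_rng(2))
        back = MLP.from_state_dict(net.state_dict())
        x = np.random.default_rng(3).normal(size=(4, 3))
        np.testing.assert_array_equal(ad.value_of(net(x)), ad.value_of(back(x)))


@pytest.fixture(scope="module")
def short_series(single_site_dataset):
    return single_site_dataset.df.iloc[:90].reset_index(drop=True)


class TestEmbedding:
    def test_tau_always_within_prior_bounds(self, short_series, rng):
        variant = build_variant("embedding", rng=rng)
        _, _, tau = embedding_forward(variant.networks[0], variant.networks[1], short_series)
        lo, hi = flux.prior_bounds()
        tv = ad.value_of(tau)
        assert np.all(tv >= lo) and np.all(tv <= hi)

    def test_duplicating_rows_leaves_tau_unchanged(self, short_series, rng):
        import pandas as pd

        variant = build_variant("embedding", rng=rng)
        scaler = Standardizer.fit(covariate_features(short_series))
        _, _, tau1 = embedding_forward(variant.networks[0], variant.networks[1], short_series, scaler)
        doubled = pd.concat([short_series, short_series], ignore_index=True)
        # parameter averaging only: compare the squashed parameter vector
        x = scaler.transform(covariate_features(doubled))
        raw = variant.networks[0](x).mean(axis=0)
        tau2 = variants.squash_to_bounds(raw, *flux.prior_bounds())
        np.testing.assert_allclose(ad.value_of(tau1), ad.value_of(tau2), rtol=1e-12)

    def test_gradient_flows_through_process_model(self, short_series, rng):
        variant = build_variant("embedding", rng=rng)
        pn, bn = variant.networks
        scaler = Standardizer.fit(covariate_features(short_series))
        y = short_series["P_obs"].to_numpy()

        def loss_value():
            y_nn, y_phy, _ = embedding_forward(pn, bn, short_series, scaler)
            return loss_embedding(y, y_nn, y_phy, 1.0)

        loss = loss_value()
        loss.backward()
        g = pn.weights[0].grad[0, 0]
        assert g != 0.0
        h = 1e-6
        pn.weights[0].value[0, 0] += h
        up = loss_value().item()
        pn.weights[0].value[0, 0] -= 2 * h
        dn = loss_value().item()
        pn.weights[0].value[0, 0] += h
        fd = (up - dn) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-4)

    def test_identity_like_bias_net_reproduces_pm_output(self, short_series):
        """With the parameter net frozen at the true parameters and a bias net
        wired to select the (standardized) P feature, the embedding output
        tracks the process-model output up to the affine standardization."""
        variant = build_variant("embedding", rng=np.random.default_rng(0))
        pn, bn = variant.networks
        # selector bias net: single path passing standardized P through; a
        # large first-layer bias keeps the ReLU units on the linear branch
        # and is removed again at the output
        for w in bn.weights:
            w.value[:] = 0.0
        for b in bn.biases:
            b.value[:] = 0.0
        bn.weights[0].value[0, 0] = 1.0
        bn.biases[0].value[..., 0] = 10.0
        for layer in range(1, len(bn.weights)):
            bn.weights[layer].value[0, 0] = 1.0
        bn.biases[-1].value[..., 0] = -10.0
        y_nn, y_phy, _ = embedding_forward(pn, bn, short_series)
        corr = np.corrcoef(ad.value_of(y_nn), ad.value_of(y_phy))[0, 1]
        assert corr > 0.999


class TestPredictContract:
    def test_parallel_with_zero_network_equals_pm(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:60].copy()
        pm_out = np.column_stack([np.linspace(1, 3, 60), np.ones(60), np.full(60, 100.0)])
        variant = build_variant("parallel_physics", rng=rng)
        for w in variant.networks[0].weights:
            w.value[:] = 0.0
        pred = variants.predict(variant, df, pm_outputs=pm_out)
        np.testing.assert_allclose(pred, pm_out[:, 0])

    def test_regularisation_prediction_ignores_pm_at_inference(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:60].copy()
        variant = build_variant("regularisation", lam=0.9, rng=rng)
        a = variants.predict(variant, df, pm_outputs=None)
        b = variants.predict(variant, df, pm_outputs=np.full((60, 3), 123.0))
        np.testing.assert_array_equal(a, b)

    def test_pm_variant_returns_process_model_p(self, single_site_dataset):
        df = single_site_dataset.df.iloc[:60].copy()
        pm_out = np.column_stack([np.linspace(1, 3, 60), np.ones(60), np.full(60, 100.0)])
        variant = variants.ModelVariant(kind="pm")
        np.testing.assert_array_equal(variants.predict(variant, df, pm_outputs=pm_out), pm_out[:, 0])

    def test_missing_pm_outputs_raise(self, single_site_dataset, rng):
        df = single_site_dataset.df.iloc[:30].copy()
        variant = build_variant("bias_correction", rng=rng)
        with pytest.raises(ValueError, match="pm_outputs"):
            variants.predict(variant, df, pm_outputs=None)

    def test_all_variants_finite_on_test_year(self, single_site_dataset, rng):
        df = single_site_dataset.df
        test = df.loc[df["year"] == 2008].copy()
        pm_out = flux.run_pm_sites(test, flux.PMParams.defaults())[
            ["P_pm", "E_pm", "theta_pm"]
        ].to_numpy()
        for kind in ("naive", "bias_correction", "parallel_physics", "regularisation", "domain_adaptation"):
            variant = build_variant(kind, rng=rng, pm_params=flux.PMParams.defaults())
            pred = variants.predict(variant, test, pm_outputs=pm_out)
            assert np.all(np.isfinite(pred)), kind

    def test_variant_checkpoint_roundtrip(self, single_site_dataset, rng, tmp_path):
        df = single_site_dataset.df.iloc[:60].copy()
        pm_out = np.column_stack([np.linspace(1, 3, 60), np.ones(60), np.full(60, 100.0)])
        variant = build_variant("parallel_physics", rng=rng, pm_params=flux.PMParams.defaults())
        path = tmp_path / "variant.json"
        variant.save(path)
        back = variants.ModelVariant.load(path)
        np.testing.assert_allclose(
            variants.predict(variant, df, pm_outputs=pm_out),
            variants.predict(back, df, pm_outputs=pm_out),
        )

    def test_embedding_requires_two_networks(self):
        with pytest.raises(ValueError, match="two networks"):
            variants.ModelVariant(kind="embedding", networks=[MLP(MLPSpec(3, (4,), 1))])
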