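"""Delta-learning stacks, mixture-of-experts, Shapley attribution."""

import numpy as np
import pandas as pd
import pytest

from soqy import (
    MixtureOfExperts,
    ModelSpec,
    TrainedModel,
    fit_dlm,
    fit_moe,
    fit_normalizer,
    predict_dlm,
    predict_moe,
    shapley_attributions,
    train_single_model,
)


def smooth_frame(n=40, p=5, seed=0, noise=0.0, bias=False):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.uniform(size=(n, p)), columns=[f"d{k}" for k in range(p)])
    y = np.sin(2 * x["d0"]) + x["d1"] ** 2 + 0.5 * x["d2"]
    if bias:
        y = y + 0.3 * (x["d3"] > 0.5)  # structured bias the base misses
    return x, y + noise * rng.normal(size=n)


class _ConstantEstimator:
    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full(len(x), self.value)


def constant_model(rows, value):
    return TrainedModel(
        family="KNR",
        estimator=_ConstantEstimator(value),
        params={},
        normalizer=fit_normalizer(rows),
        descriptors=tuple(rows.columns),
    )


class TestDeltaLearning:
    def test_interpolating_delta_layer_vanishing_training_error(self):
        x, y = smooth_frame()
        dlm = fit_dlm(
            ModelSpec("KNR", seed=0, params={"n_neighbors": 5, "weights": "uniform", "p": 2}),
            ModelSpec("KRR", seed=0, params={"alpha": 1e-10, "gamma": 2.0}),
            x, y,
        )
        mse = float(np.mean((predict_dlm(dlm, x) - y) ** 2))
        assert mse < 1e-6 * float(np.var(y))

    def test_perfect_base_leaves_predictions_unchanged(self):
        x, y = smooth_frame()
        base = ModelSpec("KRR", seed=0, params={"alpha": 1e-10, "gamma": 2.0})
        delta = ModelSpec("KRR", seed=0, params={"alpha": 1e-2, "gamma": 1.0})
        dlm = fit_dlm(base, delta, x, y)
        solo = train_single_model(base, x, y)
        np.testing.assert_allclose(predict_dlm(dlm, x), solo.predict(x), atol=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_delta_layer_never_hurts_training_mse(self, seed):
        x, y = smooth_frame(seed=seed, noise=0.05, bias=True)
        base_spec = ModelSpec("KNR", seed=seed, params={"n_neighbors": 6, "weights": "uniform", "p": 2})
        dlm = fit_dlm(
            base_spec,
            ModelSpec("KRR", seed=seed, params={"alpha": 1e-4, "gamma": 1.0}),
            x, y,
        )
        base_mse = float(np.mean((dlm.layers[0].predict(x) - y) ** 2))
        dlm_mse = float(np.mean((predict_dlm(dlm, x) - y) ** 2))
        assert dlm_mse <= base_mse + 1e-12

    def test_hand_set_constant_layers_add(self):
        x, _ = smooth_frame(n=10)
        dlm_layers = [constant_model(x, 0.3), constant_model(x, 0.1)]
        from soqy.ensembles import DeltaLearningModel

        dlm = DeltaLearningModel(layers=dlm_layers)
        np.testing.assert_allclose(predict_dlm(dlm, x), 0.4)

    def test_row_permutation_permutes_predictions(self):
        x, y = smooth_frame()
        dlm = fit_dlm(
            ModelSpec("KNR", seed=0, params={"n_neighbors": 3, "weights": "uniform", "p": 2}),
            ModelSpec("KRR", seed=0, params={"alpha": 1e-3, "gamma": 1.0}),
            x, y,
        )
        perm = np.random.default_rng(1).permutation(len(x))
        np.testing.assert_allclose(
            predict_dlm(dlm, x.iloc[perm]), predict_dlm(dlm, x)[perm], atol=1e-12
        )

    def test_needs_two_layers(self):
        x, y = smooth_frame()
        with pytest.raises(ValueError, match="layers"):
            fit_dlm(ModelSpec("KRR"), ModelSpec("KRR"), x, y, layers=1)


class TestMixtureOfExperts:
    def _specs(self, seed=0):
        return [
            ModelSpec("KRR", seed=seed, params={"alpha": 1e-4, "gamma": 1.0}),
            ModelSpec("KNR", seed=seed, params={"n_neighbors": 4, "weights": "uniform", "p": 2}),
        ]

    def test_unit_weights_reduce_to_single_expert(self):
        x, y = smooth_frame()
        moe = fit_moe(self._specs(), x, y, seed=0)
        forced = MixtureOfExperts(experts=moe.experts, weights=np.array([1.0, 0.0]))
        np.testing.assert_array_equal(
            predict_moe(forced, x), moe.experts[0].predict(x)
        )

    def test_convexity_bounds_every_row(self):
        x, y = smooth_frame(seed=2)
        moe = fit_moe(self._specs(seed=2), x, y, seed=2)
        preds = np.stack([e.predict(x) for e in moe.experts])
        out = predict_moe(moe, x)
        assert np.all(out >= preds.min(axis=0) - 1e-12)
        assert np.all(out <= preds.max(axis=0) + 1e-12)

    def test_identical_experts_are_weight_invariant(self):
        x, y = smooth_frame()
        spec = ModelSpec("KRR", seed=0, params={"alpha": 1e-3, "gamma": 1.0})
        moe = fit_moe([spec, spec], x, y, seed=0)
        e0 = moe.experts[0].predict(x)
        np.testing.assert_allclose(predict_moe(moe, x), e0, atol=1e-10)

    def test_fitting_loss_not_worse_than_best_expert(self):
        x, y = smooth_frame(seed=3, noise=0.1)
        specs = self._specs(seed=3)
        moe = fit_moe(specs, x, y, seed=3, weight_fit="fit")
        preds = np.stack([e.predict(x) for e in moe.experts])
        expert_losses = np.mean((preds - y.to_numpy()) ** 2, axis=1)
        assert moe.metadata["fitting_loss"] <= expert_losses.min() + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_dominant_expert_gets_top_weight(self, seed):
        x, y = smooth_frame(seed=seed, noise=0.02)
        specs = [
            ModelSpec("KRR", seed=seed, params={"alpha": 1e-5, "gamma": 1.0}),
            # deliberately weak expert: single distant neighbor
            ModelSpec("KNR", seed=seed, params={"n_neighbors": 15, "weights": "uniform", "p": 1}),
        ]
        moe = fit_moe(specs, x, y, seed=seed)
        assert moe.weights[0] >= moe.weights[1]

    def test_budget_must_cover_unit_vectors(self):
        x, y = smooth_frame()
        with pytest.raises(ValueError, match="budget"):
            fit_moe(self._specs(), x, y, weight_budget=2)

    def test_weights_validated(self):
        x, y = smooth_frame()
        moe = fit_moe(self._specs(), x, y, seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureOfExperts(experts=moe.experts, weights=np.array([0.7, 0.7]))


class TestShapleyAttribution:
    def test_efficiency_property_exact(self):
        # attributions sum to f(x) - mean f(background) for any predictor
        rng = np.random.default_rng(0)
        w = np.array([1.0, -2.0, 0.5, 0.0])
        predict = lambda z: z @ w + 0.3 * np.sin(z[:, 0] * z[:, 1])
        x = rng.uniform(size=(6, 4))
        bg = rng.uniform(size=(8, 4))
        phi = shapley_attributions(predict, x, bg, n_permutations=4, seed=1)
        np.testing.assert_allclose(
            phi.sum(axis=1), predict(x) - predict(bg).mean(), atol=1e-10
        )

    def test_linear_model_recovers_exact_attributions(self):
        # for linear f, the Shapley value is w_j (x_j - mean bg_j) exactly
        rng = np.random.default_rng(2)
        w = np.array([2.0, -1.0, 0.0])
        predict = lambda z: z @ w
        x = rng.uniform(size=(5, 3))
        bg = rng.uniform(size=(10, 3))
        phi = shapley_attributions(predict, x, bg, n_permutations=2, seed=0)
        np.testing.assert_allclose(phi, (x - bg.mean(axis=0)) * w, atol=1e-10)

    def test_single_signal_descriptor_ranked_first(self):
        from soqy import shap_rank

        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.uniform(size=(60, 8)), columns=[f"d{k}" for k in range(8)])
        y = 3.0 * x["d4"] + 0.01 * rng.normal(size=60)
        model = train_single_model(
            ModelSpec("KRR", seed=0, params={"alpha": 1e-4, "gamma": 1.0}), x, y
        )
        order, importance = shap_rank(model, x, seed=0)
        assert order[0] == "d4"
        assert importance["d4"] > 5 * importance.drop("d4").max()

    def test_duplicated_descriptor_splits_credit(self):
        from soqy import shap_rank

        rng = np.random.default_rng(4)
        base = rng.uniform(size=60)
        x = pd.DataFrame({
            "s1": base, "s2": base,  # duplicated signal column
            "n1": rng.uniform(size=60), "n2": rng.uniform(size=60),
        })
        y = 2.0 * base
        model = train_single_model(
            ModelSpec("KRR", seed=0, params={"alpha": 1e-4, "gamma": 1.0}), x, y
        )
        _, importance = shap_rank(model, x, seed=0)
        assert importance["s1"] > importance[["n1", "n2"]].max()
        assert importance["s2"] > importance[["n1", "n2"]].max()
        # neither copy hoards the credit
        ratio = importance["s1"] / importance["s2"]
        assert 0.5 < ratio < 2.0
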