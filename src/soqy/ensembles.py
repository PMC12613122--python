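"""Hybrid regressors: delta-learning stacks and mixture-of-experts.

A delta-learning model (DLM) chains regressors: the base model predicts the
target, each subsequent "delta" layer is fitted to the training residuals
left by the stage before it, and the final prediction is the sum of all
layers.  The default is the bilayer with an SVR base and a KRR delta.

A mixture-of-experts (MoE) model fits several experts independently and
predicts a fixed convex combination of their outputs.  Weights are chosen
by seeded search over the probability simplex against the experts'
out-of-fold training predictions (so an overfit expert cannot buy all the
weight with its in-sample fit); fitting against raw training predictions is
available as an option.  The candidate set always includes every unit
vector, so the fitted-set loss of the mixture is never worse than the best
single expert's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .modeling import (
    ModelSpec,
    TrainedModel,
    apply_normalizer,
    fit_normalizer,
    train_single_model,
    _build_estimator,
)

__all__ = ["DeltaLearningModel", "MixtureOfExperts", "fit_dlm", "predict_dlm", "fit_moe", "predict_moe"]


@dataclass
class DeltaLearningModel:
    """Base model plus one or more residual-correcting delta layers."""

    layers: list[TrainedModel]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a delta-learning model needs at least 2 layers")

    @property
    def descriptors(self) -> tuple[str, ...]:
        return self.layers[0].descriptors

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict_dlm(self, rows)


@dataclass
class MixtureOfExperts:
    """Independently fitted experts combined with fixed convex weights."""

    experts: list[TrainedModel]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.experts),):
            raise ValueError("one weight per expert required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        self.weights = w

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict_moe(self, rows)


def fit_dlm(
    base_spec: ModelSpec,
    delta_spec: ModelSpec,
    rows: pd.DataFrame,
    target,
    descriptors: Sequence[str] | None = None,
    layers: int = 2,
) -> DeltaLearningModel:
    """Fit a delta-learning stack of ``layers`` models on the training rows.

    The base model fits the target; layer k >= 2 fits the residual the
    first k-1 layers leave on the training rows.  All layers share the
    descriptor manifest.
    """
    if layers < 2:
        raise ValueError("a delta-learning model needs layers >= 2")
    y = np.asarray(target, dtype=float).ravel()
    descriptors = tuple(descriptors if descriptors is not None else rows.columns)
    fitted = [train_single_model(base_spec, rows, y, descriptors=descriptors)]
    residual = y - fitted[0].predict(rows)
    for _ in range(layers - 1):
        delta = train_single_model(delta_spec, rows, residual, descriptors=descriptors)
        fitted.append(delta)
        residual = residual - delta.predict(rows)
    return DeltaLearningModel(layers=fitted)


def predict_dlm(model: DeltaLearningModel, rows: pd.DataFrame) -> np.ndarray:
    """Sum of the base prediction and every delta correction."""
    missing = [c for c in model.descriptors if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack descriptor column(s) {missing}")
    return np.sum([layer.predict(rows) for layer in model.layers], axis=0)


def _out_of_fold_predictions(
    expert: TrainedModel, rows: pd.DataFrame, y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Cross-validated training predictions using the expert's hyperparameters."""
    sub = rows[list(expert.descriptors)].reset_index(drop=True)
    n = len(sub)
    preds = np.empty(n)
    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    for tr, te in kf.split(sub):
        norm = fit_normalizer(sub.iloc[tr])
        est = _build_estimator(expert.family, expert.params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(apply_normalizer(norm, sub.iloc[tr]).to_numpy(), y[tr])
        preds[te] = est.predict(apply_normalizer(norm, sub.iloc[te]).to_numpy())
    return preds


def fit_moe(
    expert_specs: Sequence[ModelSpec],
    rows: pd.DataFrame,
    target,
    descriptors: Sequence[str] | None = None,
    weight_budget: int = 200,
    seed: int = 0,
    weight_fit: str = "oof",
    n_folds: int = 5,
) -> MixtureOfExperts:
    """Fit the experts and choose convex weights on training predictions.

    ``weight_fit="oof"`` (default) scores candidate weights against 5-fold
    out-of-fold predictions; ``"fit"`` scores against raw training fits.
    ``weight_budget`` counts candidate weight vectors and must be at least
    the number of experts plus one so every unit vector is covered.
    """
    if len(expert_specs) < 2:
        raise ValueError("a mixture needs at least 2 experts")
    if weight_budget < len(expert_specs) + 1:
        raise ValueError(
            f"weight budget {weight_budget} cannot cover the {len(expert_specs)} "
            "unit-weight vectors plus one candidate"
        )
    if weight_fit not in ("oof", "fit"):
        raise ValueError(f"weight_fit must be 'oof' or 'fit', got {weight_fit!r}")
    y = np.asarray(target, dtype=float).ravel()
    descriptors = tuple(descriptors if descriptors is not None else rows.columns)
    experts = [
        train_single_model(spec, rows, y, descriptors=descriptors) for spec in expert_specs
    ]
    if weight_fit == "oof":
        pred_matrix = np.stack(
            [_out_of_fold_predictions(e, rows, y, n_folds, seed) for e in experts]
        )
    else:
        pred_matrix = np.stack([e.predict(rows) for e in experts])

    k = len(experts)
    rng = np.random.default_rng(seed)
    candidates = [np.eye(k)[i] for i in range(k)]
    candidates.append(np.full(k, 1.0 / k))
    while len(candidates) < weight_budget:
        candidates.append(rng.dirichlet(np.ones(k)))
    losses = [float(np.mean((w @ pred_matrix - y) ** 2)) for w in candidates]
    best = int(np.argmin(losses))
    return MixtureOfExperts(
        experts=experts,
        weights=candidates[best],
        metadata={
            "weight_fit": weight_fit,
            "seed": seed,
            "weight_budget": weight_budget,
            "fitting_loss": losses[best],
        },
    )


def predict_moe(model: MixtureOfExperts, rows: pd.DataFrame) -> np.ndarray:
    """Weighted average of the expert predictions."""
    preds = np.stack([e.predict(rows) for e in model.experts])
    return model.weights @ preds
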