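"""Small-data QSPR modeling protocol.

The protocol: min-max normalization fitted on training data only (the
spin-orbit coupling descriptor is log10-transformed first), a 90:10 random
split, six candidate single regressors (SVR, KRR, GPR, XGBoost, RFR, KNR)
with seeded random-search hyperparameter optimization, leave-one-out
cross-validated Q^2 as the stability measure, Shapley-based descriptor
ranking, a descriptor-filter loop over sizes 30-50 in steps of 5, and a
QSPR acceptability gate (Q^2 >= 0.6 in cross-validation and R^2 >= 0.6 on
the external test set).

Hyperparameter search is a sequential random sampler over per-family spaces
(log-uniform for scale-type parameters); it is fully deterministic under a
seed and its budget is the number of sampled configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = [
    "NormalizationSpec",
    "ModelSpec",
    "TrainedModel",
    "MetricsRecord",
    "MODEL_FAMILIES",
    "fit_normalizer",
    "apply_normalizer",
    "split_dataset",
    "train_single_model",
    "loo_q2",
    "evaluate",
    "qspr_gate",
    "descriptor_filter",
]

SOC_LOG_FLOOR = 1e-3  # cm^-1; admits zero-coupling toy inputs

MODEL_FAMILIES = ("SVR", "KRR", "GPR", "XGBoost", "RFR", "KNR")


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Per-descriptor min-max statistics from the training rows.

    Descriptors listed in ``log_columns`` (by default the spin-orbit
    coupling) are log10-transformed before the min and max are taken.
    Constant columns map to 0 and are flagged.
    """

    columns: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    log_columns: tuple[str, ...] = ("soc",)
    constant_columns: tuple[str, ...] = ()


def _apply_log(frame: pd.DataFrame, log_columns: Sequence[str]) -> pd.DataFrame:
    frame = frame.copy()
    for col in log_columns:
        if col in frame.columns:
            frame[col] = np.log10(np.maximum(frame[col].astype(float), SOC_LOG_FLOOR))
    return frame


def fit_normalizer(
    rows: pd.DataFrame, log_columns: Sequence[str] = ("soc",)
) -> NormalizationSpec:
    """Min-max statistics over the given (training) rows only."""
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    bad = rows.columns[~rows.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"non-numeric values in column(s) {list(bad)}")
    tf = _apply_log(rows.astype(float), log_columns)
    mins = tf.min(axis=0).to_numpy()
    maxs = tf.max(axis=0).to_numpy()
    constant = tuple(tf.columns[mins == maxs])
    if constant:
        warnings.warn(f"constant descriptor column(s) mapped to 0: {constant}")
    return NormalizationSpec(
        columns=tuple(tf.columns),
        mins=mins,
        maxs=maxs,
        log_columns=tuple(log_columns),
        constant_columns=constant,
    )


def apply_normalizer(spec: NormalizationSpec, rows: pd.DataFrame) -> pd.DataFrame:
    """(x - min) / (max - min) with the spec's training statistics.

    Out-of-range values are not clipped; they may fall outside [0, 1].
    """
    missing = [c for c in spec.columns if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack normalized column(s) {missing}")
    tf = _apply_log(rows[list(spec.columns)].astype(float), spec.log_columns)
    span = spec.maxs - spec.mins
    safe = np.where(span == 0, 1.0, span)
    out = (tf.to_numpy() - spec.mins) / safe
    out[:, span == 0] = 0.0
    return pd.DataFrame(out, columns=spec.columns, index=rows.index)


# --------------------------------------------------------------------------
# split
# --------------------------------------------------------------------------

def split_dataset(
    frame: pd.DataFrame, ratio: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split with round-to-nearest training size."""
    if len(frame) == 0:
        raise ValueError("cannot split an empty table")
    n = len(frame)
    n_train = int(round(n * ratio))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = frame.iloc[perm[:n_train]].reset_index(drop=True)
    test = frame.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


# --------------------------------------------------------------------------
# model families and search spaces
# --------------------------------------------------------------------------

def _build_estimator(family: str, params: Mapping[str, object], seed: int):
    if family == "SVR":
        return SVR(C=params["C"], epsilon=params["epsilon"], kernel=params["kernel"],
                   gamma=params.get("gamma", "scale"), cache_size=200, max_iter=100_000)
    if family == "KRR":
        return KernelRidge(alpha=params["alpha"], kernel="rbf", gamma=params["gamma"])
    if family == "GPR":
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=params["length_scale"], length_scale_bounds=(1e-3, 1e3)
        ) + WhiteKernel(noise_level=params["noise"], noise_level_bounds=(1e-10, 1e1))
        return GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed,
            n_restarts_optimizer=int(params.get("n_restarts", 0)),
        )
    if family == "XGBoost":
        return XGBRegressor(
            max_depth=int(params["max_depth"]), learning_rate=params["learning_rate"],
            n_estimators=int(params["n_estimators"]), subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"], random_state=seed,
            n_jobs=1, verbosity=0,
        )
    if family == "RFR":
        return RandomForestRegressor(
            n_estimators=int(params["n_estimators"]), max_depth=int(params["max_depth"]),
            max_features=params["max_features"], random_state=seed, n_jobs=1,
        )
    if family == "KNR":
        return KNeighborsRegressor(
            n_neighbors=int(params["n_neighbors"]), weights=params["weights"],
            p=int(params["p"]),
        )
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


def _default_space(family: str) -> dict:
    spaces = {
        "SVR": {
            "C": ("log", 1e-2, 1e3),
            "epsilon": ("log", 1e-4, 1e-1),
            "kernel": ("choice", ["rbf", "linear", "poly"]),
        },
        "KRR": {
            "alpha": ("log", 1e-6, 1e1),
            "gamma": ("log", 1e-4, 1e2),
        },
        "GPR": {
            "noise": ("log", 1e-8, 1e-1),
            "length_scale": ("log", 1e-2, 1e2),
            "n_restarts": ("int", 0, 2),
        },
        "XGBoost": {
            "max_depth": ("int", 2, 8),
            "learning_rate": ("log", 1e-3, 0.3),
            "n_estimators": ("int", 50, 500),
            "subsample": ("uniform", 0.5, 1.0),
            "colsample_bytree": ("uniform", 0.5, 1.0),
        },
        "RFR": {
            "n_estimators": ("int", 50, 500),
            "max_depth": ("int", 2, 12),
            "max_features": ("uniform", 0.2, 1.0),
        },
        "KNR": {
            "n_neighbors": ("int", 1, 15),
            "weights": ("choice", ["uniform", "distance"]),
            "p": ("choice", [1, 2]),
        },
    }
    return spaces[family]


def _sample_params(space: Mapping[str, tuple], rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "uniform":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "choice":
            out[name] = spec[1][int(rng.integers(len(spec[1])))]
        else:
            raise ValueError(f"unknown space kind {kind!r} for {name}")
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One regressor family plus its search space, budget and seed."""

    family: str
    budget: int = 30
    seed: int = 0
    objective: str = "cv5"  # or "loo"
    space: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)  # fixed params bypass the search

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        if self.budget < 1:
            raise ValueError("search budget must be >= 1")


@dataclass
class TrainedModel:
    """A fitted regressor with its normalization and descriptor manifest."""

    family: str
    estimator: object
    params: dict
    normalizer: NormalizationSpec
    descriptors: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.descriptors if c not in rows.columns]
        if missing:
            raise ValueError(f"rows lack descriptor column(s) {missing}")
        x = apply_normalizer(self.normalizer, rows[list(self.descriptors)])
        pred = np.asarray(self.estimator.predict(x.to_numpy()), dtype=float).ravel()
        if not np.all(np.isfinite(pred)):
            raise RuntimeError("model produced non-finite predictions")
        return pred


def _cv_objective(
    family: str, params: dict, x: np.ndarray, y: np.ndarray, objective: str, seed: int
) -> float:
    n = len(y)
    if objective == "loo":
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        k = min(5, n)
        splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(x))
    preds = np.empty(n)
    for tr, te in splits:
        est = _build_estimator(family, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x[tr], y[tr])
        preds[te] = est.predict(x[te])
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return -ss_res
    return 1.0 - ss_res / ss_tot


def train_single_model(
    spec: ModelSpec,
    rows: pd.DataFrame,
    target: pd.Series | np.ndarray,
    descriptors: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one regressor on ``rows`` with seeded random hyperparameter search.

    The normalizer is fitted on these rows only and stored with the model;
    the best configuration (by the spec's cross-validation objective) is
    refit on all rows.  With ``spec.params`` set, the search is skipped.
    """
    descriptors = tuple(descriptors if descriptors is not None else rows.columns)
    y = np.asarray(target, dtype=float).ravel()
    sub = rows[list(descriptors)]
    norm = fit_normalizer(sub)
    x = apply_normalizer(norm, sub).to_numpy()
    rng = np.random.default_rng(spec.seed)

    if spec.params:
        candidates = [dict(spec.params)]
    else:
        space = {**_default_space(spec.family), **spec.space}
        candidates = [_sample_params(space, rng) for _ in range(spec.budget)]

    best_params, best_score = None, -np.inf
    for params in candidates:
        if len(candidates) == 1:
            score = 0.0  # nothing to compare
        else:
            score = _cv_objective(spec.family, params, x, y, spec.objective, spec.seed)
        if score > best_score:
            best_params, best_score = params, score

    est = _build_estimator(spec.family, best_params, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, y)
    return TrainedModel(
        family=spec.family,
        estimator=est,
        params=dict(best_params),
        normalizer=norm,
        descriptors=descriptors,
        metadata={
            "seed": spec.seed,
            "budget": spec.budget,
            "objective": spec.objective,
            "objective_value": float(best_score),
        },
    )


def loo_q2(
    spec: ModelSpec,
    rows: pd.DataFrame,
    target: pd.Series | np.ndarray,
    descriptors: Sequence[str] | None = None,
    params: Mapping[str, object] | None = None,
) -> float:
    """Leave-one-out cross-validated Q^2 on the training rows.

    Each fold refits the normalizer and the model on the remaining n-1 rows
    and predicts the left-out row; Q^2 = 1 - PRESS / SS_tot.  ``params``
    fixes the hyperparameters for every fold (the usual stability check for
    an already-optimized configuration); otherwise ``spec.params`` or the
    family defaults sampled once under the spec seed are used.
    """
    y = np.asarray(target, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 rows")
    descriptors = tuple(descriptors if descriptors is not None else rows.columns)
    if params is None:
        params = spec.params or _sample_params(
            {**_default_space(spec.family), **spec.space}, np.random.default_rng(spec.seed)
        )
    sub = rows[list(descriptors)].reset_index(drop=True)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        tr = sub[mask]
        norm = fit_normalizer(tr)
        est = _build_estimator(spec.family, params, spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(apply_normalizer(norm, tr).to_numpy(), y[mask])
        preds[i] = est.predict(apply_normalizer(norm, sub[~mask]).to_numpy())[0]
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# --------------------------------------------------------------------------
# metrics and gate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsRecord:
    """R^2, maximum/mean absolute error and mean squared error."""

    r2: float
    maxae: float
    mae: float
    mse: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "maxae": self.maxae, "mae": self.mae, "mse": self.mse}


def evaluate(y_true, y_pred) -> MetricsRecord:
    """Standard regression metrics; R^2 = 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length truth/prediction vectors of size >= 2")
    err = np.abs(y_true - y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("truths have zero variance; R^2 undefined")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return MetricsRecord(
        r2=r2, maxae=float(err.max()), mae=float(err.mean()), mse=float(np.mean(err**2))
    )


def qspr_gate(
    q2: float, external_r2: float, q2_threshold: float = 0.6, r2_threshold: float = 0.6
) -> tuple[bool, list[str]]:
    """QSPR acceptability: internal Q^2 and external R^2 both at threshold."""
    reasons = []
    if q2 < q2_threshold:
        reasons.append(f"Q^2 {q2:.3f} < {q2_threshold}")
    if external_r2 < r2_threshold:
        reasons.append(f"external R^2 {external_r2:.3f} < {r2_threshold}")
    return (not reasons), reasons


# --------------------------------------------------------------------------
# descriptor filter
# --------------------------------------------------------------------------

def descriptor_filter(
    spec: ModelSpec,
    train_rows: pd.DataFrame,
    train_target,
    ranking: Sequence[str],
    sizes: Sequence[int] = (30, 35, 40, 45, 50),
    test_rows: pd.DataFrame | None = None,
    test_target=None,
    compute_loo: bool = True,
    select_by: str = "loo_q2",
) -> tuple[TrainedModel, pd.DataFrame]:
    """Retrain on the top-k ranked descriptors for each size k.

    Returns the selected model (highest LOO Q^2 by default; ties break to
    the smaller k) and a per-size report with training/test metrics and
    LOO Q^2.  Sizes beyond the number of available descriptors collapse to
    a single capped evaluation.
    """
    ranking = list(ranking)
    capped = sorted({min(k, len(ranking)) for k in sizes})
    if capped != sorted(set(sizes)):
        warnings.warn(
            f"descriptor sizes {sorted(set(sizes))} capped to {capped} "
            f"({len(ranking)} descriptors available)"
        )
    report_rows = []
    best = None
    for k in capped:
        top = ranking[:k]
        model = train_single_model(spec, train_rows, train_target, descriptors=top)
        row: dict = {"size": k}
        train_metrics = evaluate(train_target, model.predict(train_rows))
        row.update({f"train_{m}": v for m, v in train_metrics.as_dict().items()})
        if test_rows is not None:
            test_metrics = evaluate(test_target, model.predict(test_rows))
            row.update({f"test_{m}": v for m, v in test_metrics.as_dict().items()})
        if compute_loo:
            row["loo_q2"] = loo_q2(
                spec, train_rows, train_target, descriptors=top, params=model.params
            )
        report_rows.append(row)
        key = row.get(select_by)
        if key is None:
            raise ValueError(f"selection criterion {select_by!r} was not computed")
        if best is None or key > best[0]:  # strict >: ties keep the smaller k
            best = (key, model)
    return best[1], pd.DataFrame(report_rows)
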