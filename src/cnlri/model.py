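"""Gradient-boosted-tree retention-index regressors.

Two named hyperparameter presets are shipped, one for descriptor-based
models and one for CNL (neutral-loss) models; both use an RMSE
objective with early stopping after 5 non-improving rounds on a
validation set. Splitting is stratified over three retention-index
classes (200-440, 440-700, 700-1041 r_i units) so the skewed label
distribution is represented in every subset. Evaluation reports the
coefficient of determination, RMSE and the maximum absolute error.

The boosting backend sits behind a thin contract (fit with early
stopping, predict, feature importance); LightGBM implements it here.
Training is single-threaded and deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "GBTConfig",
    "DESCRIPTOR_PRESET",
    "CNL_PRESET",
    "SplitSpec",
    "EvalReport",
    "TrainedModel",
    "stratified_split",
    "ri_classes",
    "train",
    "cross_validate",
    "refit_top_features",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GBTConfig:
    """Hyperparameters of one boosted-tree regressor (RMSE loss)."""

    iterations: int
    learning_rate: float
    depth: int
    max_leaves: int
    min_data_in_leaf: int = 1
    l2_leaf_reg: float = 0.0
    early_stopping_rounds: int = 5
    random_seed: int = 0

    def with_seed(self, seed: int) -> "GBTConfig":
        return GBTConfig(**{**asdict(self), "random_seed": int(seed)})


#: Preset for descriptor-based models.
DESCRIPTOR_PRESET = GBTConfig(
    iterations=450, learning_rate=0.03, depth=8, max_leaves=256,
    min_data_in_leaf=1, l2_leaf_reg=10.0,
)

#: Preset for cumulative-neutral-loss models.
CNL_PRESET = GBTConfig(
    iterations=5000, learning_rate=0.077, depth=6, max_leaves=64,
    min_data_in_leaf=1, l2_leaf_reg=3.0,
)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified-split specification over retention-index classes.

    ``class_edges`` delimit contiguous classes; the defaults give the
    three classes 200-440, 440-700 and 700-1041 r_i units. Values
    outside the outer edges join the nearest class.
    """

    class_edges: tuple[float, ...] = (200.0, 440.0, 700.0, 1041.0)
    train_fraction: float = 0.85
    seed: int = 0


@dataclass(frozen=True)
class EvalReport:
    r_squared: float
    rmse: float
    max_error: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedModel:
    """A fitted booster with its feature contract and provenance."""

    booster: lgb.LGBMRegressor
    feature_names: list[str]
    config: GBTConfig
    used_features: list[str]
    best_iteration: int | None
    training_fingerprint: str

    @property
    def importances(self) -> pd.Series:
        """Split-gain importance per feature (the backend's native metric)."""
        gains = self.booster.booster_.feature_importance(importance_type="gain")
        return pd.Series(gains, index=self.feature_names)


def ri_classes(labels: np.ndarray, spec: SplitSpec = SplitSpec()) -> np.ndarray:
    """Class index (0..k-1) of each retention-index value."""
    labels = np.asarray(labels, dtype=float)
    inner = np.asarray(spec.class_edges[1:-1], dtype=float)
    return np.digitize(labels, inner, right=False)


def stratified_split(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test index split, stratified over the r_i classes.

    Within each class the train fraction is honored to within one
    sample; empty classes are skipped with a warning. Deterministic for
    a fixed ``spec.seed``.
    """
    labels = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    classes = ri_classes(labels, spec)
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(len(spec.class_edges) - 1):
        members = np.flatnonzero(classes == c)
        if members.size == 0:
            logger.warning("retention-index class %d is empty; skipped", c)
            continue
        perm = rng.permutation(members)
        n_train = int(round(spec.train_fraction * members.size))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], dtype=int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    return train, test


def _as_frame(features, feature_names: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    features = np.asarray(features)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[1])]
    return pd.DataFrame(features, columns=list(feature_names))


def _fingerprint(X: pd.DataFrame, y: np.ndarray, config: GBTConfig) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(dtype=np.float64)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=np.float64)).tobytes())
    h.update(json.dumps(asdict(config), sort_keys=True).encode())
    return h.hexdigest()[:16]


def train(
    features,
    labels: np.ndarray,
    config: GBTConfig,
    validation: tuple | None = None,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a boosted-tree r_i regressor under ``config``.

    ``validation`` is an optional ``(features, labels)`` holdout; when
    given, training stops once validation RMSE has not improved for
    ``config.early_stopping_rounds`` rounds.
    """
    X = _as_frame(features, feature_names)
    y = np.asarray(labels, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and labels disagree on length")
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; regression is degenerate")

    booster = lgb.LGBMRegressor(
        objective="regression",
        n_estimators=config.iterations,
        learning_rate=config.learning_rate,
        max_depth=config.depth,
        num_leaves=config.max_leaves,
        min_child_samples=config.min_data_in_leaf,
        reg_lambda=config.l2_leaf_reg,
        random_state=config.random_seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    fit_kwargs: dict = {}
    if validation is not None:
        Xv = _as_frame(validation[0], list(X.columns))
        yv = np.asarray(validation[1], dtype=float)
        fit_kwargs["eval_set"] = [(Xv[X.columns], yv)]
        fit_kwargs["eval_metric"] = "rmse"
        fit_kwargs["callbacks"] = [
            lgb.early_stopping(config.early_stopping_rounds, verbose=False)
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        booster.fit(X, y, **fit_kwargs)
    best_iter = getattr(booster, "best_iteration_", None)
    gains = booster.booster_.feature_importance(importance_type="gain")
    used = [name for name, g in zip(X.columns, gains) if g > 0]
    return TrainedModel(
        booster=booster,
        feature_names=list(X.columns),
        config=config,
        used_features=used,
        best_iteration=best_iter,
        training_fingerprint=_fingerprint(X, y, config),
    )


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predict r_i; DataFrame columns are aligned to the model by name."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in model.feature_names]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}; extra: {extra}")
        X = features[model.feature_names]
    else:
        X = _as_frame(features, model.feature_names)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
    return np.asarray(model.booster.predict(X))


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> EvalReport:
    """R^2 = 1 - SSres/SStot, RMSE and maximum absolute error."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape or predictions.size < 2:
        raise ValueError("predictions and truth must share a length >= 2")
    resid = predictions - truth
    rmse = float(np.sqrt(np.mean(resid**2)))
    max_err = float(np.max(np.abs(resid)))
    if np.ptp(truth) == 0:
        logger.warning("zero-variance truth: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = float(r2_score(truth, predictions))
    return EvalReport(r_squared=r2, rmse=rmse, max_error=max_err, n=truth.size)


def cross_validate(
    features,
    labels: np.ndarray,
    config: GBTConfig,
    k: int = 5,
    spec: SplitSpec = SplitSpec(),
) -> tuple[list[EvalReport], dict]:
    """k-fold cross-validation stratified over the r_i classes.

    Each fold serves as the validation set (early stopping) and is then
    scored, mirroring the tuning protocol. Returns per-fold reports and
    a mean +/- sd summary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels, dtype=float)
    if len(y) < k:
        raise ValueError(f"n={len(y)} rows cannot be split into k={k} folds")
    X = _as_frame(features, None)
    classes = ri_classes(y, spec)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    reports = []
    for train_rows, valid_rows in splitter.split(X, classes):
        m = train(
            X.iloc[train_rows],
            y[train_rows],
            config,
            validation=(X.iloc[valid_rows], y[valid_rows]),
        )
        reports.append(evaluate(predict(m, X.iloc[valid_rows]), y[valid_rows]))
    summary = {
        "r_squared_mean": float(np.mean([r.r_squared for r in reports])),
        "r_squared_sd": float(np.std([r.r_squared for r in reports], ddof=1)),
        "rmse_mean": float(np.mean([r.rmse for r in reports])),
        "rmse_sd": float(np.std([r.rmse for r in reports], ddof=1)),
    }
    return reports, summary


def refit_top_features(
    model: TrainedModel,
    features,
    labels: np.ndarray,
    top_k: int = 40,
    validation: tuple | None = None,
) -> TrainedModel:
    """Refit on the ``top_k`` most important features of a fitted model.

    Features are ranked by the backend's gain importance; ties break by
    original feature order (stable sort). Validation, when given, is
    restricted to the same columns.
    """
    if top_k > len(model.feature_names):
        raise ValueError("top_k exceeds the number of features")
    order = np.argsort(-model.importances.to_numpy(), kind="stable")
    top = [model.feature_names[i] for i in order[:top_k]]
    X = _as_frame(features, model.feature_names)[top]
    val = None
    if validation is not None:
        val = (_as_frame(validation[0], model.feature_names)[top], validation[1])
    return train(X, labels, model.config, validation=val)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize to one binary plus a JSON sidecar with the contract."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "feature_names": model.feature_names,
        "used_features": model.used_features,
        "config": asdict(model.config),
        "best_iteration": model.best_iteration,
        "training_fingerprint": model.training_fingerprint,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
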