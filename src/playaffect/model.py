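"""User-tailored neural classifier: one network per subject.

Each subject gets their own single-hidden-layer feed-forward network,
trained exclusively on that subject's calibration data.  Hyperparameters
(hidden units, L2 strength, learning rate) are chosen by random search
scored by mean ROC AUC over repeated stratified k-fold cross-validation
(default 3 x 10-fold), then the best candidate is refit on all training
data.  Features are z-standardized inside the fitted pipeline, so the
scaling is learned from training data only and applied verbatim at test
time — no leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import RandomizedSearchCV, RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import InvalidInputError, InvalidTrainingSetError

LABELS = ("boredom", "stress")  # classes_ order; stress is the positive class


@dataclass
class ModelConfig:
    """Search space and cross-validation settings for one subject's model."""

    search_iterations: int = 30
    hidden_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    l2_range: tuple[float, float] = (1e-5, 1.0)
    lr_range: tuple[float, float] = (1e-4, 1e-1)
    cv_folds: int = 10
    cv_repeats: int = 3
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise InvalidInputError("cv_folds must be >= 2")
        if self.search_iterations < 1:
            raise InvalidInputError("search_iterations must be >= 1")


@dataclass
class UserModel:
    """A fitted per-subject network with its selection provenance."""

    subject_id: int
    feature_names: tuple[str, ...]
    pipeline: Pipeline
    best_params: dict
    cv_auc: float
    seed: int

    @property
    def classes_(self) -> np.ndarray:
        return self.pipeline.named_steps["mlp"].classes_

    @property
    def standardization(self) -> tuple[np.ndarray, np.ndarray]:
        scaler = self.pipeline.named_steps["scale"]
        return scaler.mean_, scaler.scale_


def _make_pipeline(cfg: ModelConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    solver="adam",
                    learning_rate="constant",
                    max_iter=cfg.max_epochs,
                    early_stopping=False,
                    random_state=cfg.seed,
                ),
            ),
        ]
    )


def train_user_model(
    samples: pd.DataFrame,
    feature_names: Sequence[str],
    cfg: ModelConfig | None = None,
    subject_id: int = 0,
) -> UserModel:
    """Random-search-train one subject's network on labeled calibration samples.

    ``samples`` must hold the feature columns plus a ``label`` column with
    both classes present (>= 2 samples each); provenance columns, when
    present, must point at calibration games only.
    """
    cfg = cfg or ModelConfig()
    feature_names = tuple(feature_names)
    if len(samples) == 0:
        raise InvalidTrainingSetError("empty training set")
    missing = set(feature_names) - set(samples.columns)
    if missing or "label" not in samples.columns:
        raise InvalidInputError(f"training table missing columns: {sorted(missing) or ['label']}")
    if "source" in samples.columns and samples["source"].str.startswith("level").any():
        raise InvalidTrainingSetError("evaluation-game samples found in training data")
    y = samples["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if set(counts.index) != set(LABELS) or counts.min() < 2:
        raise InvalidTrainingSetError(
            f"need >= 2 samples of each of {LABELS}, got {counts.to_dict()}"
        )
    X = samples.loc[:, feature_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("training features must be finite")

    space = {
        "mlp__hidden_layer_sizes": [(h,) for h in cfg.hidden_sizes],
        "mlp__alpha": loguniform(*cfg.l2_range),
        "mlp__learning_rate_init": loguniform(*cfg.lr_range),
    }
    folds = min(cfg.cv_folds, int(counts.min()))
    search = RandomizedSearchCV(
        _make_pipeline(cfg),
        space,
        n_iter=cfg.search_iterations,
        scoring="roc_auc",
        cv=RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=cfg.cv_repeats, random_state=cfg.seed
        ),
        random_state=cfg.seed,
        n_jobs=1,
        refit=True,
        error_score="raise",
    )
    with warnings.catch_warnings():
        # fixed epoch budget is intentional (reproducibility over convergence)
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(X, y)
    return UserModel(
        subject_id=subject_id,
        feature_names=feature_names,
        pipeline=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        seed=cfg.seed,
    )


def _vector_from(sample: Mapping[str, float] | pd.Series | pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    if isinstance(sample, pd.DataFrame):
        missing = set(names) - set(sample.columns)
        if missing:
            raise InvalidInputError(f"sample missing features {sorted(missing)}")
        return sample.loc[:, names].to_numpy(dtype=float)
    try:
        row = [float(sample[f]) for f in names]
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"sample missing feature: {exc}") from exc
    return np.asarray([row])


def predict(model: UserModel, sample: Mapping[str, float] | pd.Series) -> tuple[str, float]:
    """Classify one feature vector; returns (label, stress-class probability)."""
    X = _vector_from(sample, model.feature_names)
    proba = model.pipeline.predict_proba(X)[0]
    stress_idx = int(np.flatnonzero(model.classes_ == "stress")[0])
    score = float(proba[stress_idx])
    label = "stress" if score >= 0.5 else "boredom"
    return label, score


def predict_table(model: UserModel, samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorized prediction: columns ``label, stress_score`` per input row."""
    X = _vector_from(samples, model.feature_names)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("prediction features must be finite")
    proba = model.pipeline.predict_proba(X)
    stress_idx = int(np.flatnonzero(model.classes_ == "stress")[0])
    score = proba[:, stress_idx]
    return pd.DataFrame(
        {"label": np.where(score >= 0.5, "stress", "boredom"), "stress_score": score},
        index=samples.index,
    )


# ------------------------------------------------------------------ persistence

def save_user_model(model: UserModel, path: str | Path) -> None:
    """Write a self-describing JSON archive (metadata + numeric arrays)."""
    scaler = model.pipeline.named_steps["scale"]
    mlp = model.pipeline.named_steps["mlp"]
    payload = {
        "format": "playaffect-user-model/1",
        "subject_id": model.subject_id,
        "feature_names": list(model.feature_names),
        "best_params": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in model.best_params.items()},
        "cv_auc": model.cv_auc,
        "seed": model.seed,
        "scaler": {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
        "mlp": {
            "hidden_layer_sizes": list(np.atleast_1d(mlp.hidden_layer_sizes)),
            "activation": mlp.activation,
            "classes": mlp.classes_.tolist(),
            "coefs": [c.tolist() for c in mlp.coefs_],
            "intercepts": [b.tolist() for b in mlp.intercepts_],
        },
    }
    def _coerce(obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, default=_coerce) + "\n")


def load_user_model(path: str | Path) -> UserModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "playaffect-user-model/1":
        raise InvalidInputError(f"not a playaffect model archive: {path}")
    scaler = StandardScaler()
    scaler.mean_ = np.asarray(payload["scaler"]["mean"])
    scaler.scale_ = np.asarray(payload["scaler"]["scale"])
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = len(scaler.mean_)
    m = payload["mlp"]
    mlp = MLPClassifier(hidden_layer_sizes=tuple(m["hidden_layer_sizes"]),
                        activation=m["activation"])
    mlp.classes_ = np.asarray(m["classes"])
    mlp.coefs_ = [np.asarray(c) for c in m["coefs"]]
    mlp.intercepts_ = [np.asarray(b) for b in m["intercepts"]]
    mlp.n_layers_ = len(mlp.coefs_) + 1
    mlp.n_outputs_ = 1
    mlp.out_activation_ = "logistic"
    mlp.n_features_in_ = len(scaler.mean_)
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(mlp.classes_)
    mlp._label_binarizer = lb
    pipeline = Pipeline([("scale", scaler), ("mlp", mlp)])
    best_params = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in payload["best_params"].items()
    }
    return UserModel(
        subject_id=int(payload["subject_id"]),
        feature_names=tuple(payload["feature_names"]),
        pipeline=pipeline,
        best_params=best_params,
        cv_auc=float(payload["cv_auc"]),
        seed=int(payload["seed"]),
    )
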