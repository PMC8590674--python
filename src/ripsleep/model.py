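"""The sleep-stage classifier: configuration, training recipe, prediction.

The model is the dense + GRU network of :mod:`ripsleep.nn`, trained with
Adam on class-weighted categorical cross-entropy.  Training follows a
fixed recipe: dropout 0.22 in the dense and GRU layers, class weights
wake 1.0 / REM 0.7 / NREM 0.6 (down-weighting the prevalent sleep
classes), learning rate 1e-4, batch size 120, a fixed number of training
epochs with no early stopping, and 5-fold cross-validation with 80/20
splits at the *recording* level (a night is never split across folds).
The fold with the best validation kappa supplies the returned weights.

A :class:`TrainedModel` bundles weights, configuration and the ordered
feature schema so that training and prediction can never silently disagree
about feature meaning.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold

from .evaluation import cohens_kappa, confusion_matrix
from .features import FEATURE_NAMES, WINDOW_FUTURE, WINDOW_PAST, make_windows
from .nn import AdamOptimizer, GRUNet
from .types import (
    STAGES,
    FeatureMatrix,
    as_hypnogram,
    stages_to_indices,
)

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "relu",
    "build_model",
    "train",
    "predict_hypnogram",
    "SleepStageClassifier",
]

_PREDICT_CHUNK = 512

#: Saturation bound for network inputs, in IQR units.  Median/IQR scaling
#: leaves genuinely rare events (a movement burst in an otherwise still
#: night) at hundreds of IQRs from the median; values that far out carry
#: no extra information but destabilize ReLU activations, so the network
#: sees them clipped.  The stored feature matrices are untouched.
FEATURE_CLIP = 25.0


def relu(x):
    """Rectified linear unit: negative inputs map to zero, positive inputs
    pass through unchanged."""
    return np.maximum(x, 0.0)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    dense_layers: int = 3
    dense_width: int = 70
    gru_units: int = 50
    n_classes: int = 3
    dropout: float = 0.22
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 1.0, "REM": 0.7, "NREM": 0.6}
    )
    learning_rate: float = 1e-4
    batch_size: int = 120
    training_epochs: int = 50
    window_past: int = WINDOW_PAST
    window_future: int = WINDOW_FUTURE
    n_folds: int = 5
    gru_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")
        if self.window_past + 1 + self.window_future != 25:
            raise ValueError("window lengths (past + current + future) must sum to 25")

    @property
    def window_length(self) -> int:
        return self.window_past + 1 + self.window_future

    def class_weight_vector(self) -> np.ndarray:
        return np.array([self.class_weights[s] for s in STAGES])


@dataclass
class TrainedModel:
    """Weights + configuration + feature schema + training log."""

    net: GRUNet
    config: ModelConfig
    feature_schema: tuple[str, ...]
    training_log: dict = field(default_factory=dict)

    # ----- persistence: a single zip archive with npz weights and JSON meta

    def save(self, path: str | Path) -> None:
        """Serialize to a single versioned archive (bit-exact round trip)."""
        state = self.net.get_state()
        buf = io.BytesIO()
        np.savez(buf, **state.pop("params"))
        meta = {
            "format_version": 1,
            "net": state,
            "config": asdict(self.config),
            "feature_schema": list(self.feature_schema),
            "training_log": self.training_log,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
                params = {k: npz[k] for k in npz.files}
        state = dict(meta["net"], params=params)
        net = GRUNet.from_state(state)
        return cls(
            net=net,
            config=ModelConfig(**meta["config"]),
            feature_schema=tuple(meta["feature_schema"]),
            training_log=meta["training_log"],
        )


def build_model(
    config: ModelConfig | None = None,
    n_features: int | None = None,
    feature_schema: tuple[str, ...] = FEATURE_NAMES,
) -> TrainedModel:
    """Construct an untrained model with seeded weight initialization.

    The dense stack at 14 input features has (14*70+70) + 2*(70*70+70) =
    10,990 parameters and the classification head 50*3+3 = 153; these
    closed-form counts are exposed via ``net.parameter_counts()``.
    """
    config = config or ModelConfig()
    if n_features is None:
        n_features = len(feature_schema)
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    if len(feature_schema) != n_features:
        raise ValueError("feature_schema length must equal n_features")
    net = GRUNet(
        n_features=n_features,
        dense_layers=config.dense_layers,
        dense_width=config.dense_width,
        gru_units=config.gru_units,
        n_classes=config.n_classes,
        dropout=config.dropout,
        gru_activation=config.gru_activation,
        seed=config.seed,
    )
    return TrainedModel(net=net, config=config, feature_schema=tuple(feature_schema))


def _stack_windows(
    recordings: list[tuple[FeatureMatrix, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for fm, hyp in recordings:
        if not fm.normalized:
            raise ValueError("training features must be normalized per study")
        hyp = as_hypnogram(hyp)
        if len(hyp) != fm.n_epochs:
            raise ValueError(
                f"feature matrix has {fm.n_epochs} epochs but hypnogram has "
                f"{len(hyp)}"
            )
        windows, _ = make_windows(fm)
        xs.append(np.clip(windows, -FEATURE_CLIP, FEATURE_CLIP))
        ys.append(stages_to_indices(hyp))
    return np.concatenate(xs), np.concatenate(ys)


def _validation_kappa(net: GRUNet, X: np.ndarray, y: np.ndarray) -> float:
    pred = np.empty(len(y), dtype=np.int64)
    for i in range(0, len(y), _PREDICT_CHUNK):
        pred[i:i + _PREDICT_CHUNK] = np.argmax(
            net.predict_proba(X[i:i + _PREDICT_CHUNK]), axis=1
        )
    stages = np.array(STAGES)
    cm = confusion_matrix(stages[y], stages[pred])
    return cohens_kappa(cm)


def _train_one_fold(
    X_tr, y_tr, X_va, y_va, config: ModelConfig, fold_seed: int,
    feature_schema,
) -> tuple[GRUNet, dict]:
    net = GRUNet(
        n_features=X_tr.shape[2],
        dense_layers=config.dense_layers,
        dense_width=config.dense_width,
        gru_units=config.gru_units,
        n_classes=config.n_classes,
        dropout=config.dropout,
        gru_activation=config.gru_activation,
        seed=fold_seed,
    )
    opt = AdamOptimizer(net.params, learning_rate=config.learning_rate)
    rng = np.random.default_rng(fold_seed + 1)
    w = config.class_weight_vector()
    n = len(y_tr)
    log = {"loss": [], "val_kappa": [],
           "adam": {"beta1": opt.beta1, "beta2": opt.beta2, "eps": opt.eps,
                    "clip_norm": opt.clip_norm}}
    for _epoch in range(config.training_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = net.loss_and_grads(X_tr[idx], y_tr[idx], w, rng=rng)
            opt.step(net.params, grads)
            losses.append(loss)
        log["loss"].append(float(np.mean(losses)))
        log["val_kappa"].append(
            _validation_kappa(net, X_va, y_va) if len(y_va) else float("nan")
        )
    return net, log


def train(
    training_set: list[tuple[FeatureMatrix, np.ndarray]],
    config: ModelConfig | None = None,
    feature_schema: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Train with recording-level 5-fold cross-validation.

    Parameters
    ----------
    training_set : list of (FeatureMatrix, hypnogram)
        Per-recording normalized features and reference labels.
    config : ModelConfig
        The training recipe; ``config.seed`` fixes fold assignment, weight
        initialization, shuffling and dropout.

    Returns
    -------
    TrainedModel
        The fold-best model (highest final validation kappa), carrying the
        full per-fold training log.
    """
    config = config or ModelConfig()
    if not training_set:
        raise ValueError("training set is empty")
    if len(training_set) < config.n_folds:
        raise ValueError(
            f"{len(training_set)} recordings but {config.n_folds} folds; "
            "need at least one recording per fold"
        )
    schema = tuple(
        feature_schema
        if feature_schema is not None
        else training_set[0][0].feature_names
    )
    for fm, _ in training_set:
        if tuple(fm.feature_names) != schema:
            raise ValueError("inconsistent feature schemas across recordings")

    per_rec = [
        _stack_windows([rec]) for rec in training_set
    ]  # windows per recording, so folds never split a night

    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    best_net, best_kappa, fold_logs = None, -np.inf, []
    for fold, (tr_idx, va_idx) in enumerate(kf.split(per_rec)):
        X_tr = np.concatenate([per_rec[i][0] for i in tr_idx])
        y_tr = np.concatenate([per_rec[i][1] for i in tr_idx])
        X_va = np.concatenate([per_rec[i][0] for i in va_idx])
        y_va = np.concatenate([per_rec[i][1] for i in va_idx])
        net, log = _train_one_fold(
            X_tr, y_tr, X_va, y_va, config, config.seed + 1000 * (fold + 1),
            schema,
        )
        log["fold"] = fold
        log["n_train_windows"] = int(len(y_tr))
        log["n_val_windows"] = int(len(y_va))
        fold_logs.append(log)
        final_kappa = log["val_kappa"][-1]
        if final_kappa > best_kappa:
            best_kappa, best_net = final_kappa, net

    return TrainedModel(
        net=best_net,
        config=config,
        feature_schema=schema,
        training_log={"folds": fold_logs, "best_val_kappa": float(best_kappa)},
    )


def predict_hypnogram(
    model: TrainedModel, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Predict one stage label (and class posterior) per epoch.

    ``features`` must be normalized and carry exactly the model's feature
    schema (names and order).  Returns ``(hypnogram, probs)`` with
    ``probs`` of shape (n_epochs, 3) summing to 1 per row.
    """
    if tuple(features.feature_names) != tuple(model.feature_schema):
        for i, (got, want) in enumerate(
            zip(features.feature_names, model.feature_schema)
        ):
            if got != want:
                raise ValueError(
                    f"feature schema mismatch at column {i}: "
                    f"got {got!r}, model expects {want!r}"
                )
        raise ValueError(
            f"feature schema length mismatch: {len(features.feature_names)} "
            f"vs {len(model.feature_schema)}"
        )
    if features.n_epochs == 0:
        return np.empty(0, dtype="<U4"), np.empty((0, model.config.n_classes))
    if not features.normalized:
        raise ValueError("features must be normalized before prediction")
    windows, _ = make_windows(features)
    windows = np.clip(windows, -FEATURE_CLIP, FEATURE_CLIP)
    probs = np.empty((len(windows), model.config.n_classes))
    for i in range(0, len(windows), _PREDICT_CHUNK):
        probs[i:i + _PREDICT_CHUNK] = model.net.predict_proba(
            windows[i:i + _PREDICT_CHUNK]
        )
    labels = np.array(STAGES, dtype="<U4")[np.argmax(probs, axis=1)]
    return labels, probs


class SleepStageClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style interface to the dense + GRU sleep stager.

    ``fit`` consumes a list of per-recording feature matrices and a list of
    matching hypnograms (sequence data; a recording is the sample unit).
    Unnormalized feature matrices are normalized per study on the way in.

    Examples
    --------
    >>> clf = SleepStageClassifier(training_epochs=5, n_folds=2, seed=7)
    >>> clf.fit([fm1, fm2], [hyp1, hyp2])      # doctest: +SKIP
    >>> clf.predict(fm_new)                    # doctest: +SKIP
    """

    def __init__(
        self,
        dense_layers: int = 3,
        dense_width: int = 70,
        gru_units: int = 50,
        dropout: float = 0.22,
        learning_rate: float = 1e-4,
        batch_size: int = 120,
        training_epochs: int = 50,
        n_folds: int = 5,
        gru_activation: str = "relu",
        class_weights: dict[str, float] | None = None,
        seed: int = 0,
    ):
        self.dense_layers = dense_layers
        self.dense_width = dense_width
        self.gru_units = gru_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.training_epochs = training_epochs
        self.n_folds = n_folds
        self.gru_activation = gru_activation
        self.class_weights = class_weights
        self.seed = seed

    def _config(self) -> ModelConfig:
        kw = dict(
            dense_layers=self.dense_layers,
            dense_width=self.dense_width,
            gru_units=self.gru_units,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            training_epochs=self.training_epochs,
            n_folds=self.n_folds,
            gru_activation=self.gru_activation,
            seed=self.seed,
        )
        if self.class_weights is not None:
            kw["class_weights"] = dict(self.class_weights)
        return ModelConfig(**kw)

    @staticmethod
    def _ensure_normalized(fm: FeatureMatrix) -> FeatureMatrix:
        from .features import robust_normalize

        return fm if fm.normalized else robust_normalize(fm)

    def fit(self, X: list[FeatureMatrix], y: list[np.ndarray]):
        """Fit on per-recording (features, hypnogram) pairs."""
        if len(X) != len(y):
            raise ValueError("X and y must pair one hypnogram per recording")
        pairs = [(self._ensure_normalized(fm), as_hypnogram(h))
                 for fm, h in zip(X, y)]
        self.model_ = train(pairs, self._config())
        self.classes_ = np.array(STAGES)
        self.cv_log_ = self.model_.training_log
        return self

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        """Predict a hypnogram for one recording's feature matrix."""
        self._check_fitted()
        labels, _ = predict_hypnogram(self.model_, self._ensure_normalized(X))
        return labels

    def predict_proba(self, X: FeatureMatrix) -> np.ndarray:
        self._check_fitted()
        _, probs = predict_hypnogram(self.model_, self._ensure_normalized(X))
        return probs

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("SleepStageClassifier is not fitted yet")
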