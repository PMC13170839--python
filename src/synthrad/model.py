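"""Final consistency classifier: an MLP on the selected features.

A small multilayer perceptron (default one hidden layer of 16 ReLU units,
L2 penalty 1e-3, early stopping on 20% of the training rows) predicts the
probability that a tumor is fibrous from the selected radiomic features.
Feature standardization is fitted on the training rows and frozen for
test application; the test set never influences training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

POSITIVE_LABEL = "fibrous"  # positive class for consistency prediction

NON_FEATURE_COLS = ("case_id", "modality", "label")


@dataclass
class MLPConfig:
    """Defaults are sized for n ~ 100 training cohorts.

    ``early_stop_fraction`` is off by default: with small validation
    splits the accuracy-based early stopping saturates at epoch one and
    snapshots a near-initial network, silently destroying the fit; the L2
    penalty and the single small hidden layer are the regularizers.
    """

    hidden_sizes: tuple[int, ...] = (16,)
    activation: str = "relu"
    max_epochs: int = 500
    l2_penalty: float = 1e-3
    early_stop_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")


@dataclass
class PredictionSet:
    """Per-case fibrous probabilities for one feature source."""

    table: pd.DataFrame = field(repr=False)  # case_id, p_positive, pred_label
    source_feature_set: str = "unknown"
    threshold: float = 0.5

    @property
    def probabilities(self) -> pd.Series:
        return self.table.set_index("case_id")["p_positive"]

    def save(self, path):
        self.table.to_csv(path, index=False)
        return path


def combine_modalities(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation of per-modality feature tables.

    Feature columns are prefixed with their modality so names never
    collide; case rows (and labels) must agree across tables.
    """
    if not tables:
        raise ValueError("no tables to combine")
    items = sorted(tables.items(), key=lambda kv: str(kv[0]))
    base = items[0][1].sort_values("case_id").reset_index(drop=True)
    ref_ids = base["case_id"].tolist()
    out = base[[c for c in NON_FEATURE_COLS if c in base.columns]].copy()
    out = out.drop(columns=["modality"], errors="ignore")
    for mod, tab in items:
        tab = tab.sort_values("case_id").reset_index(drop=True)
        if tab["case_id"].tolist() != ref_ids:
            raise ValueError(f"case rows of modality {mod} do not match")
        if "label" in tab.columns and not tab["label"].equals(base["label"]):
            raise ValueError(f"labels of modality {mod} disagree")
        feats = [c for c in tab.columns if c not in NON_FEATURE_COLS]
        renamed = tab[feats].add_prefix(f"{mod}__")
        out = pd.concat([out, renamed], axis=1)
    return out


@dataclass
class FittedMLP:
    """Trained classifier plus its frozen preprocessing."""

    estimator: MLPClassifier
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    config: MLPConfig
    classes: list
    train_probabilities: pd.DataFrame = field(repr=False, default=None)

    def weights_checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for w in self.estimator.coefs_ + self.estimator.intercepts_:
            h.update(np.round(np.asarray(w, dtype=np.float64), 10).tobytes())
        return h.hexdigest()


def _design(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing[:5]}")
    X = table[feature_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def fit_mlp(train_table: pd.DataFrame, chosen_subset: list[str],
            config: MLPConfig | None = None, label_col: str = "label"
            ) -> FittedMLP:
    """Train the MLP on the selected features of the training table."""
    config = config or MLPConfig()
    y = train_table[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 5:
        raise ValueError(f"need >= 5 cases per class, got {dict(zip(classes, counts))}")
    X = _design(train_table, list(chosen_subset))
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    est = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_sizes),
        activation=config.activation,
        alpha=config.l2_penalty,
        max_iter=config.max_epochs,
        early_stopping=config.early_stop_fraction > 0,
        validation_fraction=config.early_stop_fraction or 0.1,
        n_iter_no_change=20,
        random_state=config.seed,
        solver="adam",
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xs, y)
    fitted = FittedMLP(estimator=est, feature_names=list(chosen_subset),
                       mean=mean, scale=scale, config=config,
                       classes=est.classes_.tolist())
    # training-set probabilities support calibration diagnostics downstream
    p = est.predict_proba(Xs)[:, fitted.classes.index(POSITIVE_LABEL)
                              if POSITIVE_LABEL in fitted.classes else 1]
    fitted.train_probabilities = pd.DataFrame(
        {"case_id": train_table.get("case_id", pd.RangeIndex(len(y))),
         "p_positive": p, "label": y})
    return fitted


def predict(model: FittedMLP, test_table: pd.DataFrame,
            source_feature_set: str = "unknown",
            threshold: float = 0.5) -> PredictionSet:
    """Probabilities and thresholded labels for unseen cases."""
    X = _design(test_table, model.feature_names)
    Xs = (X - model.mean) / model.scale
    pos_idx = (model.classes.index(POSITIVE_LABEL)
               if POSITIVE_LABEL in model.classes else 1)
    p = model.estimator.predict_proba(Xs)[:, pos_idx]
    pos_label = model.classes[pos_idx]
    neg_label = next(c for c in model.classes if c != pos_label)
    table = pd.DataFrame({
        "case_id": test_table.get("case_id", pd.RangeIndex(len(p))),
        "p_positive": p,
        "pred_label": np.where(p >= threshold, pos_label, neg_label),
    })
    return PredictionSet(table=table, source_feature_set=source_feature_set,
                         threshold=threshold)
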