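"""Feature assembly and the gradient-boosted-tree classification stage.

Local per-nucleotide features and graph-embedding features are joined
columnwise into one table; a gradient-boosted decision-tree ensemble
(LightGBM backend) is then fitted on the training rows only.  The graph
stage upstream is transductive, but the classifier never sees test-row
labels; class imbalance is handled by inverse-frequency class weights
rather than resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .embeddings import EmbeddingMatrix


@dataclass
class TrainingConfig:
    """Backend-agnostic boosted-tree configuration."""

    iterations: int = 500
    depth: int = 6
    learning_rate: float = 0.05
    balance: str = "auto"   # "auto" = inverse-frequency class weights, "none"
    seed: int = 0


@dataclass
class PredictionResult:
    """Per-row positive-class scores and thresholded calls."""

    scores: np.ndarray
    labels: np.ndarray
    threshold: float


def assemble_features(
    local: pd.DataFrame | np.ndarray,
    embedded: EmbeddingMatrix | pd.DataFrame | np.ndarray | None,
    local_names: list[str] | None = None,
) -> pd.DataFrame:
    """Join local and embedding features columnwise, local block first.

    ``embedded`` may be None or zero-width for the "before graph
    embedding" ablation arm, in which case the table is the local block
    alone. Column names must end up unique.
    """
    if isinstance(local, pd.DataFrame):
        local_df = local
    else:
        local = np.asarray(local)
        if local_names is None:
            local_names = [f"Local_{k}" for k in range(local.shape[1])]
        local_df = pd.DataFrame(local, columns=local_names)
    if embedded is None:
        table = local_df.copy()
    else:
        if isinstance(embedded, EmbeddingMatrix):
            emb_df = pd.DataFrame(embedded.vectors, columns=embedded.column_names)
        elif isinstance(embedded, pd.DataFrame):
            emb_df = embedded
        else:
            embedded = np.asarray(embedded)
            emb_df = pd.DataFrame(
                embedded,
                columns=[f"GraphEmbeddings_{k}" for k in range(embedded.shape[1])],
            )
        if len(local_df) != len(emb_df):
            raise ValueError(
                f"row mismatch: local {len(local_df)} vs embedded {len(emb_df)}"
            )
        emb_df.index = local_df.index
        table = pd.concat([local_df, emb_df], axis=1)
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicated feature names: {dupes}")
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


class PromoterBoostedClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted decision trees for promoter vs non-promoter calls.

    A thin, deterministic wrapper around LightGBM: single-threaded,
    seeded, with optional inverse-frequency class weighting for the
    imbalanced 1:2 / 1:5 settings. Stores a feature-name snapshot at fit
    time and refuses to predict on a differently named table.
    """

    def __init__(
        self,
        iterations: int = 500,
        depth: int = 6,
        learning_rate: float = 0.05,
        balance: str = "auto",
        seed: int = 0,
    ):
        self.iterations = iterations
        self.depth = depth
        self.learning_rate = learning_rate
        self.balance = balance
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_ = [f"f{k}" for k in range(X.shape[1])]
            X = pd.DataFrame(X, columns=self.feature_names_)
        self.booster_ = LGBMClassifier(
            n_estimators=self.iterations,
            max_depth=self.depth,
            num_leaves=2**self.depth - 1,
            learning_rate=self.learning_rate,
            class_weight="balanced" if self.balance == "auto" else None,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        self.booster_.fit(X, y)
        self.classes_ = self.booster_.classes_
        return self

    def _validate_table(self, X) -> pd.DataFrame:
        check_is_fitted(self, "booster_")
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names_:
                raise ValueError("feature names do not match the fitted snapshot")
            return X
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names_):
            raise ValueError("feature count does not match the fitted snapshot")
        return pd.DataFrame(X, columns=self.feature_names_)

    def predict_proba(self, X) -> np.ndarray:
        return self.booster_.predict_proba(self._validate_table(X))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive class per row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_scores(X) >= threshold).astype(int)


def train_ensemble(
    table: pd.DataFrame,
    labels: np.ndarray,
    train_indices: np.ndarray,
    config: TrainingConfig | None = None,
    seed: int | None = None,
) -> PromoterBoostedClassifier:
    """Fit the ensemble on the training rows of an assembled feature table."""
    config = config or TrainingConfig()
    labels = np.asarray(labels, dtype=int)
    clf = PromoterBoostedClassifier(
        iterations=config.iterations,
        depth=config.depth,
        learning_rate=config.learning_rate,
        balance=config.balance,
        seed=config.seed if seed is None else seed,
    )
    clf.fit(table.iloc[train_indices], labels[train_indices])
    return clf


def predict(
    model: PromoterBoostedClassifier,
    table: pd.DataFrame,
    rows: np.ndarray | None = None,
    threshold: float = 0.5,
) -> PredictionResult:
    """Score the requested rows; a score >= threshold is called positive."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sub = table if rows is None else table.iloc[rows]
    scores = model.decision_scores(sub)
    return PredictionResult(
        scores=scores, labels=(scores >= threshold).astype(int), threshold=threshold
    )
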