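"""Model/results objects tying the pipeline together.

``DriverClassifier`` is constructed from a feature matrix (or a plain
DataFrame via :meth:`DriverClassifier.from_dataframe`); ``fit`` runs
feature selection, stratified 10-fold cross-validation and a final training
pass, returning a :class:`DriverClassifierResults` that carries the trained
bundle, per-fold metrics and a ``summary()`` table.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mlpipe import (
    FeatureMatrix,
    MetricsReport,
    MedianImputer,
    MinMaxScaler,
    TrainedModel,
    kfold_cv,
    metrics,
    protein_grouped_split,
    select_k_best,
    split_80_20,
    sweep_k,
    train,
)
from .nn import ModelConfig

BUNDLE_VERSION = 1


class DriverClassifier:
    """Driver-vs-passenger classifier over a per-mutation feature matrix."""

    def __init__(self, matrix: FeatureMatrix, config: ModelConfig | None = None):
        self.matrix = matrix
        self.config = config if config is not None else ModelConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        group_column: str | None = None,
        onehot_columns: Sequence[str] = (),
        config: ModelConfig | None = None,
    ) -> "DriverClassifier":
        """Build from a flat DataFrame; the label column holds 0/1 or
        'passenger'/'driver'."""
        raw = df[label_column]
        if raw.dtype == object:
            labels = raw.map({"driver": 1, "passenger": 0})
            if labels.isna().any():
                bad = raw[labels.isna()].unique().tolist()
                raise ValueError(f"unmappable labels: {bad}")
            labels = labels.to_numpy(int)
        else:
            labels = raw.to_numpy(int)
        drop = [label_column] + ([group_column] if group_column else [])
        features = df.drop(columns=drop)
        groups = df[group_column].to_numpy() if group_column else None
        matrix = FeatureMatrix(
            features=features,
            labels=labels,
            groups=groups,
            onehot_columns=frozenset(onehot_columns),
        )
        return cls(matrix, config=config)

    def train_test_split(
        self, seed: int = 0, grouped: bool = False, test_fraction: float = 0.2
    ) -> tuple[FeatureMatrix, FeatureMatrix]:
        """80:20 split — label-stratified, or protein-grouped when
        ``grouped`` (mutations of one protein never straddle the split)."""
        if grouped:
            if self.matrix.groups is None:
                raise ValueError("grouped split requires protein groups")
            tr, te = protein_grouped_split(self.matrix.groups, seed, test_fraction)
        else:
            tr, te = split_80_20(self.matrix.labels, seed, test_fraction)
        return self.matrix.subset(tr), self.matrix.subset(te)

    def fit(
        self,
        select_k: int | None = None,
        cv: int = 10,
        seed: int = 0,
        scorer: str = "anova_f",
    ) -> "DriverClassifierResults":
        """Cross-validate and fit the final model.

        ``select_k`` fixes the feature count (None = use all features); the
        per-fold selection is refitted inside each fold, and the final model
        selects on the full training matrix.
        """
        reports, mean, selections = kfold_cv(
            self.matrix,
            config=self.config,
            k=cv,
            seed=seed,
            select_k=select_k,
            scorer=scorer,
        )
        cols = None
        if select_k is not None:
            imput = MedianImputer().fit(self.matrix.features)
            cols = select_k_best(
                imput.transform(self.matrix.features),
                self.matrix.labels,
                select_k,
                scorer,
            )
        final = train(self.matrix, self.config, feature_names=cols)
        return DriverClassifierResults(
            model=final,
            cv_reports=reports,
            cv_mean=mean,
            fold_selections=selections,
            selected_features=final.feature_names,
            config=self.config,
            seed=seed,
        )

    def sweep_feature_count(
        self,
        k_grid: Sequence[int],
        cv: int = 5,
        seed: int = 0,
        scorer: str = "anova_f",
    ) -> tuple[int, dict[int, float]]:
        """Grid-search the selected-feature count by mean CV balanced accuracy."""
        return sweep_k(
            self.matrix, k_grid, config=self.config, cv=cv, seed=seed, scorer=scorer
        )


@dataclass
class DriverClassifierResults:
    """Fitted classifier plus its cross-validated evaluation."""

    model: TrainedModel
    cv_reports: list[MetricsReport]
    cv_mean: MetricsReport
    fold_selections: list[list[str]]
    selected_features: list[str]
    config: ModelConfig
    seed: int

    def predict(self, df: pd.DataFrame, threshold: float | None = None):
        """(probabilities, hard labels) for new feature rows."""
        return self.model.predict(df, threshold=threshold)

    def evaluate(self, df: pd.DataFrame, labels) -> MetricsReport:
        proba, pred = self.model.predict(df)
        return metrics(np.asarray(labels), pred, proba)

    def fold_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.cv_reports]
        return pd.DataFrame(rows, index=[f"fold{i}" for i in range(len(rows))])

    def summary(self) -> str:
        m = self.cv_mean
        lines = [
            "Driver/passenger classifier - cross-validated performance",
            "=" * 58,
            f"folds: {len(self.cv_reports)}    seed: {self.seed}    "
            f"features: {len(self.selected_features)}",
            f"hidden layers: {self.config.hidden_units}  lr={self.config.lr}  "
            f"momentum={self.config.momentum}  l2={self.config.l2}",
            "-" * 58,
            f"{'sensitivity':<20s} {m.sensitivity:8.4f}",
            f"{'specificity':<20s} {m.specificity:8.4f}",
            f"{'accuracy':<20s} {m.accuracy:8.4f}",
            f"{'balanced accuracy':<20s} {m.balanced_accuracy:8.4f}",
            f"{'MCC':<20s} {m.mcc:8.4f}",
        ]
        if m.auc_roc is not None:
            lines.append(f"{'ROC-AUC':<20s} {m.auc_roc:8.4f}")
        if m.auc_pr is not None:
            lines.append(f"{'PR-AUC':<20s} {m.auc_pr:8.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize model + scaler + selected features as one versioned bundle."""
        bundle = {"version": BUNDLE_VERSION, "results": self}
        with open(path, "wb") as fh:
            pickle.dump(bundle, fh)

    @staticmethod
    def load(path: str | Path) -> "DriverClassifierResults":
        with open(path, "rb") as fh:
            bundle = pickle.load(fh)
        if bundle.get("version") != BUNDLE_VERSION:
            raise ValueError(f"unsupported bundle version {bundle.get('version')}")
        return bundle["results"]
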