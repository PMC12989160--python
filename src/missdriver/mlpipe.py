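"""Normalization, feature selection, splitting, cross-validation and metrics
for the driver/passenger classifier.

Conventions: drivers are the positive class (label 1), passengers negative
(label 0). Normalization is min-max to [0, 1] fitted on training rows only;
one-hot secondary-structure columns pass through untouched. Missing feature
values are median-imputed with medians computed on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2, f_classif, mutual_info_classif
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .nn import MLPClassifier, ModelConfig

POSITIVE_LABEL = "driver"


@dataclass
class FeatureMatrix:
    """Per-mutation feature table with labels and protein grouping.

    ``features`` has one row per mutation; missing cells are nan until an
    explicit imputation step. ``labels`` is 1 for drivers, 0 for passengers.
    ``onehot_columns`` (e.g. secondary-structure indicators) are exempt from
    min-max normalization.
    """

    features: pd.DataFrame
    labels: np.ndarray
    groups: np.ndarray | None = None  # protein id per row
    onehot_columns: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features disagree on row count")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != len(self.features):
                raise ValueError("groups and features disagree on row count")
        unknown = set(self.onehot_columns) - set(self.features.columns)
        if unknown:
            raise ValueError(f"onehot_columns not in matrix: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            groups=None if self.groups is None else self.groups[idx],
            onehot_columns=self.onehot_columns,
        )


# ---------------------------------------------------------------------------
# imputation + normalization
# ---------------------------------------------------------------------------

@dataclass
class MedianImputer:
    medians: pd.Series | None = None

    def fit(self, df: pd.DataFrame) -> "MedianImputer":
        self.medians = df.median(axis=0, skipna=True).fillna(0.0)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.medians is None:
            raise RuntimeError("imputer not fitted")
        return df.fillna(self.medians)


@dataclass
class MinMaxScaler:
    """Per-column (x - min) / (max - min) to [0, 1], fitted on training data.

    Constant columns map to 0. At transform time out-of-range values (test
    rows beyond the training min/max) are clipped with a warning. Columns in
    ``passthrough`` (one-hot encodings) are not rescaled.
    """

    passthrough: frozenset[str] = frozenset()
    mins: pd.Series | None = None
    maxs: pd.Series | None = None

    def fit(self, df: pd.DataFrame) -> "MinMaxScaler":
        cols = [c for c in df.columns if c not in self.passthrough]
        self.mins = df[cols].min(axis=0)
        self.maxs = df[cols].max(axis=0)
        return self

    def transform(self, df: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        if self.mins is None or self.maxs is None:
            raise RuntimeError("scaler not fitted")
        out = df.copy()
        span = self.maxs - self.mins
        for col in self.mins.index:
            if col not in out.columns:
                raise KeyError(f"column {col!r} missing at transform time")
            s = span[col]
            if s == 0 or not np.isfinite(s):
                out[col] = 0.0
            else:
                out[col] = (out[col] - self.mins[col]) / s
        scaled = out[list(self.mins.index)]
        if clip and ((scaled < 0).any().any() or (scaled > 1).any().any()):
            warnings.warn(
                "values outside the training range clipped to [0, 1]",
                stacklevel=2,
            )
            out[list(self.mins.index)] = scaled.clip(0.0, 1.0)
        return out

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def minmax_normalize(
    matrix: FeatureMatrix,
) -> tuple[FeatureMatrix, MinMaxScaler]:
    """Normalize a training matrix to [0, 1]; returns the fitted scaler for
    verbatim reapplication to test data."""
    scaler = MinMaxScaler(passthrough=matrix.onehot_columns)
    scaled = scaler.fit_transform(matrix.features)
    return (
        FeatureMatrix(
            features=scaled,
            labels=matrix.labels,
            groups=matrix.groups,
            onehot_columns=matrix.onehot_columns,
        ),
        scaler,
    )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

_SCORERS = {
    "anova_f": lambda x, y: f_classif(x, y)[0],
    "chi2": lambda x, y: chi2(x, y)[0],
    "mutual_info": lambda x, y: mutual_info_classif(x, y, random_state=0),
}


def feature_scores(
    df: pd.DataFrame, labels: np.ndarray, scorer: str = "anova_f"
) -> pd.Series:
    """Univariate relevance score per feature column (higher = better)."""
    if scorer not in _SCORERS:
        raise ValueError(f"scorer must be one of {sorted(_SCORERS)}, got {scorer!r}")
    scores = np.asarray(_SCORERS[scorer](df.to_numpy(dtype=float), labels))
    # nan (undefined) scores never rank; +inf (perfect separation) ranks first
    scores = np.where(np.isnan(scores), 0.0, scores)
    return pd.Series(scores, index=df.columns)


def select_k_best(
    df: pd.DataFrame, labels: np.ndarray, k: int, scorer: str = "anova_f"
) -> list[str]:
    """Top-k feature columns by univariate score, descending; ties broken by
    column-name order so the selection is deterministic."""
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > df.shape[1]:
        raise ValueError(f"k={k} exceeds {df.shape[1]} columns")
    scores = feature_scores(df, labels, scorer)
    order = sorted(df.columns, key=lambda c: (-scores[c], c))
    return order[:k]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _largest_remainder(counts: Mapping, fraction: float) -> dict:
    """Integer per-class test counts summing to round(fraction * total)."""
    total = sum(counts.values())
    target = int(round(fraction * total))
    ideal = {c: fraction * n for c, n in counts.items()}
    base = {c: int(np.floor(v)) for c, v in ideal.items()}
    short = target - sum(base.values())
    remainders = sorted(
        counts, key=lambda c: (-(ideal[c] - base[c]), str(c))
    )
    for c in remainders[:short]:
        base[c] += 1
    return base


def split_80_20(
    labels: Sequence, seed: int, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified 80:20 split; returns (train_idx, test_idx).

    Per-class test counts use largest-remainder rounding, so class
    proportions in each side stay within one record of the global ones.
    """
    labels = np.asarray(labels)
    if len(labels) < 5:
        raise ValueError("need at least 5 records to split 80:20")
    classes, class_counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    counts = dict(zip(classes.tolist(), class_counts.tolist()))
    test_per_class = _largest_remainder(counts, test_fraction)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in classes:
        cls_idx = np.flatnonzero(labels == cls)
        rng.shuffle(cls_idx)
        test_idx.extend(cls_idx[: test_per_class[cls.item()]].tolist())
    test_mask = np.zeros(len(labels), dtype=bool)
    test_mask[test_idx] = True
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


def protein_grouped_split(
    groups: Sequence, seed: int, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Split at protein granularity: every protein's mutations land entirely
    in train or entirely in test (leakage guard), targeting an 80:20 mutation
    count best-effort."""
    groups = np.asarray(groups)
    proteins = np.unique(groups)
    if len(proteins) < 2:
        raise ValueError("grouped split needs at least 2 proteins")
    rng = np.random.default_rng(seed)
    order = proteins.copy()
    rng.shuffle(order)
    target = test_fraction * len(groups)
    test_proteins: set = set()
    n_test = 0
    for p in order:
        if n_test >= target:
            break
        test_proteins.add(p.item() if hasattr(p, "item") else p)
        n_test += int(np.sum(groups == p))
    if len(test_proteins) == len(proteins):  # keep at least one protein in train
        test_proteins.pop()
    test_mask = np.isin(groups, list(test_proteins))
    return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts plus derived classification metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/n; balanced_accuracy = (sens+spec)/2;
    mcc = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), 0 when any
    factor of the denominator vanishes. AUCs are None when the truth is
    single-class (flagged, not silently 0).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    auc_roc: float | None = None
    auc_pr: float | None = None

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Metrics from raw confusion counts (no probabilities, so no AUCs)."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion table")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    bacc = (sens + spec) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        balanced_accuracy=bacc, mcc=float(mcc),
    )


def metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    probabilities: Sequence[float] | None = None,
) -> MetricsReport:
    """Full metrics report; drivers (1) are the positive class.

    ROC-AUC is the trapezoidal rank statistic; PR-AUC is the step integration
    of the precision-recall curve.
    """
    y = np.asarray(labels).astype(int)
    pred = np.asarray(predictions).astype(int)
    if len(y) != len(pred):
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    report = confusion_metrics(tp, tn, fp, fn)
    if probabilities is not None:
        proba = np.asarray(probabilities, dtype=float)
        if len(np.unique(y)) == 2:
            report.auc_roc = float(roc_auc_score(y, proba))
            report.auc_pr = float(average_precision_score(y, proba))
    return report


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of per-fold metrics (counts summed, rates averaged)."""
    def avg(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        tp=sum(r.tp for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        sensitivity=avg("sensitivity"),
        specificity=avg("specificity"),
        accuracy=avg("accuracy"),
        balanced_accuracy=avg("balanced_accuracy"),
        mcc=avg("mcc"),
        auc_roc=avg("auc_roc"),
        auc_pr=avg("auc_pr"),
    )


# ---------------------------------------------------------------------------
# training / prediction / cross-validation
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier bundled with its preprocessing state: imputation
    medians, min-max scaler and the selected feature schema."""

    network: MLPClassifier
    imputer: MedianImputer
    scaler: MinMaxScaler
    feature_names: list[str]
    config: ModelConfig

    def _prepare(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in df.columns]
        extra = [c for c in df.columns if c not in self.feature_names]
        if missing:
            raise ValueError(
                f"schema mismatch: missing columns {missing}"
                + (f", extra columns {extra}" if extra else "")
            )
        df = df[self.feature_names]
        df = self.imputer.transform(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = self.scaler.transform(df)
        return df.to_numpy(dtype=float)

    def predict(
        self, df: pd.DataFrame, threshold: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, labels); label = probability >= threshold."""
        x = self._prepare(df)
        proba = self.network.predict_proba(x)
        t = self.config.threshold if threshold is None else threshold
        return proba, (proba >= t).astype(int)


def train(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit imputer, scaler and network on a training matrix.

    ``feature_names`` restricts training to a selected column subset (the
    output of ``select_k_best``); default is all columns.
    """
    if config is None:
        config = ModelConfig()
    cols = list(feature_names) if feature_names is not None else list(matrix.features.columns)
    df = matrix.features[cols]
    imputer = MedianImputer().fit(df)
    df = imputer.transform(df)
    scaler = MinMaxScaler(
        passthrough=frozenset(c for c in matrix.onehot_columns if c in cols)
    )
    df = scaler.fit_transform(df)
    net = MLPClassifier(n_features=len(cols), config=config)
    net.fit(df.to_numpy(dtype=float), matrix.labels)
    return TrainedModel(
        network=net,
        imputer=imputer,
        scaler=scaler,
        feature_names=cols,
        config=config,
    )


def kfold_cv(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    select_k: int | None = None,
    scorer: str = "anova_f",
) -> tuple[list[MetricsReport], MetricsReport, list[list[str]]]:
    """Stratified k-fold cross-validation with per-fold refitting.

    Every preprocessing step (imputation, normalization, feature selection)
    is refitted inside each fold on its training part only, so no information
    leaks from validation rows. Returns (per-fold reports, mean report,
    per-fold selected feature lists).
    """
    if config is None:
        config = ModelConfig()
    y = matrix.labels
    if len(y) < k:
        raise ValueError(f"n={len(y)} rows cannot form {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    selections: list[list[str]] = []
    for fold, (tr_idx, va_idx) in enumerate(splitter.split(matrix.features, y)):
        tr = matrix.subset(tr_idx)
        va = matrix.subset(va_idx)
        cols = list(tr.features.columns)
        if select_k is not None:
            imput = MedianImputer().fit(tr.features)
            cols = select_k_best(
                imput.transform(tr.features), tr.labels, select_k, scorer
            )
        selections.append(cols)
        fold_config = ModelConfig(**{**config.__dict__, "seed": config.seed + fold})
        model = train(tr, fold_config, feature_names=cols)
        proba, pred = model.predict(va.features)
        reports.append(metrics(va.labels, pred, proba))
    return reports, mean_report(reports), selections


def sweep_k(
    matrix: FeatureMatrix,
    k_grid: Sequence[int],
    config: ModelConfig | None = None,
    cv: int = 5,
    seed: int = 0,
    scorer: str = "anova_f",
) -> tuple[int, dict[int, float]]:
    """Pick the feature count maximizing mean CV balanced accuracy over a
    grid (up to 50); ties resolve to the smallest k."""
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    results: dict[int, float] = {}
    for k in k_grid:
        _, mean, _ = kfold_cv(
            matrix, config=config, k=cv, seed=seed, select_k=k, scorer=scorer
        )
        results[k] = mean.balanced_accuracy
    best = min(results, key=lambda k: (-results[k], k))
    return best, results
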