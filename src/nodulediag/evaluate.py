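"""End-to-end evaluation: panel-only vs. feature-subset vs. combined model.

Every method is scored on the identical held-out records (the report keeps a
hash of the fold assignment).  The binary 7-AAB panel enters the ROC
comparison through its marker-count score (number of positive markers,
0-7), a documented surrogate since a single binary call has no threshold to
sweep; its sensitivity/specificity use the combined call itself.  The
positive class for recall/F1 is malignant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nodulediag import net as _net
from nodulediag import panel as _panel
from nodulediag import preprocess as _pre
from nodulediag.cohort import CohortConfig
from nodulediag.net import NetworkParams, TrainConfig
from nodulediag.preprocess import FeatureSpec, NormalizationStats


@dataclass
class TrainedModel:
    """A network bundled with the feature specs and normalization it was
    trained under."""

    params: NetworkParams
    specs: list[FeatureSpec]
    stats: NormalizationStats

    def scores(self, cohort: pd.DataFrame) -> np.ndarray:
        feats = _pre.transform(cohort, self.stats, self.specs)
        return _net.predict_scores(feats, self.params)


@dataclass(frozen=True)
class MethodMetrics:
    """All scalar metrics for one method on one evaluation set."""

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "sensitivity", "specificity", "accuracy",
                 "recall", "f1", "tp", "fp", "tn", "fn")}


@dataclass
class EvaluationReport:
    methods: dict[str, MethodMetrics]
    n_test: int
    test_index_hash: str
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "methods": {k: v.to_dict() for k, v in self.methods.items()},
            "n_test": self.n_test,
            "test_index_hash": self.test_index_hash,
            "config_fingerprint": self.config_fingerprint,
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.to_dict() for k, v in self.methods.items()}).T


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2PR/(P+R) with the malignant class positive."""
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def score_metrics(labels: Sequence, calls: Sequence, scores: Sequence[float]
                  ) -> MethodMetrics:
    """Metrics for one method: binary calls for the confusion-based
    quantities, a continuous score for the ROC/AUC."""
    perf = _panel.diagnostic_performance(labels, calls)
    points, auc = _panel.roc_curve(scores, labels)
    return MethodMetrics(
        auc=auc,
        sensitivity=perf.sensitivity,
        specificity=perf.specificity,
        accuracy=perf.accuracy,
        recall=perf.sensitivity,  # identical by definition
        f1=f1_score(perf.tp, perf.fp, perf.fn),
        tp=perf.tp, fp=perf.fp, tn=perf.tn, fn=perf.fn,
        roc_points=points,
    )


def _index_hash(idx: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(idx, dtype=np.int64).tobytes()).hexdigest()[:16]


def evaluate_methods(
    cohort: pd.DataFrame,
    cutoffs: Mapping[str, float],
    models: Mapping[str, TrainedModel],
    test_index: np.ndarray,
    threshold: float = 0.0,
    config_fingerprint: str = "",
) -> EvaluationReport:
    """Score the panel and every trained model on the same held-out rows."""
    test_index = np.asarray(test_index, dtype=int)
    test = cohort.iloc[test_index]
    labels = test["label"].to_numpy()

    calls = _panel.call_panel(test, cutoffs)
    methods = {
        "panel": score_metrics(
            labels,
            calls["panel_positive"].to_numpy(),
            _panel.marker_count_score(calls).to_numpy(dtype=float),
        )
    }
    for name, model in models.items():
        scores = model.scores(test)
        methods[name] = score_metrics(labels, scores > threshold, scores)
    return EvaluationReport(
        methods=methods,
        n_test=len(test),
        test_index_hash=_index_hash(test_index),
        config_fingerprint=config_fingerprint,
    )


def fingerprint(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def train_model(
    cohort: pd.DataFrame,
    train_index: np.ndarray,
    val_index: np.ndarray | None,
    config: TrainConfig,
    specs: list[FeatureSpec] | None = None,
) -> tuple[TrainedModel, list[dict]]:
    """Fit normalization on the training rows only, then train the network."""
    if specs is None:
        specs = _pre.default_feature_specs()
    tr = cohort.iloc[np.asarray(train_index, dtype=int)]
    stats = _pre.fit_normalization(tr, specs, fitted_on=f"n={len(tr)}")
    feats = _pre.transform(tr, stats, specs)
    labels = np.where(tr["label"].to_numpy() == "malignant", 1.0, -1.0)
    if val_index is not None:
        va = cohort.iloc[np.asarray(val_index, dtype=int)]
        params, log = _net.train(
            feats, labels, config,
            val_features=_pre.transform(va, stats, specs),
            val_labels=np.where(va["label"].to_numpy() == "malignant", 1.0, -1.0),
        )
    else:
        params, log = _net.train(feats, labels, config)
    return TrainedModel(params=params, specs=specs, stats=stats), log


def stratified_kfold(labels: Sequence, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint test folds with class ratios preserved."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in np.unique(y):
        idx = np.flatnonzero(y == value)
        rng.shuffle(idx)
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[j].extend(chunk)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def cross_validate(
    cohort: pd.DataFrame,
    cutoffs: Mapping[str, float],
    k: int,
    seed: int,
    config: TrainConfig | None = None,
    specs: list[FeatureSpec] | None = None,
) -> tuple[list[EvaluationReport], pd.DataFrame]:
    """Stratified k-fold train/evaluate; returns per-fold reports plus a
    mean/SD summary per metric for the network and the panel."""
    if config is None:
        config = TrainConfig()
    labels = cohort["label"].to_numpy()
    folds = stratified_kfold(labels, k, seed)
    if any(len(np.unique(labels[f])) < 2 for f in folds):
        raise ValueError("a fold lacks one of the classes; reduce k")
    all_idx = np.arange(len(cohort))
    reports = []
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fold_config = TrainConfig(**{**config.__dict__, "seed": config.seed + j})
        model, _ = train_model(cohort, train_idx, None, fold_config, specs)
        reports.append(evaluate_methods(cohort, cutoffs, {"network": model}, test_idx))
    rows = {}
    for method in reports[0].methods:
        frame = pd.DataFrame([r.methods[method].to_dict() for r in reports])
        rows[(method, "mean")] = frame.mean()
        rows[(method, "sd")] = frame.std(ddof=1)
    return reports, pd.DataFrame(rows).T
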