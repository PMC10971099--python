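"""Lame / sound classification on backbone height profiles.

Three classical classifiers - Random Forest, K-Nearest Neighbours and a
Decision Tree - are trained on length-176 backbone profiles, plus a
transparent baseline that thresholds the profile maximum at the 1.2 m
dorsal-height boundary (an arched, lowered back rarely tops 1.2 m; an
upright back usually does).  Accuracy is reported per frame; per-cow
aggregation by majority vote over a track's frames is offered as an
optional reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .synthetic import LAME_CUTOFF_M

CLASS_ORDER = ("lame", "sound")

#: Default hyperparameters, recorded in every report for provenance.
DEFAULT_HYPERPARAMS = {
    "rf": {"n_estimators": 100},
    "knn": {"n_neighbors": 5},
    "dt": {"max_depth": None},
}


@dataclass
class LabelledDataset:
    """Feature rows with labels and a per-row train/test split tag."""

    features: np.ndarray
    labels: np.ndarray
    split: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.split = np.asarray(self.split)
        n = self.features.shape[0]
        if self.labels.shape[0] != n or self.split.shape[0] != n:
            raise ValueError("features, labels and split must align row-wise")
        if np.any(~np.isin(self.labels, CLASS_ORDER)):
            raise ValueError(f"labels must be one of {CLASS_ORDER}")
        if np.any(~np.isin(self.split, ("train", "test"))):
            raise ValueError("split tags must be 'train' or 'test'")
        if np.any(np.all(self.features == 0, axis=1)):
            raise ValueError(
                "all-zero feature rows must be excluded upstream"
            )

    def rows(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == tag
        return self.features[sel], self.labels[sel]


@dataclass
class ClassifierReport:
    """Evaluation of one model: accuracies (%), confusion, predictions.

    Accuracies are percentages rounded to one decimal; ``confusion`` is a
    2x2 frame of test-split counts (rows: true label, columns: predicted)
    in the order (lame, sound).
    """

    model: str
    train_accuracy: float
    test_accuracy: float
    confusion: pd.DataFrame
    predictions: pd.DataFrame
    params: dict = field(default_factory=dict)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    counts = np.zeros((2, 2), dtype=int)
    for i, true_lab in enumerate(CLASS_ORDER):
        for j, pred_lab in enumerate(CLASS_ORDER):
            counts[i, j] = int(np.sum((y_true == true_lab) & (y_pred == pred_lab)))
    return pd.DataFrame(counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))


def _accuracy_pct(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if len(y_true) == 0:  # e.g. the baseline scored on an empty split
        return float("nan")
    return round(100.0 * float(np.mean(y_true == y_pred)), 1)


def _report(
    model_name: str,
    params: dict,
    splits: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> ClassifierReport:
    pred_rows = []
    accuracies = {}
    for tag, (y_true, y_pred, _) in splits.items():
        accuracies[tag] = _accuracy_pct(y_true, y_pred)
        pred_rows.extend(
            {
                "split": tag,
                "row": i,
                "label": t,
                "prediction": p,
                "correct": bool(t == p),
            }
            for i, (t, p) in enumerate(zip(y_true, y_pred))
        )
    y_true_test, y_pred_test, _ = splits["test"]
    return ClassifierReport(
        model=model_name,
        train_accuracy=accuracies["train"],
        test_accuracy=accuracies["test"],
        confusion=_confusion(y_true_test, y_pred_test),
        predictions=pd.DataFrame(pred_rows),
        params=params,
    )


def _build_model(model: str, seed: int, hyperparams: dict):
    params = dict(DEFAULT_HYPERPARAMS[model])
    params.update(hyperparams)
    if model == "rf":
        return RandomForestClassifier(random_state=seed, **params), params
    if model == "knn":
        return KNeighborsClassifier(**params), params
    return DecisionTreeClassifier(random_state=seed, **params), params


def train_eval(
    dataset: LabelledDataset,
    model: str,
    seed: int = 0,
    **hyperparams,
) -> ClassifierReport:
    """Fit one of {rf, knn, dt} on the train split and evaluate both splits.

    ``seed`` fixes any stochastic fitting, so reports are reproducible
    bit-for-bit.  Raises if the training split contains a single class.
    """
    if model not in DEFAULT_HYPERPARAMS:
        raise ValueError(f"model must be one of {tuple(DEFAULT_HYPERPARAMS)}")
    x_train, y_train = dataset.rows("train")
    x_test, y_test = dataset.rows("test")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split must contain both classes")
    clf, params = _build_model(model, seed, hyperparams)
    clf.fit(x_train, y_train)
    splits = {
        "train": (y_train, clf.predict(x_train), x_train),
        "test": (y_test, clf.predict(x_test), x_test),
    }
    return _report(model.upper(), params, splits)


def threshold_baseline(
    dataset: LabelledDataset, cutoff: float = LAME_CUTOFF_M
) -> ClassifierReport:
    """Predict lame iff the profile maximum falls below ``cutoff`` metres."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def predict(x: np.ndarray) -> np.ndarray:
        return np.where(x.max(axis=1) < cutoff, "lame", "sound")

    splits = {}
    for tag in ("train", "test"):
        x, y = dataset.rows(tag)
        splits[tag] = (y, predict(x), x)
    return _report("baseline", {"cutoff": cutoff}, splits)


def majority_vote(
    predictions: pd.DataFrame, track_ids: Sequence[int]
) -> pd.DataFrame:
    """Optional per-cow layer: majority vote over each track's frames.

    ``predictions`` is a ClassifierReport.predictions frame whose rows are
    aligned with ``track_ids``.  Ties go to 'lame' (err on the side of
    flagging an animal for inspection).
    """
    df = predictions.copy()
    df["track_id"] = list(track_ids)
    rows = []
    for (split, tid), grp in df.groupby(["split", "track_id"]):
        lame_votes = int((grp["prediction"] == "lame").sum())
        verdict = "lame" if lame_votes * 2 >= len(grp) else "sound"
        rows.append(
            {
                "split": split,
                "track_id": tid,
                "prediction": verdict,
                "label": grp["label"].iloc[0],
                "n_frames": len(grp),
            }
        )
    return pd.DataFrame(rows)
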