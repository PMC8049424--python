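"""Outcome prediction from joint features.

A random forest (500 trees by default) evaluated by leave-one-out
cross-validation, plus variable importances rescaled so the top feature
scores 100; features above a cutoff (default 50) are reported as
candidate biomarkers. An optional gradient-boosting backend (xgboost)
is exposed behind ``model="xgb"`` when that library is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .tables import FeatureTable, format_key

__all__ = [
    "PredictionReport",
    "loocv_accuracy",
    "variable_importance",
    "prediction_report",
]


@dataclass
class PredictionReport:
    model_name: str
    n_trees: int
    n_features: int
    loocv_accuracy: float
    importances: dict[str, float] = field(default_factory=dict)
    selected_features: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "model_name": self.model_name,
                "n_trees": self.n_trees,
                "n_features": self.n_features,
                "loocv_accuracy": self.loocv_accuracy,
                "importances": self.importances,
                "selected_features": self.selected_features,
                "seed": self.seed,
            },
            indent=indent,
            sort_keys=False,
        )


def _design(table: FeatureTable, outcomes: Mapping[str, int]):
    samples = table.sample_ids
    missing = [s for s in samples if s not in outcomes]
    if missing:
        raise ValueError(f"samples without outcome: {missing}")
    X = table.values.T  # samples × features
    y = np.array([int(outcomes[s]) for s in samples])
    if len(np.unique(y)) < 2:
        raise ValueError("outcomes contain a single class")
    return X, y


def _make_model(model: str, n_trees: int, seed: int):
    if model == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    if model == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=n_trees, random_state=seed, verbosity=0)
    raise ValueError(f"unknown model {model!r}")


def loocv_accuracy(
    table: FeatureTable,
    outcomes: Mapping[str, int],
    n_trees: int = 500,
    seed: int = 0,
    model: Literal["rf", "xgb"] = "rf",
) -> float:
    """Leave-one-out cross-validated accuracy.

    Each sample is predicted by a forest trained on the other n-1;
    accuracy is the exact fraction of correct predictions. Deterministic
    for a fixed seed (each fold reuses the same seed; prediction ties in
    the vote resolve to the lower class label).
    """
    X, y = _design(table, outcomes)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = _make_model(model, n_trees, seed)
        clf.fit(X[train], y[train])
        if int(clf.predict(X[i : i + 1])[0]) == y[i]:
            correct += 1
    return correct / n


def variable_importance(
    table: FeatureTable,
    outcomes: Mapping[str, int],
    n_trees: int = 500,
    seed: int = 0,
    threshold: float = 50.0,
    mode: Literal["impurity", "permutation"] = "impurity",
) -> tuple[dict[str, float], list[str]]:
    """Variable importances on a full-data forest, min–max scaled to [0, 100].

    Returns (importances keyed by "taxon|gene", features with importance
    strictly above ``threshold``, sorted descending). All-constant
    feature matrices yield all-zero importances and an empty selection.
    """
    X, y = _design(table, outcomes)
    clf = _make_model("rf", n_trees, seed)
    clf.fit(X, y)
    if mode == "impurity":
        raw = np.asarray(clf.feature_importances_, dtype=float)
    elif mode == "permutation":
        raw = permutation_importance(
            clf, X, y, n_repeats=10, random_state=seed
        ).importances_mean
        raw = np.clip(raw, 0.0, None)
    else:
        raise ValueError(f"unknown importance mode {mode!r}")
    raw = np.nan_to_num(raw, nan=0.0)
    lo, hi = float(raw.min()), float(raw.max())
    scaled = np.zeros_like(raw) if hi <= lo or hi == 0 else (raw - lo) / (hi - lo) * 100.0
    keys = [format_key(t, g) for t, g in table.feature_keys]
    importances = dict(zip(keys, (float(v) for v in scaled)))
    selected = sorted(
        (k for k, v in importances.items() if v > threshold),
        key=lambda k: (-importances[k], k),
    )
    return importances, selected


def prediction_report(
    table: FeatureTable,
    outcomes: Mapping[str, int],
    n_trees: int = 500,
    seed: int = 0,
    threshold: float = 50.0,
    model: Literal["rf", "xgb"] = "rf",
) -> PredictionReport:
    """LOOCV accuracy plus scaled importances in one report object."""
    acc = loocv_accuracy(table, outcomes, n_trees=n_trees, seed=seed, model=model)
    importances, selected = variable_importance(
        table, outcomes, n_trees=n_trees, seed=seed, threshold=threshold
    )
    return PredictionReport(
        model_name="random forest" if model == "rf" else "gradient boosting",
        n_trees=n_trees,
        n_features=table.shape[0],
        loocv_accuracy=acc,
        importances=importances,
        selected_features=selected,
        seed=seed,
    )
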