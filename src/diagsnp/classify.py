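"""Supervised validation of the selected markers.

A linear support vector machine is trained on labeled dosage vectors
(pure samples) and evaluated on pure and mixed samples; a mixture counts
as correct when the prediction matches its majority parent (either parent
is acceptable at an exact 50–50 split).  The classifier is a contract —
features in a recorded variant order, deterministic for a given seed —
with the learning algorithm taken off the shelf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .mixtures import MixtureSample

__all__ = ["SpeciesClassifier", "ClassifierReport", "train", "evaluate"]


@dataclass
class ClassifierReport:
    """Per-sample predictions plus aggregate accuracies."""

    predictions: pd.DataFrame  # sample_id, truth, predicted, correct, proportion
    accuracy_pure: float | None
    accuracy_mixed: float | None
    per_proportion: dict[float, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "accuracy_pure": self.accuracy_pure,
            "accuracy_mixed": self.accuracy_mixed,
            "per_proportion": {str(k): v for k, v in self.per_proportion.items()},
            "predictions": self.predictions.to_dict(orient="records"),
        }, indent=2)


class SpeciesClassifier:
    """Linear one-vs-rest SVM over a fixed variant order."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self.variant_ids: list[str] | None = None
        self._svc: SVC | None = None
        self._train_X: pd.DataFrame | None = None
        self._train_labels: list[str] | None = None

    def fit(self, X: pd.DataFrame, labels: Sequence[str]) -> "SpeciesClassifier":
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError(f"need >= 2 classes to train, got {classes}")
        self.variant_ids = list(X.columns)
        self._train_X = X.copy()
        self._train_labels = list(labels)
        self._svc = SVC(
            kernel="linear", C=self.C, decision_function_shape="ovr",
            random_state=self.seed,
        )
        self._svc.fit(self._matrix(X), np.asarray(labels))
        return self

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        if self.variant_ids is None:
            raise ValueError("classifier is not fitted")
        missing = [v for v in self.variant_ids if v not in X.columns]
        if missing:
            raise ValueError(
                f"feature mismatch: {len(missing)} of {len(self.variant_ids)} "
                f"training variants absent (e.g. {missing[0]})"
            )
        return np.nan_to_num(X[self.variant_ids].to_numpy(dtype=float), nan=0.5)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._svc.predict(self._matrix(X))

    def decision_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = self._svc.decision_function(self._matrix(X))
        if scores.ndim == 1:  # binary
            scores = np.column_stack([-scores, scores])
        return pd.DataFrame(scores, index=X.index, columns=self._svc.classes_)

    # -- persistence ---------------------------------------------------
    # Versioned JSON carrying the training matrix and hyper-parameters;
    # loading refits, which is deterministic for a fixed seed and therefore
    # reproduces predictions exactly while staying pickle-free.
    def save(self, path: str | Path) -> None:
        if self._svc is None or self._train_X is None:
            raise ValueError("classifier is not fitted")
        payload = {
            "format_version": 1,
            "C": self.C,
            "seed": self.seed,
            "variant_ids": self.variant_ids,
            "sample_ids": list(map(str, self._train_X.index)),
            "X": self._train_X.to_numpy(dtype=float).tolist(),
            "labels": list(self._train_labels),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SpeciesClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError("unsupported classifier file version")
        obj = cls(C=payload["C"], seed=payload["seed"])
        X = pd.DataFrame(
            payload["X"], index=payload["sample_ids"], columns=payload["variant_ids"]
        )
        return obj.fit(X, payload["labels"])


def _samples_xy(samples: Sequence[MixtureSample]) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame({s.sample_id: s.dosage for s in samples}).T
    labels = [s.parents[0] for s in samples]
    return X, labels


def train(samples: Sequence[MixtureSample], C: float = 1.0, seed: int = 0) -> SpeciesClassifier:
    """Fit the SVM on pure labeled samples (label = the single parent)."""
    if any(not s.is_pure for s in samples):
        raise ValueError("training samples must be pure")
    X, labels = _samples_xy(samples)
    return SpeciesClassifier(C=C, seed=seed).fit(X, labels)


def evaluate(model: SpeciesClassifier, samples: Sequence[MixtureSample]) -> ClassifierReport:
    """Predict every sample; mixtures score against the majority parent.

    At an exact 50–50 mixture either parent is accepted.  Aggregates report
    pure-sample accuracy, mixed-sample accuracy and a per-proportion
    breakdown.
    """
    if not samples:
        return ClassifierReport(
            predictions=pd.DataFrame(
                columns=["sample_id", "kind", "truth", "predicted", "correct",
                         "proportion"]
            ),
            accuracy_pure=None, accuracy_mixed=None,
        )
    X = pd.DataFrame({s.sample_id: s.dosage for s in samples}).T
    predicted = model.predict(X)
    rows = []
    for s, pred in zip(samples, predicted):
        if s.is_pure:
            truth = s.parents[0]
            correct = pred == truth
            kind = "pure"
        else:
            maj = s.majority_parent
            truth = maj if maj is not None else "|".join(s.parents)
            correct = pred == maj if maj is not None else pred in s.parents
            kind = "mixed"
        rows.append({
            "sample_id": s.sample_id, "kind": kind, "truth": truth,
            "predicted": pred, "correct": bool(correct),
            "proportion": s.proportion,
        })
    frame = pd.DataFrame(rows)
    pure = frame[frame["kind"] == "pure"]
    mixed = frame[frame["kind"] == "mixed"]
    per_prop = {
        float(p): float(sub["correct"].mean())
        for p, sub in mixed.groupby("proportion")
    }
    return ClassifierReport(
        predictions=frame,
        accuracy_pure=float(pure["correct"].mean()) if len(pure) else None,
        accuracy_mixed=float(mixed["correct"].mean()) if len(mixed) else None,
        per_proportion=per_prop,
    )
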