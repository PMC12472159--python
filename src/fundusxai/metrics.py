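"""Classification metrics and prediction-score statistics for DR graders.

Multi-class metrics are macro one-vs-rest: F1 and specificity are
computed per class and averaged; AUC is the macro one-vs-rest ROC AUC
from the probability vectors.  Score statistics summarize classifier
confidence per (grade, correctness) stratum: for a correct prediction
the score is the probability assigned to the true class, for an
incorrect one it is the probability of the (wrong) predicted class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "PredictionRecord",
    "N_GRADES",
    "confusion_matrix",
    "classification_metrics",
    "score_statistics",
    "records_from_frame",
]

N_GRADES = 5  # ICDR grades 0 (no DR) .. 4 (proliferative DR)


@dataclass
class PredictionRecord:
    image_id: str
    true_grade: int
    predicted_grade: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise ValueError(
                f"probability vector for {self.image_id!r} is not a distribution"
            )
        self.probabilities = p

    @property
    def correct(self) -> bool:
        return self.true_grade == self.predicted_grade

    @property
    def score(self) -> float:
        """The reported confidence: p(true class) when correct, else
        p(predicted class)."""
        idx = self.true_grade if self.correct else self.predicted_grade
        return float(self.probabilities[idx])


def records_from_frame(df: pd.DataFrame) -> list[PredictionRecord]:
    """Build records from a predictions CSV with columns image_id,
    true_grade, predicted_grade, p0..p4."""
    prob_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    prob_cols.sort(key=lambda c: int(c[1:]))
    return [
        PredictionRecord(
            str(row["image_id"]),
            int(row["true_grade"]),
            int(row["predicted_grade"]),
            row[prob_cols].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]


def confusion_matrix(
    records: Sequence[PredictionRecord], normalize: bool = False
) -> np.ndarray:
    """Rows = true grade, columns = predicted grade."""
    mat = np.zeros((N_GRADES, N_GRADES), dtype=float)
    for r in records:
        if not (0 <= r.true_grade < N_GRADES and 0 <= r.predicted_grade < N_GRADES):
            raise ValueError(
                f"grade out of range for {r.image_id!r}: "
                f"true={r.true_grade}, predicted={r.predicted_grade}"
            )
        mat[r.true_grade, r.predicted_grade] += 1
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            mat = np.where(sums > 0, mat / sums, 0.0)
    return mat


def _macro_specificity(cm: np.ndarray) -> float:
    """Mean over present classes of TN / (TN + FP)."""
    total = cm.sum()
    vals = []
    for c in range(cm.shape[0]):
        if cm[c].sum() == 0 and cm[:, c].sum() == 0:
            continue
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c].sum() - tp
        tn = total - tp - fp - fn
        vals.append(tn / (tn + fp) if tn + fp > 0 else 1.0)
    return float(np.mean(vals)) if vals else float("nan")


def classification_metrics(records: Sequence[PredictionRecord]) -> dict:
    """accuracy, macro F1, macro specificity, macro one-vs-rest AUC."""
    y_true = np.array([r.true_grade for r in records])
    y_pred = np.array([r.predicted_grade for r in records])
    probs = np.vstack([r.probabilities for r in records])
    cm = confusion_matrix(records)
    accuracy = float(np.trace(cm) / len(records))
    present = sorted(set(y_true) | set(y_pred))
    f1 = float(f1_score(y_true, y_pred, labels=present, average="macro", zero_division=0))
    specificity = _macro_specificity(cm)
    # per-class one-vs-rest AUC over classes with both positives and negatives
    aucs = []
    for c in range(probs.shape[1]):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos.astype(int), probs[:, c]))
    if aucs:
        auc: float | None = float(np.mean(aucs))
    else:
        warnings.warn("AUC undefined: fewer than two classes present", stacklevel=2)
        auc = None
    return {"accuracy": accuracy, "f1": f1, "specificity": specificity, "auc": auc}


def score_statistics(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Count/min/max/mean/median/std of scores per (grade, correctness).

    Sample std (n-1 denominator); 0 for a single observation; empty
    strata carry NaN statistics (rendered as dashes at report time).
    """
    rows = []
    for grade in range(N_GRADES):
        for correct in (True, False):
            scores = [
                r.score for r in records if r.true_grade == grade and r.correct == correct
            ]
            n = len(scores)
            if n == 0:
                stats = dict.fromkeys(("min", "max", "mean", "median", "std"), np.nan)
            else:
                arr = np.asarray(scores)
                stats = {
                    "min": arr.min(),
                    "max": arr.max(),
                    "mean": arr.mean(),
                    "median": np.median(arr),
                    "std": arr.std(ddof=1) if n > 1 else 0.0,
                }
            rows.append({"grade": grade, "correct": correct, "count": n, **stats})
    return pd.DataFrame(rows)
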