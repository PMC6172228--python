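"""ROC construction, threshold diagnostics and classifier calibration.

A humanness score becomes a binary human/non-human classifier once a
threshold is chosen.  Sweeping the threshold over all observed score values
traces a ROC curve; the operating point is picked by maximizing Youden's
index J = TPR − FPR (or the Matthews correlation coefficient, which in
practice selects nearly the same point).  The regularization weight λ of
the Gaussian model is selected by maximizing the area under the validation
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .alignment import CDRMask, SequenceDatabase
from .gaussian import MultivariateGaussianScorer
from .similarity import NearestReferenceScorer, two_reference_score

DIRECTIONS = ("higher_is_positive", "lower_is_positive")


@dataclass
class ROCResult:
    """Threshold sweep of a score-based classifier.

    ``thresholds`` are on the original score scale, in order of increasing
    number of predicted positives; with ``direction="higher_is_positive"``
    a query is positive when score >= threshold, with
    ``"lower_is_positive"`` when score <= threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    youden: np.ndarray
    mcc: np.ndarray
    auc: float
    direction: str
    best_index: int

    @property
    def best_threshold(self) -> float:
        return float(self.thresholds[self.best_index])

    @property
    def best_youden(self) -> float:
        return float(self.youden[self.best_index])

    @property
    def best_mcc(self) -> float:
        return float(self.mcc[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr,
             "youden": self.youden, "mcc": self.mcc}
        )

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "direction": self.direction,
            "best_threshold": self.best_threshold,
            "best_youden": self.best_youden,
            "best_mcc": self.best_mcc,
        }


class ConfusionStats(NamedTuple):
    youden: float
    mcc: float
    tpr: float
    fpr: float


def confusion_stats(
    tp: int, fp: int, tn: int, fn: int, youden_variant: str = "standard"
) -> ConfusionStats:
    """Youden's index, MCC, TPR and FPR from confusion counts.

    ``youden_variant="standard"`` is sensitivity + specificity − 1
    (= TPR − FPR); ``"printed"`` is the TP/(TP+FN) + TN/(TN+FN) − 1 variant
    occasionally seen in print.  MCC with a zero denominator is defined as 0.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all confusion counts are zero")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TPR/FPR undefined: empty positive or negative class")
    tpr = tp / (tp + fn)
    fpr = fp / (tn + fp)
    if youden_variant == "standard":
        youden = tpr - fpr
    elif youden_variant == "printed":
        if tn + fn == 0:
            raise ValueError("printed Youden variant undefined: TN + FN == 0")
        youden = tp / (tp + fn) + tn / (tn + fn) - 1.0
    else:
        raise ValueError(f"unknown youden_variant {youden_variant!r}")
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / np.sqrt(den)
    return ConfusionStats(float(youden), float(mcc), float(tpr), float(fpr))


def roc_curve(
    scores_pos: np.ndarray,
    scores_neg: np.ndarray,
    direction: str = "higher_is_positive",
) -> ROCResult:
    """ROC over all distinct score thresholds; AUC by the trapezoid rule.

    The best operating point maximizes Youden's index; ties are broken
    toward the threshold classifying fewer queries as positive.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("score arrays must be non-empty")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    P, N = scores_pos.size, scores_neg.size
    y = np.concatenate([np.ones(P), np.zeros(N)])
    s = np.concatenate([scores_pos, scores_neg])
    if direction == "lower_is_positive":
        s = -s
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    tp = np.rint(tpr * P)
    fp = np.rint(fpr * N)
    fn_ = P - tp
    tn = N - fp
    youden = tpr - fpr
    num = tp * tn - fp * fn_
    den = (tp + fp) * (tp + fn_) * (tn + fp) * (tn + fn_)
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(den > 0, num / np.sqrt(np.maximum(den, 1)), 0.0)
    # sklearn thresholds are decreasing: index 0 predicts the fewest
    # positives, so argmax on ties already picks the conservative end.
    best_index = int(np.argmax(youden))
    thresholds = thr if direction == "higher_is_positive" else -thr
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        youden=youden,
        mcc=mcc,
        auc=auc,
        direction=direction,
        best_index=best_index,
    )


def select_threshold(roc: ROCResult, criterion: str = "youden") -> float:
    """Threshold maximizing Youden's index or the MCC along the sweep;
    ties go to the threshold classifying fewer positives."""
    if criterion == "youden":
        values = roc.youden
    elif criterion == "mcc":
        values = roc.mcc
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(roc.thresholds[int(np.argmax(values))])


def select_lambda(
    learn: SequenceDatabase,
    val_pos: SequenceDatabase,
    val_neg: SequenceDatabase,
    grid,
    ablation: str | None = None,
    boundary: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the regularization weight λ maximizing validation AUC.

    One model is fitted per grid value on ``learn`` (optionally ablated),
    scored on held-out positive/negative validation ensembles, and the λ of
    the largest AUC is returned together with the full table.  AUC ties go
    to the smaller λ (stronger regularization).
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty lambda grid")
    if any(not (0.0 < g <= 1.0) for g in grid):
        raise ValueError("grid values must lie in (0, 1]")
    rows = []
    for lam in sorted(grid):
        model = MultivariateGaussianScorer(lam=lam, alphabet=learn.alphabet).fit(learn)
        if ablation is not None:
            model = model.ablated(ablation, boundary=boundary)
        roc = roc_curve(
            model.score_samples(val_pos),
            model.score_samples(val_neg),
            direction="higher_is_positive",
        )
        rows.append({"lam": lam, "auc": roc.auc})
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax()]  # idxmax: first max => smallest lam
    return float(best["lam"]), table


def classify_sequences(
    queries: SequenceDatabase,
    mode: str,
    *,
    model: MultivariateGaussianScorer | None = None,
    model_neg: MultivariateGaussianScorer | None = None,
    ref: SequenceDatabase | None = None,
    ref_neg: SequenceDatabase | None = None,
    k: int | str = 1,
    threshold: float | None = None,
    mask: CDRMask | None = None,
) -> pd.DataFrame:
    """Label every query human / non-human under one of four schemes.

    ``mg_one_ref``: model score > threshold ⇒ human.
    ``mg_two_ref``: human-model score > murine-model score ⇒ human.
    ``t_k_one_ref``: T_k distance < threshold ⇒ human.
    ``t_k_two_ref``: mean-distance contrast > 0 ⇒ human.

    Exact ties are labeled non-human (conservative for humanization use).
    """
    ids = [s.id for s in queries]
    if mode == "mg_one_ref":
        if model is None or threshold is None:
            raise ValueError("mg_one_ref requires a model and a frozen threshold")
        scores = model.score_samples(queries)
        labels = np.where(scores > threshold, "human", "non-human")
        return pd.DataFrame({"id": ids, "score": scores, "label": labels})
    if mode == "mg_two_ref":
        if model is None or model_neg is None:
            raise ValueError("mg_two_ref requires human and murine models")
        sh = model.score_samples(queries)
        sm = model_neg.score_samples(queries)
        labels = np.where(sh > sm, "human", "non-human")
        return pd.DataFrame(
            {"id": ids, "score_human": sh, "score_murine": sm, "label": labels}
        )
    if mode == "t_k_one_ref":
        if ref is None or threshold is None:
            raise ValueError("t_k_one_ref requires a reference and a threshold")
        scores = NearestReferenceScorer(k=k, exclude=mask).fit(ref).score_samples(queries)
        labels = np.where(scores < threshold, "human", "non-human")
        return pd.DataFrame({"id": ids, "score": scores, "label": labels})
    if mode == "t_k_two_ref":
        if ref is None or ref_neg is None:
            raise ValueError("t_k_two_ref requires human and murine references")
        scores = np.array(
            [two_reference_score(ref, ref_neg, q, mask=mask) for q in queries]
        )
        labels = np.where(scores > 0, "human", "non-human")
        return pd.DataFrame({"id": ids, "score": scores, "label": labels})
    raise ValueError(f"unknown mode {mode!r}")
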