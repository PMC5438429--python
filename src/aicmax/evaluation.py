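"""Raw-vs-reduced representation comparison: CV, MCC, Wilcoxon test.

A reduced fingerprint is only useful if a classifier trained on it
matches (or beats) one trained on the full representation. This module
scores each task with stratified cross-validation, pools the
out-of-fold predictions into one confusion matrix, summarizes it by the
Matthews Correlation Coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and compares the paired per-task MCCs of the two representations with a
one-sided Wilcoxon signed-rank test (alternative: reduced ≥ raw).

The classifier is a pluggable adapter (``fit(X, y)`` / ``predict(X)``);
the default is a random forest, but the harness is equally testable
with a trivial deterministic stub.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _tool_version
from .errors import DegenerateTaskError
from .fingerprints import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 10
DEFAULT_NC_TOLERANCE = 0.005
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient of a confusion matrix.

    +1 is perfect prediction, 0 random, −1 inverse. If any marginal of
    the confusion matrix is empty the coefficient is undefined; the
    common 0 convention is applied and logged.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        logger.warning("MCC denominator is zero (%s); returning 0 by convention", counts)
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom_sq))


class Learner(Protocol):
    """Classifier adapter: anything with fit/predict on binary matrices."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class RandomForestLearner:
    """Default learner: a random forest on the 0/1 bit matrix.

    Defaults: 500 trees, sqrt(#bits) candidate features per split, fixed
    seed. All settings pass through to scikit-learn.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: str | int | float = "sqrt",
        random_state: int = 0,
        **kwargs,
    ) -> None:
        self.params = dict(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=random_state,
            **kwargs,
        )
        self._model: RandomForestClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestLearner":
        self._model = RandomForestClassifier(**self.params).fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("fit must be called before predict")
        return self._model.predict(X)


class ParityStubLearner:
    """Deterministic stub for harness tests: predicts the parity of the row sum.

    Ignores the training labels entirely, so it carries no information
    about them — useful for exercising the comparison machinery under a
    known null.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ParityStubLearner":
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X).sum(axis=1) % 2).astype(int)


def cross_validated_mcc(
    dataset: LabeledDataset,
    bit_subset: Sequence[int] | None,
    learner: Learner,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> float:
    """Pooled out-of-fold MCC under stratified k-fold cross-validation.

    ``bit_subset=None`` uses every bit (the raw representation); a bit
    list restricts columns before training. Predictions from all folds
    are pooled into a single confusion matrix scored once. If the
    smaller class cannot fill the requested folds the fold count is
    reduced with a warning; fewer than 2 possible folds is an error.
    """
    y = dataset.labels.astype(int)
    dataset.require_both_classes()
    X = (
        dataset.matrix.values
        if bit_subset is None
        else dataset.matrix.columns(list(bit_subset))
    )
    min_class = int(min(np.sum(y == 0), np.sum(y == 1)))
    if min_class < 2:
        raise DegenerateTaskError(
            f"task {dataset.task_id!r}: smallest class has {min_class} member(s), "
            "cannot stratify"
        )
    folds_eff = min(folds, min_class)
    if folds_eff < folds:
        logger.warning(
            "task %r: reducing folds from %d to %d (smallest class size)",
            dataset.task_id, folds, folds_eff,
        )
    splitter = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train_idx, test_idx in splitter.split(X, y):
        fitted = learner.fit(X[train_idx], y[train_idx])
        pred[test_idx] = np.asarray(fitted.predict(X[test_idx])).astype(int)
    return mcc(ConfusionCounts.from_predictions(y, pred))


def wilcoxon_signed_rank(
    diffs: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |differences| are ranked with average
    ranks on ties; the statistic is the sum of the ranks of the positive
    differences. The null tail is exact (full enumeration of the
    sign-assignment distribution via the rank generating polynomial) for
    n ≤ 25 and a tie-corrected normal approximation with continuity
    correction beyond that. ``alternative`` ∈ {greater, less, two-sided};
    "greater" tests whether differences are shifted above zero.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(list(diffs), dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))

    if n <= EXACT_WILCOXON_MAX_N:
        p_ge, p_le = _exact_tail_probs(ranks, w_pos)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        sd = math.sqrt(var)
        p_ge = float(stats.norm.sf((w_pos - mu - 0.5) / sd))
        p_le = float(stats.norm.cdf((w_pos - mu + 0.5) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_pos, float(min(max(p, 0.0), 1.0))


def _exact_tail_probs(ranks: np.ndarray, w_pos: float) -> tuple[float, float]:
    """Exact P(W ≥ w) and P(W ≤ w) over all 2^n sign assignments.

    Average ranks on ties are half-integers, so ranks are doubled to
    integers and the distribution of 2W is built by polynomial
    convolution — equivalent to enumerating every sign assignment.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    poly /= poly.sum()
    w2 = int(np.rint(2.0 * w_pos))
    return float(poly[w2:].sum()), float(poly[: w2 + 1].sum())


@dataclass
class EvaluationReport:
    """Paired raw-vs-reduced MCC comparison across tasks."""

    per_task: list[tuple[str, float, float, str]]
    n_improved: int
    n_worse: int
    n_nc: int
    wilcoxon_statistic: float | None
    wilcoxon_p: float | None
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_task": [
                {"task_id": t, "mcc_raw": raw, "mcc_reduced": red, "sign": sign}
                for t, raw, red, sign in self.per_task
            ],
            "n_improved": self.n_improved,
            "n_worse": self.n_worse,
            "n_nc": self.n_nc,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_p": self.wilcoxon_p,
            "seed": self.seed,
            "parameters": self.parameters,
            "tool_version": _tool_version,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=1)

    def sign_table(self) -> str:
        """TSV grid of per-task signs, the +/−/nc summary view."""
        lines = ["task_id\tmcc_raw\tmcc_reduced\tsign"]
        for t, raw, red, sign in self.per_task:
            lines.append(f"{t}\t{raw:.6f}\t{red:.6f}\t{sign}")
        return "\n".join(lines) + "\n"


def compare_representations(
    tasks: Sequence[LabeledDataset],
    reduced_subsets: Mapping[str, Sequence[int]],
    learner: Learner | None = None,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    nc_tolerance: float = DEFAULT_NC_TOLERANCE,
) -> EvaluationReport:
    """Score every task with the full and the reduced bit set and compare.

    A task counts as improved (+) when MCC_reduced − MCC_raw exceeds
    ``nc_tolerance``, worse (−) below −nc_tolerance, and no-change (nc)
    inside the band. The Wilcoxon signed-rank test (one-sided,
    reduced ≥ raw) runs on the non-nc paired differences; with no such
    differences the test is skipped and reported as null.
    """
    if learner is None:
        learner = RandomForestLearner(random_state=seed)
    per_task: list[tuple[str, float, float, str]] = []
    diffs: list[float] = []
    for task in tasks:
        if task.task_id not in reduced_subsets:
            raise KeyError(f"no reduced subset for task {task.task_id!r}")
        mcc_raw = cross_validated_mcc(task, None, learner, folds=folds, seed=seed)
        mcc_red = cross_validated_mcc(
            task, reduced_subsets[task.task_id], learner, folds=folds, seed=seed
        )
        delta = mcc_red - mcc_raw
        if delta > nc_tolerance:
            sign = "+"
        elif delta < -nc_tolerance:
            sign = "-"
        else:
            sign = "nc"
        if sign != "nc":
            diffs.append(delta)
        per_task.append((task.task_id, mcc_raw, mcc_red, sign))

    n_improved = sum(1 for row in per_task if row[3] == "+")
    n_worse = sum(1 for row in per_task if row[3] == "-")
    n_nc = sum(1 for row in per_task if row[3] == "nc")
    if diffs and any(d != 0 for d in diffs):
        statistic, p = wilcoxon_signed_rank(diffs, alternative="greater")
    else:
        statistic, p = None, None
    return EvaluationReport(
        per_task=per_task,
        n_improved=n_improved,
        n_worse=n_worse,
        n_nc=n_nc,
        wilcoxon_statistic=statistic,
        wilcoxon_p=p,
        seed=seed,
        parameters={
            "folds": folds,
            "nc_tolerance": nc_tolerance,
            "learner": type(learner).__name__,
            "alternative": "greater",
            "cv": "stratified k-fold, pooled out-of-fold predictions",
        },
    )
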