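"""Normalized mutual-information scoring of bit groups and greedy selection.

The score of a bit group ``X = {X_1, ..., X_N}`` against a binary activity
label ``Y`` is the mutual information between the group's joint bit
pattern and the label, normalized by the Shannon entropy of the label::

    AIC_Y(X) = I(X; Y) / H(Y)
             = sum_{x,y} P(x, y) log2[ P(x, y) / (P(x) P(y)) ]
               / ( -sum_y P(y) log2 P(y) )

where ``x`` ranges over the observed patterns in {0,1}^N. All
probabilities are maximum-likelihood relative frequencies over the
compounds of a dataset; the score lies in [0, 1], equals 1 when the
observed patterns determine the label exactly, and 0 when the group is
empirically independent of the label.

``greedy_select`` runs forward selection: starting from the empty set it
repeatedly adds the bit whose inclusion maximizes the (multi-task
averaged) score, with deterministic tie-breaking, producing an ordered
reduced representation. For several tasks the group score is the
unweighted mean of per-task scores ("average information content"),
which yields one joint reduced representation for several targets.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__ as _tool_version
from .errors import DegenerateTaskError
from .fingerprints import FingerprintMatrix, LabeledDataset

DEFAULT_K = 100
"""Default number of bits selected per task (size of the reduced
representation found adequate for serotonin-receptor ligand sets)."""

_SATURATION_TOL = 1e-9
_SCORE_TIE_TOL = 1e-12


def label_entropy(labels: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy of a binary label vector, in bits.

    ``H(Y) = -sum_y P(y) log2 P(y)`` with the convention 0·log2 0 = 0;
    0 for single-class labels, 1 for balanced ones.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    p1 = float(np.mean(labels))
    out = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0.0:
            out -= p * np.log2(p)
    return float(out)


@dataclass
class PatternDistribution:
    """Empirical joint distribution of a bit-subset's patterns and the label.

    ``pattern_probs`` maps each observed pattern (a 0/1 tuple ordered as
    ``subset``) to P(x); ``joint_probs`` maps (pattern, y) to P(x, y);
    ``label_probs`` maps y to P(y). Patterns never observed do not appear.
    """

    subset: tuple[int, ...]
    pattern_probs: dict[tuple[int, ...], float]
    joint_probs: dict[tuple[tuple[int, ...], int], float]
    label_probs: dict[int, float]
    n_samples: int

    def mutual_information(self) -> float:
        """I(X; Y) in bits over the observed support."""
        mi = 0.0
        for (pattern, y), pxy in self.joint_probs.items():
            if pxy > 0.0:
                mi += pxy * np.log2(pxy / (self.pattern_probs[pattern] * self.label_probs[y]))
        return float(mi)

    def validate(self, atol: float = 1e-12) -> None:
        """Check normalization and marginal consistency."""
        assert abs(sum(self.pattern_probs.values()) - 1.0) < atol
        assert abs(sum(self.label_probs.values()) - 1.0) < atol
        assert abs(sum(self.joint_probs.values()) - 1.0) < atol
        for pattern, px in self.pattern_probs.items():
            marg = sum(self.joint_probs.get((pattern, y), 0.0) for y in (0, 1))
            assert abs(marg - px) < atol
        for y, py in self.label_probs.items():
            marg = sum(p for (_, yy), p in self.joint_probs.items() if yy == y)
            assert abs(marg - py) < atol


def empirical_joint(
    matrix: FingerprintMatrix,
    subset: Sequence[int],
    labels: Sequence[int] | np.ndarray,
) -> PatternDistribution:
    """Maximum-likelihood joint distribution of subset patterns and labels."""
    subset = tuple(int(b) for b in subset)
    if not subset:
        raise ValueError("bit subset must be non-empty")
    labels = np.asarray(labels).astype(int)
    sub = matrix.columns(subset)
    n = sub.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with matrix rows")
    pattern_counts: dict[tuple[int, ...], int] = {}
    joint_counts: dict[tuple[tuple[int, ...], int], int] = {}
    for i in range(n):
        pattern = tuple(int(v) for v in sub[i])
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
        key = (pattern, int(labels[i]))
        joint_counts[key] = joint_counts.get(key, 0) + 1
    label_probs = {
        y: float(np.mean(labels == y)) for y in (0, 1) if np.any(labels == y)
    }
    return PatternDistribution(
        subset=subset,
        pattern_probs={p: c / n for p, c in pattern_counts.items()},
        joint_probs={k: c / n for k, c in joint_counts.items()},
        label_probs=label_probs,
        n_samples=n,
    )


def _pattern_codes(sub: np.ndarray) -> np.ndarray:
    """Compact integer codes (0..P-1) for the rows of a 0/1 submatrix."""
    if sub.shape[1] == 0:
        return np.zeros(sub.shape[0], dtype=np.int64)
    _, codes = np.unique(sub, axis=0, return_inverse=True)
    return codes.astype(np.int64)


def _nmi_from_codes(codes: np.ndarray, labels: np.ndarray, h_y: float) -> float:
    """Normalized MI between integer pattern codes and 0/1 labels."""
    n = codes.size
    n_patterns = int(codes.max()) + 1
    counts = np.bincount(codes * 2 + labels, minlength=2 * n_patterns).reshape(
        n_patterns, 2
    )
    pxy = counts / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pxy / (px[:, None] * py[None, :])
        terms = np.where(mask, pxy * np.log2(np.where(mask, ratio, 1.0)), 0.0)
    score = float(terms.sum()) / h_y
    if score < 0.0:
        if score < -1e-9:
            raise AssertionError(f"mutual information went negative: {score}")
        score = 0.0
    return min(score, 1.0)


def _require_nondegenerate(labels: np.ndarray, task_id: str = "") -> float:
    h = label_entropy(labels)
    if h == 0.0:
        raise DegenerateTaskError(
            f"task {task_id!r} has a single label class; the normalized score "
            "would divide by zero entropy"
        )
    return h


def aic_score(
    matrix: FingerprintMatrix,
    subset: Sequence[int],
    labels: Sequence[int] | np.ndarray,
) -> float:
    """Normalized mutual information of one bit group with the label.

    Returns ``I(X_subset; Y) / H(Y)`` in [0, 1], with base-2 logs and
    maximum-likelihood probabilities. Single-class labels raise
    :class:`DegenerateTaskError`.
    """
    labels = np.asarray(labels).astype(np.int64)
    h_y = _require_nondegenerate(labels)
    subset = [int(b) for b in subset]
    if not subset:
        raise ValueError("bit subset must be non-empty")
    codes = _pattern_codes(matrix.columns(subset))
    return _nmi_from_codes(codes, labels, h_y)


def aic_score_multi(
    tasks: Sequence[LabeledDataset],
    subset: Sequence[int],
) -> float:
    """Unweighted mean of per-task scores of one bit group.

    Every task must contain every bit of the subset and have both label
    classes present.
    """
    tasks = list(tasks)
    if not tasks:
        raise ValueError("at least one task required")
    return float(
        np.mean([aic_score(t.matrix, subset, t.labels) for t in tasks])
    )


def brute_force_aic(
    matrix: FingerprintMatrix,
    subset: Sequence[int],
    labels: Sequence[int] | np.ndarray,
) -> float:
    """Independent oracle: the same normalized MI by explicit enumeration.

    Walks all 2^N patterns of the subset (N ≤ 16), counts matching rows
    per pattern and label by direct comparison, and sums the definition
    term by term. Zero-probability patterns contribute nothing.
    """
    subset = [int(b) for b in subset]
    if len(subset) > 16:
        raise ValueError("brute-force enumeration is limited to 16 bits")
    labels = np.asarray(labels).astype(int)
    h_y = _require_nondegenerate(labels)
    sub = matrix.columns(subset)
    n = sub.shape[0]
    p_y = {y: float(np.mean(labels == y)) for y in (0, 1)}
    mi = 0.0
    for pattern in itertools.product((0, 1), repeat=len(subset)):
        match = np.all(sub == np.array(pattern, dtype=sub.dtype), axis=1)
        p_x = float(match.sum()) / n
        if p_x == 0.0:
            continue
        for y in (0, 1):
            p_xy = float(np.sum(match & (labels == y))) / n
            if p_xy > 0.0:
                mi += p_xy * np.log2(p_xy / (p_x * p_y[y]))
    return mi / h_y


def rank_bits_individual(dataset: LabeledDataset) -> list[tuple[int, float]]:
    """Score every bit on its own; descending score, ties by ascending id."""
    dataset.require_both_classes()
    scores = _singleton_scores([dataset])
    order = sorted(
        range(len(dataset.matrix.bit_ids)),
        key=lambda j: (-scores[j], dataset.matrix.bit_ids[j]),
    )
    return [(dataset.matrix.bit_ids[j], float(scores[j])) for j in order]


@dataclass
class SelectionResult:
    """Outcome of one greedy selection run."""

    task_ids: list[str]
    selected: list[int]
    trajectory: list[float]
    saturated_at: int | None = None
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task_ids": self.task_ids,
            "selected": self.selected,
            "trajectory": self.trajectory,
            "saturated_at": self.saturated_at,
            "parameters": self.parameters,
            "tool_version": _tool_version,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "SelectionResult":
        return cls(
            task_ids=list(payload["task_ids"]),
            selected=[int(b) for b in payload["selected"]],
            trajectory=[float(v) for v in payload["trajectory"]],
            saturated_at=payload.get("saturated_at"),
            parameters=dict(payload.get("parameters", {})),
        )


def _as_task_list(tasks) -> list[LabeledDataset]:
    if isinstance(tasks, LabeledDataset):
        return [tasks]
    return list(tasks)


def _aligned_arrays(tasks: list[LabeledDataset]) -> tuple[list[int], list[np.ndarray]]:
    """Common bit-id order and per-task column-aligned matrices."""
    bit_ids = list(tasks[0].matrix.bit_ids)
    universe = set(bit_ids)
    for task in tasks[1:]:
        if set(task.matrix.bit_ids) != universe:
            raise KeyError(
                f"task {task.task_id!r} does not share the bit universe of the first task"
            )
    mats = [np.ascontiguousarray(t.matrix.columns(bit_ids)) for t in tasks]
    return bit_ids, mats


def _singleton_scores(tasks: list[LabeledDataset]) -> np.ndarray:
    """Mean singleton score of every bit across tasks (vectorized)."""
    bit_ids, mats = _aligned_arrays(tasks)
    total = np.zeros(len(bit_ids))
    for task, X in zip(tasks, mats):
        y = task.labels.astype(np.int64)
        h_y = _require_nondegenerate(y, task.task_id)
        pid = np.zeros(y.size, dtype=np.int64)
        total += _candidate_scores(X, y, pid, h_y, np.arange(X.shape[1]))
    return total / len(tasks)


def _candidate_scores(
    X: np.ndarray,
    y: np.ndarray,
    pid: np.ndarray,
    h_y: float,
    cand: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Score pid ∪ {candidate column} for every candidate, vectorized.

    ``pid`` holds compact pattern codes of the already-selected bits; the
    candidate's column refines each code by one binary digit. Cost is
    O(n_samples) per candidate and never O(2^N).
    """
    n = y.size
    n_pat = int(pid.max()) + 1 if n else 1
    p_y = np.bincount(y, minlength=2) / n
    scores = np.empty(cand.size)
    cells_per_cand = 4 * n_pat
    for start in range(0, cand.size, chunk):
        idx = cand[start : start + chunk]
        b = idx.size
        codes = pid[:, None] * 2 + X[:, idx].astype(np.int64)  # (n, b)
        flat = np.arange(b, dtype=np.int64)[None, :] * cells_per_cand + codes * 2 + y[:, None]
        counts = np.bincount(flat.ravel(), minlength=b * cells_per_cand).reshape(
            b, 2 * n_pat, 2
        )
        pxy = counts / n
        px = pxy.sum(axis=2)
        mask = counts > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = pxy / (px[:, :, None] * p_y[None, None, :])
            terms = np.where(mask, pxy * np.log2(np.where(mask, ratio, 1.0)), 0.0)
        scores[start : start + b] = terms.sum(axis=(1, 2)) / h_y
    return np.clip(scores, 0.0, 1.0)


def greedy_select(
    tasks: LabeledDataset | Sequence[LabeledDataset],
    k: int = DEFAULT_K,
) -> SelectionResult:
    """Forward greedy selection of the k jointly most informative bits.

    Starting from the empty set, each step adds the candidate bit that
    maximizes the (task-averaged) group score of the enlarged set. Ties
    are broken first by higher individual (singleton) score, then by
    lower bit id, which makes the run fully deterministic — important
    because once the observed patterns separate the classes the score
    saturates at 1.0 and every candidate ties. The trajectory records
    the score after each addition and is non-decreasing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tasks = _as_task_list(tasks)
    if not tasks:
        raise ValueError("at least one task required")
    for task in tasks:
        task.require_both_classes()
    bit_ids, mats = _aligned_arrays(tasks)
    n_bits = len(bit_ids)
    labels = [t.labels.astype(np.int64) for t in tasks]
    entropies = [_require_nondegenerate(y, t.task_id) for y, t in zip(labels, tasks)]
    singleton = _singleton_scores(tasks)

    pids = [np.zeros(y.size, dtype=np.int64) for y in labels]
    remaining = np.ones(n_bits, dtype=bool)
    selected: list[int] = []
    trajectory: list[float] = []
    saturated_at: int | None = None

    n_steps = min(k, n_bits)
    for _ in range(n_steps):
        cand = np.flatnonzero(remaining)
        mean_scores = np.zeros(cand.size)
        for X, y, pid, h_y in zip(mats, labels, pids, entropies):
            mean_scores += _candidate_scores(X, y, pid, h_y, cand)
        mean_scores /= len(tasks)
        best = float(mean_scores.max())
        tied = cand[mean_scores >= best - _SCORE_TIE_TOL]
        # higher singleton score first, then lower bit id
        pick = min(tied, key=lambda j: (-singleton[j], bit_ids[j]))
        remaining[pick] = False
        selected.append(bit_ids[pick])
        score = best
        if trajectory:
            score = max(score, trajectory[-1])
        trajectory.append(min(score, 1.0))
        if saturated_at is None and trajectory[-1] >= 1.0 - _SATURATION_TOL:
            saturated_at = len(selected) - 1
        for t_idx, (X, pid) in enumerate(zip(mats, pids)):
            refined = pid * 2 + X[:, pick].astype(np.int64)
            _, pids[t_idx] = np.unique(refined, return_inverse=True)
            pids[t_idx] = pids[t_idx].astype(np.int64)

    return SelectionResult(
        task_ids=[t.task_id for t in tasks],
        selected=selected,
        trajectory=trajectory,
        saturated_at=saturated_at,
        parameters={"k": int(k), "n_bits": n_bits, "n_tasks": len(tasks)},
    )
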