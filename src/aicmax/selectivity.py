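"""Pairwise ligand-selectivity tasks and all-pairs bit selection.

Selectivity bits are the bits that best separate the *actives* of one
target from the *actives* of another — compounds inactive at either
target play no role. For T targets the greedy selector runs once per
unordered target pair (C(T, 2) runs; 66 for the twelve serotonin
receptors), and per-target summaries aggregate the runs:

* ``union_bits(t)``  — every bit selected in at least one pair involving t;
* ``core_bits(t)``   — the bits selected in *every* pair involving t,
  i.e. features that discriminate t's ligands from each of the other
  targets' ligands.

Compounds active at both targets of a pair have no well-defined
selectivity label and are excluded from that pair's task (their count is
recorded as ``excluded_overlap``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _tool_version
from .aic_core import DEFAULT_K, SelectionResult, greedy_select
from .errors import DegenerateTaskError
from .fingerprints import FingerprintMatrix, LabeledDataset

logger = logging.getLogger(__name__)


@dataclass
class PairTask:
    """An A-vs-B actives discrimination task.

    Label 1 marks actives of ``target_a``, label 0 actives of
    ``target_b``; dual-active compounds are excluded and counted.
    """

    target_a: str
    target_b: str
    dataset: LabeledDataset
    excluded_overlap: int


def build_pair_task(
    actives_by_target: Mapping[str, set[str]],
    matrix: FingerprintMatrix,
    a: str,
    b: str,
) -> PairTask:
    """Assemble the selectivity task for one unordered target pair."""
    if a == b:
        raise ValueError(f"pair targets must differ, got {a!r} twice")
    for t in (a, b):
        if t not in actives_by_target:
            raise KeyError(f"target {t!r} absent from actives map")
    actives_a = set(actives_by_target[a])
    actives_b = set(actives_by_target[b])
    overlap = actives_a & actives_b
    only_a = sorted(actives_a - overlap)
    only_b = sorted(actives_b - overlap)
    if len(only_a) < 2 or len(only_b) < 2:
        raise DegenerateTaskError(
            f"pair ({a}, {b}): fewer than 2 selective actives on one side "
            f"after excluding {len(overlap)} dual-active compounds"
        )
    compounds = only_a + only_b
    labels = np.array([1] * len(only_a) + [0] * len(only_b), dtype=np.int8)
    dataset = LabeledDataset(
        matrix.select_compounds(compounds), labels, task_id=f"{a}_vs_{b}"
    )
    return PairTask(a, b, dataset, excluded_overlap=len(overlap))


@dataclass
class PairwiseSelectionResult:
    """Greedy selections for every unordered target pair."""

    pair_results: dict[tuple[str, str], SelectionResult]
    skipped: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    k: int = DEFAULT_K

    @property
    def targets(self) -> list[str]:
        seen = set()
        for a, b in self.pair_results:
            seen.update((a, b))
        for (a, b), _ in self.skipped:
            seen.update((a, b))
        return sorted(seen)

    def pairs_for(self, target: str) -> list[tuple[str, str]]:
        if target not in self.targets:
            raise KeyError(f"target {target!r} absent from pairwise results")
        return [p for p in self.pair_results if target in p]


def select_all_pairs(
    actives_by_target: Mapping[str, set[str]],
    matrix: FingerprintMatrix,
    k: int = DEFAULT_K,
) -> PairwiseSelectionResult:
    """Run greedy selection on every unordered target pair exactly once.

    Degenerate pairs (one side left with fewer than two compounds) are
    recorded as skipped rather than aborting the sweep.
    """
    targets = sorted(actives_by_target)
    if len(targets) < 2:
        raise ValueError("at least two targets are required for a pairwise sweep")
    results: dict[tuple[str, str], SelectionResult] = {}
    skipped: list[tuple[tuple[str, str], str]] = []
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            try:
                task = build_pair_task(actives_by_target, matrix, a, b)
            except DegenerateTaskError as exc:
                logger.warning("skipping pair (%s, %s): %s", a, b, exc)
                skipped.append(((a, b), str(exc)))
                continue
            results[(a, b)] = greedy_select(task.dataset, k=k)
    return PairwiseSelectionResult(pair_results=results, skipped=skipped, k=k)


def union_bits(results: PairwiseSelectionResult, target: str) -> set[int]:
    """Bits selected in at least one pair involving the target."""
    pairs = results.pairs_for(target)
    out: set[int] = set()
    for pair in pairs:
        out.update(results.pair_results[pair].selected)
    return out


def core_bits(results: PairwiseSelectionResult, target: str) -> set[int]:
    """Bits selected in every (non-skipped) pair involving the target."""
    pairs = results.pairs_for(target)
    if not pairs:
        return set()
    out = set(results.pair_results[pairs[0]].selected)
    for pair in pairs[1:]:
        out &= set(results.pair_results[pair].selected)
    return out


def occurrence_matrix(
    results: PairwiseSelectionResult, target: str | None = None
) -> pd.DataFrame:
    """0/1 table of selected bits (rows) per pair (columns).

    With ``target`` given, columns are restricted to pairs involving it —
    the per-off-target view of the selection sweep.
    """
    pairs = (
        results.pairs_for(target) if target is not None else sorted(results.pair_results)
    )
    bits = sorted({b for p in pairs for b in results.pair_results[p].selected})
    table = pd.DataFrame(0, index=bits, columns=[f"{a}|{b}" for a, b in pairs], dtype=int)
    for a, b in pairs:
        for bit in results.pair_results[(a, b)].selected:
            table.loc[bit, f"{a}|{b}"] = 1
    table.index.name = "bit_id"
    return table


def write_pairwise_results(results: PairwiseSelectionResult, outdir: str | Path) -> None:
    """One JSON per pair plus a manifest, and the occurrence matrix as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "k": results.k,
        "targets": results.targets,
        "pairs": [],
        "skipped": [
            {"pair": list(pair), "reason": reason} for pair, reason in results.skipped
        ],
        "tool_version": _tool_version,
    }
    for (a, b), result in sorted(results.pair_results.items()):
        fname = f"pair_{a}_vs_{b}.json"
        result.to_json(outdir / fname)
        manifest["pairs"].append({"pair": [a, b], "file": fname})
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1)
    occurrence_matrix(results).to_csv(outdir / "occurrence_matrix.tsv", sep="\t")


def read_pairwise_results(outdir: str | Path) -> PairwiseSelectionResult:
    """Load a results directory written by :func:`write_pairwise_results`."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as handle:
        manifest = json.load(handle)
    pair_results = {}
    for entry in manifest["pairs"]:
        a, b = entry["pair"]
        with open(outdir / entry["file"]) as handle:
            pair_results[(a, b)] = SelectionResult.from_dict(json.load(handle))
    skipped = [((s["pair"][0], s["pair"][1]), s["reason"]) for s in manifest["skipped"]]
    return PairwiseSelectionResult(pair_results=pair_results, skipped=skipped, k=manifest["k"])
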