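"""Binary fingerprint matrices, structure-key computation and activity labels.

The central container is :class:`FingerprintMatrix` — a compounds × bits
0/1 occurrence matrix with stable compound identifiers (opaque strings)
and bit identifiers (non-negative integers, following the substructure-key
index convention of the source dictionary when fingerprints are computed
from structures).

Potency tables (Ki or an equivalent affinity measure in nM) are turned
into binary activity labels by thresholding: a compound is *active* when
its potency is at or below ``active_max_nM`` (default 100 nM), *inactive*
when strictly above ``inactive_min_nM`` (default 1000 nM), and *discarded*
in the intermediate grey zone. Replicate measurements for the same
compound–target pair are collapsed to their median before thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTaskError, InputFormatError

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"
DISCARDED = "discarded"

DEFAULT_ACTIVE_MAX_NM = 100.0
DEFAULT_INACTIVE_MIN_NM = 1000.0


@dataclass
class FingerprintMatrix:
    """Compounds × bits binary occurrence matrix.

    Parameters
    ----------
    compound_ids
        Unique opaque compound identifiers, one per row.
    bit_ids
        Unique non-negative integer bit identifiers, one per column.
    values
        0/1 matrix of shape ``(len(compound_ids), len(bit_ids))``.
    """

    compound_ids: list[str]
    bit_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.bit_ids = [int(b) for b in self.bit_ids]
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InputFormatError("fingerprint values must be a 2-D matrix")
        if not np.isin(values, (0, 1)).all():
            raise InputFormatError("fingerprint matrix entries must be 0 or 1")
        self.values = values.astype(np.uint8)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise InputFormatError("duplicate compound ids in fingerprint matrix")
        if len(set(self.bit_ids)) != len(self.bit_ids):
            raise InputFormatError("duplicate bit ids in fingerprint matrix")
        if any(b < 0 for b in self.bit_ids):
            raise InputFormatError("bit ids must be non-negative")
        n, m = self.values.shape
        if n != len(self.compound_ids) or m != len(self.bit_ids):
            raise InputFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.bit_ids)} bits"
            )
        self._bit_index = {b: j for j, b in enumerate(self.bit_ids)}
        self._row_index = {c: i for i, c in enumerate(self.compound_ids)}

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_bits(self) -> int:
        return self.values.shape[1]

    def bit_column(self, bit_id: int) -> np.ndarray:
        """Return the 0/1 column for one bit id."""
        return self.columns([bit_id])[:, 0]

    def columns(self, bit_ids: Sequence[int]) -> np.ndarray:
        """Return the submatrix of the given bit ids, in the given order."""
        try:
            idx = [self._bit_index[int(b)] for b in bit_ids]
        except KeyError as exc:
            raise KeyError(f"bit id {exc.args[0]} not present in matrix") from None
        return self.values[:, idx]

    def select_compounds(self, compound_ids: Sequence[str]) -> "FingerprintMatrix":
        """Row-restrict to the given compounds, preserving the given order."""
        try:
            idx = [self._row_index[str(c)] for c in compound_ids]
        except KeyError as exc:
            raise KeyError(f"compound id {exc.args[0]!r} not present in matrix") from None
        return FingerprintMatrix(
            compound_ids=[str(c) for c in compound_ids],
            bit_ids=list(self.bit_ids),
            values=self.values[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view: compound ids as index, bit ids as columns."""
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.bit_ids, copy=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FingerprintMatrix":
        return cls(
            compound_ids=[str(c) for c in frame.index],
            bit_ids=[int(b) for b in frame.columns],
            values=frame.to_numpy(),
        )


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement: compound, target and Ki (or equivalent) in nM."""

    compound_id: str
    target_id: str
    potency_nM: float

    def __post_init__(self) -> None:
        if not self.potency_nM > 0:
            raise InputFormatError(
                f"potency must be positive, got {self.potency_nM!r} for "
                f"({self.compound_id!r}, {self.target_id!r})"
            )


@dataclass
class LabeledDataset:
    """A fingerprint matrix paired with binary labels for one task."""

    matrix: FingerprintMatrix
    labels: np.ndarray
    task_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.isin(labels, (0, 1)).all():
            raise InputFormatError("labels must be 0/1")
        self.labels = labels.astype(np.int8)
        if self.labels.shape != (self.matrix.n_compounds,):
            raise InputFormatError(
                f"label vector length {self.labels.shape} does not match "
                f"{self.matrix.n_compounds} compounds"
            )

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise DegenerateTaskError(
                f"task {self.task_id!r} has a single label class"
            )


# ---------------------------------------------------------------------------
# matrix I/O

_SEPS = {"csv": ",", "tsv": "\t"}


def read_bit_matrix(path: str | Path, format: str = "csv") -> FingerprintMatrix:
    """Read a compounds × bits 0/1 matrix from CSV or TSV.

    The header row carries integer bit ids; the first column carries
    compound ids. Any cell that is not exactly 0 or 1 is a hard error
    naming the offending row and column.
    """
    if format not in _SEPS:
        raise ValueError(f"format must be one of {sorted(_SEPS)}, got {format!r}")
    frame = pd.read_csv(path, sep=_SEPS[format], index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise InputFormatError(f"duplicate compound id {dup!r} in {path}")
    try:
        bit_ids = [int(c) for c in frame.columns]
    except ValueError as exc:
        raise InputFormatError(f"non-integer bit id in header of {path}: {exc}") from None
    values = np.empty(frame.shape, dtype=np.uint8)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in ("0", "1"):
                raise InputFormatError(
                    f"non-binary cell {cell!r} at compound {frame.index[i]!r}, "
                    f"bit {frame.columns[j]} in {path}"
                )
            values[i, j] = int(cell)
    return FingerprintMatrix(list(frame.index), bit_ids, values)


def write_bit_matrix(matrix: FingerprintMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a matrix in the layout :func:`read_bit_matrix` expects."""
    if format not in _SEPS:
        raise ValueError(f"format must be one of {sorted(_SEPS)}, got {format!r}")
    matrix.to_frame().to_csv(path, sep=_SEPS[format], index_label="compound_id")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column CSV ``compound_id,label`` with 0/1 labels."""
    frame = pd.read_csv(path, dtype={"compound_id": str})
    for col in ("compound_id", "label"):
        if col not in frame.columns:
            raise InputFormatError(f"labels file {path} lacks column {col!r}")
    labels = {}
    for _, row in frame.iterrows():
        lab = int(row["label"])
        if lab not in (0, 1):
            raise InputFormatError(
                f"label for compound {row['compound_id']!r} is {row['label']!r}, not 0/1"
            )
        labels[str(row["compound_id"])] = lab
    return labels


def read_activity_table(path: str | Path) -> list[ActivityRecord]:
    """Read a CSV with columns compound_id, target_id, potency_nM."""
    frame = pd.read_csv(path, dtype={"compound_id": str, "target_id": str})
    for col in ("compound_id", "target_id", "potency_nM"):
        if col not in frame.columns:
            raise InputFormatError(f"activity table {path} lacks column {col!r}")
    return [
        ActivityRecord(str(r.compound_id), str(r.target_id), float(r.potency_nM))
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# activity thresholding


def split_activity(
    records: Iterable[ActivityRecord],
    target: str,
    active_max_nM: float = DEFAULT_ACTIVE_MAX_NM,
    inactive_min_nM: float = DEFAULT_INACTIVE_MIN_NM,
) -> dict[str, str]:
    """Assign active / inactive / discarded status per compound for a target.

    Potency at or below ``active_max_nM`` → active; strictly above
    ``inactive_min_nM`` → inactive; in between → discarded. Replicate
    measurements for the same compound are aggregated by their median
    first, so the outcome does not depend on record order.
    """
    if not active_max_nM < inactive_min_nM:
        raise ValueError(
            f"active_max_nM ({active_max_nM}) must be below "
            f"inactive_min_nM ({inactive_min_nM})"
        )
    by_compound: dict[str, list[float]] = {}
    known_targets = set()
    for rec in records:
        known_targets.add(rec.target_id)
        if rec.target_id == target:
            by_compound.setdefault(rec.compound_id, []).append(rec.potency_nM)
    if target not in known_targets:
        raise KeyError(f"target {target!r} absent from activity records")
    out: dict[str, str] = {}
    for compound, potencies in by_compound.items():
        potency = float(np.median(potencies))
        if potency <= active_max_nM:
            out[compound] = ACTIVE
        elif potency > inactive_min_nM:
            out[compound] = INACTIVE
        else:
            out[compound] = DISCARDED
    return out


def actives_by_target(
    records: Iterable[ActivityRecord],
    active_max_nM: float = DEFAULT_ACTIVE_MAX_NM,
    inactive_min_nM: float = DEFAULT_INACTIVE_MIN_NM,
) -> dict[str, set[str]]:
    """Map each target id to its set of active compound ids."""
    records = list(records)
    targets = sorted({r.target_id for r in records})
    out = {}
    for t in targets:
        split = split_activity(records, t, active_max_nM, inactive_min_nM)
        out[t] = {c for c, s in split.items() if s == ACTIVE}
    return out


def labeled_dataset_from_split(
    matrix: FingerprintMatrix,
    split: Mapping[str, str],
    task_id: str,
) -> LabeledDataset:
    """Build a classification task from an activity split.

    Active compounds get label 1, inactive 0; discarded compounds and
    compounds without fingerprints are dropped. Row order follows the
    matrix.
    """
    ids, labels = [], []
    for compound in matrix.compound_ids:
        status = split.get(compound)
        if status == ACTIVE:
            ids.append(compound)
            labels.append(1)
        elif status == INACTIVE:
            ids.append(compound)
            labels.append(0)
    missing = [c for c in split if c not in matrix._row_index]
    if missing:
        logger.warning(
            "%d compounds with activity for %s have no fingerprint row", len(missing), task_id
        )
    return LabeledDataset(matrix.select_compounds(ids), np.array(labels), task_id=task_id)


# ---------------------------------------------------------------------------
# substructure-key fingerprints


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, optional id column.

    Returns (compound_id, smiles) pairs; lines without an explicit id get
    a positional id ``mol<k>``.
    """
    out = []
    with open(path) as handle:
        for k, line in enumerate(handle):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{k}"
            out.append((cid, smiles))
    return out


def compute_krfp(
    structures: Sequence[tuple[str, object]],
    keys: Sequence[tuple[int, str]],
) -> FingerprintMatrix:
    """Compute a substructure-key fingerprint matrix.

    Parameters
    ----------
    structures
        (compound_id, molecule) pairs where molecule is a SMILES string
        or an RDKit Mol. Molecules that fail to parse are logged and
        dropped (never silently skipped).
    keys
        Ordered (bit index, SMARTS) pairs; bit ids in the output follow
        this order. An unparsable SMARTS is a hard error naming the key.

    Entry (i, j) is 1 iff key j matches molecule i as a substructure.
    Substructure semantics (aromaticity model in particular) follow
    RDKit, which may differ bit-for-bit from other toolkits.
    """
    from rdkit import Chem

    keys = list(keys)
    if not keys:
        raise ValueError("empty substructure key dictionary")
    queries = []
    for bit_id, smarts in keys:
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise InputFormatError(f"unparsable SMARTS for key {bit_id}: {smarts!r}")
        queries.append((int(bit_id), query))

    mols: list[tuple[str, object]] = []
    for cid, mol in structures:
        if isinstance(mol, str):
            parsed = Chem.MolFromSmiles(mol)
            if parsed is None:
                logger.warning("dropping compound %r: SMILES failed to parse (%r)", cid, mol)
                continue
            mols.append((cid, parsed))
        elif mol is None:
            logger.warning("dropping compound %r: molecule failed to parse", cid)
        else:
            mols.append((cid, mol))

    values = np.zeros((len(mols), len(queries)), dtype=np.uint8)
    for i, (_, mol) in enumerate(mols):
        for j, (_, query) in enumerate(queries):
            if mol.HasSubstructMatch(query):
                values[i, j] = 1
    return FingerprintMatrix(
        compound_ids=[cid for cid, _ in mols],
        bit_ids=[bit_id for bit_id, _ in queries],
        values=values,
    )
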