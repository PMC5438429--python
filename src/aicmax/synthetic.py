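"""Synthetic fingerprint datasets with known ground truth.

The generator emulates the statistical structure the normalized
mutual-information score reacts to, without any chemistry: binary bit
columns whose occurrence probability differs between actives and
inactives (planted signal), bit *pairs* that determine the label only
jointly (XOR structure — each bit alone is uninformative), exact
duplicate columns (redundancy), and label-independent noise columns.

Labels are fixed first (exact class sizes), then bits are drawn
conditionally on the class, so every planted bit's population-level
normalized mutual information is available in closed form and recorded
in the manifest. XOR pairs are constructed so that the parity of the
two bits equals the label on every row while each bit is marginally
uniform, giving singleton information 0 and pair information 1.

One global integer seed drives a hierarchical stream keyed by (seed,
target, role, bit id), so adding bits or targets never perturbs
existing columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _tool_version
from .aic_core import label_entropy
from .fingerprints import FingerprintMatrix, LabeledDataset

_ROLE_PLANTED, _ROLE_XOR, _ROLE_NOISE = 1, 2, 3


def closed_form_singleton_aic(
    p_active: float, p_inactive: float, positive_fraction: float
) -> float:
    """Population normalized MI of one conditionally-Bernoulli bit.

    The bit is 1 with probability ``p_active`` given label 1 and
    ``p_inactive`` given label 0; ``positive_fraction`` is P(y=1).
    """
    q = positive_fraction
    joint = {
        (1, 1): q * p_active,
        (0, 1): q * (1.0 - p_active),
        (1, 0): (1.0 - q) * p_inactive,
        (0, 0): (1.0 - q) * (1.0 - p_inactive),
    }
    px = {x: joint[(x, 1)] + joint[(x, 0)] for x in (0, 1)}
    py = {1: q, 0: 1.0 - q}
    h_y = -sum(p * np.log2(p) for p in py.values() if p > 0)
    if h_y == 0.0:
        raise ValueError("positive_fraction must be strictly between 0 and 1")
    mi = sum(
        p * np.log2(p / (px[x] * py[y]))
        for (x, y), p in joint.items()
        if p > 0
    )
    return float(mi / h_y)


@dataclass(frozen=True)
class PlantedBit:
    """A bit with class-conditional occurrence probabilities."""

    bit_id: int
    p_active: float
    p_inactive: float

    def __post_init__(self) -> None:
        for p in (self.p_active, self.p_inactive):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occurrence probability {p} outside [0, 1]")


@dataclass
class SyntheticSpec:
    """Recipe for one or several synthetic classification tasks.

    Defaults describe a mid-sized receptor-ligand task: a few hundred
    compounds per class, a handful of moderately informative planted
    bits, and a background of sparse noise bits.
    """

    n_active: int = 300
    n_inactive: int = 300
    planted_bits: list[PlantedBit] = field(default_factory=list)
    xor_pairs: list[tuple[int, int]] = field(default_factory=list)
    duplicate_of: dict[int, int] = field(default_factory=dict)
    n_noise_bits: int = 50
    p_noise: float = 0.1
    n_targets: int = 1
    per_target: dict[int, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes need at least one compound")
        if self.n_targets < 1:
            raise ValueError("n_targets must be positive")
        planted_ids = [b.bit_id for b in self.planted_bits]
        xor_ids = [b for pair in self.xor_pairs for b in pair]
        dup_ids = list(self.duplicate_of)
        if set(planted_ids) & set(xor_ids):
            raise ValueError("xor-pair bits must not also be planted bits")
        declared = planted_ids + xor_ids + dup_ids
        if len(set(declared)) != len(declared):
            raise ValueError("bit ids must be unique across roles")
        for dup, src in self.duplicate_of.items():
            if src not in planted_ids + xor_ids:
                raise ValueError(f"duplicate bit {dup} copies unknown source {src}")
        for pair in self.xor_pairs:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"xor pair must hold two distinct bit ids: {pair}")

    def _resolved(self, target: int) -> "SyntheticSpec":
        if target not in self.per_target:
            return self
        fields = {
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "planted_bits": self.planted_bits,
            "xor_pairs": self.xor_pairs,
            "duplicate_of": self.duplicate_of,
            "n_noise_bits": self.n_noise_bits,
            "p_noise": self.p_noise,
        }
        fields.update(self.per_target[target])
        return SyntheticSpec(seed=self.seed, n_targets=1, **fields)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, *[int(k) % 2**31 for k in key]])


def generate(spec: SyntheticSpec) -> tuple[list[LabeledDataset], dict]:
    """Draw one labeled dataset per target plus a ground-truth manifest."""
    datasets = []
    manifest = {"seed": spec.seed, "tool_version": _tool_version, "targets": []}
    for t in range(spec.n_targets):
        local = spec._resolved(t)
        n = local.n_active + local.n_inactive
        y = np.array([1] * local.n_active + [0] * local.n_inactive, dtype=np.int8)
        pos_frac = local.n_active / n

        declared = (
            [b.bit_id for b in local.planted_bits]
            + [b for pair in local.xor_pairs for b in pair]
            + list(local.duplicate_of)
        )
        noise_start = max(declared, default=-1) + 1
        noise_ids = list(range(noise_start, noise_start + local.n_noise_bits))

        columns: dict[int, np.ndarray] = {}
        bit_info: dict[int, dict] = {}
        for bit in local.planted_bits:
            rng = _rng(spec.seed, t, _ROLE_PLANTED, bit.bit_id)
            probs = np.where(y == 1, bit.p_active, bit.p_inactive)
            columns[bit.bit_id] = (rng.random(n) < probs).astype(np.uint8)
            bit_info[bit.bit_id] = {
                "role": "planted",
                "p_active": bit.p_active,
                "p_inactive": bit.p_inactive,
                "closed_form_aic": closed_form_singleton_aic(
                    bit.p_active, bit.p_inactive, pos_frac
                ),
            }
        for a, b in local.xor_pairs:
            rng = _rng(spec.seed, t, _ROLE_XOR, a)
            xa = (rng.random(n) < 0.5).astype(np.uint8)
            columns[a] = xa
            columns[b] = np.bitwise_xor(xa, y.astype(np.uint8))
            for bit, partner in ((a, b), (b, a)):
                bit_info[bit] = {
                    "role": "xor",
                    "partner": partner,
                    "closed_form_aic": 0.0,
                    "pair_aic": 1.0,
                }
        for dup, src in local.duplicate_of.items():
            columns[dup] = columns[src].copy()
            bit_info[dup] = {"role": "duplicate", "source": src}
        for bit_id in noise_ids:
            rng = _rng(spec.seed, t, _ROLE_NOISE, bit_id)
            columns[bit_id] = (rng.random(n) < local.p_noise).astype(np.uint8)
            bit_info[bit_id] = {
                "role": "noise",
                "p": local.p_noise,
                "closed_form_aic": 0.0,
            }

        bit_ids = sorted(columns)
        values = np.column_stack([columns[b] for b in bit_ids]) if bit_ids else np.zeros((n, 0), dtype=np.uint8)
        task_id = f"target{t}"
        matrix = FingerprintMatrix(
            compound_ids=[f"T{t}_C{i:05d}" for i in range(n)],
            bit_ids=bit_ids,
            values=values,
        )
        datasets.append(LabeledDataset(matrix, y, task_id=task_id))
        manifest["targets"].append(
            {
                "task_id": task_id,
                "n_active": local.n_active,
                "n_inactive": local.n_inactive,
                "label_entropy": label_entropy(y),
                "bits": {str(b): bit_info[b] for b in bit_ids},
            }
        )
    return datasets, manifest


def generate_pairwise_suite(
    n_targets: int,
    n_active_per_target: int = 300,
    n_char_bits_per_target: int = 3,
    p_char_hi: float = 0.8,
    p_char_lo: float = 0.2,
    n_noise_bits: int = 40,
    p_noise: float = 0.2,
    overlap_rate: float = 0.0,
    degenerate_pair: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, set[str]], FingerprintMatrix, dict]:
    """Multi-target actives with per-pair discriminative planted bits.

    Each target owns ``n_char_bits_per_target`` characteristic bits that
    occur with probability ``p_char_hi`` in its own actives and
    ``p_char_lo`` in every other target's actives — so each pair (a, b)
    is discriminated by the characteristic bits of a and of b (effect
    |p_hi − p_lo|), and each target's characteristic bits discriminate
    it from *every* other target (universal discriminators, expected in
    its core-bit set). Noise bits are label-independent background.

    ``overlap_rate`` injects dual-active compounds: that fraction of each
    target's actives is also registered as active at the next target.
    ``degenerate_pair=(i, j)`` rewrites target j's active set to coincide
    with target i's (plus one own compound), so the (i, j) pair cannot
    form a valid task — for exercising skip handling.

    Returns (actives_by_target, matrix, manifest); the manifest lists
    every pair's discriminative bits and expected overlap counts.
    """
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    target_names = [f"T{t}" for t in range(n_targets)]
    char_bits = {
        target_names[t]: list(
            range(t * n_char_bits_per_target, (t + 1) * n_char_bits_per_target)
        )
        for t in range(n_targets)
    }
    noise_start = n_targets * n_char_bits_per_target
    noise_ids = list(range(noise_start, noise_start + n_noise_bits))
    bit_ids = sorted([b for bits in char_bits.values() for b in bits] + noise_ids)

    pos = {b: j for j, b in enumerate(bit_ids)}
    compound_ids: list[str] = []
    blocks: list[np.ndarray] = []
    owners: dict[str, list[str]] = {name: [] for name in target_names}
    for t, name in enumerate(target_names):
        ids = [f"{name}_C{i:04d}" for i in range(n_active_per_target)]
        compound_ids.extend(ids)
        owners[name] = ids
        block = np.zeros((n_active_per_target, len(bit_ids)), dtype=np.uint8)
        for uname in target_names:
            p = p_char_hi if uname == name else p_char_lo
            for bit in char_bits[uname]:
                rng = _rng(seed, t, _ROLE_PLANTED, bit)
                block[:, pos[bit]] = rng.random(n_active_per_target) < p
        for bit in noise_ids:
            rng = _rng(seed, t, _ROLE_NOISE, bit)
            block[:, pos[bit]] = rng.random(n_active_per_target) < p_noise
        blocks.append(block)

    matrix = FingerprintMatrix(compound_ids, bit_ids, np.vstack(blocks))
    actives = {name: set(ids) for name, ids in owners.items()}

    n_overlap = int(round(overlap_rate * n_active_per_target))
    for t, name in enumerate(target_names):
        nxt = target_names[(t + 1) % n_targets]
        for cid in owners[name][:n_overlap]:
            actives[nxt].add(cid)

    if degenerate_pair is not None:
        i, j = degenerate_pair
        keep_one = owners[target_names[j]][0]
        actives[target_names[j]] = set(owners[target_names[i]]) | {keep_one}

    pair_discriminative = {}
    pair_overlaps = {}
    for a_idx in range(n_targets):
        for b_idx in range(a_idx + 1, n_targets):
            a, b = target_names[a_idx], target_names[b_idx]
            pair_discriminative[f"{a}|{b}"] = sorted(char_bits[a] + char_bits[b])
            pair_overlaps[f"{a}|{b}"] = len(actives[a] & actives[b])

    manifest = {
        "seed": seed,
        "tool_version": _tool_version,
        "targets": target_names,
        "char_bits": char_bits,
        "noise_bits": noise_ids,
        "effect_size": abs(p_char_hi - p_char_lo),
        "pair_discriminative": pair_discriminative,
        "pair_overlaps": pair_overlaps,
        "degenerate_pair": list(degenerate_pair) if degenerate_pair else None,
    }
    return actives, matrix, manifest
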