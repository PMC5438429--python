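import numpy as np
import pytest

from aicmax import FingerprintMatrix, LabeledDataset


def make_matrix(values, bit_ids=None, prefix="c"):
    values = np.asarray(values)
    bit_ids = list(range(values.shape[1])) if bit_ids is None else list(bit_ids)
    return FingerprintMatrix(
        compound_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        bit_ids=bit_ids,
        values=values,
    )


def random_dataset(rng, n=50, bits=12, task_id="rand"):
    """Random binary task with both classes guaranteed present."""
    values = (rng.random((n, bits)) < 0.5).astype(np.uint8)
    labels = (rng.random(n) < 0.5).astype(np.int8)
    labels[0], labels[1] = 0, 1
    return LabeledDataset(make_matrix(values), labels, task_id=task_id)


def xor_dataset(m=8, n_noise=8):
    """XOR task: y = x0 ^ x1 with all four patterns equally frequent.

    Noise bits are balanced exactly within every (x0, x1) pattern block,
    so they are empirically independent of the label both alone and in
    any pair with x0, x1 or each other — only the pair {x0, x1} reaches
    score 1, and every singleton ties at exactly 0.
    """
    assert m % 2 == 0
    patterns = np.array([(a, b) for a in (0, 1) for b in (0, 1) for _ in range(m)])
    y = patterns[:, 0] ^ patterns[:, 1]
    n = len(y)
    noise = np.zeros((n, n_noise), dtype=np.uint8)
    for j in range(n_noise):
        for block in range(4):
            rows = block * m + (np.arange(j, j + m // 2) % m)
            noise[rows, j] = 1
    values = np.column_stack([patterns, noise]).astype(np.uint8)
    return LabeledDataset(make_matrix(values), y, task_id="xor")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def eight_row_dataset():
    """The hand-countable example: bit (1,1,1,0,0,0,0,0), y (1,1,1,1,0,0,0,0)."""
    values = np.array([[1], [1], [1], [0], [0], [0], [0], [0]])
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    return LabeledDataset(make_matrix(values), labels, task_id="hand8")
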