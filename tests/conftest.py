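from __future__ import annotations

import numpy as np
import pytest

from npcda import QMatrix, ResponseMatrix, simulate_responses


@pytest.fixture
def table1_qmatrix() -> QMatrix:
    """The three-item, three-attribute example design."""
    return QMatrix(
        [[1, 0, 0], [0, 1, 0], [1, 0, 1]],
        item_ids=("1", "2", "3"),
        attribute_names=("Neurology", "Endocrinology", "Rheumatology"),
    )


def random_qmatrix(rng: np.random.Generator, n_items: int, n_attrs: int,
                   max_attrs: int = 3, complete: bool = True) -> QMatrix:
    """Random valid Q-matrix; with ``complete`` the first K rows are the
    identity (distinct conjunctive IRPs guaranteed)."""
    q = np.zeros((n_items, n_attrs), dtype=np.int8)
    start = 0
    if complete:
        assert n_items >= n_attrs
        q[:n_attrs] = np.eye(n_attrs, dtype=np.int8)
        start = n_attrs
    for i in range(start, n_items):
        m = int(rng.integers(1, min(max_attrs, n_attrs) + 1))
        q[i, rng.choice(n_attrs, size=m, replace=False)] = 1
    return QMatrix(q)


def random_instance(rng: np.random.Generator, n_attrs: int | None = None,
                    n_items: int | None = None, n_examinees: int | None = None,
                    slip: float = 0.15, guess: float = 0.15):
    """A random classification problem: Q, noisy responses, true states."""
    n_attrs = n_attrs or int(rng.integers(2, 6))
    n_items = n_items or int(rng.integers(n_attrs + 2, n_attrs + 10))
    n_examinees = n_examinees or int(rng.integers(4, 21))
    q = random_qmatrix(rng, n_items, n_attrs)
    states = (rng.random((n_examinees, n_attrs)) < 0.5).astype(np.uint8)
    y = simulate_responses(q, states, slip, guess, rng)
    return q, y, states
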