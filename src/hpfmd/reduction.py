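"""Global summation strategies for observable accumulation.

Two deterministic strategies are provided: ordered sequential accumulation
(the serial analogue of atomic-function accumulation) and balanced pairwise
tree reduction.  On double-precision data the two agree to within round-off;
the pairwise error bound grows as O(log n) against O(n) for the sequential
loop, which the test suite measures on an ill-conditioned fixture.
"""

from __future__ import annotations

import numpy as np

STRATEGIES = ("sequential", "pairwise")


def sequential_sum(values) -> float:
    """Left-to-right accumulation in index order; deterministic."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return 0.0
    # cumsum accumulates strictly left-to-right in IEEE double
    return float(np.cumsum(values)[-1])


def pairwise_sum(values) -> float:
    """Balanced binary-tree reduction; deterministic for a fixed length."""
    values = np.asarray(values, dtype=float).ravel().copy()
    if values.size == 0:
        return 0.0
    while values.size > 1:
        half = values.size // 2
        paired = values[: 2 * half : 2] + values[1 : 2 * half : 2]
        if values.size % 2:
            paired = np.append(paired, values[-1])
        values = paired
    return float(values[0])


def reduce_values(values, strategy: str) -> float:
    if strategy == "sequential":
        return sequential_sum(values)
    if strategy == "pairwise":
        return pairwise_sum(values)
    raise ValueError(f"unknown reduction strategy {strategy!r}")
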