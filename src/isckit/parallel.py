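"""Deterministic local parallel execution.

Work inside each pipeline stage decomposes into independent items (voxel
blocks, permutation chunks, band or window indices).  ``parallel_map`` runs
such items on a thread pool — the heavy lifting is numpy, which releases the
GIL — and returns results in item order, so the gathered output is identical
to a serial run regardless of worker count or completion order.  Randomized
items must carry their own seed (derived from the master seed by item index),
never share a generator; combined with ordered gathering this gives the
end-to-end determinism contract: (config, seed) fully determines every output,
for any n_workers.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence, TypeVar

import numpy as np
from joblib import Parallel, delayed

T = TypeVar("T")
R = TypeVar("R")

__all__ = ["parallel_map", "chunk_sizes", "derive_seeds"]


class WorkItemError(RuntimeError):
    """A work item failed; carries the originating item."""

    def __init__(self, index: int, item, cause: BaseException):
        super().__init__(f"work item {index} ({item!r}) failed: {cause}")
        self.index = index
        self.item = item
        self.__cause__ = cause


def parallel_map(func: Callable[[T], R], items: Sequence[T], n_workers: int = 1) -> list[R]:
    """Apply ``func`` to each item, in parallel, gathering in item order."""
    items = list(items)
    if not items:
        return []

    def run(k: int, item: T) -> R:
        try:
            return func(item)
        except Exception as exc:  # surface which item failed
            raise WorkItemError(k, item, exc) from exc

    if n_workers <= 1 or len(items) == 1:
        return [run(k, it) for k, it in enumerate(items)]
    return Parallel(n_jobs=n_workers, prefer="threads")(
        delayed(run)(k, it) for k, it in enumerate(items)
    )


def chunk_sizes(total: int, chunk: int) -> list[int]:
    """Sizes of consecutive chunks partitioning ``total``."""
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    full, rest = divmod(total, chunk)
    return [chunk] * full + ([rest] if rest else [])


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-item seeds, a pure function of the master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]
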