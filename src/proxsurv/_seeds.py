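"""Deterministic seed derivation.

A single master seed is expanded into named per-stage seeds through
:class:`numpy.random.SeedSequence`, so any stage can be re-run in isolation
with the same stream it saw inside the full pipeline.  All derived seeds are
kept below 2**31 so they are valid for every downstream library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds", "child_seed"]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from ``master_seed``."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def child_seed(master_seed: int, index: int) -> int:
    """The ``index``-th seed of :func:`spawn_seeds` without building the list."""
    return spawn_seeds(master_seed, index + 1)[index]
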