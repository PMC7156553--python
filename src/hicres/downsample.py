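"""Simulate low-coverage Hi-C by random read thinning.

Retaining each read pair independently with probability ``ratio`` is, at the
matrix level, a per-entry binomial draw: an entry with count ``k`` becomes
``Binomial(k, ratio)``.  This is distributionally identical to subsampling
the raw paired-end reads before matrix building, without ever touching
read-level files.
"""

from __future__ import annotations

import numpy as np

from .io import ContactMatrix

__all__ = ["thin_counts"]


def thin_counts(matrix: ContactMatrix, ratio: float, seed: int) -> ContactMatrix:
    """Binomially thin every upper-triangle entry and mirror the result.

    Each entry's expectation after thinning is ``ratio`` times its original
    value, its value never exceeds the original, and symmetry is preserved.
    Diagonal entries are thinned like any other entry.
    """
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    counts = matrix.counts
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError(
                "thin_counts needs integer counts; round the matrix first"
            )
        counts = counts.astype(np.int64)
    if ratio == 1.0:
        return ContactMatrix(counts.copy(), matrix.resolution, matrix.chromosome)
    rng = np.random.default_rng(seed)
    n = matrix.n_bins
    out = np.zeros_like(counts)
    iu, ju = np.triu_indices(n)
    out[iu, ju] = rng.binomial(counts[iu, ju], ratio)
    out[ju, iu] = out[iu, ju]
    return ContactMatrix(out, matrix.resolution, matrix.chromosome)
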