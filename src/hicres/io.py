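"""Reading, writing and validation of intra-chromosomal contact matrices.

A Hi-C contact matrix for one chromosome at a fixed bin width is a symmetric
non-negative grid: entry ``(i, j)`` counts read pairs linking genomic bins
``i`` and ``j``.  Two on-disk dialects are supported:

* sparse triplet text (``start1 start2 count`` per line, coordinates in bp,
  the dialect used by the GEO GSE63525 raw-observed dumps), and
* dense tab-separated numeric grids.

Coordinates in triplet files are 0-based bin-start positions in bp; all
in-memory indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "ContactMatrix",
    "MatrixFormatError",
    "Diagnostics",
    "read_triplets",
    "write_triplets",
    "read_dense",
    "write_dense",
    "validate",
]

DEFAULT_RESOLUTION = 10_000


class MatrixFormatError(ValueError):
    """Raised when a contact-matrix file violates the expected format."""


@dataclasses.dataclass
class ContactMatrix:
    """Symmetric count grid for one chromosome at fixed bin width.

    Parameters
    ----------
    counts : ndarray, shape (n_bins, n_bins)
        Non-negative contact counts; symmetric.
    resolution : int
        Bin width in bp (default 10 kb).
    chromosome : str
        Free-form label.
    """

    counts: np.ndarray
    resolution: int = DEFAULT_RESOLUTION
    chromosome: str = "chr"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_reads(self) -> float:
        """Sum of the upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.counts.copy(), self.resolution, self.chromosome)


@dataclasses.dataclass
class Diagnostics:
    """Validation report for a :class:`ContactMatrix` (pure report, no errors)."""

    symmetry_violations: int
    negative_entries: int
    zero_fraction: float
    total_reads: float

    @property
    def ok(self) -> bool:
        return self.symmetry_violations == 0 and self.negative_entries == 0


def read_triplets(
    path,
    resolution: int = DEFAULT_RESOLUTION,
    n_bins: int | None = None,
    chromosome: str = "chr",
) -> ContactMatrix:
    """Read a sparse ``start1 start2 count`` triplet file into a dense matrix.

    Bin index = coordinate / resolution (0-based).  Each triplet is written to
    both ``(i, j)`` and ``(j, i)``; absent pairs are zero.  When ``n_bins`` is
    omitted it is inferred as ``max coordinate / resolution + 1``.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 'start1 start2 count', got {line.strip()!r}"
                )
            try:
                a, b = int(fields[0]), int(fields[1])
                v = float(fields[2])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: unparseable numbers") from exc
            if a < 0 or b < 0:
                raise MatrixFormatError(f"{path}:{lineno}: negative coordinate")
            if a % resolution or b % resolution:
                raise MatrixFormatError(
                    f"{path}:{lineno}: coordinate not a multiple of resolution {resolution}"
                )
            if v < 0:
                raise MatrixFormatError(f"{path}:{lineno}: negative count {v}")
            rows.append(a // resolution)
            cols.append(b // resolution)
            vals.append(v)

    if n_bins is None:
        if not rows:
            raise MatrixFormatError(f"{path}: empty file and no n_bins given")
        n_bins = max(max(rows), max(cols)) + 1
    counts = np.zeros((n_bins, n_bins))
    for i, j, v in zip(rows, cols, vals):
        if i >= n_bins or j >= n_bins:
            raise MatrixFormatError(
                f"{path}: coordinate {max(i, j) * resolution} outside {n_bins} bins"
            )
        counts[i, j] = v
        counts[j, i] = v
    # preserve integer typing for integer-valued files
    if vals and all(float(v).is_integer() for v in vals):
        counts = counts.astype(np.int64)
    return ContactMatrix(counts, resolution=resolution, chromosome=chromosome)


def write_triplets(matrix: ContactMatrix, path) -> Path:
    """Write upper-triangle nonzero entries as ``start1 start2 count`` lines.

    Lines are ordered lexicographically by (i, j); coordinates are
    ``index * resolution``.  Re-reading reproduces the matrix exactly.
    """
    path = Path(path)
    res = matrix.resolution
    iu, ju = np.triu_indices(matrix.n_bins)
    v = matrix.counts[iu, ju]
    keep = v != 0
    is_int = np.issubdtype(matrix.counts.dtype, np.integer)
    with open(path, "w") as fh:
        for i, j, val in zip(iu[keep], ju[keep], v[keep]):
            sval = str(int(val)) if is_int else repr(float(val))
            fh.write(f"{i * res} {j * res} {sval}\n")
    return path


def read_dense(path, resolution: int = DEFAULT_RESOLUTION, chromosome: str = "chr") -> ContactMatrix:
    counts = np.loadtxt(path, ndmin=2)
    return ContactMatrix(counts, resolution=resolution, chromosome=chromosome)


def write_dense(matrix: ContactMatrix, path) -> Path:
    path = Path(path)
    fmt = "%d" if np.issubdtype(matrix.counts.dtype, np.integer) else "%.17g"
    np.savetxt(path, matrix.counts, fmt=fmt, delimiter="\t")
    return path


def validate(matrix: ContactMatrix) -> Diagnostics:
    """Report symmetry violations, negative entries, zero fraction and total reads."""
    c = matrix.counts
    iu, ju = np.triu_indices(matrix.n_bins, k=1)
    sym = int(np.count_nonzero(c[iu, ju] != c[ju, iu]))
    neg = int(np.count_nonzero(c < 0))
    zero_frac = float(np.count_nonzero(c == 0) / c.size) if c.size else 0.0
    return Diagnostics(
        symmetry_violations=sym,
        negative_entries=neg,
        zero_fraction=zero_frac,
        total_reads=matrix.total_reads,
    )
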