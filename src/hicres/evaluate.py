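"""Quality metrics for comparing contact matrices.

Four metric families are provided:

* ``pearson_by_distance`` — Pearson correlation of the paired d-th diagonals,
  one value per genomic distance;
* ``scc`` — the stratum-adjusted correlation coefficient of HiCRep: both
  matrices are 2D mean-smoothed, per-distance (stratum) Pearson correlations
  are combined with weights ``N_d * s_d(A) * s_d(B)`` (stratum size times the
  two stratum standard deviations);
* ``ssim_score`` — the structural similarity index over sliding windows with
  the usual stabilizers ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2``;
* ``apa_p2ll`` — aggregate peak analysis: windows around loop anchors are
  averaged and the center value is divided by the mean of the lower-left
  corner block (P2LL), a measure of focal peak enrichment;
* ``interaction_overlap`` — the fraction of reference interaction calls in a
  genomic-distance range that a test call set recovers.

Correlations on constant strata are undefined and reported as NaN markers,
never silently dropped; the SCC skips zero-variance strata in its weighted
sum.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .io import ContactMatrix

__all__ = [
    "EvalReport",
    "EvalSettings",
    "pearson_by_distance",
    "scc",
    "ssim_score",
    "apa_p2ll",
    "interaction_overlap",
    "compare",
    "mean_smooth",
]

DEFAULT_MAX_DISTANCE = 2_000_000  # analyses focus below 2 Mb, within typical TAD span
DEFAULT_RANGES = ((50_000, 250_000), (250_000, 1_000_000), (1_000_000, 2_000_000))


def _grids(a, b) -> tuple[np.ndarray, np.ndarray, int]:
    """Unpack two matrices, enforcing equal geometry; returns resolution."""
    res = 10_000
    if isinstance(a, ContactMatrix):
        res = a.resolution
    ga = a.counts if isinstance(a, ContactMatrix) else np.asarray(a, dtype=float)
    gb = b.counts if isinstance(b, ContactMatrix) else np.asarray(b, dtype=float)
    if isinstance(a, ContactMatrix) and isinstance(b, ContactMatrix):
        if a.resolution != b.resolution:
            raise ValueError("resolution mismatch")
    if ga.shape != gb.shape:
        raise ValueError(f"geometry mismatch: {ga.shape} vs {gb.shape}")
    return np.asarray(ga, dtype=float), np.asarray(gb, dtype=float), res


def _max_diag(n: int, max_distance: int | None, resolution: int) -> int:
    if max_distance is None:
        return n - 1
    return min(n - 1, max_distance // resolution)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return np.nan
    return float((xd * yd).sum() / denom)


def pearson_by_distance(a, b, max_distance: int | None = None) -> np.ndarray:
    """Pearson correlation of the d-th diagonals for d = 0 ... max.

    Entries where either diagonal is constant are NaN (undefined), matching
    the convention that a correlation against a constant has no value.
    """
    ga, gb, res = _grids(a, b)
    dmax = _max_diag(ga.shape[0], max_distance, res)
    out = np.empty(dmax + 1)
    for d in range(dmax + 1):
        out[d] = _pearson(np.diagonal(ga, d), np.diagonal(gb, d))
    return out


def mean_smooth(grid: np.ndarray, h: int) -> np.ndarray:
    """(2h+1)x(2h+1) moving-average smoothing; edge windows average only
    in-bounds cells."""
    if h == 0:
        return np.asarray(grid, dtype=float).copy()
    size = 2 * h + 1
    summed = ndimage.uniform_filter(np.asarray(grid, dtype=float), size, mode="constant") * size**2
    counts = ndimage.uniform_filter(np.ones_like(grid, dtype=float), size, mode="constant") * size**2
    return summed / np.round(counts)


def scc(a, b, h: int = 5, max_distance: int | None = DEFAULT_MAX_DISTANCE) -> float:
    """Stratum-adjusted correlation coefficient (HiCRep-style).

    Strata are the off-diagonals d = 1 ... max (the main diagonal is
    excluded); each contributes its Pearson correlation with weight
    ``N_d * s_d(A) * s_d(B)``.  Zero-variance strata are skipped; NaN is
    returned with a warning when every stratum is degenerate.
    """
    ga, gb, res = _grids(a, b)
    sa = mean_smooth(ga, h)
    sb = mean_smooth(gb, h)
    dmax = _max_diag(ga.shape[0], max_distance, res)
    num, den = 0.0, 0.0
    for d in range(1, dmax + 1):
        x = np.diagonal(sa, d)
        y = np.diagonal(sb, d)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rho = _pearson(x, y)
        w = len(x) * sx * sy
        num += w * rho
        den += w
    if den == 0:
        warnings.warn("all strata degenerate; SCC undefined", stacklevel=2)
        return np.nan
    return num / den


def ssim_score(a, b, window: int = 11, dynamic_range: float | None = None) -> float:
    """Structural similarity index with a uniform window.

    Local means, variances and covariance (sample covariance, ddof=1) are
    computed over every fully contained ``window x window`` patch and the
    local scores averaged.  ``dynamic_range`` (L) defaults to the maximum
    value over both matrices.
    """
    ga, gb, _ = _grids(a, b)
    n = ga.shape[0]
    if window > n:
        raise ValueError(f"window {window} exceeds matrix size {n}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if dynamic_range is None:
        dynamic_range = float(max(ga.max(), gb.max()))
        if dynamic_range == 0:
            dynamic_range = 1.0
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2

    wa = sliding_window_view(ga, (window, window))
    wb = sliding_window_view(gb, (window, window))
    axis = (-2, -1)
    npix = window * window
    mu_a = wa.mean(axis=axis)
    mu_b = wb.mean(axis=axis)
    # sample moments (ddof = 1)
    var_a = (wa - mu_a[..., None, None]).reshape(*mu_a.shape, -1)
    var_b = (wb - mu_b[..., None, None]).reshape(*mu_b.shape, -1)
    cov = (var_a * var_b).sum(axis=-1) / (npix - 1)
    va = (var_a**2).sum(axis=-1) / (npix - 1)
    vb = (var_b**2).sum(axis=-1) / (npix - 1)
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )
    return float(ssim_map.mean())


def apa_p2ll(
    matrix,
    loops,
    window_radius: int = 10,
    corner_size: int = 3,
) -> float:
    """Aggregate peak analysis P2LL score.

    The ``(2r+1) x (2r+1)`` windows centered on the loop anchors are averaged
    elementwise; P2LL is the aggregate center value divided by the mean of
    the ``corner_size`` square in the lower-left of the aggregate window (the
    short-distance corner for an anchor ordered i < j).  Anchors whose window
    would cross the matrix edge or the main diagonal are dropped with a
    warning.
    """
    grid = matrix.counts if isinstance(matrix, ContactMatrix) else np.asarray(matrix, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not loops:
        raise ValueError("empty loop list")
    n = grid.shape[0]
    r = window_radius
    if corner_size < 1 or corner_size > 2 * r + 1:
        raise ValueError("corner_size must fit inside the window")
    windows = []
    for i, j in loops:
        i, j = (int(i), int(j)) if i <= j else (int(j), int(i))
        if i - r < 0 or j - r < 0 or i + r >= n or j + r >= n or j - i <= 2 * r:
            warnings.warn(
                f"anchor ({i}, {j}) too near edge or diagonal for radius {r}; dropped",
                stacklevel=2,
            )
            continue
        windows.append(grid[i - r : i + r + 1, j - r : j + r + 1])
    if not windows:
        raise ValueError("all anchors dropped; no APA window available")
    agg = np.mean(windows, axis=0)
    center = agg[r, r]
    corner = agg[2 * r + 1 - corner_size :, :corner_size]
    corner_mean = corner.mean()
    if corner_mean == 0:
        return np.nan
    return float(center / corner_mean)


def _canonical(pairs) -> set[tuple[int, int]]:
    out = set()
    for p in pairs:
        try:
            i, j = int(p[0]), int(p[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"malformed interaction pair {p!r}") from exc
        out.add((i, j) if i <= j else (j, i))
    return out


def interaction_overlap(
    calls_test,
    calls_ref,
    ranges=DEFAULT_RANGES,
    resolution: int = 10_000,
) -> dict[str, float]:
    """Per distance range: fraction of reference calls recovered by the test set.

    Pairs are compared after canonical ordering (i <= j); the distance of a
    pair is ``(j - i) * resolution`` bp and a range ``(lo, hi)`` contains
    distances ``lo <= dist < hi``.  Ranges with no reference call map to NaN.
    """
    test = _canonical(calls_test)
    ref = _canonical(calls_ref)
    out = {}
    for lo, hi in ranges:
        label = f"{lo}-{hi}"
        ref_in = {p for p in ref if lo <= (p[1] - p[0]) * resolution < hi}
        if not ref_in:
            out[label] = np.nan
            continue
        test_in = {p for p in test if lo <= (p[1] - p[0]) * resolution < hi}
        out[label] = len(test_in & ref_in) / len(ref_in)
    return out


@dataclasses.dataclass
class EvalSettings:
    max_distance: int | None = DEFAULT_MAX_DISTANCE
    scc_h: int = 5
    ssim_window: int = 11
    ssim_dynamic_range: float | None = None
    loops: tuple | None = None
    apa_window_radius: int = 10
    apa_corner_size: int = 3
    calls_test: tuple | None = None
    calls_ref: tuple | None = None
    overlap_ranges: tuple = DEFAULT_RANGES


@dataclasses.dataclass
class EvalReport:
    """All metrics for one (reference, candidate) matrix pair."""

    pearson_by_distance: np.ndarray
    scc: float
    ssim: float
    p2ll: float | None = None
    overlap_ratios: dict[str, float] | None = None

    @property
    def mean_pearson(self) -> float:
        """Mean of the defined per-distance correlations."""
        v = np.asarray(self.pearson_by_distance, dtype=float)
        defined = v[~np.isnan(v)]
        return float(defined.mean()) if defined.size else np.nan

    def to_dict(self) -> dict:
        def scrub(x):
            if isinstance(x, float) and np.isnan(x):
                return None
            return x

        return {
            "pearson_by_distance": [scrub(float(v)) for v in self.pearson_by_distance],
            "scc": scrub(float(self.scc)),
            "ssim": scrub(float(self.ssim)),
            "p2ll": None if self.p2ll is None else scrub(float(self.p2ll)),
            "overlap_ratios": None
            if self.overlap_ratios is None
            else {k: scrub(float(v)) for k, v in self.overlap_ratios.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        def fill(x):
            return np.nan if x is None else x

        return cls(
            pearson_by_distance=np.array([fill(v) for v in d["pearson_by_distance"]], dtype=float),
            scc=fill(d["scc"]),
            ssim=fill(d["ssim"]),
            p2ll=None if d["p2ll"] is None else fill(d["p2ll"]),
            overlap_ratios=None
            if d["overlap_ratios"] is None
            else {k: fill(v) for k, v in d["overlap_ratios"].items()},
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls.from_dict(json.loads(text))


def compare(reference, candidate, settings: EvalSettings | None = None) -> EvalReport:
    """Run every applicable metric on a (reference, candidate) pair.

    P2LL is computed on the candidate only when loop anchors are supplied;
    overlap ratios only when both call lists are supplied.
    """
    settings = settings or EvalSettings()
    res = reference.resolution if isinstance(reference, ContactMatrix) else 10_000
    report = EvalReport(
        pearson_by_distance=pearson_by_distance(reference, candidate, settings.max_distance),
        scc=scc(reference, candidate, h=settings.scc_h, max_distance=settings.max_distance),
        ssim=ssim_score(
            reference, candidate, window=settings.ssim_window,
            dynamic_range=settings.ssim_dynamic_range,
        ),
    )
    if settings.loops:
        report.p2ll = apa_p2ll(
            candidate, settings.loops,
            window_radius=settings.apa_window_radius,
            corner_size=settings.apa_corner_size,
        )
    if settings.calls_test is not None and settings.calls_ref is not None:
        report.overlap_ratios = interaction_overlap(
            settings.calls_test, settings.calls_ref,
            ranges=settings.overlap_ranges, resolution=res,
        )
    return report
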