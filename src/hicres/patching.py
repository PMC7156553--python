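"""Patch geometry: overlapping input windows, tiling target windows, stitching.

A full contact matrix is too large to feed to the network at once, so it is
subdivided into 40x40 input windows whose anchors advance in steps of 28
along each axis (adjacent windows overlap by 12 bins).  The corresponding
28x28 target window sits 6 bins inside its input window, so targets tile the
matrix without overlap: input rows [0, 40) map to target rows [6, 34), input
rows [28, 68) to target rows [34, 62), and so on.  ``stitch`` writes
predicted targets back at their anchors and restores symmetry by averaging
with the transpose.

All indices here are 0-based and half-open.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .io import ContactMatrix, DEFAULT_RESOLUTION

__all__ = [
    "INPUT_SIZE",
    "TARGET_SIZE",
    "STRIDE",
    "TARGET_OFFSET",
    "PatchPlan",
    "PatchSet",
    "plan_patches",
    "extract_inputs",
    "extract_targets",
    "stitch",
    "cv_groups",
]

INPUT_SIZE = 40
TARGET_SIZE = 28
STRIDE = 28          # anchor step; equals TARGET_SIZE so targets tile
TARGET_OFFSET = 6    # target window shift inside its input window


@dataclasses.dataclass(frozen=True)
class PatchPlan:
    """Deterministic patch geometry for one matrix size.

    ``anchors`` holds (row_start, col_start) of every kept 40x40 input
    window; the matching target window starts at ``anchor + 6`` on each axis.
    """

    n_bins: int
    anchors: tuple[tuple[int, int], ...]
    max_distance: int | None = None
    resolution: int = DEFAULT_RESOLUTION
    input_size: int = INPUT_SIZE
    target_size: int = TARGET_SIZE
    stride: int = STRIDE
    target_offset: int = TARGET_OFFSET

    @property
    def n_patches(self) -> int:
        return len(self.anchors)

    def axis_anchors(self) -> tuple[int, ...]:
        return tuple(sorted({r for r, _ in self.anchors} | {c for _, c in self.anchors}))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["anchors"] = [list(a) for a in self.anchors]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "PatchPlan":
        d = json.loads(text)
        d["anchors"] = tuple(tuple(a) for a in d["anchors"])
        return cls(**d)


@dataclasses.dataclass
class PatchSet:
    """Ordered stack of square patches with back-references to plan anchors.

    ``data`` has shape (n, side, side, 1); stack order matches anchor order.
    """

    data: np.ndarray
    anchors: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError(f"patch stack must be (n, s, s, 1), got {self.data.shape}")
        if self.data.shape[0] != len(self.anchors):
            raise ValueError("patch count does not match anchor count")

    @property
    def side(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.data.shape[0]


def plan_patches(
    n_bins: int,
    max_distance: int | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> PatchPlan:
    """Anchors at 0, 28, 56, ... while ``anchor + 40 <= n_bins``, on both axes.

    ``max_distance`` (bp) optionally drops windows whose center lies farther
    than that from the diagonal: anchors (r, c) are kept only when
    ``|r - c| * resolution <= max_distance``.
    """
    if n_bins < INPUT_SIZE:
        raise ValueError(f"matrix of {n_bins} bins is smaller than one {INPUT_SIZE}-bin window")
    starts = list(range(0, n_bins - INPUT_SIZE + 1, STRIDE))
    anchors = []
    for r in starts:
        for c in starts:
            if max_distance is not None and abs(r - c) * resolution > max_distance:
                continue
            anchors.append((r, c))
    return PatchPlan(
        n_bins=n_bins,
        anchors=tuple(anchors),
        max_distance=max_distance,
        resolution=resolution,
    )


def _check_geometry(matrix: ContactMatrix, plan: PatchPlan) -> None:
    if matrix.n_bins != plan.n_bins:
        raise ValueError(
            f"plan built for {plan.n_bins} bins but matrix has {matrix.n_bins}"
        )


def extract_inputs(matrix: ContactMatrix, plan: PatchPlan) -> PatchSet:
    """40x40 input windows at each plan anchor (copied, not views)."""
    _check_geometry(matrix, plan)
    s = plan.input_size
    stack = np.stack(
        [matrix.counts[r : r + s, c : c + s].copy() for r, c in plan.anchors]
    )[..., None]
    return PatchSet(stack.astype(float), plan.anchors)


def extract_targets(matrix: ContactMatrix, plan: PatchPlan) -> PatchSet:
    """28x28 target windows, offset 6 bins inside each input window."""
    _check_geometry(matrix, plan)
    o, s = plan.target_offset, plan.target_size
    stack = np.stack(
        [matrix.counts[r + o : r + o + s, c + o : c + o + s].copy() for r, c in plan.anchors]
    )[..., None]
    return PatchSet(stack.astype(float), plan.anchors)


def stitch(
    predictions: PatchSet,
    plan: PatchPlan,
    n_bins: int | None = None,
    fallback: ContactMatrix | None = None,
    fallback_scale: float = 1.0,
    clip_negative: bool = False,
) -> ContactMatrix:
    """Splice predicted 28x28 patches back into a full matrix.

    Each patch lands at ``(anchor + 6, anchor + 6)``.  Cells no patch covers
    (the 6-bin borders, any remainder past the last window, and regions a
    ``max_distance`` plan excluded) are taken from ``fallback * fallback_scale``
    when a fallback matrix is given — typically the low-coverage matrix
    rescaled by 1/ratio — and are zero otherwise.  The result is symmetrized
    by averaging with its transpose.
    """
    if n_bins is None:
        n_bins = plan.n_bins
    if len(predictions) != plan.n_patches:
        raise ValueError(
            f"{len(predictions)} predictions for a plan of {plan.n_patches} patches"
        )
    if predictions.side != plan.target_size:
        raise ValueError(f"predictions must be {plan.target_size}x{plan.target_size}")
    if fallback is not None:
        if fallback.n_bins != n_bins:
            raise ValueError("fallback geometry does not match")
        out = fallback.counts.astype(float) * fallback_scale
    else:
        out = np.zeros((n_bins, n_bins))
    o, s = plan.target_offset, plan.target_size
    for patch, (r, c) in zip(predictions.data[..., 0], plan.anchors):
        out[r + o : r + o + s, c + o : c + o + s] = patch
    out = (out + out.T) / 2.0
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    res = fallback.resolution if fallback is not None else plan.resolution
    return ContactMatrix(out, resolution=res, chromosome="stitched")


def cv_groups(chromosomes) -> list[list]:
    """Split 22 autosome labels into the five ordered cross-validation groups.

    Group sizes are 4, 4, 4, 5, 5 in order: the first group holds the first
    four labels, the last group the final five.
    """
    chromosomes = list(chromosomes)
    if len(chromosomes) != 22:
        raise ValueError(f"expected exactly 22 chromosomes, got {len(chromosomes)}")
    sizes = (4, 4, 4, 5, 5)
    groups = []
    start = 0
    for size in sizes:
        groups.append(chromosomes[start : start + size])
        start += size
    return groups
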