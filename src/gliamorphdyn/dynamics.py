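"""In vivo dynamics metrics: box-counting fractal complexity and the
volume-normalized motility index.

Complexity of a binarized projection is estimated as the box-counting
(Hausdorff) fractal dimension: occupied s x s boxes are counted on a grid
anchored at the image origin for a geometric ladder of box sizes, and the
dimension is the negative slope of the least-squares fit of log N(s)
against log s. A series of frames is summarized by the arithmetic mean of
the per-frame dimensions.

Motility is the count of pixels whose binary value changes between
consecutive frames (symmetric difference), summed over all frame pairs
(the global motility coefficient, arbitrary unit) and normalized by the
physical volume of the imaged stack in cubic micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .preprocessing import BinaryMask

__all__ = [
    "BoxCountFit",
    "FractalResult",
    "MotilitySeries",
    "fractal_dimension",
    "series_complexity",
    "motility_index",
]


@dataclass
class BoxCountFit:
    """Box-counting fit for a single binary image."""

    dimension: float
    r2: float
    box_sizes: np.ndarray
    counts: np.ndarray


@dataclass
class FractalResult:
    """Per-frame box-counting dimensions of a mask series and their mean."""

    per_frame_dimension: list[float]
    mean_dimension: float
    fit_r2: list[float]


@dataclass
class MotilitySeries:
    """Changed-pixel counts per consecutive frame pair and their
    volume-normalized sum."""

    pairwise_coefficients: list[int]
    global_coefficient: int
    normalized_index: float
    stack_volume_um3: float


def _as_bool_array(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if data.ndim != 2:
        raise DataError("mask must be 2D")
    return data.astype(bool)


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of two from 2 px up to a quarter of the shorter image side."""
    sizes = []
    s = 2
    while s <= min(shape) // 4:
        sizes.append(s)
        s *= 2
    return sizes


def _box_count(mask: np.ndarray, size: int) -> int:
    h, w = mask.shape
    ph, pw = (-h) % size, (-w) % size
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    h, w = mask.shape
    blocks = mask.reshape(h // size, size, w // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(mask, box_sizes=None) -> BoxCountFit:
    """Box-counting fractal dimension of a binary image.

    Parameters
    ----------
    mask:
        :class:`~gliamorphdyn.preprocessing.BinaryMask` or 2D boolean array
        with at least one foreground pixel.
    box_sizes:
        Box edge lengths in pixels (at least 3 distinct values); defaults
        to powers of two from 2 px to a quarter of the shorter side.
    """
    data = _as_bool_array(mask)
    if not data.any():
        raise DataError("cannot estimate a fractal dimension of an empty mask")
    sizes = sorted(set(int(s) for s in (box_sizes or default_box_sizes(data.shape))))
    if len(sizes) < 3:
        raise DataError("need at least 3 distinct box sizes")
    if sizes[0] < 1:
        raise DataError("box sizes must be >= 1")
    counts = np.array([_box_count(data, s) for s in sizes], dtype=float)
    logs, logn = np.log(sizes), np.log(counts)
    slope, intercept = np.polyfit(logs, logn, 1)
    pred = slope * logs + intercept
    ss_res = float(np.sum((logn - pred) ** 2))
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return BoxCountFit(float(-slope), r2, np.asarray(sizes), counts.astype(int))


def series_complexity(masks, box_sizes=None) -> FractalResult:
    """Per-frame box-counting dimension of a time-ordered mask series plus
    the arithmetic mean across frames (the per-cell complexity value)."""
    if len(masks) < 1:
        raise DataError("need at least one mask")
    fits = [fractal_dimension(m, box_sizes) for m in masks]
    dims = [f.dimension for f in fits]
    return FractalResult(dims, float(np.mean(dims)), [f.r2 for f in fits])


def motility_index(masks, stack_volume_um3: float) -> MotilitySeries:
    """Motility of a time-ordered binary mask series.

    The pairwise coefficient is the number of pixels differing between
    consecutive masks; the global coefficient is their sum over all pairs;
    the normalized index divides by the stack volume (per um^3).
    """
    if len(masks) < 2:
        raise DataError("need at least two masks")
    if stack_volume_um3 <= 0:
        raise DataError("stack volume must be positive")
    arrays = [_as_bool_array(m) for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise DataError("all masks must share a shape")
    pairwise = [int(np.count_nonzero(a ^ b)) for a, b in zip(arrays[:-1], arrays[1:])]
    total = int(sum(pairwise))
    return MotilitySeries(pairwise, total, total / stack_volume_um3, float(stack_volume_um3))
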