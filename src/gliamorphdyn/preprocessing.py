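"""Image conditioning for single-cell two-photon time-lapse volumes.

The in vivo analysis chain starts from a 4D stack (T x Z x Y x X) that
drifts slowly in all three spatial axes. Each volume is rigidly registered
to a reference volume using the peak of the FFT-based circular
cross-correlation (integer-pixel shifts), collapsed to a 2D image by a
per-pixel standard-deviation projection over z, and binarized. The binary
projections feed both the fractal complexity measure and the motility
index (module :mod:`gliamorphdyn.dynamics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft
from skimage.filters import threshold_otsu

from .errors import DataError, DegenerateInputError

__all__ = [
    "TimeLapseStack",
    "Projection2D",
    "BinaryMask",
    "register_stack",
    "sd_projection",
    "binarize",
    "project_and_binarize",
    "read_stack",
    "write_stack",
]


@dataclass
class TimeLapseStack:
    """A registered or raw 4D fluorescence time-lapse.

    Attributes
    ----------
    data:
        T x Z x Y x X intensity raster.
    voxel_um:
        (z, y, x) voxel dimensions in micrometres.
    frame_interval_s:
        Seconds between consecutive volumes.
    """

    data: np.ndarray
    voxel_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval_s: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"stack must be T x Z x Y x X, got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise DataError("stack needs at least one frame")
        if any(v <= 0 for v in self.voxel_um):
            raise DataError("voxel dimensions must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def volume_um3(self) -> float:
        """Physical volume of the imaged field in cubic micrometres."""
        z, y, x = self.data.shape[1:]
        vz, vy, vx = self.voxel_um
        return float(z * vz * y * vy * x * vx)


@dataclass
class Projection2D:
    """Per-pixel standard deviation across z, collapsing a volume to 2D."""

    data: np.ndarray
    pixel_um: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("projection must be 2D")


@dataclass
class BinaryMask:
    """Binarized projection with the threshold that produced it."""

    data: np.ndarray
    pixel_um: tuple[float, float] = (1.0, 1.0)
    threshold_used: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise DataError("mask must be 2D")


def shift_zero_fill(arr: np.ndarray, shift: tuple[int, ...]) -> np.ndarray:
    """Translate ``arr`` by integer ``shift`` (one entry per axis), filling
    vacated voxels with zeros rather than wrapping them around."""
    if len(shift) != arr.ndim:
        raise DataError("shift length must match array dimensionality")
    out = np.zeros_like(arr)
    src: list[slice] = []
    dst: list[slice] = []
    for n, s in zip(arr.shape, shift):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def estimate_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[int, ...]:
    """Integer displacement of ``moving`` relative to ``reference`` from the
    peak of their FFT-based circular cross-correlation.

    If ``moving == np.roll(reference, s)`` the returned shift is ``s``
    (components above N/2 are reported as negative displacements).
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise DataError("reference and moving volumes must share a shape")
    if not np.any(reference) or not np.any(moving):
        raise DegenerateInputError("cross-correlation of an all-zero volume is undefined")
    return _shift_from_conj_fft(np.conj(fft.rfftn(reference)), moving)


def _shift_from_conj_fft(conj_ref_fft: np.ndarray, moving: np.ndarray) -> tuple[int, ...]:
    cc = fft.irfftn(conj_ref_fft * fft.rfftn(moving), s=moving.shape)
    peak = np.unravel_index(int(np.argmax(cc)), cc.shape)
    return tuple(int(p - n if p > n // 2 else p) for p, n in zip(peak, cc.shape))


def register_stack(
    stack: TimeLapseStack, reference_index: int = 0
) -> tuple[TimeLapseStack, list[tuple[int, int, int]]]:
    """Rigidly register every volume of ``stack`` to a reference volume.

    Each volume is translated by the negative of its estimated (dz, dy, dx)
    displacement; voxels shifted into the field are zero-filled. The shift
    of the reference frame is (0, 0, 0) by construction.
    """
    if not 0 <= reference_index < stack.n_frames:
        raise DataError("reference_index out of range")
    ref = stack.data[reference_index]
    if not np.any(ref):
        raise DegenerateInputError("reference volume is all zero")
    conj_ref_fft = np.conj(fft.rfftn(np.asarray(ref, dtype=float)))
    registered = np.empty_like(stack.data)
    shifts: list[tuple[int, int, int]] = []
    for t in range(stack.n_frames):
        if t == reference_index:
            registered[t] = stack.data[t]
            shifts.append((0, 0, 0))
            continue
        if not np.any(stack.data[t]):
            raise DegenerateInputError(f"frame {t} is all zero")
        s = _shift_from_conj_fft(conj_ref_fft, np.asarray(stack.data[t], dtype=float))
        shifts.append(s)  # type: ignore[arg-type]
        registered[t] = shift_zero_fill(stack.data[t], tuple(-c for c in s))
    out = TimeLapseStack(registered, stack.voxel_um, stack.frame_interval_s)
    return out, shifts


def sd_projection(volume: np.ndarray, pixel_um: tuple[float, float] = (1.0, 1.0)) -> Projection2D:
    """Per-pixel population standard deviation (divisor Z) across the z axis."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or volume.size == 0:
        raise DataError("volume must be a non-empty Z x Y x X raster")
    return Projection2D(volume.std(axis=0, ddof=0), pixel_um)


def binarize(
    projection: Projection2D,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    allow_empty: bool = False,
) -> BinaryMask:
    """Threshold a projection into foreground/background.

    ``method='otsu'`` picks the threshold maximising between-class variance
    per image; ``method='fixed'`` uses ``fixed_threshold``. Foreground is
    strictly above the threshold. A constant image is degenerate: it raises
    unless ``allow_empty`` is set, in which case an empty mask is returned
    with a warning.
    """
    img = projection.data
    if img.size == 0:
        raise DataError("projection is empty")
    if method == "fixed":
        if fixed_threshold is None:
            raise DataError("fixed binarization requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            if allow_empty:
                warnings.warn("constant image: returning empty mask", stacklevel=2)
                return BinaryMask(np.zeros_like(img, dtype=bool), projection.pixel_um, float(img.flat[0]))
            raise DegenerateInputError("cannot Otsu-threshold a constant image")
        thr = float(threshold_otsu(img))
    else:
        raise DataError(f"unknown binarization method {method!r}")
    return BinaryMask(img > thr, projection.pixel_um, thr)


def project_and_binarize(stack: TimeLapseStack, **binarize_kw) -> list[BinaryMask]:
    """SD-project and binarize every frame of a (registered) stack."""
    pix = (stack.voxel_um[1], stack.voxel_um[2])
    return [binarize(sd_projection(vol, pix), **binarize_kw) for vol in stack.data]


def write_stack(stack: TimeLapseStack, path) -> None:
    """Write a stack as an ImageJ-compatible TZYX multi-page TIFF."""
    import tifffile

    vz, vy, vx = stack.voxel_um
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={
            "axes": "TZYX",
            "spacing": vz,
            "unit": "um",
            "finterval": stack.frame_interval_s,
        },
    )


def read_stack(path, voxel_um=(1.0, 1.0, 1.0), frame_interval_s=30.0) -> TimeLapseStack:
    """Read a TZYX TIFF written by :func:`write_stack`.

    Voxel size and frame interval fall back to the arguments when the file
    carries no ImageJ metadata.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.imagej_metadata or {}
    if data.ndim == 3:  # single frame
        data = data[None]
    vz = float(meta.get("spacing", voxel_um[0]))
    dt = float(meta.get("finterval", frame_interval_s))
    return TimeLapseStack(data, (vz, voxel_um[1], voxel_um[2]), dt)
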