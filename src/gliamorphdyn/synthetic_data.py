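"""Ground-truthed synthetic inputs for the whole pipeline.

Three input classes are emulated:

* 2D confocal-like rasters of single ramified microglia, built from an
  explicit branch topology (soma disk plus recursively branching
  processes) so that every root, segment, junction rank and process
  endpoint is known exactly;
* 4D time-lapse stacks of one such cell whose process tips toggle at a
  programmed rate while the whole volume drifts by a known integer vector
  per frame;
* single-channel EEG traces with the spectral signature of a vigilance
  state: broadband wake activity (half-maximum spectral width ~10 Hz),
  slow bichromatic 0.5/2 Hz oscillations under ketamine/xylazine, and
  near-isoelectric burst suppression under pentobarbital.

Everything is driven by explicit seeds and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .errors import ConfigError, DataError
from .preprocessing import TimeLapseStack, shift_zero_fill

__all__ = [
    "CellSpec",
    "TimelapseSpec",
    "EEGPreset",
    "ArborTruth",
    "GroundTruth",
    "EEG_STATES",
    "generate_cell_image",
    "generate_timelapse",
    "generate_eeg",
    "generate_paired_cohort",
]

SOMA_INTENSITY = 200.0
BRANCH_INTENSITY = 120.0

EEG_STATES = ("wake", "ketamine_xylazine", "pentobarbital")


@dataclass(frozen=True)
class CellSpec:
    """Parameters of one synthetic ramified cell.

    Defaults give a mid-sized arbor: four primary branches, ~70% chance of
    bifurcating per segment up to three branch orders, at the pixel size of
    a 200 um field imaged at ~520 px.
    """

    n_roots: int = 4
    branch_prob: float = 0.7
    max_depth: int = 3
    segment_len_um: float = 12.0
    soma_radius_um: float = 4.0
    pixel_size_um: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ConfigError("n_roots must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigError("branch_prob must be in [0, 1]")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if min(self.segment_len_um, self.soma_radius_um, self.pixel_size_um) <= 0:
            raise ConfigError("all lengths must be positive")


@dataclass(frozen=True)
class TimelapseSpec:
    """Parameters of a motile, drifting time-lapse of one cell.

    ``motility_level`` is the expected fraction of arbor pixels toggled
    (tip extension/retraction) between consecutive frames; ``drift_px`` is
    the integer (z, y, x) displacement added every frame.
    """

    cell: CellSpec = field(default_factory=CellSpec)
    n_frames: int = 10
    n_slices: int = 8
    frame_interval_s: float = 30.0
    motility_level: float = 0.12
    drift_px: tuple[int, int, int] = (0, 0, 0)
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.n_slices < 1:
            raise ConfigError("n_slices must be >= 1")
        if not 0.0 <= self.motility_level <= 1.0:
            raise ConfigError("motility_level must be in [0, 1]")
        if len(self.drift_px) != 3 or any(d != int(d) for d in self.drift_px):
            raise ConfigError("drift_px must be three integers")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class EEGPreset:
    """One anesthesia-state EEG recipe.

    wake
        white noise shaped by a 4th-order Butterworth band-pass
        (``wake_band``), calibrated so the averaged-periodogram spectral
        width at half maximum comes out at ~10 Hz.
    ketamine_xylazine
        two dominant sinusoids (0.5 Hz stable, 2 Hz linearly decaying to
        ``kx_decay_end_frac`` of its initial amplitude) over low noise.
    pentobarbital
        near-isoelectric baseline with sporadic high-amplitude
        oscillatory bursts (burst suppression).
    """

    state: str = "wake"
    fs_hz: float = 1000.0
    duration_s: float = 120.0
    seed: int = 0
    # wake; the upper band edge sits above the nominal 10 Hz width target
    # because the Hann/Welch estimate with 3-bin smoothing biases the
    # measured half-maximum width downward (the noisy spectral maximum
    # raises the half-max threshold and smoothing erodes the band edges)
    wake_band: tuple[float, float] = (0.5, 12.5)
    wake_sigma_uv: float = 40.0
    # ketamine/xylazine
    kx_freqs_hz: tuple[float, float] = (0.5, 2.0)
    kx_amplitudes_uv: tuple[float, float] = (300.0, 250.0)
    kx_decay_end_frac: float = 0.25
    kx_noise_uv: float = 15.0
    # pentobarbital
    pb_baseline_uv: float = 5.0
    pb_burst_rate_hz: float = 0.12
    pb_burst_duration_s: float = 1.0
    pb_burst_amplitude_uv: float = 250.0
    pb_burst_freq_hz: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if self.state not in EEG_STATES:
            raise ConfigError(f"unknown EEG state {self.state!r}; choose from {EEG_STATES}")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("fs_hz and duration_s must be positive")


@dataclass
class ArborTruth:
    """Exact branch topology of a generated cell (micrometre coordinates,
    soma centre at the origin)."""

    n_roots: int
    segments: list[dict]          # depth, start_um, end_um, length_um, terminal
    nodes: list[dict]             # rank, pos_um
    endpoints_um: list[tuple[float, float]]
    attachments_um: list[tuple[float, float]]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_nodes_rank(self, rank: int) -> int:
        return sum(1 for n in self.nodes if n["rank"] == rank)

    @property
    def total_length_um(self) -> float:
        return float(sum(s["length_um"] for s in self.segments))


@dataclass
class GroundTruth:
    """Everything a downstream test needs to score a recovered result."""

    graph: ArborTruth
    soma_center_px: tuple[int, int] = (0, 0)
    soma_radius_um: float = 0.0
    pixel_size_um: float = 1.0
    drift_px: tuple[int, int, int] = (0, 0, 0)
    motility_level: float = 0.0


# ---------------------------------------------------------------------------
# cell geometry


def _build_arbor(spec: CellSpec, rng: np.random.Generator) -> ArborTruth:
    """Sample the branch topology in physical (micrometre) coordinates.

    Primary branches leave the soma at evenly spaced, slightly jittered
    angles; each segment bifurcates with probability ``branch_prob`` while
    below ``max_depth``, children deviating from the parent direction by
    20-50 degrees on either side. Segment length tapers by 0.8 per order so
    distal arbors stay compact.
    """
    segments: list[dict] = []
    nodes: list[dict] = []
    endpoints: list[tuple[float, float]] = []
    attachments: list[tuple[float, float]] = []
    taper = 0.8

    def grow(start: tuple[float, float], angle: float, depth: int) -> None:
        length = spec.segment_len_um * taper ** (depth - 1) * rng.uniform(0.85, 1.15)
        end = (start[0] + length * math.sin(angle), start[1] + length * math.cos(angle))
        branch = depth < spec.max_depth and rng.random() < spec.branch_prob
        segments.append(
            {
                "depth": depth,
                "start_um": start,
                "end_um": end,
                "length_um": length,
                "terminal": not branch,
            }
        )
        if branch:
            nodes.append({"rank": depth, "pos_um": end})
            dev = math.radians(rng.uniform(20.0, 50.0))
            grow(end, angle + dev, depth + 1)
            grow(end, angle - dev, depth + 1)
        else:
            endpoints.append(end)

    jitter = 0.25 * (2 * math.pi / spec.n_roots)
    for k in range(spec.n_roots):
        angle = 2 * math.pi * k / spec.n_roots + rng.uniform(-jitter, jitter)
        start = (
            spec.soma_radius_um * math.sin(angle),
            spec.soma_radius_um * math.cos(angle),
        )
        attachments.append(start)
        grow(start, angle, 1)

    return ArborTruth(spec.n_roots, segments, nodes, endpoints, attachments)


def _arbor_reach_um(spec: CellSpec) -> float:
    taper = 0.8
    reach = spec.soma_radius_um
    reach += sum(spec.segment_len_um * 1.15 * taper**d for d in range(spec.max_depth))
    return reach


def _render(
    truth: ArborTruth, spec: CellSpec, shape: tuple[int, int] | None
) -> tuple[np.ndarray, tuple[int, int]]:
    px = spec.pixel_size_um
    if shape is None:
        from scipy.fft import next_fast_len

        half = int(math.ceil(_arbor_reach_um(spec) / px)) + 6
        side = next_fast_len(2 * half + 1)  # keeps downstream FFTs cheap
        shape = (side, side)
    center = (shape[0] // 2, shape[1] // 2)

    def to_px(p: tuple[float, float]) -> tuple[int, int]:
        return (int(round(center[0] + p[0] / px)), int(round(center[1] + p[1] / px)))

    margin = 2
    for p in [s["end_um"] for s in truth.segments] + truth.endpoints_um:
        r, c = to_px(p)
        if not (margin <= r < shape[0] - margin and margin <= c < shape[1] - margin):
            raise DataError("rendered cell exceeds the raster; enlarge shape or shrink the cell")

    branch_mask = np.zeros(shape, dtype=bool)
    for seg in truth.segments:
        r0, c0 = to_px(seg["start_um"])
        r1, c1 = to_px(seg["end_um"])
        rr, cc = draw_line(r0, c0, r1, c1)
        branch_mask[rr, cc] = True
    branch_mask = dilation(branch_mask, disk(1))

    image = np.zeros(shape, dtype=np.float32)
    image[branch_mask] = BRANCH_INTENSITY
    rr, cc = draw_disk(center, max(spec.soma_radius_um / px, 1.5), shape=shape)
    image[rr, cc] = SOMA_INTENSITY
    return image, center


def generate_cell_image(
    spec: CellSpec, shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one connected synthetic cell and return it with its ground truth.

    The raster holds a filled soma disk (intensity 200) and 2-3 px wide
    branch polylines (intensity 120) on a zero background. When ``shape``
    is omitted a raster just large enough for the arbor is chosen; a cell
    that would not fit the given raster raises :class:`DataError`.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _build_arbor(spec, rng)
    image, center = _render(truth, spec, shape)
    gt = GroundTruth(
        graph=truth,
        soma_center_px=center,
        soma_radius_um=spec.soma_radius_um,
        pixel_size_um=spec.pixel_size_um,
    )
    return image, gt


# ---------------------------------------------------------------------------
# time-lapse


def _tip_candidates(truth: ArborTruth, spec: CellSpec, shape: tuple[int, int],
                    center: tuple[int, int]) -> np.ndarray:
    """Pixels eligible for motility toggling: the distal 30% of every
    terminal segment, dilated so retraction and extension both have room."""
    px = spec.pixel_size_um
    mask = np.zeros(shape, dtype=bool)
    for seg in truth.segments:
        if not seg["terminal"]:
            continue
        (y0, x0), (y1, x1) = seg["start_um"], seg["end_um"]
        ys, xs = y0 + 0.7 * (y1 - y0), x0 + 0.7 * (x1 - x0)
        r0, c0 = int(round(center[0] + ys / px)), int(round(center[1] + xs / px))
        r1, c1 = int(round(center[0] + y1 / px)), int(round(center[1] + x1 / px))
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    mask = dilation(mask, disk(2))
    return np.argwhere(mask)


def generate_timelapse(spec: TimelapseSpec) -> tuple[TimeLapseStack, GroundTruth]:
    """Generate a drifting, noisy time-lapse stack of one motile cell.

    Frame t is frame t-1 with ``round(motility_level * n_arbor_pixels)``
    tip-region pixels toggled on/off, embedded along z with a smooth
    intensity profile, shifted by the cumulative drift, and corrupted with
    additive clipped Gaussian noise. Drift that would push the cell out of
    the raster raises :class:`DataError`.
    """
    rng = np.random.default_rng(spec.seed)
    image, gt = generate_cell_image(spec.cell)
    max_cum = tuple(abs(int(d)) * (spec.n_frames - 1) for d in spec.drift_px)

    # pad laterally so the drifting cell never clips the field of view
    if max_cum[1] or max_cum[2]:
        image = np.pad(image, ((max_cum[1], max_cum[1]), (max_cum[2], max_cum[2])))
        gt.soma_center_px = (gt.soma_center_px[0] + max_cum[1], gt.soma_center_px[1] + max_cum[2])
    shape = image.shape
    candidates = _tip_candidates(gt.graph, spec.cell, shape, gt.soma_center_px)
    n_arbor = int(np.count_nonzero(image))
    n_toggle = int(round(spec.motility_level * n_arbor))
    if n_toggle > len(candidates):
        raise ConfigError(
            f"motility_level {spec.motility_level} needs {n_toggle} toggleable pixels "
            f"but only {len(candidates)} tip pixels exist"
        )

    # the cell occupies the central half of the z range with a smooth
    # profile, leaving margins so axial drift stays inside the volume;
    # the SD projection stays proportional to the 2D image
    z0 = spec.n_slices // 4
    z1 = spec.n_slices - z0
    zprof = np.zeros(spec.n_slices)
    band = np.arange(z0, z1)
    zprof[band] = np.sin(math.pi * (band - z0 + 0.5) / (z1 - z0)) ** 2
    if max_cum[0] > z0:
        raise DataError("cumulative axial drift would push the cell off the raster")

    frames = np.empty((spec.n_frames, spec.n_slices, *shape), dtype=np.float32)
    current = image.copy()
    for t in range(spec.n_frames):
        if t > 0 and n_toggle > 0:
            idx = rng.choice(len(candidates), size=n_toggle, replace=False)
            rr, cc = candidates[idx, 0], candidates[idx, 1]
            on = current[rr, cc] > 0
            current[rr, cc] = np.where(on, 0.0, BRANCH_INTENSITY)
        vol = current[None, :, :] * zprof[:, None, None]
        cum = tuple(int(d) * t for d in spec.drift_px)
        if any(cum):
            vol = shift_zero_fill(vol, cum)
        if spec.noise_sigma > 0:
            vol = np.clip(vol + rng.normal(0.0, spec.noise_sigma, vol.shape), 0.0, None)
        frames[t] = vol

    stack = TimeLapseStack(
        frames,
        voxel_um=(1.0, spec.cell.pixel_size_um, spec.cell.pixel_size_um),
        frame_interval_s=spec.frame_interval_s,
    )
    gt.drift_px = tuple(int(d) for d in spec.drift_px)
    gt.motility_level = spec.motility_level
    return stack, gt


def generate_paired_cohort(
    n_cells: int,
    pre_spec: TimelapseSpec,
    effect: float,
    seed: int = 0,
) -> list[dict]:
    """Independent pre/post time-lapse pairs of ``n_cells`` distinct cells.

    The post-condition motility level is ``pre * (1 + effect)``; an effect
    of -0.17 reproduces the direction and size of the ketamine/xylazine
    motility reduction. Returns one dict per cell with keys
    ``pre``, ``post`` (stacks) and ``pre_truth``, ``post_truth``.
    """
    if n_cells < 2:
        raise ConfigError("n_cells must be >= 2")
    post_level = pre_spec.motility_level * (1.0 + effect)
    if not 0.0 <= post_level <= 1.0:
        raise ConfigError("effect pushes motility_level outside [0, 1]")
    rng = np.random.default_rng(seed)
    cohort: list[dict] = []
    for _ in range(n_cells):
        cell_seed, s_pre, s_post = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
        cell = replace(pre_spec.cell, seed=cell_seed)
        spec_pre = replace(pre_spec, cell=cell, seed=s_pre)
        spec_post = replace(pre_spec, cell=cell, seed=s_post, motility_level=post_level)
        pre_stack, pre_truth = generate_timelapse(spec_pre)
        post_stack, post_truth = generate_timelapse(spec_post)
        cohort.append(
            {"pre": pre_stack, "post": post_stack, "pre_truth": pre_truth, "post_truth": post_truth}
        )
    return cohort


# ---------------------------------------------------------------------------
# EEG


def _wake(preset: EEGPreset, rng: np.random.Generator, n: int) -> np.ndarray:
    # pad generously so slow band-pass transients never reach the record
    pad = int(10 * preset.fs_hz)
    noise = rng.normal(0.0, preset.wake_sigma_uv, n + 2 * pad)
    sos = butter(4, preset.wake_band, btype="bandpass", output="sos", fs=preset.fs_hz)
    return sosfiltfilt(sos, noise)[pad : pad + n]


def _ketamine_xylazine(preset: EEGPreset, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / preset.fs_hz
    f1, f2 = preset.kx_freqs_hz
    a1, a2 = preset.kx_amplitudes_uv
    phase1, phase2 = rng.uniform(0, 2 * math.pi, 2)
    # slow component stable; faster component fades over the record
    decay = np.linspace(1.0, preset.kx_decay_end_frac, n)
    sig = a1 * np.sin(2 * math.pi * f1 * t + phase1)
    sig = sig + a2 * decay * np.sin(2 * math.pi * f2 * t + phase2)
    if preset.kx_noise_uv > 0:
        sos = butter(4, (0.5, 45.0), btype="bandpass", output="sos", fs=preset.fs_hz)
        sig = sig + sosfiltfilt(sos, rng.normal(0.0, preset.kx_noise_uv, n))
    return sig


def _pentobarbital(preset: EEGPreset, rng: np.random.Generator, n: int) -> np.ndarray:
    sig = rng.normal(0.0, preset.pb_baseline_uv, n)
    burst_len = int(round(preset.pb_burst_duration_s * preset.fs_hz))
    n_bursts = rng.poisson(preset.pb_burst_rate_hz * preset.duration_s)
    window = np.hanning(burst_len)
    t = np.arange(burst_len) / preset.fs_hz
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(n - burst_len, 1)))
        f = rng.uniform(*preset.pb_burst_freq_hz)
        phase = rng.uniform(0, 2 * math.pi)
        amp = preset.pb_burst_amplitude_uv * rng.uniform(0.6, 1.0)
        sig[start : start + burst_len] += amp * window * np.sin(2 * math.pi * f * t + phase)
    return sig


def generate_eeg(preset: EEGPreset):
    """Generate a synthetic single-channel EEG trace for one vigilance state.

    Returns an :class:`~gliamorphdyn.eeg.EEGTrace` of
    ``duration_s * fs_hz`` samples in microvolts.
    """
    from .eeg import EEGTrace

    rng = np.random.default_rng(preset.seed)
    n = int(round(preset.duration_s * preset.fs_hz))
    if preset.state == "wake":
        samples = _wake(preset, rng, n)
    elif preset.state == "ketamine_xylazine":
        samples = _ketamine_xylazine(preset, rng, n)
    else:
        samples = _pentobarbital(preset, rng, n)
    return EEGTrace(np.asarray(samples, dtype=float), preset.fs_hz)
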