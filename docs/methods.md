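# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the problem sizes the test suite runs at.

## Image conditioning (preprocessing)

**Registration.** Each volume of a time-lapse stack is registered to a
reference volume (the first, by default) by the location of the maximum
of the FFT-based circular cross-correlation; shifts are integer voxels,
with no subpixel refinement. The moving volume is translated by the
negative of the estimated shift and vacated voxels are **zero-filled**,
never wrapped — rolled-in data would fabricate signal at the borders of
a cell ROI. Circular correlation is exact for cyclic shifts; for real
drift it is an approximation whose error grows with the fraction of
signal leaving the field, which is why the synthetic generator keeps the
cell inside lateral and axial margins (below). An all-zero reference or
frame is a degenerate input and raises.

**SD projection.** A volume is collapsed to 2D by the per-pixel
*population* standard deviation across z (divisor Z). The divisor is a
convention that had to be fixed; it only rescales the projection and
cannot change any downstream binary mask by more than the threshold
quantization.

**Binarization.** Default is Otsu's threshold computed per image
(parameter-free, recorded in the mask's `threshold_used`); a fixed
threshold is available. Foreground is strictly above the threshold.
Constant images raise unless the caller opts into an empty mask.

## In vivo metrics (dynamics)

**Box-counting dimension.** Occupied s × s boxes are counted on a grid
anchored at the image origin, for box sizes defaulting to powers of two
from 2 px to a quarter of the shorter image side (at least three sizes
are required). The dimension is the negative slope of the least-squares
fit of log N(s) on log s; the fit R² is reported per frame. The
estimator is exact on dyadic self-similar sets (filled square → 2,
line → 1, Sierpinski triangle → log 3 / log 2) because the counts follow
the similarity law exactly at power-of-two scales. A cell's complexity
is the arithmetic mean of per-frame dimensions.

**Motility index.** "Subtraction" of consecutive binarized projections
is interpreted as the symmetric difference: the pairwise coefficient is
the count of pixels whose binary value changes between consecutive
frames; the global coefficient is the **sum over all frame pairs** (not
a per-pair average — the alternative reading; with this convention
absolute values scale with frame count); the normalized index divides by
the physical stack volume, i.e. field area × z-extent from the voxel
metadata, in μm³. Consequently only contrasts (paired, grouped) are
comparable across acquisitions with different geometry — which is how
the metrics are used.

## Ex vivo morphometry

**Segmentation** is dual-threshold: the arbor is the connected component
above an Otsu threshold on the whole image; the soma is the bright core
above a second Otsu threshold restricted to foreground intensities,
cleaned by morphological opening (radius 2 px) and a minimum area
(8 μm²). The cytoplasm mask is the soma plus the arbor pixels around the
skeleton paths from the soma boundary to each primary branch's first
junction. Nesting soma ⊆ cytoplasm ⊆ arbor is asserted on construction.
Cells whose arbor touches the image border are flagged.

**Skeleton graph.** The arbor is skeletonized to a 1-px centerline
(8-connectivity); skeleton pixels inside the soma are removed; the
pixels adjacent to the soma boundary are the root attachments. Adjacent
junction pixels are clustered into single junction nodes. Corridors
between nodes become segments. Two cleanups run before counting:
endpoint spurs shorter than 1.5 μm attached to a junction are pruned
(sub-resolution skeletonization artifacts), and any junction left with
exactly two incident segments is dissolved into a single segment.
Skeleton fragments with no path to the soma are dropped with a warning.

**Segment length** is geodesic, measured by resampling each skeleton
path every 4 px and summing chord lengths. Summing raw 1 / √2 pixel
steps was rejected: it overestimates rasterized straight lines by up to
~8% (staircase metrication), while the chord sum is accurate to <1% for
straight and gently curved processes (validated against generator truth:
±0.7 μm on 50 μm processes across orientations).

**Node rank** is topological: breadth-first from the root attachments,
the k-th junction on a path from the soma has rank k. Junctions deeper
than rank 2 are counted but excluded from the complexity index, which
uses the rank-1/rank-2 convention:
CI = n_segments × (n_rank1 + n_rank2) / n_roots (dimensionless, exact
integer arithmetic). An alternative per-ramification reading of the CI
prose exists; the whole-cell formula is implemented. **CEA** is the
convex hull of the endpoint coordinates (shoelace area of the hull
polygon, μm²); fewer than three or collinear endpoints give 0 with a
warning. A concave (alpha-shape) variant was considered and not
implemented; the hull is the stated default reading of "linking the
extremities".

## EEG profiling

* Band-pass: zero-phase (forward–backward) 4th-order Butterworth in
  second-order-section form (transfer-function form is numerically
  unstable for narrow low-frequency bands at 1 kHz).
* Power spectrum: Welch averaged periodogram, 4 s Hann segments, 50%
  overlap — the segment length mirrors the 4 s analysis window of the
  time-frequency representation; the estimator itself is a package
  choice. Frequency resolution 0.25 Hz.
* WHM (width at mid-height): on the 3-bin moving-average smoothed
  spectrum, the contiguous frequency span around the global maximum
  where power ≥ half the maximum, with linear interpolation of the two
  crossing points. Width-at-half-maximum is ill-defined on raw
  periodograms, hence the smoothing.
* Amplitude distribution: normalized histogram (101 bins by default)
  plus Fisher excess kurtosis. Burst suppression shows up as a sharp
  near-zero peak with long wings, i.e. large excess kurtosis.
* Spectrogram: Hann-tapered FFT magnitude per 4 s window stepped by
  0.5 s (time bins = floor((T − 4)/0.5) + 1), log10 amplitude normalized
  to the per-record maximum for display.

EEG I/O is two-column CSV (time_s, amplitude_uV); the sampling rate is
inferred from the median time step on read.

## Statistics

The cell is the statistical unit (matching the paired design of n = 18
cells). Paired metrics use the two-tailed paired t-test; the
d'Agostino–Pearson screen runs on the paired differences, is recorded,
and never gates the test (it needs n ≥ 8; smaller samples record a
note). Group metrics use Kruskal–Wallis (tie-corrected H) with a
Shapiro–Wilk screen per group, followed by pairwise two-sided
Mann–Whitney post-hoc tests with Sidak adjustment
p_adj = 1 − (1 − p)^m; both the adjusted p-values and the
Sidak-adjusted per-comparison alpha 1 − (1 − α)^(1/m) are reported,
since "alpha adjusted for the number of comparisons" and Sidak p
correction are both defensible readings. Summaries report sample SD
(divisor n − 1) and SEM. Alpha is 0.05 throughout.

## Synthetic-data generator

**Cells.** An arbor is a tree in physical (μm) coordinates: `n_roots`
primary branches leave the soma at evenly spaced, jittered angles; each
segment bifurcates with probability `branch_prob` while below
`max_depth`, children deviating 20–50° to either side of the parent
direction (within the ±60° envelope that produces plausible radial
arbors without anatomical modeling); segment length tapers by 0.8 per
order with ±15% variation. Rendering draws 1-px polylines thickened by a
radius-1 disk (2–3 px wide) at `pixel_size_um` (default 0.4 μm/px, the
scale of a 200 μm field at ~520 px), soma as a filled disk, branch
intensity 120 and soma intensity 200 on a zero background — chosen so
dual-threshold segmentation and skeletonization recover the drawn
topology cleanly. Canvas sides are rounded up to FFT-friendly lengths.
Ground truth records every root, segment, ranked junction and endpoint.
Graph recovery from noise-free renders is pixel-exact up to 4 roots ×
depth 3 (the default regime); denser arbors (5 roots × depth 3, or
depth 4) occasionally self-collide and can differ by ±1 segment.

**Time-lapses.** Frame t is frame t−1 with `round(motility_level ×
n_arbor_pixels)` pixels toggled on/off among candidates in the distal
30% of terminal segments (dilated by 2 px so extension has room) —
motility is confined to process tips, where microglial dynamics
concentrate. The 2D cell occupies the central half of the z range with a
smooth sin² intensity profile (margins absorb axial drift; the SD
projection stays proportional to the cell image); the volume is shifted
by the cumulative integer drift per frame with zero fill (the raster is
pre-padded laterally by the total drift so the cell never clips), then
clipped additive Gaussian noise (default σ = 4 intensity units, ~3% of
branch intensity) is applied. Drift that would push the cell off the
raster raises. Defaults: 10 frames, 8 slices, 30 s frame interval,
motility level 0.12.

**Paired cohorts** draw independent cells per subject; the post
condition multiplies the motility level by (1 + effect). The −17%
default effect reproduces the relative motility reduction reported
under ketamine/xylazine (714.82 / 860.73 − 1).

**EEG presets.** wake: white noise shaped by a 4th-order Butterworth
band-pass, with 10 s of padding trimmed so filter transients never
reach the record. The band (0.5–12.5 Hz) is calibrated so the realized
WHM through the prescribed estimator (Welch + 3-bin smoothing) comes
out at the 10 Hz wake signature: the nominal half-power width reads
~1.5 Hz too narrow through that measure because the noisy spectral
maximum raises the half-max threshold and smoothing erodes the band
edges. A strict 1/f spectrum was rejected for the wake preset: its
power halves within one octave of the peak, so it cannot carry a 10 Hz
half-maximum width. ketamine_xylazine: 0.5 Hz (stable, 300 μV) and 2 Hz
(250 μV, decaying linearly to 25% over the record) sinusoids with
random phases over low band-limited noise — the 2 Hz decay rate is a
free parameter; the generator makes the fade linear. pentobarbital:
near-isoelectric Gaussian baseline (5 μV) with Poisson-timed (0.12 Hz)
1 s Hann-windowed oscillatory bursts (2–8 Hz, ~250 μV). All generators
are bit-reproducible under a fixed seed.

**What the generator does not emulate:** optics (no PSF, no depth
attenuation), photon statistics (noise is additive Gaussian, not
Poisson), microglial biophysics (toggling is not a migration model),
EEG nonstationarity beyond the programmed 2 Hz fade, and EMG. Passing
tests therefore demonstrate that the *computational chain* is correct
and sensitive at realistic geometry and noise, not that it is robust to
every optical artifact of real two-photon data.

## Problem sizes in the test suite

Simulation-heavy checks run on a desk-scale time-lapse configuration —
0.6 μm/px cells (≈ 120 px rasters), 6 frames × 6 slices — chosen so a
full generate-register-project-binarize-measure pass costs ~50 ms per
stack while preserving the motility model and noise level. At this
scale: programmed motility levels (0.04–0.20, 20 replicates each) map
to recovered indices with Spearman ρ > 0.9; a −17% paired effect at
n = 18 cells is detected in ≥ 80% of 50 cohort replicates while
zero-effect cohorts stay null ≥ 90% of the time; and the paired t-test
holds 5% ± 1.5% type-I error over 1000 null replicates. Registration is
validated against an exhaustive-search oracle on random 16³ volumes and
against injected integer drifts on noise-free stacks, where recovery is
exact.

## Known limitations

* Integer-shift rigid registration only; no subpixel or nonrigid motion.
* The skeleton-graph contraction assumes a tree-like arbor; loops
  created by touching processes are kept but ranks follow the BFS tree.
* Morphometry is 2D, matching the published metric definitions; no 3D
  section morphometry.
* The motility index counts changed pixels without decomposing extension
  vs retraction or tracking filopodia.
* EDF input is not supported; EEG I/O is CSV.
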