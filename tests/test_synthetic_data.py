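import numpy as np
import pytest
from scipy.stats import kurtosis

from gliamorphdyn.errors import ConfigError, DataError
from gliamorphdyn.eeg import bandpass, dominant_low_peaks, power_spectrum
from gliamorphdyn.synthetic_data import (
    CellSpec,
    EEGPreset,
    TimelapseSpec,
    generate_cell_image,
    generate_eeg,
    generate_paired_cohort,
    generate_timelapse,
)


class TestCellGenerator:
    @pytest.mark.parametrize(
        "spec,expected",  # (n_roots, n_segments, rank1, rank2)
        [
            (CellSpec(n_roots=1, branch_prob=0, max_depth=1, seed=0), (1, 1, 0, 0)),
            (CellSpec(n_roots=4, branch_prob=1, max_depth=2, seed=0), (4, 12, 4, 0)),
            (CellSpec(n_roots=2, branch_prob=1, max_depth=3, seed=0), (2, 14, 2, 4)),
        ],
    )
    def test_deterministic_topology_counts(self, spec, expected):
        """branch_prob 0/1 makes the arbor a deterministic (non-)binary tree
        whose segment and node counts follow in closed form."""
        _, truth = generate_cell_image(spec)
        g = truth.graph
        assert (g.n_roots, g.n_segments, g.n_nodes_rank(1), g.n_nodes_rank(2)) == expected

    def test_rendered_image_is_single_connected_cell(self, default_cell):
        from skimage.measure import label

        _, image, truth = default_cell
        assert image.max() == 200.0  # soma intensity
        assert label(image > 0, connectivity=2).max() == 1
        assert len(truth.graph.endpoints_um) >= truth.graph.n_roots

    def test_seeded_reproducibility(self):
        spec = CellSpec(seed=7)
        img1, _ = generate_cell_image(spec)
        img2, _ = generate_cell_image(spec)
        np.testing.assert_array_equal(img1, img2)

    def test_cell_too_large_for_raster_rejected(self):
        with pytest.raises(DataError):
            generate_cell_image(CellSpec(seed=1), shape=(32, 32))

    @pytest.mark.parametrize(
        "kwargs", [{"n_roots": 0}, {"branch_prob": 1.5}, {"segment_len_um": -1.0}]
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CellSpec(**kwargs)


class TestTimelapseGenerator:
    def test_static_cell_gives_identical_frames(self):
        spec = TimelapseSpec(
            cell=CellSpec(pixel_size_um=0.6, seed=3),
            n_frames=4, n_slices=4, motility_level=0.0, noise_sigma=0.0, seed=3,
        )
        stack, _ = generate_timelapse(spec)
        for t in range(1, 4):
            np.testing.assert_array_equal(stack.data[t], stack.data[0])

    def test_injected_drift_appears_in_cross_correlation(self):
        from gliamorphdyn.preprocessing import estimate_shift

        spec = TimelapseSpec(
            cell=CellSpec(pixel_size_um=0.6, seed=4),
            n_frames=3, n_slices=6, motility_level=0.0, noise_sigma=0.0,
            drift_px=(0, 2, 3), seed=4,
        )
        stack, truth = generate_timelapse(spec)
        assert truth.drift_px == (0, 2, 3)
        assert estimate_shift(stack.data[0], stack.data[1]) == (0, 2, 3)
        assert estimate_shift(stack.data[0], stack.data[2]) == (0, 4, 6)

    def test_seeded_reproducibility(self, coarse_timelapse_spec):
        s1, _ = generate_timelapse(coarse_timelapse_spec)
        s2, _ = generate_timelapse(coarse_timelapse_spec)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_offscale_drift_rejected(self):
        spec = TimelapseSpec(
            cell=CellSpec(pixel_size_um=0.6, seed=1), n_frames=8, n_slices=4,
            drift_px=(1, 0, 0), seed=1,
        )
        with pytest.raises(DataError):
            generate_timelapse(spec)

    def test_higher_motility_level_toggles_more_pixels(self, coarse_timelapse_spec):
        """More programmed motility means more pixels differ frame to frame
        (direct generator property, before any pipeline processing)."""
        from dataclasses import replace

        diffs = {}
        for level in (0.05, 0.20):
            spec = replace(coarse_timelapse_spec, motility_level=level,
                           noise_sigma=0.0, seed=42)
            stack, _ = generate_timelapse(spec)
            proj = stack.data[:, 3]  # central slice carries the cell
            diffs[level] = np.mean([
                np.count_nonzero((proj[t] > 0) ^ (proj[t - 1] > 0))
                for t in range(1, spec.n_frames)
            ])
        assert diffs[0.20] > 2.5 * diffs[0.05]


class TestEEGPresets:
    def test_ketamine_xylazine_is_bichromatic(self):
        trace = generate_eeg(EEGPreset(state="ketamine_xylazine", seed=42))
        spec = power_spectrum(bandpass(trace, 0.5, 300))
        assert dominant_low_peaks(spec) == pytest.approx([0.5, 2.0], abs=0.25)

    def test_burst_suppression_has_heavier_tails_than_wake(self):
        wake = generate_eeg(EEGPreset(state="wake", duration_s=60, seed=5))
        pento = generate_eeg(EEGPreset(state="pentobarbital", duration_s=60, seed=5))
        assert kurtosis(pento.samples) > kurtosis(wake.samples) + 3

    def test_seeded_reproducibility(self):
        p = EEGPreset(state="pentobarbital", duration_s=10, seed=9)
        np.testing.assert_array_equal(generate_eeg(p).samples, generate_eeg(p).samples)

    def test_unknown_state_rejected(self):
        with pytest.raises(ConfigError):
            EEGPreset(state="isoflurane")


class TestPairedCohort:
    def test_size_contract(self, coarse_timelapse_spec):
        cohort = generate_paired_cohort(2, coarse_timelapse_spec, effect=-0.5, seed=0)
        assert len(cohort) == 2
        for pair in cohort:
            assert pair["pre"].data.shape == pair["post"].data.shape

    def test_effect_outside_unit_interval_rejected(self, coarse_timelapse_spec):
        with pytest.raises(ConfigError):
            generate_paired_cohort(3, coarse_timelapse_spec, effect=9.0, seed=0)

    def test_programmed_effect_reduces_post_motility(self, coarse_timelapse_spec):
        cohort = generate_paired_cohort(2, coarse_timelapse_spec, effect=-0.5, seed=1)
        for pair in cohort:
            assert pair["post_truth"].motility_level == pytest.approx(
                pair["pre_truth"].motility_level * 0.5
            )
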