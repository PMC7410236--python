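import warnings

import networkx as nx
import numpy as np
import pytest

from gliamorphdyn.errors import DataError
from gliamorphdyn.morphometry import (
    MorphologyGraph,
    complexity_index,
    covered_environment_area,
    extract_graph,
    morphometrics,
    segment_cells,
)
from gliamorphdyn.synthetic_data import CellSpec, generate_cell_image


def build_graph(n_roots, n_segments, rank1, rank2, endpoints_um=()):
    """Assemble a MorphologyGraph with prescribed counts for formula tests."""
    g = nx.MultiGraph()
    idx = 0
    for _ in range(n_roots):
        g.add_node(idx, kind="root", pos_px=(0.0, 0.0))
        idx += 1
    for rank, count in ((1, rank1), (2, rank2)):
        for _ in range(count):
            g.add_node(idx, kind="junction", pos_px=(0.0, 0.0), rank=rank)
            idx += 1
    for y, x in endpoints_um:
        g.add_node(idx, kind="endpoint", pos_px=(y, x))
        idx += 1
    nodes = list(g.nodes)
    for k in range(n_segments):  # ring of edges; topology is irrelevant to the counts
        g.add_edge(nodes[k % len(nodes)], nodes[(k + 1) % len(nodes)], length_um=1.0)
    return MorphologyGraph(g, n_roots, (1.0, 1.0))


class TestSegmentation:
    def test_single_cell_round_trip(self, default_cell):
        spec, image, truth = default_cell
        segs = segment_cells(image, (spec.pixel_size_um,) * 2)
        assert len(segs) == 1
        seg = segs[0]
        # nesting enforced by construction
        assert not (seg.soma_mask & ~seg.cytoplasm_mask).any()
        assert not (seg.cytoplasm_mask & ~seg.arbor_mask).any()
        soma_centroid = np.argwhere(seg.soma_mask).mean(axis=0)
        assert np.linalg.norm(soma_centroid - truth.soma_center_px) < 2.0

    def test_blank_image_yields_no_cells(self):
        assert segment_cells(np.zeros((64, 64))) == []

    def test_two_disjoint_cells_found_separately(self):
        img1, _ = generate_cell_image(CellSpec(max_depth=2, seed=1))
        img2, _ = generate_cell_image(CellSpec(max_depth=2, seed=2))
        h, w = img1.shape
        canvas = np.zeros((h, 2 * w + 20), dtype=img1.dtype)
        canvas[:, :w] = img1
        canvas[:, w + 20 :] = img2
        segs = segment_cells(canvas, (0.4, 0.4))
        assert len(segs) == 2
        assert not (segs[0].arbor_mask & segs[1].arbor_mask).any()


class TestGraphExtraction:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (CellSpec(n_roots=3, branch_prob=0, max_depth=2, seed=5), (3, 3, 0, 0)),
            (CellSpec(n_roots=2, branch_prob=1, max_depth=2, seed=5), (2, 6, 2, 0)),
            (CellSpec(n_roots=4, branch_prob=1, max_depth=2, seed=5), (4, 12, 4, 0)),
        ],
    )
    def test_deterministic_topology_recovered_exactly(self, spec, expected):
        image, _ = generate_cell_image(spec)
        seg = segment_cells(image, (spec.pixel_size_um,) * 2)[0]
        g = extract_graph(seg)
        assert (g.n_roots, g.n_segments, g.n_nodes_rank1, g.n_nodes_rank2) == expected

    def test_straight_process_length_close_to_truth(self):
        spec = CellSpec(n_roots=1, branch_prob=0, max_depth=1,
                        segment_len_um=50.0, pixel_size_um=0.5, seed=8)
        image, truth = generate_cell_image(spec)
        seg = segment_cells(image, (0.5, 0.5))[0]
        g = extract_graph(seg)
        assert g.total_length_um == pytest.approx(truth.graph.total_length_um, abs=1.5)

    def test_random_arbors_match_ground_truth(self):
        for seed in range(8):
            spec = CellSpec(seed=seed)  # branch_prob 0.7, depth 3
            image, truth = generate_cell_image(spec)
            seg = segment_cells(image, (spec.pixel_size_um,) * 2)[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = extract_graph(seg)
            t = truth.graph
            assert (g.n_roots, g.n_segments) == (t.n_roots, t.n_segments)
            assert (g.n_nodes_rank1, g.n_nodes_rank2) == (t.n_nodes_rank(1), t.n_nodes_rank(2))


class TestComplexityIndex:
    def test_worked_example(self):
        assert complexity_index(build_graph(2, 6, 2, 1)) == 9.0

    def test_unbranched_cell_is_zero(self):
        assert complexity_index(build_graph(3, 3, 0, 0)) == 0.0

    def test_matches_independent_formula_on_random_counts(self, rng):
        for _ in range(50):
            roots = int(rng.integers(1, 7))
            segs = int(rng.integers(1, 40))
            r1 = int(rng.integers(0, 8))
            r2 = int(rng.integers(0, 8))
            g = build_graph(roots, segs, r1, r2)
            assert complexity_index(g) == pytest.approx(segs * (r1 + r2) / roots)

    def test_zero_roots_rejected(self):
        g = build_graph(1, 2, 1, 0)
        g.n_roots = 0
        with pytest.raises(DataError):
            complexity_index(g)


def gift_wrap_area(points):
    """Convex-hull area by gift wrapping + shoelace (independent oracle)."""
    pts = sorted(map(tuple, points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    hull = []
    for phase in range(2):
        seq = pts if phase == 0 else pts[::-1]
        part = []
        for p in seq:
            while len(part) >= 2 and cross(part[-2], part[-1], p) <= 0:
                part.pop()
            part.append(p)
        hull.extend(part[:-1])
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestCoveredEnvironmentArea:
    def test_unit_square(self):
        g = build_graph(1, 4, 0, 0, endpoints_um=[(0, 0), (0, 1), (1, 0), (1, 1)])
        assert covered_environment_area(g) == pytest.approx(1.0)

    def test_right_triangle(self):
        g = build_graph(1, 3, 0, 0, endpoints_um=[(0, 0), (4, 0), (0, 3)])
        assert covered_environment_area(g) == pytest.approx(6.0)

    def test_collinear_endpoints_give_zero_with_warning(self):
        g = build_graph(1, 3, 0, 0, endpoints_um=[(0, 0), (1, 1), (2, 2)])
        with pytest.warns(UserWarning):
            assert covered_environment_area(g) == 0.0

    def test_matches_gift_wrapping_oracle(self, rng):
        for _ in range(10):
            pts = rng.random((20, 2)) * 40
            g = build_graph(1, 3, 0, 0, endpoints_um=[tuple(p) for p in pts])
            assert covered_environment_area(g) == pytest.approx(gift_wrap_area(pts))


class TestMorphometrics:
    def test_soma_disk_area(self):
        spec = CellSpec(n_roots=1, branch_prob=0, max_depth=1,
                        soma_radius_um=5.0, pixel_size_um=0.4, seed=3)
        image, _ = generate_cell_image(spec)
        seg = segment_cells(image, (0.4, 0.4))[0]
        rec = morphometrics(seg, extract_graph(seg))
        assert rec.cell_body_area_um2 == pytest.approx(np.pi * 25.0, rel=0.05)

    def test_counts_flow_from_graph(self, default_cell):
        spec, image, truth = default_cell
        seg = segment_cells(image, (spec.pixel_size_um,) * 2)[0]
        g = extract_graph(seg)
        rec = morphometrics(seg, g, region="frontal_cortex", condition="control")
        assert rec.n_segments == truth.graph.n_segments
        assert rec.complexity_index == pytest.approx(complexity_index(g))
        assert rec.region == "frontal_cortex"
        assert rec.total_ramification_length_um > 0

    def test_mismatched_pixel_scales_rejected(self, default_cell):
        spec, image, _ = default_cell
        seg = segment_cells(image, (spec.pixel_size_um,) * 2)[0]
        g = extract_graph(seg)
        g.pixel_um = (1.0, 1.0)
        with pytest.raises(DataError):
            morphometrics(seg, g)


class TestBatchDirectionOfEffect:
    def test_lower_branching_probability_lowers_mean_ci(self):
        """The pipeline-level direction of the anesthesia finding: sparser
        branching must read out as a lower mean complexity index."""
        cis = {}
        for bp in (0.3, 0.9):
            vals = []
            for seed in range(10):
                spec = CellSpec(branch_prob=bp, seed=seed)
                image, _ = generate_cell_image(spec)
                seg = segment_cells(image, (spec.pixel_size_um,) * 2)[0]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals.append(complexity_index(extract_graph(seg)))
            cis[bp] = np.mean(vals)
        assert cis[0.9] > cis[0.3]
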