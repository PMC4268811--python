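"""Contiguity graphs, join-count inference and kernel density surfaces."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retmosaic import (
    NeighbourGraph,
    SyntheticRetinaParams,
    count_types,
    dirichlet_contiguity,
    enumerate_join_count_moments,
    generate_hex_retina,
    hex_adjacency,
    join_count_moments,
    join_count_test,
    kernel_density,
    observed_join_counts,
    strip_marks,
    to_point_pattern,
)
from retmosaic.mosaic_model import MarkedPointPattern
from retmosaic.spatial_stats import DuplicatePointError
from shapely.geometry import Polygon

from .conftest import ROSETTE_CELLS, build_map


def rosette_graph():
    return hex_adjacency(build_map([(c, r, "Y") for c, r in ROSETTE_CELLS]))


class TestHexAdjacency:
    def test_rosette_has_12_edges_and_centre_degree_6(self, rosette_map):
        g = hex_adjacency(rosette_map)
        assert g.m == 12
        assert sorted(g.degrees) == [3, 3, 3, 3, 3, 3, 6]

    def test_non_adjacent_ommatidia_share_no_edge(self):
        g = hex_adjacency(build_map([(0, 0, "Y"), (5, 5, "P_OC")]))
        assert g.m == 0

    def test_max_degree_six_on_generated_retina(self, small_retina):
        assert hex_adjacency(small_retina).degrees.max() <= 6

    def test_weight_sums_match_brute_force(self, small_retina):
        g = hex_adjacency(small_retina)
        deg = np.zeros(g.n, dtype=int)
        for i, j in g.edges:
            deg[i] += 1
            deg[j] += 1
        assert g.S0 == 2 * len(g.edges)
        assert g.S1 == 2 * g.S0
        assert g.S2 == 4 * int((deg**2).sum())


class TestDirichletContiguity:
    def _pattern(self, pts, pad=10.0):
        pts = np.asarray(pts, dtype=float)
        lo = pts.min(axis=0) - pad
        hi = pts.max(axis=0) + pad
        window = Polygon(
            [(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])]
        )
        return MarkedPointPattern(pts, np.array(["Y"] * len(pts)), window)

    def test_three_points_give_complete_graph(self):
        g = dirichlet_contiguity(self._pattern([(0, 0), (10, 0), (5, 9)]))
        assert g.m == 3

    def test_unit_square_tie_broken_to_five_edges(self):
        g = dirichlet_contiguity(self._pattern([(0, 0), (1, 0), (1, 1), (0, 1)]))
        assert g.m == 5  # four sides + one diagonal after the documented jitter

    def test_matches_hex_adjacency_on_lattice_interior(self, small_retina):
        hexg = hex_adjacency(small_retina)
        dirg = dirichlet_contiguity(to_point_pattern(small_retina))
        hex_edges = set(map(tuple, hexg.edges))
        dir_edges = set(map(tuple, dirg.edges))
        # interior nodes: all six hex neighbours present
        interior = {i for i in range(hexg.n) if hexg.degrees[i] == 6}
        interior_hex = {e for e in hex_edges if e[0] in interior and e[1] in interior}
        assert interior_hex <= dir_edges

    def test_duplicate_points_raise(self):
        with pytest.raises(DuplicatePointError):
            dirichlet_contiguity(self._pattern([(0, 0), (0, 0), (1, 1)]))


class TestStripAndObserved:
    def test_dra_only_map_strips_to_empty_graph(self):
        m = build_map([(0, 0, "DRA"), (1, 0, "DRA"), (0, 1, "DRA")])
        g, marks = strip_marks(hex_adjacency(m), m)
        assert g.n == 0 and g.m == 0 and len(marks) == 0

    def test_strip_commutes_with_graph_construction(self, small_retina):
        # strip after building vs. build on the stripped map
        g1, marks1 = strip_marks(hex_adjacency(small_retina), small_retina)
        keep = [o for o in small_retina.ommatidia if o.type in ("P_OC", "Y")]
        stripped_map = build_map([(o.col, o.row, o.type) for o in keep])
        g2 = hex_adjacency(stripped_map)
        assert g1.n == g2.n
        assert set(map(tuple, g1.edges)) == set(map(tuple, g2.edges))

    def test_node_count_is_p_plus_y(self, small_retina):
        g, marks = strip_marks(hex_adjacency(small_retina), small_retina)
        c = count_types(small_retina)
        assert g.n == c.n_p_oc + c.n_y == len(marks)
        assert marks.sum() == c.n_p_oc

    def test_single_mixed_edge(self):
        m = build_map([(0, 0, "P_OC"), (1, 0, "Y")])
        g, marks = strip_marks(hex_adjacency(m), m)
        assert observed_join_counts(g, marks) == (0, 0, 1)

    def test_all_yellow_rosette(self, rosette_map):
        g, marks = strip_marks(hex_adjacency(rosette_map), rosette_map)
        assert observed_join_counts(g, marks) == (0, 12, 0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_tallies_partition_the_edge_set(self, seed):
        m = generate_hex_retina(
            SyntheticRetinaParams(n_target=120, p0=0.4, dra_count=8, seed=seed)
        )
        g, marks = strip_marks(hex_adjacency(m), m)
        j = observed_join_counts(g, marks)
        assert sum(j) == g.m


class TestMoments:
    def test_rosette_same_type_expectation(self):
        # n=7, S0=24, n_p=2: E[J_pp] = 12 * 2 / 42 = 4/7, checked two ways
        g = rosette_graph()
        analytic = join_count_moments(g, 2, 5, exact=True)
        assert analytic["pp"][0] == Fraction(4, 7)
        exhaustive = enumerate_join_count_moments(g, 2)
        assert exhaustive["pp"] == analytic["pp"]

    def test_k3_enumeration_mixed_pair_constant(self):
        g = NeighbourGraph(n=3, edges=np.array([[0, 1], [0, 2], [1, 2]]))
        mom = enumerate_join_count_moments(g, 1)
        assert mom["py"] == (Fraction(2), Fraction(0))

    def test_analytic_requires_four_nodes(self):
        g = NeighbourGraph(n=3, edges=np.array([[0, 1], [0, 2], [1, 2]]))
        with pytest.raises(ValueError, match="n >= 4"):
            join_count_moments(g, 1, 2)

    def test_zero_count_pair_has_zero_moments(self):
        g = rosette_graph()
        mom = join_count_moments(g, 0, 7, exact=True)
        assert mom["pp"] == (0, 0)

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=20, deadline=None)
    def test_analytic_equals_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5]
        g = NeighbourGraph(n=n, edges=np.array(edges, dtype=int).reshape(-1, 2))
        n_a = int(rng.integers(0, n + 1))
        assert join_count_moments(g, n_a, n - n_a, exact=True) == \
            enumerate_join_count_moments(g, n_a)


class TestJoinCountTest:
    def test_segregated_halves_give_strongly_negative_mixed_z(self):
        # 10x10 hex block, left half pale, right half yellow
        cells = [
            (c, r, "P_OC" if c < 5 else "Y") for c in range(10) for r in range(10)
        ]
        m = build_map(cells)
        g, marks = strip_marks(hex_adjacency(m), m)
        res = join_count_test(g, marks, method="analytic")
        assert res.pairs["py"].z < -3.0

    def test_variance_zero_reports_note_not_p(self, rosette_map):
        g, marks = strip_marks(hex_adjacency(rosette_map), rosette_map)
        res = join_count_test(g, marks, method="analytic")
        assert res.pairs["pp"].p_analytic is None
        assert "Var" in res.pairs["pp"].note

    def test_label_swap_symmetry(self, plain_retina):
        g, marks = strip_marks(hex_adjacency(plain_retina), plain_retina)
        a = join_count_test(g, marks, method="analytic")
        b = join_count_test(g, 1 - marks, method="analytic")
        assert a.pairs["py"].z == pytest.approx(b.pairs["py"].z, abs=1e-12)
        assert a.pairs["pp"].z == pytest.approx(b.pairs["yy"].z, abs=1e-12)
        assert a.pairs["yy"].z == pytest.approx(b.pairs["pp"].z, abs=1e-12)

    def test_permutation_is_seed_deterministic(self, small_retina):
        g, marks = strip_marks(hex_adjacency(small_retina), small_retina)
        r1 = join_count_test(g, marks, method="permutation", n_perm=199, seed=7)
        r2 = join_count_test(g, marks, method="permutation", n_perm=199, seed=7)
        assert all(
            r1.pairs[k].p_perm == r2.pairs[k].p_perm for k in ("pp", "yy", "py")
        )

    def test_permutation_needs_99(self, small_retina):
        g, marks = strip_marks(hex_adjacency(small_retina), small_retina)
        with pytest.raises(ValueError, match="99"):
            join_count_test(g, marks, method="permutation", n_perm=10)


class TestKernelDensity:
    def _one_point_pattern(self):
        window = Polygon([(0, 0), (1400, 0), (1400, 1400), (0, 1400)])
        return MarkedPointPattern(
            np.array([[700.0, 700.0]]), np.array(["P_OC"]), window
        )

    def test_single_point_peak_matches_kernel_maximum(self):
        sigma = 70.0
        grid = kernel_density(
            self._one_point_pattern(), sigma=sigma, edge_correction="none"
        )
        peak = np.nanmax(grid.values)
        assert peak == pytest.approx(1.0 / (2 * math.pi * sigma**2), rel=0.01)

    def test_mass_conserved_with_diggle_correction(self, plain_retina):
        pat = to_point_pattern(plain_retina)
        n = count_types(plain_retina).n_p_oc
        grid = kernel_density(pat, "P_OC", edge_correction="diggle")
        assert grid.integral() == pytest.approx(n, rel=1e-6)

    def test_doubling_sigma_does_not_increase_maximum(self, plain_retina):
        pat = to_point_pattern(plain_retina)
        g1 = kernel_density(pat, "P_OC", sigma=70.0)
        g2 = kernel_density(pat, "P_OC", sigma=140.0)
        assert np.nanmax(g2.values) <= np.nanmax(g1.values) + 1e-12

    def test_empty_filtered_pattern_gives_zero_grid(self):
        pat = self._one_point_pattern()
        grid = kernel_density(pat, "DRA")
        assert np.nansum(grid.values) == 0.0

    def test_cells_outside_window_are_null(self, plain_retina):
        pat = to_point_pattern(plain_retina)
        grid = kernel_density(pat, "P_OC")
        assert np.isnan(grid.values).any()

    def test_tsv_round_trip(self, tmp_path, plain_retina):
        pat = to_point_pattern(plain_retina)
        grid = kernel_density(pat, "P_OC")
        grid.to_tsv(tmp_path / "g.tsv")
        back = np.loadtxt(tmp_path / "g.tsv", delimiter="\t")
        assert np.allclose(back, grid.values, equal_nan=True, atol=1e-6)
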