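import math

import numpy as np
import pytest

from helpers_oracle import (
    oracle_grid_count,
    oracle_neighborhood,
    oracle_pair_mi,
    oracle_standardize,
)
from sinum import (
    ExpressionMatrix,
    ValidationError,
    build_grid,
    compute_grid_count,
    degree_matrix,
    infer_scns,
    local_mi,
    pair_profile,
    snap_to_grid,
    tentative_neighborhood,
    write_scns,
)


class TestGrid:
    @pytest.mark.parametrize("n,expected", [(100, 10), (124, 11), (758, 28), (1, 1), (2, 1)])
    def test_grid_count(self, n, expected):
        assert compute_grid_count(n) == expected

    def test_grid_count_invalid(self):
        with pytest.raises(ValueError):
            compute_grid_count(0)

    def test_equal_width_edges(self):
        gem = ExpressionMatrix(np.array([[1.0, 1, 2, 2], [0.0, 1, 2, 3]]),
                               ["a", "b"], list("wxyz"), is_log_transformed=True)
        grid = build_grid(gem)
        assert grid.grid_count == 2
        np.testing.assert_allclose(grid.gene_edges(0), [1.0, 1.5, 2.0])

    def test_nine_cell_edges(self):
        values = np.vstack([np.arange(1.0, 10.0), np.arange(1.0, 10.0)])
        gem = ExpressionMatrix(values, ["a", "b"], [f"c{j}" for j in range(9)],
                               is_log_transformed=True)
        grid = build_grid(gem)
        assert grid.grid_count == 3
        np.testing.assert_allclose(grid.gene_edges(0), [1.0, 11 / 3, 19 / 3, 9.0])

    def test_constant_gene_flagged_degenerate(self):
        gem = ExpressionMatrix(np.array([[5.0, 5, 5, 5], [0.0, 1, 2, 3]]),
                               ["flat", "b"], list("wxyz"), is_log_transformed=True)
        grid = build_grid(gem)
        assert grid.degenerate[0] and not grid.degenerate[1]


class TestNeighborhood:
    def test_duplicate_values_zero_width(self):
        assert tentative_neighborhood(np.array([1.0, 1, 2, 2]), 0, 0.5) == (1.0, 1.0)

    def test_nearest_two_of_nine(self):
        assert tentative_neighborhood(np.arange(1.0, 10.0), 0, 0.2) == (1.0, 2.0)

    def test_box_one_spans_range(self):
        vals = np.array([3.0, 9.0, 1.0, 4.0])
        assert tentative_neighborhood(vals, 0, 1.0) == (1.0, 9.0)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            vals = np.round(rng.random(17) * 4, 1)  # ties likely
            cell = int(rng.integers(17))
            box = float(rng.choice([0.1, 0.3, 0.5]))
            assert tentative_neighborhood(vals, cell, box) == \
                oracle_neighborhood(list(vals), cell, box)

    def test_snap_point_interval(self):
        box = snap_to_grid((1.0, 1.0), np.array([1.0, 1.5, 2.0]))
        assert box.bin_range == (0, 0)

    def test_snap_interval_within_first_bin(self):
        edges = np.array([1.0, 11 / 3, 19 / 3, 9.0])
        assert snap_to_grid((1.0, 2.0), edges).bin_range == (0, 0)

    def test_snap_full_range(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        assert snap_to_grid((0.0, 3.0), edges).bin_range == (0, 2)

    def test_snap_member_counts_over_all_cells(self):
        edges = np.array([0.0, 1.0, 2.0])
        values = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        box = snap_to_grid((0.0, 2.0), edges, values=values)
        np.testing.assert_array_equal(box.member_count_per_bin, [2, 3])


class TestLocalMI:
    def test_symmetric_four_cell_example(self, symmetric_gem):
        grid = build_grid(symmetric_gem)
        expected = 0.5 * math.log(2.0)
        for cell in range(4):
            assert local_mi(symmetric_gem, grid, 0, 1, cell, 0.5) == \
                pytest.approx(expected, abs=1e-12)

    def test_full_box_gives_constant_profile(self, random_gem):
        # box_size = 1 makes every cell's neighborhood the whole grid, so the
        # local MI is the same in every cell and no z-score can exceed 0
        grid = build_grid(random_gem)
        prof = pair_profile(random_gem, grid, 0, 1, 1.0)
        assert prof.sd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(prof.z_per_cell, np.zeros(random_gem.n_cells))

    def test_degenerate_gene_returns_zero(self):
        values = np.array([[5.0, 5, 5, 5], [0.0, 1, 2, 3]])
        gem = ExpressionMatrix(values, ["flat", "b"], list("wxyz"),
                               is_log_transformed=True)
        grid = build_grid(gem)
        assert local_mi(gem, grid, 0, 1, 2, 0.5) == 0.0

    def test_matches_loop_oracle(self, random_gem):
        grid = build_grid(random_gem)
        for gx, gy in [(0, 1), (2, 5), (3, 7)]:
            prof = pair_profile(random_gem, grid, gx, gy, 0.2)
            expected = oracle_pair_mi(list(random_gem.values[gx]),
                                      list(random_gem.values[gy]), 0.2)
            np.testing.assert_allclose(prof.mi_per_cell, expected, atol=1e-12)

    def test_non_negative(self, random_gem):
        grid = build_grid(random_gem)
        for gx in range(random_gem.n_genes):
            for gy in range(gx + 1, random_gem.n_genes):
                prof = pair_profile(random_gem, grid, gx, gy, 0.2)
                assert prof.mi_per_cell.min() >= -1e-12


class TestPairProfile:
    def test_standardization_of_known_vector(self):
        from sinum.core import _standardize

        mean, sd, z = _standardize(np.array([1.0, 2.0, 3.0]), "population")
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(math.sqrt(2.0 / 3.0))
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_profile_gives_zero_z(self, symmetric_gem):
        grid = build_grid(symmetric_gem)
        prof = pair_profile(symmetric_gem, grid, 0, 1, 0.5)
        assert prof.sd == 0.0
        np.testing.assert_array_equal(prof.z_per_cell, np.zeros(4))

    def test_z_standardized(self, random_gem):
        grid = build_grid(random_gem)
        prof = pair_profile(random_gem, grid, 0, 3, 0.2)
        assert prof.sd > 0
        assert abs(prof.z_per_cell.mean()) < 1e-9
        assert abs(prof.z_per_cell.std() - 1.0) < 1e-9

    def test_symmetry_in_gene_order(self, random_gem):
        grid = build_grid(random_gem)
        a = pair_profile(random_gem, grid, 1, 6, 0.2)
        b = pair_profile(random_gem, grid, 6, 1, 0.2)
        np.testing.assert_allclose(a.mi_per_cell, b.mi_per_cell, atol=1e-12)
        np.testing.assert_allclose(a.z_per_cell, b.z_per_cell, atol=1e-9)

    def test_self_pair_rejected(self, random_gem):
        grid = build_grid(random_gem)
        with pytest.raises(ValueError):
            pair_profile(random_gem, grid, 2, 2, 0.2)

    def test_log_base_leaves_z_unchanged(self, random_gem):
        # entropies in log2 rescale every local MI by 1/ln 2; the z-scores
        # (and hence the edge sets) are invariant
        grid = build_grid(random_gem)
        prof = pair_profile(random_gem, grid, 0, 4, 0.2)
        mi_log2 = oracle_pair_mi(list(random_gem.values[0]),
                                 list(random_gem.values[4]), 0.2, log=math.log2)
        z_log2 = oracle_standardize(mi_log2)
        np.testing.assert_allclose(prof.z_per_cell, z_log2, atol=1e-9)


class TestInferScns:
    def test_sigma_zero_means_no_edges(self, symmetric_gem):
        scns = infer_scns(symmetric_gem, box_size=0.5, z_threshold=0.0)
        assert all(s.edge_count == 0 for s in scns)

    def test_infinite_threshold_empties_all(self, random_gem):
        scns = infer_scns(random_gem, z_threshold=math.inf)
        assert all(s.edge_count == 0 for s in scns)

    def test_monotone_in_threshold(self, random_gem):
        lo = infer_scns(random_gem, z_threshold=0.0)
        hi = infer_scns(random_gem, z_threshold=1.0)
        for a, b in zip(lo, hi):
            assert set(b.edges) <= set(a.edges)

    def test_strict_inequality_at_threshold(self, random_gem):
        scns = infer_scns(random_gem, z_threshold=0.0)
        for s in scns:
            assert all(z > 0.0 for z in s.edges.values())

    def test_deterministic_and_thread_invariant(self, random_gem):
        a = infer_scns(random_gem, threads=1)
        b = infer_scns(random_gem, threads=4)
        c = infer_scns(random_gem, threads=1)
        for x, y, w in zip(a, b, c):
            assert x.edges == y.edges == w.edges

    def test_pair_restriction(self, random_gem):
        restricted = infer_scns(
            random_gem, pair_restriction=[("g0", "g1"), ("g2", "g3"), ("nope", "g0")]
        )
        allowed = {(0, 1), (2, 3)}
        for s in restricted:
            assert set(s.edges) <= allowed

    def test_empty_restriction_rejected(self, random_gem):
        with pytest.raises(ValidationError):
            infer_scns(random_gem, pair_restriction=[("x", "y")])

    def test_requires_log_transformed(self, raw_counts_gem):
        with pytest.raises(ValidationError):
            infer_scns(raw_counts_gem)

    def test_drop_zero_edges(self):
        rng = np.random.default_rng(5)
        values = rng.random((4, 30)) * 3
        values[0, :10] = 0.0
        gem = ExpressionMatrix(values, [f"g{i}" for i in range(4)],
                               [f"c{j}" for j in range(30)], is_log_transformed=True)
        scns = infer_scns(gem, drop_zero_edges=True)
        for c in range(10):
            assert all(0 not in e for e in scns[c].edges)


class TestDegreeMatrix:
    def test_empty_scns_zero_matrix(self, symmetric_gem):
        scns = infer_scns(symmetric_gem, box_size=0.5)
        dm = degree_matrix(scns, symmetric_gem)
        np.testing.assert_array_equal(dm.values, np.zeros((2, 4)))

    def test_handshake(self, random_gem):
        scns = infer_scns(random_gem)
        dm = degree_matrix(scns, random_gem)
        for c, s in enumerate(scns):
            assert dm.values[:, c].sum() == 2 * s.edge_count

    def test_single_edge_column(self, random_gem):
        from sinum.core import SingleCellNetwork

        scns = [SingleCellNetwork(cell_id=c) for c in random_gem.cell_ids]
        scns[0].edges[(1, 2)] = 3.0
        dm = degree_matrix(scns, random_gem)
        assert dm.values[1, 0] == 1 and dm.values[2, 0] == 1
        assert dm.values[:, 0].sum() == 2

    def test_log10p1_transform(self, raw_counts_gem):
        from sinum.core import SingleCellNetwork

        scns = [SingleCellNetwork(cell_id=c) for c in raw_counts_gem.cell_ids]
        for j in range(1, 10):
            scns[0].edges[(0, j)] = 1.0  # degree 9 for gene 0
        dm = degree_matrix(scns, raw_counts_gem, transform="log10p1")
        assert dm.values[0, 0] == pytest.approx(1.0)  # log10(9 + 1)

    def test_misalignment_rejected(self, random_gem, symmetric_gem):
        scns = infer_scns(symmetric_gem, box_size=0.5)
        with pytest.raises(ValidationError):
            degree_matrix(scns, random_gem)


def test_scn_writer_sorted_symbol_pairs(tmp_path, random_gem):
    scns = infer_scns(random_gem, z_threshold=1.5)
    path = tmp_path / "scns.tsv"
    write_scns(scns, random_gem, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "cell_id\tgene_a\tgene_b\tz"
    for line in lines[1:]:
        _, a, b, z = line.split("\t")
        assert a < b
        assert float(z) > 1.5
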