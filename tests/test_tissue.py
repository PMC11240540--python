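import numpy as np
import pytest
from hypothesis import given, strategies as st

from emdr.tissue import (EMPTY, EXCLUDED, STROMA, STROMA_INACTIVE, TUMOR,
                         PointPattern, TissueGrid, compute_niche_map,
                         extract_quadrant, load_mask, pixelate_stroma,
                         stroma_metrics, write_mask)


def random_grid(seed, side=40, p_stroma=0.1, p_excl=0.02):
    rng = np.random.default_rng(seed)
    u = rng.random((side, side))
    state = np.where(u < p_stroma, STROMA,
                     np.where(u < p_stroma + p_excl, EXCLUDED, EMPTY))
    return TissueGrid(state.astype(np.int8))


class TestTissueGrid:
    def test_rejects_unknown_codes_and_bad_scale(self):
        with pytest.raises(ValueError):
            TissueGrid(np.full((3, 3), 9, dtype=np.int8))
        with pytest.raises(ValueError):
            TissueGrid(np.zeros((3, 3), dtype=np.int8), cell_size=0)

    def test_physical_extent(self):
        grid = TissueGrid(np.zeros((100, 100), dtype=np.int8), cell_size=15.0)
        assert grid.side_um == (1500.0, 1500.0)


class TestMaskIO:
    @pytest.mark.parametrize("suffix", [".png", ".tif"])
    def test_round_trip_reproduces_states(self, tmp_path, suffix):
        grid = random_grid(3)
        grid.state[0, 0] = STROMA_INACTIVE
        path = tmp_path / f"mask{suffix}"
        write_mask(grid, path)
        back = load_mask(path)
        assert np.array_equal(back.state, grid.state)

    def test_empty_mask_has_no_tissue(self, tmp_path):
        path = tmp_path / "empty.png"
        write_mask(TissueGrid(np.zeros((100, 100), dtype=np.int8)), path)
        grid = load_mask(path)
        assert (grid.state == STROMA).sum() == 0
        assert (grid.state == TUMOR).sum() == 0

    def test_single_stroma_pixel_lands_at_center(self, tmp_path):
        state = np.zeros((3, 3), dtype=np.int8)
        state[1, 1] = STROMA
        path = tmp_path / "one.png"
        write_mask(TissueGrid(state), path)
        grid = load_mask(path)
        assert grid.state[1, 1] == STROMA
        assert (grid.state == STROMA).sum() == 1

    def test_unknown_label_code_raises(self, tmp_path):
        from PIL import Image

        arr = np.full((4, 4), 7, dtype=np.uint8)
        path = tmp_path / "bad.png"
        Image.fromarray(arr, mode="L").save(path)
        with pytest.raises(ValueError, match="unknown label"):
            load_mask(path)

    def test_point_table_rasterizes_stroma_and_cells(self, tmp_path):
        pat = PointPattern((60.0, 60.0), [(22.0, 22.0)],
                           [(7.0, 7.0), (52.0, 37.0)], [True, False])
        path = tmp_path / "points.csv"
        pat.to_csv(path)
        grid = load_mask(path, cell_size=15.0)
        assert grid.state[1, 1] == STROMA
        assert grid.state[0, 0] == TUMOR
        assert grid.state[2, 3] == TUMOR


class TestPointPattern:
    def test_rejects_out_of_window_coordinates(self):
        with pytest.raises(ValueError):
            PointPattern((10.0, 10.0), [(5.0, 5.0)], [(11.0, 1.0)], [True])

    def test_csv_round_trip_preserves_marks(self, tmp_path):
        rng = np.random.default_rng(0)
        pat = PointPattern((100.0, 100.0), rng.uniform(0, 100, (5, 2)),
                           rng.uniform(0, 100, (20, 2)),
                           rng.random(20) < 0.3)
        path = tmp_path / "pat.csv"
        pat.to_csv(path)
        back = PointPattern.from_csv(path, window=(100.0, 100.0))
        assert np.allclose(back.cells, pat.cells)
        assert np.array_equal(back.marker, pat.marker)
        assert np.allclose(back.stroma, pat.stroma)


class TestPixelateStroma:
    def test_all_zero_mask_gives_no_tiles(self):
        assert len(pixelate_stroma(np.zeros((30, 30)), pixel_size=1.0)) == 0

    def test_single_aligned_stroma_square(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:15, :15] = True  # one 15x15 um block at the origin, 1 um pixels
        centers = pixelate_stroma(mask, pixel_size=1.0, tile=15.0)
        assert centers.shape == (1, 2)
        assert np.allclose(centers[0], (7.5, 7.5))

    def test_tile_larger_than_window_raises(self):
        with pytest.raises(ValueError):
            pixelate_stroma(np.ones((4, 4)), pixel_size=1.0, tile=15.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_tiling(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((45, 60)) < 0.3
        tile, res = 15.0, 1.0
        got = pixelate_stroma(mask, pixel_size=res, tile=tile)
        expected = []
        for ty in range(mask.shape[0] * 1 // 15):
            for tx in range(mask.shape[1] * 1 // 15):
                cov, tot = 0, 0
                for py in range(mask.shape[0]):
                    for px in range(mask.shape[1]):
                        cx, cy = (px + 0.5) * res, (py + 0.5) * res
                        if tx * tile <= cx < (tx + 1) * tile \
                                and ty * tile <= cy < (ty + 1) * tile:
                            tot += 1
                            cov += mask[py, px]
                if tot and cov / tot >= 0.5:
                    expected.append(((tx + 0.5) * tile, (ty + 0.5) * tile))
        assert sorted(map(tuple, got.tolist())) == sorted(expected)


class TestNicheMap:
    def test_no_stroma_gives_empty_niche(self):
        grid = TissueGrid(np.zeros((20, 20), dtype=np.int8))
        assert compute_niche_map(grid, 3).n_sites == 0

    def test_single_stroma_chebyshev_ball(self):
        state = np.zeros((21, 21), dtype=np.int8)
        state[10, 10] = STROMA
        niche = compute_niche_map(TissueGrid(state), 3, "chebyshev")
        assert niche.n_sites == 48  # 7x7 block minus the stroma site
        assert not niche.inside[10, 10]

    def test_border_clipping(self):
        state = np.zeros((10, 10), dtype=np.int8)
        state[0, 0] = STROMA
        niche = compute_niche_map(TissueGrid(state), 3, "chebyshev")
        assert niche.n_sites == 16 - 1

    def test_inactive_stroma_confers_no_niche(self):
        state = np.zeros((21, 21), dtype=np.int8)
        state[10, 10] = STROMA_INACTIVE
        assert compute_niche_map(TissueGrid(state), 5).n_sites == 0

    def test_distance_zero_empty_and_negative_raises(self):
        state = np.zeros((9, 9), dtype=np.int8)
        state[4, 4] = STROMA
        grid = TissueGrid(state)
        assert compute_niche_map(grid, 0).n_sites == 0
        with pytest.raises(ValueError):
            compute_niche_map(grid, -1)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 5))
    def test_niche_grows_monotonically_with_distance(self, seed, d):
        grid = random_grid(seed, side=25)
        near = compute_niche_map(grid, d).inside
        far = compute_niche_map(grid, d + 1).inside
        assert (near <= far).all()

    def test_euclidean_tighter_than_chebyshev(self):
        grid = random_grid(11, side=30)
        eu = compute_niche_map(grid, 3, "euclidean").inside
        ch = compute_niche_map(grid, 3, "chebyshev").inside
        assert (eu <= ch).all()


class TestExtractQuadrant:
    def test_identity_and_right_half(self):
        rng = np.random.default_rng(5)
        state = (rng.random((100, 200)) < 0.1).astype(np.int8) * STROMA
        grid = TissueGrid(state)
        same = extract_quadrant(grid, (0.0, 0.0), 1500.0)
        assert np.array_equal(same.state, state[:, :100])
        right = extract_quadrant(grid, (1500.0, 0.0), 1500.0)
        assert np.array_equal(right.state, state[:, 100:])

    def test_out_of_bounds_raises(self):
        grid = TissueGrid(np.zeros((100, 100), dtype=np.int8))
        with pytest.raises(ValueError):
            extract_quadrant(grid, (15.0, 0.0), 1500.0)

    def test_abundance_matches_direct_count(self):
        rng = np.random.default_rng(6)
        state = (rng.random((200, 200)) < 0.12).astype(np.int8) * STROMA
        grid = TissueGrid(state)
        quad = extract_quadrant(grid, (1500.0, 0.0), 1500.0)
        direct = state[0:100, 100:200] == STROMA
        assert stroma_metrics(quad)[0] == direct.sum() / 10000


class TestStromaMetrics:
    def test_empty_grid(self):
        grid = TissueGrid(np.zeros((10, 10), dtype=np.int8))
        assert stroma_metrics(grid) == (0.0, 0.0)

    def test_isolated_site_is_all_boundary(self):
        state = np.zeros((100, 100), dtype=np.int8)
        state[50, 50] = STROMA
        ab, disp = stroma_metrics(TissueGrid(state))
        assert ab == pytest.approx(1 / 10000)
        assert disp == 1.0

    def test_solid_block_dispersal_is_perimeter_fraction(self):
        state = np.zeros((30, 30), dtype=np.int8)
        state[10:20, 10:20] = STROMA
        _, disp = stroma_metrics(TissueGrid(state))
        assert disp == pytest.approx(36 / 100)

    def test_excluded_sites_leave_abundance_denominator(self):
        state = np.zeros((10, 10), dtype=np.int8)
        state[0, :] = EXCLUDED
        state[5, 5] = STROMA
        ab, _ = stroma_metrics(TissueGrid(state))
        assert ab == pytest.approx(1 / 90)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariance_under_flips(self, seed):
        grid = random_grid(seed, side=30)
        ab, disp = stroma_metrics(grid)
        for flipped in (grid.state[::-1], grid.state[:, ::-1], grid.state.T):
            ab2, disp2 = stroma_metrics(TissueGrid(flipped.copy()))
            assert ab2 == pytest.approx(ab)
            assert disp2 == pytest.approx(disp)
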