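"""Region rule, peak detection, interpeak suppression, node labeling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coalternet as cn
from coalternet.ale import AleMap
from coalternet.nodes import Peak, _sorted_peaks


def as_ale(atlas_or_grid, values):
    grid = getattr(atlas_or_grid, "grid", atlas_or_grid)
    return AleMap(grid=grid, values=np.asarray(values, dtype=float),
                  n_experiments=1, fwhm_mm=10.0, threshold_value=0.01)


class TestAlteredRegions:
    @pytest.mark.parametrize("n_voxels,expected", [(19, False), (20, True)])
    def test_region_rule_boundary(self, two_region_atlas, n_voxels, expected):
        values = np.zeros(two_region_atlas.grid.dims)
        vox = np.argwhere(two_region_atlas.labels == 1)[:n_voxels]
        values[tuple(vox.T)] = 0.5
        regions = cn.altered_regions(as_ale(two_region_atlas, values),
                                     two_region_atlas)
        by_name = {r.region_name: r for r in regions}
        assert by_name["Box_L"].altered_voxel_count == n_voxels
        assert by_name["Box_L"].passes is expected
        assert by_name["Box_R"].passes is False

    def test_empty_map_fails_all_regions(self, two_region_atlas):
        values = np.zeros(two_region_atlas.grid.dims)
        regions = cn.altered_regions(as_ale(two_region_atlas, values),
                                     two_region_atlas)
        assert all(not r.passes for r in regions)

    def test_saturated_region(self, two_region_atlas):
        values = np.where(two_region_atlas.labels == 2, 0.4, 0.0)
        regions = cn.altered_regions(as_ale(two_region_atlas, values),
                                     two_region_atlas)
        by_name = {r.region_name: r for r in regions}
        assert by_name["Box_R"].altered_voxel_count == 1000
        assert by_name["Box_R"].passes

    def test_grid_mismatch_rejected(self, two_region_atlas, small_grid):
        ale = as_ale(small_grid, np.zeros(small_grid.dims))
        with pytest.raises(ValueError, match="grid"):
            cn.altered_regions(ale, two_region_atlas)


class TestDetectPeaks:
    def test_single_gaussian_blob_single_peak(self, small_grid):
        exp = cn.Experiment(id="E", label="", foci=[cn.Focus(4.0, 0.0, -2.0)])
        ma = cn.ma_map(exp, small_grid, fwhm_mm=10.0)
        peaks = cn.detect_peaks(as_ale(small_grid, ma.values), percentile=0)
        assert len(peaks) == 1
        assert peaks[0].voxel == tuple(small_grid.world_to_voxel([4, 0, -2]))

    def test_two_separated_equal_blobs(self):
        grid = cn.VolumeGrid(origin=(-30, -6, -6), voxel_size=2.0,
                             dims=(31, 7, 7))
        exp = cn.Experiment(id="E", label="", foci=[cn.Focus(-20, 0, 0),
                                                    cn.Focus(20, 0, 0)])
        ma = cn.ma_map(exp, grid, fwhm_mm=8.0)
        peaks = cn.detect_peaks(as_ale(grid, ma.values), percentile=0)
        assert len(peaks) == 2
        assert peaks[0].ale_value == pytest.approx(peaks[1].ale_value)

    def test_percentile_filter_on_graded_maxima(self, small_grid):
        # 10 isolated single-voxel maxima with graded heights: the
        # suprathreshold value distribution is exactly those 10 values, so
        # the 90th-percentile rule (strictly greater) keeps only the top one
        values = np.zeros(small_grid.dims)
        heights = np.linspace(0.1, 1.0, 10)
        for i, h in enumerate(heights):
            values[2 * i, 10, 10] = h
        cutoff = np.percentile(heights, 90)  # independent brute-force cutoff
        expected = {i for i, h in enumerate(heights) if h > cutoff}
        peaks = cn.detect_peaks(as_ale(small_grid, values), percentile=90)
        assert {p.voxel[0] // 2 for p in peaks} == expected
        assert len(peaks) == 1

    def test_plateau_contributes_single_peak(self, small_grid):
        values = np.zeros(small_grid.dims)
        values[10, 10, 10] = values[10, 11, 10] = 0.5
        peaks = cn.detect_peaks(as_ale(small_grid, values), percentile=0)
        assert len(peaks) == 1
        assert peaks[0].voxel in {(10, 10, 10), (10, 11, 10)}

    def test_empty_map_gives_no_peaks(self, small_grid):
        peaks = cn.detect_peaks(as_ale(small_grid,
                                       np.zeros(small_grid.dims)))
        assert peaks == []

    @pytest.mark.parametrize("pct", [-1, 100, 150])
    def test_percentile_domain(self, small_grid, pct):
        with pytest.raises(ValueError):
            cn.detect_peaks(as_ale(small_grid, np.zeros(small_grid.dims)),
                            percentile=pct)

    def test_peaks_basis_uses_peak_distribution(self, small_grid):
        # broad low plateau floor + two bumps: voxel-basis cutoff differs
        # from peak-basis cutoff
        values = np.zeros(small_grid.dims)
        values[2, 2, 2] = 0.9
        values[10, 10, 10] = 0.8
        peaks = cn.detect_peaks(as_ale(small_grid, values), percentile=50,
                                basis="peaks")
        assert [p.ale_value for p in peaks] == [0.9]


class TestInterpeakDistance:
    def _peak(self, xyz, value, vox=None):
        vox = vox or tuple(int(c) for c in xyz)
        return Peak(voxel=vox, xyz=tuple(float(c) for c in xyz),
                    ale_value=value)

    def test_close_pair_keeps_stronger(self):
        p1 = self._peak((0, 0, 0), 0.9)
        p2 = self._peak((5, 0, 0), 0.8)
        kept = cn.enforce_interpeak_distance([p2, p1], 10.0)
        assert [p.ale_value for p in kept] == [0.9]

    def test_exactly_ten_mm_is_inclusive(self):
        p1 = self._peak((0, 0, 0), 0.9)
        p2 = self._peak((10, 0, 0), 0.8)
        kept = cn.enforce_interpeak_distance([p1, p2], 10.0)
        assert len(kept) == 2

    def test_distant_peaks_all_preserved(self):
        peaks = [self._peak((20 * i, 0, 0), 0.5 + 0.01 * i) for i in range(5)]
        kept = cn.enforce_interpeak_distance(peaks, 10.0)
        assert len(kept) == 5
        assert [p.ale_value for p in kept] == sorted(
            (p.ale_value for p in peaks), reverse=True)

    @given(st.permutations(range(6)))
    def test_result_independent_of_input_order(self, order):
        rng = np.random.default_rng(99)
        pts = rng.uniform(-30, 30, (6, 3))
        vals = rng.uniform(0.1, 1.0, 6)
        peaks = [self._peak(tuple(pts[i]), float(vals[i]),
                            vox=(i, 0, 0)) for i in range(6)]
        ref = cn.enforce_interpeak_distance(peaks, 12.0)
        shuffled = cn.enforce_interpeak_distance([peaks[i] for i in order],
                                                 12.0)
        assert [p.voxel for p in shuffled] == [p.voxel for p in ref]

    def test_empty_input(self):
        assert cn.enforce_interpeak_distance([], 10.0) == []


class TestLabelNodes:
    def _passing(self, atlas, labels):
        return [cn.RegionAlteration(lab, atlas.name_of(lab), 100, True)
                for lab in labels]

    def test_rostrocaudal_numbering(self, two_region_atlas):
        atlas = two_region_atlas
        grid = atlas.grid
        ys = [8.0, 4.0, 0.0, -4.0, -8.0, 6.0]
        peaks = []
        for i, y in enumerate(ys):
            xyz = (-10.0, y, 0.0)
            peaks.append(Peak(voxel=tuple(grid.world_to_voxel(xyz)),
                              xyz=xyz, ale_value=0.5 + 0.01 * i))
        nodes = cn.label_nodes(peaks, atlas, self._passing(atlas, [1]))
        assert [n.id for n in nodes] == [f"Box_L_{k}" for k in range(1, 7)]
        assert [n.y for n in nodes] == sorted(ys, reverse=True)

    def test_background_peak_dropped(self, two_region_atlas, caplog):
        atlas = two_region_atlas
        p = Peak(voxel=(0, 0, 0), xyz=(-40.0, -40.0, -40.0), ale_value=0.9)
        with caplog.at_level("WARNING"):
            nodes = cn.label_nodes([p], atlas, self._passing(atlas, [1, 2]))
        assert nodes == []
        assert any("background" in r.message for r in caplog.records)

    def test_nonpassing_region_peak_dropped(self, two_region_atlas):
        atlas = two_region_atlas
        xyz = (10.0, 0.0, 0.0)
        p = Peak(voxel=tuple(atlas.grid.world_to_voxel(xyz)), xyz=xyz,
                 ale_value=0.9)
        regions = [cn.RegionAlteration(2, "Box_R", 5, False),
                   cn.RegionAlteration(1, "Box_L", 100, True)]
        assert cn.label_nodes([p], atlas, regions) == []

    def test_equal_y_tie_broken_by_value(self, two_region_atlas):
        atlas = two_region_atlas
        a = Peak(voxel=tuple(atlas.grid.world_to_voxel((-14.0, 0.0, 0.0))),
                 xyz=(-14.0, 0.0, 0.0), ale_value=0.4)
        b = Peak(voxel=tuple(atlas.grid.world_to_voxel((-6.0, 0.0, 0.0))),
                 xyz=(-6.0, 0.0, 0.0), ale_value=0.7)
        nodes = cn.label_nodes([a, b], atlas, self._passing(atlas, [1]))
        assert nodes[0].id == "Box_L_1"
        assert nodes[0].ale_value == 0.7


@pytest.fixture(scope="module")
def fixture_map():
    spec = cn.GenerativeSpec(n_experiments=25, seed=4)
    grid = cn.VolumeGrid.talairach(4.0)
    data = cn.simulate_dataset(spec, grid)
    ale = cn.compute_ale(data.experiments, grid)
    cutoff = np.quantile(ale.values[ale.values > 0], 0.8)
    values = np.where(ale.values >= cutoff, ale.values, 0.0)
    return as_ale(grid, values), data.atlas


class TestBuildNodesMonotonicity:
    def test_node_count_nonincreasing_in_each_threshold(self, fixture_map):
        ale, atlas = fixture_map
        counts = [len(cn.build_nodes(ale, atlas, min_region_voxels=v))
                  for v in (1, 10, 20, 50)]
        assert counts == sorted(counts, reverse=True)
        counts = [len(cn.build_nodes(ale, atlas, percentile=p))
                  for p in (0, 50, 90)]
        assert counts == sorted(counts, reverse=True)
        counts = [len(cn.build_nodes(ale, atlas, min_interpeak_mm=d))
                  for d in (0, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_peaks_canonical(self):
        p1 = Peak((0, 0, 1), (0, 0, 2.0), 0.5)
        p2 = Peak((0, 0, 0), (0, 0, 0.0), 0.5)
        assert _sorted_peaks([p1, p2]) == [p2, p1]
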