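"""Point mapping, uncertainty-bounded baseline search, percent changes."""

import numpy as np
import pytest

from percist.alignment import DisplacementField
from percist.hotspots import detect_hotspots, classify_hotspots
from percist.longitudinal import (
    build_pairs,
    map_point,
    paired_sulpeak,
    percent_change,
)
from percist.volumes import ImageGrid, ScalarVolume


def make_field(grid, u_fn):
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    pts = grid.voxel_to_world(idx)
    u = u_fn(pts)
    return DisplacementField(grid=grid, u=u, regions=np.ones(grid.shape, dtype=np.int32))


class TestMapPoint:
    def _grid(self):
        return ImageGrid(shape=(16, 16, 16), spacing=(2, 2, 2))

    def test_zero_field_identity(self):
        field = make_field(self._grid(), lambda p: np.zeros(p.shape))
        p = np.array([10.0, 12.0, 14.0])
        assert np.allclose(map_point(field, p), p)

    def test_constant_field_shifts(self):
        field = make_field(self._grid(), lambda p: np.broadcast_to([5.0, 0, 0], p.shape).copy())
        p = np.array([10.0, 12.0, 14.0])
        assert np.allclose(map_point(field, p), p + [5.0, 0, 0])

    def test_linear_field_interpolates(self):
        # u_x grows linearly from 0 at x=0 mm to 10 at x=30 mm
        field = make_field(self._grid(), lambda p: np.stack(
            [p[..., 0] / 3.0, np.zeros(p.shape[:-1]), np.zeros(p.shape[:-1])], axis=-1
        ))
        p = np.array([15.0, 16.0, 16.0])
        mapped = map_point(field, p)
        assert mapped[0] == pytest.approx(15.0 + 5.0, abs=0.1)

    def test_outside_grid_raises(self):
        field = make_field(self._grid(), lambda p: np.zeros(p.shape))
        with pytest.raises(ValueError, match="outside"):
            map_point(field, np.array([100.0, 0, 0]))


class TestPairedSulpeak:
    def _scene(self):
        grid = ImageGrid(shape=(40, 40, 40), spacing=(2, 2, 2))
        values = np.full(grid.shape, 0.5)
        idx = np.stack(np.meshgrid(*[np.arange(40)] * 3, indexing="ij"), axis=-1)
        pts = idx * 2.0
        lesion = np.sum((pts - np.array([40.0, 40, 40])) ** 2, axis=-1) <= 10**2
        values[lesion] = 6.0
        sul = ScalarVolume(grid=grid, values=values, kind="SUL")
        return grid, sul

    def test_radius_zero_single_centre(self):
        grid, sul = self._scene()
        none_mask = np.zeros(grid.shape, dtype=bool)
        v0, _ = paired_sulpeak(sul, none_mask, np.array([40.0, 40, 40]), 0.0)
        from percist.hotspots import peak_mean_map

        assert v0 == pytest.approx(peak_mean_map(sul)[20, 20, 20])

    def test_radius_recovers_displaced_lesion_peak(self):
        grid, sul = self._scene()
        none_mask = np.zeros(grid.shape, dtype=bool)
        # mapped centre off by 6 mm; radius 8 mm must reach the true peak
        v, _ = paired_sulpeak(sul, none_mask, np.array([46.0, 40, 40]), 8.0)
        v_true, _ = paired_sulpeak(sul, none_mask, np.array([40.0, 40, 40]), 0.0)
        assert v == pytest.approx(v_true, rel=0.01)

    def test_physiological_sphere_absent(self):
        grid, sul = self._scene()
        normal = np.ones(grid.shape, dtype=bool)
        v, loc = paired_sulpeak(sul, normal, np.array([40.0, 40, 40]), 6.0)
        assert v is None and loc is None

    def test_radius_monotonicity(self):
        grid, sul = self._scene()
        none_mask = np.zeros(grid.shape, dtype=bool)
        centre = np.array([50.0, 44, 40])
        vals = [
            paired_sulpeak(sul, none_mask, centre, r)[0] for r in (0.0, 4.0, 8.0, 12.0, 20.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPercentChange:
    def test_halving_is_minus_fifty(self):
        assert percent_change(10.0, 5.0) == pytest.approx(-50.0)

    def test_signed_increase(self):
        assert percent_change(2.0, 2.8) == pytest.approx(40.0)

    def test_no_change_is_zero(self):
        for b in (0.5, 1.0, 7.3):
            assert percent_change(b, b) == 0.0

    def test_absent_baseline_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_change(0.0, 5.0)


class TestBuildPairs:
    def _identity_setup(self, static_pair, shipped_table):
        from percist.background import background_stats, place_liver_voi
        from percist.uncertainty import uncertainty_map

        organs = static_pair.followup_organs
        sul = static_pair.followup_sul
        liver_label = [k for k, v in organs.legend.items() if v == "liver"][0]
        voi = place_liver_voi(sul, organs.mask(liver_label))
        thr = background_stats(sul, voi).threshold
        spots = detect_hotspots(sul, thr)
        classify_hotspots(spots, static_pair.followup_normal.labels > 0, sul.grid.shape)
        lesions = [h for h in spots if h.hotspot_class == "lesion"]
        grid = sul.grid
        field = DisplacementField(
            grid=grid,
            u=np.zeros(tuple(grid.shape) + (3,)),
            regions=np.ones(grid.shape, dtype=np.int32),
        )
        umap = uncertainty_map(organs, shipped_table)
        return lesions, field, umap

    def test_identity_phantom_changes_near_zero(self, static_pair, shipped_table):
        lesions, field, umap = self._identity_setup(static_pair, shipped_table)
        pairs = build_pairs(
            lesions,
            field,
            umap,
            static_pair.baseline_sul,
            static_pair.baseline_normal.labels > 0,
        )
        assert len(pairs) == 2
        for p in pairs:
            assert p.percent_change == pytest.approx(0.0, abs=2.0)

    def test_pairs_sorted_by_followup_peak(self, static_pair, shipped_table):
        lesions, field, umap = self._identity_setup(static_pair, shipped_table)
        pairs = build_pairs(
            lesions,
            field,
            umap,
            static_pair.baseline_sul,
            static_pair.baseline_normal.labels > 0,
        )
        peaks = [p.followup_sul_peak for p in pairs]
        assert peaks == sorted(peaks, reverse=True)

    def test_two_close_lesions_share_hotter_baseline(self):
        # documented failure mode: when two lesions fall inside one search
        # sphere, both follow-up lesions pair with the hotter baseline one
        grid = ImageGrid(shape=(48, 48, 24), spacing=(2, 2, 2))
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
        pts = idx * 2.0
        values = np.full(grid.shape, 0.5)
        hot = np.sum((pts - np.array([30.0, 48, 24])) ** 2, axis=-1) <= 8**2
        cool = np.sum((pts - np.array([58.0, 48, 24])) ** 2, axis=-1) <= 8**2
        values[hot] = 8.0
        values[cool] = 5.0
        sul = ScalarVolume(grid=grid, values=values, kind="SUL")
        spots = detect_hotspots(sul, threshold=3.0)
        classify_hotspots(spots, np.zeros(grid.shape, dtype=bool), grid.shape)
        field = DisplacementField(
            grid=grid,
            u=np.zeros(tuple(grid.shape) + (3,)),
            regions=np.ones(grid.shape, dtype=np.int32),
        )
        umap = ScalarVolume(grid=grid, values=np.full(grid.shape, 30.0), kind="uncertainty_mm")
        pairs = build_pairs(spots, field, umap, sul, np.zeros(grid.shape, dtype=bool))
        assert len(pairs) == 2
        # both report the hotter lesion's baseline SULpeak
        assert pairs[0].baseline_sul_peak == pytest.approx(pairs[1].baseline_sul_peak)
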