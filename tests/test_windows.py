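"""Tiling, window classification and the per-class segmentation policy."""

import numpy as np
import pytest

import fruitdefect as fd
from fruitdefect import WindowAction, WindowClass
from fruitdefect._counters import counters, reset_counters
from fruitdefect.errors import ConfigError
from oracles import exhaustive_otsu


class TestTile:
    @pytest.mark.parametrize(
        "extent, n, offset, step, expected",
        [
            ((400, 400), 100, (0, 0), 100, 16),  # primary grid
            ((400, 400), 100, (50, 50), 100, 9),  # offset secondary grid
            ((200, 200), 100, (0, 0), 100, 4),
            ((400, 400), 100, (0, 0), 50, 49),  # 50% overlap mode
        ],
    )
    def test_window_counts(self, extent, n, offset, step, expected):
        assert len(fd.tile(extent, n, offset=offset, step=step)) == expected

    def test_partition_covers_each_pixel_once(self):
        grid = fd.tile((400, 400), 100)
        cover = np.zeros((400, 400), dtype=int)
        for w in grid.windows:
            cover[w.slices] += 1
        assert (cover == 1).all()

    def test_row_major_half_open(self):
        grid = fd.tile((200, 200), 100)
        first = grid.windows[0]
        assert (first.row, first.col, first.y0, first.x0, first.y1, first.x1) == (0, 0, 0, 0, 100, 100)
        assert [(w.row, w.col) for w in grid.windows] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_non_divisible_extent_rejected(self):
        with pytest.raises(ConfigError):
            fd.tile((410, 400), 100)

    def test_offset_bounds_enforced(self):
        with pytest.raises(ConfigError):
            fd.tile((400, 400), 100, offset=(100, 0))


class TestClassifyWindow:
    def make_window(self, n_zeros, size=10000):
        w = np.full(size, 150, dtype=np.uint8)
        w[:n_zeros] = 0
        return w.reshape(100, 100)

    @pytest.mark.parametrize(
        "n_zeros, expected",
        [
            (10000, WindowClass.BACKGROUND),
            (501, WindowClass.EDGE),  # just above the 1/20 boundary
            (500, WindowClass.FOREGROUND),  # exactly 1/20: not an edge block
            (0, WindowClass.FOREGROUND),
        ],
    )
    def test_zero_count_rules(self, n_zeros, expected):
        assert fd.classify_window(self.make_window(n_zeros)) == expected


class TestSegmentWindow:
    def test_uniform_window_adopts_mask(self):
        s = np.full((50, 50), 200, dtype=np.uint8)
        mask = np.ones((50, 50), dtype=bool)
        sound, rec = fd.segment_window(s, mask, WindowClass.FOREGROUND)
        assert rec.action is WindowAction.ADOPT_MASK
        assert np.array_equal(sound, mask)
        assert rec.delta_d is None  # degenerate split carries no gate evidence

    def test_two_level_window_is_otsu_split(self):
        s = np.full((40, 40), 200, dtype=np.uint8)
        s[:, :20] = 60
        mask = np.ones((40, 40), dtype=bool)
        sound, rec = fd.segment_window(s, mask, WindowClass.FOREGROUND, delta_gate=30)
        assert rec.action is WindowAction.OTSU_SEGMENTED
        assert rec.delta_d == pytest.approx(140.0)
        hist = np.bincount(s.ravel(), minlength=256)
        assert rec.T == exhaustive_otsu(hist)
        assert sound.sum() == 40 * 20 and sound[:, 20:].all()

    def test_all_zero_window_skips_without_otsu(self):
        reset_counters()
        s = np.zeros((30, 30), dtype=np.uint8)
        sound, rec = fd.segment_window(s, np.zeros((30, 30), dtype=bool), WindowClass.BACKGROUND)
        assert rec.action is WindowAction.SKIP_ZERO
        assert not sound.any()
        assert counters["otsu_calls"] == 0

    def test_sparse_edge_sliver_treated_as_background(self):
        s = np.zeros((50, 50), dtype=np.uint8)
        s[0, :10] = 180  # fewer than min_pixels nonzero
        sound, rec = fd.segment_window(s, s > 0, WindowClass.EDGE)
        assert rec.action is WindowAction.SKIP_ZERO
        assert not sound.any()


class TestRunPass:
    def test_sound_scene_triggers_no_otsu_segmentation(self, sound_scene):
        fm = fd.compute_fruit_mask(sound_scene.image)
        masked = fd.apply_mask(sound_scene.image, fm)
        res = fd.run_pass(masked.s_channel, fm.mask, 100)
        assert res.n_otsu_segmented == 0

    def test_defect_window_located_by_ground_truth(self, one_defect_scene):
        fm = fd.compute_fruit_mask(one_defect_scene.image)
        masked = fd.apply_mask(one_defect_scene.image, fm)
        res = fd.run_pass(masked.s_channel, fm.mask, 100)
        segmented = [r.grid_pos for r in res.records if r.action is WindowAction.OTSU_SEGMENTED]
        assert segmented == [(1, 1)]  # the window containing the defect

    def test_pass2_grid_has_nine_records(self, sound_scene):
        fm = fd.compute_fruit_mask(sound_scene.image)
        masked = fd.apply_mask(sound_scene.image, fm)
        res = fd.run_pass(masked.s_channel, fm.mask, 100, offset=(50, 50), pass_id=2)
        assert len(res.records) == 9
        assert all(r.pass_id == 2 for r in res.records)

    def test_every_window_gets_exactly_one_class(self, three_defect_scene):
        fm = fd.compute_fruit_mask(three_defect_scene.image)
        masked = fd.apply_mask(three_defect_scene.image, fm)
        res = fd.run_pass(masked.s_channel, fm.mask, 100)
        assert len(res.records) == 16
        by_class = {c: sum(1 for r in res.records if r.window_class is c) for c in WindowClass}
        assert sum(by_class.values()) == 16

    def test_sound_map_zero_outside_fruit(self, three_defect_scene):
        fm = fd.compute_fruit_mask(three_defect_scene.image)
        masked = fd.apply_mask(three_defect_scene.image, fm)
        res = fd.run_pass(masked.s_channel, fm.mask, 100)
        assert not (res.sound_map & ~fm.mask).any()

    def test_gate_monotonicity(self, three_defect_scene):
        # raising the gate never enlarges the otsu-segmented window set
        fm = fd.compute_fruit_mask(three_defect_scene.image)
        masked = fd.apply_mask(three_defect_scene.image, fm)
        sets = []
        for gate in (20, 30, 40, 80):
            res = fd.run_pass(masked.s_channel, fm.mask, 100, delta_gate=gate)
            sets.append({r.grid_pos for r in res.records if r.action is WindowAction.OTSU_SEGMENTED})
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


def test_records_csv_export(one_defect_scene):
    res = fd.detect(one_defect_scene.image)
    from fruitdefect.windows import records_to_csv

    text = records_to_csv(res.records)
    lines = text.strip().splitlines()
    assert lines[0] == "pass,row,col,class,T,delta_d,action"
    assert len(lines) == 1 + 16 + 9
    assert any("otsu_segmented" in ln for ln in lines)
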