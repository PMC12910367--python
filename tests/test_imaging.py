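"""Canopy segmentation, per-plant projected leaf area and floor coverage."""

import math

import numpy as np
import pytest

from clgrow.imaging import (
    CanopyImage,
    CanopyMask,
    OverlapError,
    PlantLayout,
    chessboard_layout,
    floor_coverage_series,
    per_plant_pla,
    segment_canopy,
)
from clgrow.synth import render_topview


def _uniform_image(r, g, b, shape=(60, 80)):
    px = np.zeros((*shape, 3), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return CanopyImage(pixels=px, cm_per_px=0.05)


class TestSegmentation:
    def test_uniform_green_is_all_plant(self):
        with pytest.warns(RuntimeWarning):
            mask = segment_canopy(_uniform_image(30, 200, 30))
        assert mask.coverage_fraction == 1.0

    def test_uniform_black_is_all_background(self):
        with pytest.warns(RuntimeWarning):
            mask = segment_canopy(_uniform_image(0, 0, 0))
        assert mask.coverage_fraction == 0.0

    def test_fixed_threshold_mode(self):
        mask = segment_canopy(_uniform_image(30, 200, 30), "fixed", fixed_threshold=10.0)
        assert mask.coverage_fraction == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            segment_canopy(_uniform_image(0, 100, 0), "quantile")

    def test_disc_coverage_matches_analytic_area(self):
        """Rendered discs: segmented coverage within 2% of k*pi*r^2/total."""
        layout = chessboard_layout(2, 3)
        pla = 60.0  # cm2 per plant, radius ~4.4 cm, well separated
        img, truth = render_topview([pla] * 6, layout, cm_per_px=0.05, seed=1)
        mask = segment_canopy(img)
        total_cm2 = mask.mask.size * 0.05 ** 2
        analytic = 6 * pla / total_cm2
        assert mask.coverage_fraction == pytest.approx(analytic, rel=0.02)

    def test_segmentation_f1_against_ground_truth(self):
        layout = chessboard_layout(2, 3)
        img, truth = render_topview([45.0] * 6, layout, cm_per_px=0.05, seed=2)
        pred = segment_canopy(img).mask
        tp = np.count_nonzero(pred & truth.mask)
        fp = np.count_nonzero(pred & ~truth.mask)
        fn = np.count_nonzero(~pred & truth.mask)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.99

    def test_coverage_invariant_under_rotation(self):
        layout = chessboard_layout(2, 2)
        img, _ = render_topview([30.0] * 4, layout, cm_per_px=0.1, seed=3)
        base = segment_canopy(img).coverage_fraction
        for k in (1, 2, 3):
            rot = CanopyImage(pixels=np.rot90(img.pixels, k), cm_per_px=0.1)
            assert segment_canopy(rot).coverage_fraction == pytest.approx(base, abs=1e-12)

    def test_degenerate_raster_rejected(self):
        with pytest.raises(ValueError):
            CanopyImage(pixels=np.zeros((4, 4)), cm_per_px=0.05)
        with pytest.raises(ValueError):
            CanopyImage(pixels=np.zeros((4, 4, 3)), cm_per_px=0.0)


class TestPerPlantPLA:
    def test_single_disc_area(self):
        """Disc of radius 50 px at 0.05 cm/px has PLA ~ pi*2.5^2 cm2."""
        layout = PlantLayout(centres=((5.0, 5.0),))
        yy, xx = np.mgrid[0:200, 0:200]
        disc = (xx - 100) ** 2 + (yy - 100) ** 2 <= 50 ** 2
        mask = CanopyMask(mask=disc, cm_per_px=0.05)
        # place the centre where the disc is: (100 px * 0.05 = 5 cm)
        [res] = per_plant_pla(mask, layout)
        assert res.pla_cm2 == pytest.approx(math.pi * 50 ** 2 * 0.05 ** 2, rel=0.02)
        assert not res.touches_border

    def test_empty_mask_gives_empty_list(self):
        layout = PlantLayout(centres=((1.0, 1.0),))
        mask = CanopyMask(mask=np.zeros((50, 50), dtype=bool), cm_per_px=0.05)
        assert per_plant_pla(mask, layout) == []

    def test_two_discs_matched_to_nearest_centres(self):
        layout = PlantLayout(centres=((2.0, 2.0), (6.0, 2.0)))
        yy, xx = np.mgrid[0:80, 0:160]
        m = ((xx - 40) ** 2 + (yy - 40) ** 2 <= 15 ** 2) | (
            (xx - 120) ** 2 + (yy - 40) ** 2 <= 20 ** 2
        )
        mask = CanopyMask(mask=m, cm_per_px=0.05)
        res = per_plant_pla(mask, layout)
        assert [r.plant_id for r in res] == [0, 1]
        assert res[0].pla_cm2 < res[1].pla_cm2  # smaller disc on the left

    def test_merged_plants_raise_overlap_error(self):
        layout = PlantLayout(centres=((2.0, 2.0), (4.0, 2.0)))
        yy, xx = np.mgrid[0:80, 0:120]
        # one blob spanning both centres (40 px and 80 px at 0.05 cm/px)
        m = ((xx - 60) ** 2 + (yy - 40) ** 2 <= 35 ** 2)
        mask = CanopyMask(mask=m, cm_per_px=0.05)
        with pytest.raises(OverlapError):
            per_plant_pla(mask, layout)

    def test_border_component_flagged_and_sum_bounded(self):
        layout = PlantLayout(centres=((0.5, 0.5), (3.0, 2.0)))
        yy, xx = np.mgrid[0:80, 0:120]
        m = ((xx - 5) ** 2 + (yy - 5) ** 2 <= 12 ** 2) | (
            (xx - 60) ** 2 + (yy - 40) ** 2 <= 10 ** 2
        )
        mask = CanopyMask(mask=m, cm_per_px=0.05)
        res = per_plant_pla(mask, layout)
        assert res[0].touches_border and not res[1].touches_border
        total = np.count_nonzero(m) * 0.05 ** 2
        assert sum(r.pla_cm2 for r in res) <= total + 1e-9
        assert sum(r.pla_cm2 for r in res) == pytest.approx(total, abs=1e-9)


class TestFloorCoverage:
    def test_fraction_passthrough(self):
        masks = [
            CanopyMask(mask=np.ones((10, 10), dtype=bool), cm_per_px=1.0, dat=3),
            CanopyMask(mask=np.zeros((10, 10), dtype=bool), cm_per_px=1.0, dat=1),
        ]
        masks[0].mask[5:, :] = True
        half = np.zeros((10, 10), dtype=bool)
        half[:5, :] = True
        masks.append(CanopyMask(mask=half, cm_per_px=1.0, dat=2))
        series = floor_coverage_series(masks)
        assert series == [(1, 0.0), (2, 50.0), (3, 100.0)]

    def test_duplicate_dat_requires_explicit_aggregation(self):
        m = np.ones((4, 4), dtype=bool)
        masks = [CanopyMask(mask=m, cm_per_px=1.0, dat=1),
                 CanopyMask(mask=~m, cm_per_px=1.0, dat=1)]
        with pytest.raises(ValueError):
            floor_coverage_series(masks)
        assert floor_coverage_series(masks, aggregate="mean") == [(1, 50.0)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            floor_coverage_series([])

    def test_growing_disc_stack_tracks_analytic_area(self):
        """Coverage of an exponentially growing disc stack follows
        min(1, n*pi*r(t)^2/A) within 2%."""
        layout = chessboard_layout(2, 2)
        area_cm2 = None
        for dat in (2, 6, 10):
            pla = 4.0 * math.exp(0.25 * dat)
            img, _ = render_topview([pla] * 4, layout, cm_per_px=0.05,
                                    seed=dat, dat=dat)
            mask = segment_canopy(img)
            if area_cm2 is None:
                area_cm2 = mask.mask.size * 0.05 ** 2
            expected = min(1.0, 4 * pla / area_cm2) * 100.0
            assert mask.coverage_fraction * 100 == pytest.approx(expected, rel=0.02)
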