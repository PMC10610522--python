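"""Cone-mask refinement: smoothing, dilation, application, extraction."""

import numpy as np
import pytest
from skimage import measure

from echoseg import phantom
from echoseg.cone import (
    apply_cone,
    dilate_cone_mask,
    extract_cone_geometric,
    smooth_cone_mask,
)
from echoseg.metrics import dice


def _sector(size=112, half_angle=45.0):
    return phantom.cone_sector_mask((size, size), (size / 2, 2.0), half_angle, size * 0.9)


def _boundary_notch_count(mask):
    """Foreground boundary pixels with >= 6 background 8-neighbours."""
    m = mask.astype(int)
    pad = np.pad(m, 1)
    neigh = sum(
        pad[1 + dy : 1 + dy + m.shape[0], 1 + dx : 1 + dx + m.shape[1]]
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dy, dx) != (0, 0)
    )
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = True
    return int((mask & interior & (neigh <= 2)).sum())


class TestSmooth:
    def test_smooth_sector_is_near_fixed_point(self):
        sector = _sector()
        out = smooth_cone_mask(sector)
        assert dice(out, sector) > 0.98
        # boundary moves at most ~1 px: symmetric difference is thin
        assert (out ^ sector).sum() < 0.05 * sector.sum()

    def test_notches_are_removed(self):
        rng = np.random.default_rng(0)
        sector = _sector()
        noisy = sector.copy()
        boundary = sector & ~np.roll(sector, 1, axis=0)
        ys, xs = np.nonzero(boundary)
        pick = rng.choice(len(ys), size=min(200, len(ys)), replace=False)
        noisy[ys[pick], xs[pick]] = False
        out = smooth_cone_mask(noisy)
        assert _boundary_notch_count(out) == 0

    def test_satellite_blob_removed(self):
        sector = _sector()
        noisy = sector.copy()
        noisy[2:4, 2:5] = True  # 6-px blob far from the sector
        out = smooth_cone_mask(noisy)
        assert measure.label(out).max() == 1
        assert not out[2:4, 2:5].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            smooth_cone_mask(np.zeros((32, 32), bool))

    def test_near_idempotent(self):
        sector = _sector()
        once = smooth_cone_mask(sector)
        twice = smooth_cone_mask(once)
        assert (once ^ twice).sum() < 0.01 * once.sum()


class TestDilate:
    def test_extensive_and_strictly_growing(self):
        sector = _sector()
        out = dilate_cone_mask(sector, iterations=2)
        assert (out & sector).sum() == sector.sum()  # superset
        assert out.sum() > sector.sum()

    def test_full_frame_saturates(self):
        full = np.ones((20, 20), bool)
        np.testing.assert_array_equal(dilate_cone_mask(full, 1), full)

    def test_single_pixel_becomes_square(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = dilate_cone_mask(m, iterations=1)
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_monotone_in_the_mask(self):
        small = _sector(half_angle=30.0)
        big = _sector(half_angle=45.0)
        ds, db = dilate_cone_mask(small, 2), dilate_cone_mask(big, 2)
        assert not (ds & ~db).any()


class TestApply:
    def test_identity_under_full_mask(self, default_frame_labels):
        frame, _ = default_frame_labels
        np.testing.assert_array_equal(
            apply_cone(frame, np.ones_like(frame, bool)), frame
        )

    def test_empty_mask_rejected(self, default_frame_labels):
        frame, _ = default_frame_labels
        with pytest.raises(ValueError):
            apply_cone(frame, np.zeros_like(frame, bool))

    def test_size_mismatch_rejected(self, default_frame_labels):
        frame, _ = default_frame_labels
        with pytest.raises(ValueError):
            apply_cone(frame, np.ones((10, 10), bool))

    def test_idempotent_in_the_mask(self, default_frame_labels):
        frame, _ = default_frame_labels
        mask = _sector()
        once = apply_cone(frame, mask)
        np.testing.assert_array_equal(apply_cone(once, mask), once)

    def test_true_cone_blanks_burn_in_bands(self, default_scene):
        frame, _ = phantom.render(default_scene)
        cone = phantom.cone_sector_mask(
            default_scene.frame_size,
            default_scene.cone_apex,
            default_scene.cone_half_angle,
            default_scene.cone_depth,
        )
        out = apply_cone(frame, cone)
        for r0, r1, c0, c1 in default_scene.artifact_bands:
            band = np.zeros_like(cone)
            band[r0:r1, c0:c1] = True
            assert out[band & ~cone].max() == 0


class TestExtract:
    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_analytic_sector(self, seed):
        scene = phantom.generate_scene(seed=seed)
        frame, _ = phantom.render(scene)
        true_cone = phantom.cone_sector_mask(
            scene.frame_size, scene.cone_apex, scene.cone_half_angle, scene.cone_depth
        )
        mask = extract_cone_geometric(frame)
        assert dice(mask, true_cone) >= 0.95

    def test_black_frame_rejected(self):
        with pytest.raises(ValueError):
            extract_cone_geometric(np.zeros((64, 64), np.uint8))

    def test_selects_larger_of_two_sectors(self):
        frame = np.zeros((112, 112), np.uint8)
        big = phantom.cone_sector_mask((112, 112), (30, 2), 30, 90)
        small = phantom.cone_sector_mask((112, 112), (95, 60), 20, 40)
        frame[big] = 150
        frame[small] = 150
        mask = extract_cone_geometric(frame)
        assert (mask & big).sum() / big.sum() > 0.95
        assert (mask & small).sum() / small.sum() < 0.5
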