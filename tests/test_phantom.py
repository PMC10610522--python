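"""Phantom generator: determinism, placement invariants, rendering
contracts and the leak-injection defect model."""

import numpy as np
import pytest

from echoseg import phantom
from echoseg.phantom import (
    PhantomConfig,
    ScenePlacementError,
    generate_scene,
    inject_leak,
    render,
)


def test_generation_is_deterministic():
    a = generate_scene(seed=0)
    b = generate_scene(seed=0)
    assert a == b
    fa, la = render(a)
    fb, lb = render(b)
    np.testing.assert_array_equal(fa, fb)
    np.testing.assert_array_equal(la, lb)


def test_impossible_cone_raises_with_reason():
    cfg = PhantomConfig(cone_half_angle=1.0)
    with pytest.raises(ScenePlacementError, match="outside the cone"):
        generate_scene(cfg, seed=0)


def test_small_frame_rejected():
    with pytest.raises(ValueError):
        generate_scene(PhantomConfig(frame_size=(32, 32)), seed=0)


@pytest.mark.parametrize("seed", range(8))
def test_scene_invariants(seed):
    """Ventricles above same-side atria, chambers inside the cone and
    pairwise disjoint (checked by area accounting on the label map)."""
    scene = generate_scene(seed=seed)
    _, labels = render(scene)
    cone = phantom.cone_sector_mask(
        scene.frame_size, scene.cone_apex, scene.cone_half_angle, scene.cone_depth
    )
    areas = {}
    for ch in scene.chambers:
        em = phantom.ellipse_mask(
            scene.frame_size, ch.center, ch.semi_axes, ch.rotation
        )
        # rendered region == ellipse ∩ cone (disjointness by construction)
        np.testing.assert_array_equal(labels == ch.class_id, em & cone)
        areas[ch.class_id] = int(em.sum())
    assert sum(areas.values()) == int((labels > 0).sum())
    for v, a in ((1, 2), (3, 4)):
        assert (
            np.flatnonzero((labels == v).any(axis=1))[0]
            < np.flatnonzero((labels == a).any(axis=1))[0]
        )


def test_render_intensity_contracts(default_scene):
    frame, labels = render(default_scene)
    assert frame.dtype == np.uint8
    assert set(np.unique(labels)) <= {0, 1, 2, 3, 4}
    cone = phantom.cone_sector_mask(
        default_scene.frame_size,
        default_scene.cone_apex,
        default_scene.cone_half_angle,
        default_scene.cone_depth,
    )
    bands = np.zeros_like(cone)
    for r0, r1, c0, c1 in default_scene.artifact_bands:
        bands[r0:r1, c0:c1] = True
    outside = ~cone & ~bands
    assert frame[outside].max() == 0
    assert frame[bands & ~cone].min() > 0  # burn-ins visible outside the cone


def test_noise_free_render_is_piecewise_constant(default_scene):
    from dataclasses import replace

    scene = replace(default_scene, speckle_scale=0.0)
    frame, labels = render(scene)
    for ch in scene.chambers:
        mean = frame[labels == ch.class_id].mean() / 255.0
        assert mean == pytest.approx(ch.intensity, abs=0.5 / 255 + 1e-9)


def test_speckle_adds_in_cone_variance(default_scene):
    frame, labels = render(default_scene)
    cone = phantom.cone_sector_mask(
        default_scene.frame_size,
        default_scene.cone_apex,
        default_scene.cone_half_angle,
        default_scene.cone_depth,
    )
    tissue = cone & (labels == 0)
    assert frame[tissue].std() > 1.0


class TestInjectLeak:
    def test_zero_extent_is_identity(self, default_frame_labels):
        _, labels = default_frame_labels
        np.testing.assert_array_equal(inject_leak(labels, 3, 0), labels)

    def test_leak_crosses_atrium_top(self, default_frame_labels):
        _, labels = default_frame_labels
        ra_top = np.flatnonzero((labels == 4).any(axis=1))[0]
        rv_bot = np.flatnonzero((labels == 3).any(axis=1))[-1]
        leaked = inject_leak(labels, 3, int(ra_top - rv_bot) + 25, seed=0)
        assert np.flatnonzero((leaked == 3).any(axis=1))[-1] > ra_top

    def test_leak_only_adds_pixels_and_preserves_other_classes(
        self, default_frame_labels
    ):
        _, labels = default_frame_labels
        leaked = inject_leak(labels, 3, 30, seed=1)
        assert (leaked == 3).sum() > (labels == 3).sum()
        for c in (1, 2, 4):
            np.testing.assert_array_equal(leaked == c, labels == c)
        # overwrites background only
        changed = leaked != labels
        assert np.all(labels[changed] == 0)

    def test_leak_remains_connected(self, default_frame_labels):
        from skimage import measure

        _, labels = default_frame_labels
        leaked = inject_leak(labels, 3, 40, seed=2)
        assert measure.label(leaked == 3).max() == 1

    def test_missing_classes_raise(self, default_frame_labels):
        _, labels = default_frame_labels
        no_ra = labels.copy()
        no_ra[no_ra == 4] = 0
        with pytest.raises(ValueError, match="adjacent"):
            inject_leak(no_ra, 3, 10)
        with pytest.raises(ValueError, match="not present"):
            inject_leak(np.zeros((64, 64), np.uint8), 3, 10)
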