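"""Color metric, normal estimation and region-growth behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shootpheno import ColoredPointCloud, DenoiseParams, NoiseColorList
from shootpheno.denoise import (
    color_difference, denoise_region_growth, estimate_normals, seed_indices,
)

channel = st.integers(0, 255)
rgb = st.tuples(channel, channel, channel)


def test_color_difference_identity_and_extremes():
    assert color_difference((100, 100, 100), (100, 100, 100)) == 0.0
    # oracle: direct hand evaluation — rbar = 127.5, coefficients
    # 2 + 127.5/256, 4, 2 + 127.5/256 give 255 * sqrt(8 + 255/256)
    expected = 255.0 * np.sqrt(8.0 + 255.0 / 256.0)
    assert color_difference((0, 0, 0), (255, 255, 255)) == pytest.approx(
        expected, abs=1e-9
    )


@settings(max_examples=200, deadline=None)
@given(rgb, rgb)
def test_color_difference_symmetric_and_nonnegative(a, b):
    d1 = color_difference(a, b)
    d2 = color_difference(b, a)
    assert d1 == pytest.approx(d2, abs=1e-9)
    assert d1 >= 0.0
    if a == b:
        assert d1 == 0.0


def test_color_difference_rejects_out_of_range():
    with pytest.raises(ValueError):
        color_difference((0, 0, 300), (0, 0, 0))


def test_normals_on_plane_are_vertical():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 100, 500),
                           rng.uniform(0, 100, 500), np.zeros(500)])
    cloud = ColoredPointCloud(pts, np.full((500, 3), 120, dtype=np.uint8))
    out = estimate_normals(cloud, k=12)
    np.testing.assert_allclose(np.abs(out.normals[:, 2]), 1.0, atol=1e-6)


def test_normals_on_cylinder_are_radial():
    rng = np.random.default_rng(1)
    theta = rng.uniform(0, 2 * np.pi, 3000)
    z = rng.uniform(0, 300, 3000)
    pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta), z])
    cloud = ColoredPointCloud(pts, np.full((3000, 3), 120, dtype=np.uint8))
    out = estimate_normals(cloud, k=16)
    radial = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(3000)])
    ang = np.degrees(np.arccos(
        np.clip(np.abs(np.einsum("ni,ni->n", out.normals, radial)), -1, 1)
    ))
    assert np.percentile(ang, 95) < 5.0
    # outward orientation from the axis
    assert (np.einsum("ni,ni->n", out.normals, radial) > 0).mean() > 0.99


def test_normals_k_larger_than_cloud_errors():
    cloud = ColoredPointCloud(np.zeros((5, 3)), np.zeros((5, 3), np.uint8))
    with pytest.raises(ValueError):
        estimate_normals(cloud, k=10)


def test_no_gray_points_is_a_no_op():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 100, (400, 3))
    colors = np.tile([50, 160, 55], (400, 1)).astype(np.uint8)
    cloud = ColoredPointCloud(pts, colors)
    clean, removed = denoise_region_growth(cloud)
    assert len(removed) == 0
    assert len(clean) == len(cloud)


def test_partition_and_index_validity(small_shoot):
    _, cloud, truth = small_shoot
    clean, removed = denoise_region_growth(cloud)
    assert len(clean) + len(removed) == len(cloud)
    assert len(np.unique(removed)) == len(removed)
    assert removed.min() >= 0 and removed.max() < len(cloud)


def test_noise_recovery_under_defaults(small_shoot):
    """Palette-seeded removal recovers injected gray-back noise."""
    _, cloud, truth = small_shoot
    _, removed = denoise_region_growth(cloud)
    rem = np.zeros(len(cloud), bool)
    rem[removed] = True
    recall = (rem & truth.noise_mask).sum() / truth.noise_mask.sum()
    leaf_real = (truth.labels >= 10) & ~truth.noise_mask
    false_removal = (rem & leaf_real).sum() / leaf_real.sum()
    assert recall >= 0.95
    assert false_removal <= 0.01


def test_threshold_monotonicity():
    """Raising the discriminant cutoff never removes fewer points."""
    from shootpheno.synth import generate_shoot, random_spec

    for seed in (3, 4):
        cloud, _ = generate_shoot(random_spec("v5", seed=seed,
                                              point_density=0.2))
        sizes = []
        for thr in (-10.0, -6.0, -3.0):
            params = DenoiseParams(delta_threshold=thr)
            _, removed = denoise_region_growth(cloud, params=params)
            sizes.append(len(removed))
        assert sizes == sorted(sizes)


def test_idempotence(small_shoot):
    _, cloud, _ = small_shoot
    clean, removed1 = denoise_region_growth(cloud)
    clean2, removed2 = denoise_region_growth(clean)
    assert len(removed2) <= max(1, 0.001 * len(clean))


def test_inverted_sign_grows_through_similar_colors():
    """delta = eta1*dC + eta2*theta at zero classifies iff 0 < threshold.

    A gray seed surrounded by identically colored, identically oriented
    neighbors has delta exactly 0 for every neighbor: with the inverted
    sign convention and its positive default threshold the patch is
    consumed; the as-printed negative threshold leaves growth inert but
    still removes the seeds themselves.
    """
    rng = np.random.default_rng(5)
    n = 300
    pts = np.column_stack([rng.uniform(0, 50, n), rng.uniform(0, 50, n),
                           np.zeros(n)])
    colors = np.tile([128, 128, 128], (n, 1)).astype(np.uint8)
    cloud = ColoredPointCloud(pts, colors)
    # every point matches the palette, so everything seeds either way
    assert len(seed_indices(cloud, NoiseColorList())) == n
    for invert, thr in ((True, 1.5), (False, -8.0)):
        params = DenoiseParams(delta_threshold=thr, invert_color_term=invert)
        _, removed = denoise_region_growth(cloud, NoiseColorList(), params)
        assert len(removed) == n
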