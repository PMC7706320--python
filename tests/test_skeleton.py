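"""Contraction, topology extraction, refinement and spline resampling."""

import numpy as np
import pytest

from shootpheno import ColoredPointCloud, ContractionParams, contract_cloud, topologize
from shootpheno.skeleton import (
    chain_arc_length, refine_skeleton, resample_chain, voxel_downsample,
    _farthest_point_sampling,
)


def _gray(pts):
    return ColoredPointCloud(pts, np.full((len(pts), 3), 100, np.uint8))


def test_line_stays_collinear_under_contraction():
    rng = np.random.default_rng(0)
    t = rng.uniform(0, 300, 2000)
    pts = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    out = contract_cloud(_gray(pts), ContractionParams(downsample_voxel=2.0))
    assert np.abs(out[:, 1:]).max() < 1e-3


def test_cylinder_contracts_to_axis():
    rng = np.random.default_rng(1)
    n = 6000
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, 200, n)
    pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), z])
    out = contract_cloud(_gray(pts), ContractionParams(downsample_voxel=2.0))
    # off-axis distance of the contracted interior (ends flare slightly)
    interior = (out[:, 2] > 20) & (out[:, 2] < 180)
    assert np.median(np.linalg.norm(out[interior, :2], axis=1)) < 1.0


def test_contraction_never_grows_bounding_box():
    rng = np.random.default_rng(2)
    pts = rng.normal(0, 30, (3000, 3))
    params = ContractionParams(downsample_voxel=2.0, max_contraction_iters=1)
    vol_prev = np.prod(np.ptp(voxel_downsample(pts, 2.0), axis=0))
    X = voxel_downsample(pts, 2.0)
    for _ in range(4):
        X = contract_cloud(X, ContractionParams(downsample_voxel=0.0,
                                                max_contraction_iters=1))
        vol = np.prod(np.ptp(X, axis=0))
        assert vol <= vol_prev * (1 + 1e-9)
        vol_prev = vol


def test_topologize_y_shape():
    """A Y of three straight segments: one stem chain plus one leaf chain."""
    z = np.linspace(0, 200, 120)
    stem = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    s = np.linspace(0, 120, 80)
    branch = np.column_stack([s * 0.7, np.zeros_like(s), 100 + s * 0.7])
    skel = topologize(np.vstack([stem, branch]), sample_radius=10.0)
    assert len(skel.leaves) == 1
    assert skel.stem[0, 2] < skel.stem[-1, 2]              # bottom -> top
    leaf = skel.leaves[0]
    assert np.linalg.norm(leaf[0] - [0, 0, 100]) < 25      # rooted at the fork
    assert leaf[-1][0] > leaf[0][0]                        # base -> tip


def test_topologize_single_segment_has_no_leaves():
    z = np.linspace(0, 150, 100)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    skel = topologize(pts, sample_radius=10.0)
    assert skel.leaves == []


def test_fps_covers_at_radius():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 100, (2000, 3))
    samples = _farthest_point_sampling(pts, 15.0)
    from scipy.spatial import cKDTree
    d, _ = cKDTree(samples).query(pts)
    assert d.max() <= 15.0 + 1e-9


def test_refinement_recenters_offset_tube_axis():
    """A chain offset 5 mm from a tube's axis moves back within 1 mm."""
    rng = np.random.default_rng(4)
    n = 8000
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, 300, n)
    pts = np.column_stack([8 * np.cos(theta), 8 * np.sin(theta), z])
    cloud = _gray(pts)
    zc = np.linspace(10, 290, 30)
    chain = np.column_stack([np.full_like(zc, 5.0), np.zeros_like(zc), zc])
    from shootpheno.skeleton import Skeleton
    skel = Skeleton(stem=chain)
    refined = refine_skeleton(skel, cloud, sample_radius=10.0,
                              extend_tips=False)
    interior = (refined.stem[:, 2] > 30) & (refined.stem[:, 2] < 270)
    off = np.linalg.norm(refined.stem[interior, :2], axis=1)
    assert np.median(off) < 1.0
    # bounded update: no point moved farther than the disk radius
    move = np.linalg.norm(refined.stem - chain, axis=1)
    assert move.max() <= 1.5 * 10.0 + 1e-9


def test_resample_line_is_uniform():
    chain = np.array([[0, 0, 0], [100, 0, 0], [250, 0, 0], [400, 0, 0.0]])
    out = resample_chain(chain, 10)
    assert out.shape == (10, 3)
    steps = np.diff(out[:, 0])
    np.testing.assert_allclose(steps, steps[0], rtol=1e-9)
    np.testing.assert_allclose(out[0], chain[0])
    np.testing.assert_allclose(out[-1], chain[-1])


def test_resample_two_points_returns_endpoints():
    chain = np.array([[0, 0, 0], [5, 0, 0], [10, 1, 0], [20, 0, 0.0]])
    out = resample_chain(chain, 2)
    np.testing.assert_allclose(out[0], chain[0])
    np.testing.assert_allclose(out[-1], chain[-1])


def test_resample_quarter_circle_arc_length():
    """Closed-form oracle: quarter circle r=100 has length 50*pi ~ 157.08."""
    theta = np.linspace(0, np.pi / 2, 20)
    chain = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta),
                             np.zeros_like(theta)])
    out = resample_chain(chain, 50)
    seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert chain_arc_length(out) == pytest.approx(50 * np.pi, rel=2e-3)
    assert seg.std() / seg.mean() < 0.005


def test_resample_length_converges_monotonically():
    theta = np.linspace(0, np.pi / 2, 30)
    chain = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta),
                             np.zeros_like(theta)])
    lengths = [chain_arc_length(resample_chain(chain, n))
               for n in (5, 10, 20, 40, 80)]
    assert all(b >= a - 1e-9 for a, b in zip(lengths, lengths[1:]))
    assert lengths[-1] == pytest.approx(50 * np.pi, rel=2e-3)


def test_leaf_count_matches_generator(recovery_battery):
    """Stem/leaf decomposition finds every leaf on randomized shoots,
    allowing at most one miscount in twenty."""
    miscounts = sum(
        1 for b in recovery_battery
        if len(b["skeleton"].leaves) != len(b["truth"].leaves)
    )
    assert miscounts <= 1


def test_skeleton_json_round_trip(recovery_battery):
    from shootpheno.skeleton import Skeleton
    skel = recovery_battery[0]["skeleton"]
    back = Skeleton.from_json(skel.to_json())
    np.testing.assert_allclose(back.stem, skel.stem)
    assert len(back.leaves) == len(skel.leaves)
    assert back.attachments == list(skel.attachments)
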