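"""Circle fitting, pot segmentation and scale estimation."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from shootpheno import ColoredPointCloud, apply_scale, estimate_scale, segment_pot
from shootpheno.calibrate import PotNotFoundError, fit_circle_slice, kasa_circle
from shootpheno.synth import POT_COLOR, generate_shoot, random_spec


def _circle_points(r=150.0, n=200, arc=2 * np.pi, noise=0.0, seed=0,
                   center=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, arc, n)
    xy = np.column_stack([center[0] + r * np.cos(theta),
                          center[1] + r * np.sin(theta)])
    if noise:
        xy += rng.normal(0, noise, xy.shape)
    return xy


def geometric_circle(xy):
    """Independent oracle: nonlinear geometric least squares (LM)."""
    x0 = np.array([xy[:, 0].mean(), xy[:, 1].mean(),
                   np.linalg.norm(xy - xy.mean(axis=0), axis=1).mean()])
    res = least_squares(
        lambda p: np.linalg.norm(xy - p[:2], axis=1) - p[2], x0, method="lm"
    )
    return float(res.x[2])


def test_exact_circle_recovered_to_machine_precision():
    for arc in (2 * np.pi, np.pi / 2):
        xy = _circle_points(arc=arc)
        r, center, rms = kasa_circle(xy)
        assert r == pytest.approx(150.0, abs=1e-9)
        assert rms < 1e-9


def test_three_point_interpolation():
    xy = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    r, center, _ = kasa_circle(xy)
    assert r == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(center, [0, 0], atol=1e-12)


def test_collinear_points_are_degenerate():
    xy = np.column_stack([np.linspace(0, 10, 30), np.linspace(0, 20, 30)])
    with pytest.raises(ValueError):
        kasa_circle(xy)


def test_noisy_circle_and_geometric_oracle_agreement():
    xy = _circle_points(noise=1.0, seed=1)
    r, _, rms = kasa_circle(xy)
    assert r == pytest.approx(150.0, abs=0.5)
    assert rms < 0.02 * r
    assert r == pytest.approx(geometric_circle(xy), rel=1e-3)


def test_circle_fit_rotation_invariance():
    xy = _circle_points(noise=1.0, seed=2, arc=np.pi)
    r1, _, _ = kasa_circle(xy)
    ang = 0.7
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    r2, _, _ = kasa_circle(xy @ R.T)
    assert r1 == pytest.approx(r2, abs=1e-9)


def test_fit_circle_slice_requires_enough_points():
    pts = np.column_stack([_circle_points(n=10), np.zeros(10)])
    pot = ColoredPointCloud(pts, np.full((10, 3), 100, np.uint8))
    with pytest.raises(ValueError):
        fit_circle_slice(pot, 0.0, 1.0)


# ---------------------------------------------------------------------------
# segmentation

def test_segment_pot_matches_generator_labels(small_shoot):
    _, cloud, truth = small_shoot
    pot, idx = segment_pot(cloud)
    is_pot = truth.labels == 0
    sel = np.zeros(len(cloud), bool)
    sel[idx] = True
    assert (sel & is_pot).sum() / is_pot.sum() >= 0.99
    assert (sel & ~is_pot).sum() / len(idx) <= 0.005


def test_segment_pot_without_pot_colored_points_errors():
    cloud = ColoredPointCloud(np.random.default_rng(0).uniform(0, 10, (500, 3)),
                              np.tile([50, 160, 55], (500, 1)).astype(np.uint8))
    with pytest.raises(PotNotFoundError):
        segment_pot(cloud)


def test_segment_pot_zero_tolerance_exact_colors():
    rng = np.random.default_rng(3)
    # regular grid so the connected-component step cannot isolate points
    theta, zz = np.meshgrid(np.linspace(0, 2 * np.pi, 200, endpoint=False),
                            np.linspace(0, 250, 100))
    theta, zz = theta.ravel(), zz.ravel()
    n = len(theta)
    pot_pts = np.column_stack([150 * np.cos(theta), 150 * np.sin(theta), zz])
    other = rng.uniform(-50, 50, (200, 3)) + [0, 0, 400]
    pts = np.vstack([pot_pts, other])
    colors = np.vstack([np.tile(POT_COLOR, (n, 1)),
                        np.tile([50, 160, 55], (200, 1))]).astype(np.uint8)
    _, idx = segment_pot(ColoredPointCloud(pts, colors), tolerance=0.0)
    assert set(idx) == set(range(n))


# ---------------------------------------------------------------------------
# scale

def test_identity_scale_recovered(v5_shoot):
    _, cloud, truth = v5_shoot
    est = estimate_scale(cloud)
    assert est.tau == pytest.approx(1.0, abs=2e-3)
    assert len(est.slice_radii) == 3


def test_scale_recovery_and_self_consistency():
    spec = random_spec("v5", seed=9, point_density=0.25, scale_factor=0.37,
                       jitter_sd=1.0)
    cloud, truth = generate_shoot(spec)
    est = estimate_scale(cloud, pot_radius_true=spec.pot_radius)
    assert est.tau * spec.scale_factor == pytest.approx(1.0, abs=5e-3)
    metric = apply_scale(cloud, est.tau)
    again = estimate_scale(metric, pot_radius_true=spec.pot_radius)
    assert again.tau == pytest.approx(1.0, abs=5e-3)
    assert metric.frame_note == "metric"


def test_apply_scale_trivial_cases(v5_shoot):
    _, cloud, _ = v5_shoot
    same = apply_scale(cloud, 1.0)
    np.testing.assert_array_equal(same.points, cloud.points)
    cube = ColoredPointCloud(np.array([[0, 0, 0], [1, 1, 1.0]]),
                             np.zeros((2, 3), np.uint8))
    doubled = apply_scale(cube, 2.0)
    np.testing.assert_allclose(doubled.points[1], [2, 2, 2])
    with pytest.raises(ValueError):
        apply_scale(cube, -1.0)
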