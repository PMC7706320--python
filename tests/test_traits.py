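"""Trait arithmetic, invariances and parameter recovery on synthetic shoots."""

import numpy as np
import pytest

from shootpheno import ColoredPointCloud, TraitConfig, extract_all, plant_height
from shootpheno.skeleton import Skeleton
from shootpheno.traits import (
    LeafTraits, RingCut, TraitRecord, leaf_angles, leaf_area, leaf_length,
    leaf_width, ring_width,
)
from tests.conftest import run_recovery


def _ring(s, width, n=200, spacing=1.0):
    """A clean synthetic cut: n points spread along a segment of ``width``."""
    x = np.linspace(-width / 2, width / 2, n)
    pts = np.column_stack([x, np.zeros_like(x)])
    r = RingCut(node=np.zeros(3), tangent=np.array([0, 0, 1.0]),
                radius=width, length=2.0, arc_position=float(s),
                cut_points=pts, spacing=spacing)
    return r


def test_ring_width_two_points_is_their_separation():
    r = _ring(0.0, 30.0, n=2)
    assert ring_width(r) == pytest.approx(30.0)


def test_ring_width_never_exceeds_ring_diameter():
    r = _ring(0.0, 50.0, n=40)
    r.radius = 20.0
    assert ring_width(r) <= 40.0 + 1e-9


def test_leaf_width_is_max_over_rings():
    rings = [_ring(s, w) for s, w in
             zip((0, 50, 100, 150, 200), (30, 48, 52, 45, 20))]
    assert leaf_width(rings) == pytest.approx(52.0, rel=0.02)
    assert leaf_width([_ring(0, 40.0)]) == pytest.approx(40.0, rel=0.02)
    assert np.isnan(leaf_width([]))


def test_leaf_area_trapezoid_arithmetic():
    """Two rings, widths 40 and 60, separation 100 -> trapezoid term 5000."""
    chain = np.column_stack([np.linspace(0, 100, 12), np.zeros(12), np.zeros(12)])
    rings = [_ring(0.0, 40.0, n=200), _ring(100.0, 60.0, n=200)]
    # n large so the order-statistics factor is negligible; caps are zero
    # because the rings sit at the chain ends and widths do not taper
    area = leaf_area(rings, chain)
    assert area == pytest.approx(5000.0, rel=0.02)


def test_leaf_area_constant_width_rectangle():
    chain = np.column_stack([np.linspace(0, 200, 12), np.zeros(12), np.zeros(12)])
    rings = [_ring(s, 50.0, n=200) for s in (0.0, 100.0, 200.0)]
    assert leaf_area(rings, chain) == pytest.approx(10_000.0, rel=0.02)


def test_leaf_area_needs_two_valid_rings():
    chain = np.column_stack([np.linspace(0, 100, 12), np.zeros(12), np.zeros(12)])
    assert np.isnan(leaf_area([_ring(0.0, 40.0)], chain))


def test_leaf_length_straight_chain():
    chain = np.column_stack([np.linspace(0, 200, 5), np.zeros(5), np.zeros(5)])
    assert leaf_length(chain) == pytest.approx(200.0)


def test_plant_height_vertical_bare_stem():
    z = np.linspace(0, 500, 40)
    stem = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    skel = Skeleton(stem=stem)
    cloud = ColoredPointCloud(stem, np.full((40, 3), 100, np.uint8))
    assert plant_height(cloud, skel, soil_z=0.0) == pytest.approx(500.0)


def test_leaf_angles_axis_aligned_cases():
    z = np.linspace(0, 300, 40)
    stem = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    # leaf leaving horizontally along +x at z=100
    s = np.linspace(0, 150, 40)
    horiz = np.column_stack([s, np.zeros_like(s), np.full_like(s, 100.0)])
    incl, az, top, growth = leaf_angles(horiz, stem, attachment=10, soil_z=0.0)
    assert incl == pytest.approx(90.0, abs=0.5)
    assert az == pytest.approx(0.0, abs=0.5)
    assert top == pytest.approx(100.0, abs=1e-6)
    # leaf along +y, rising at 45 degrees
    diag = np.column_stack([np.zeros_like(s), s, 100.0 + s])
    incl, az, top, growth = leaf_angles(diag, stem, attachment=10, soil_z=0.0)
    assert incl == pytest.approx(45.0, abs=0.5)
    assert az == pytest.approx(90.0, abs=0.5)


def test_leaf_angles_invalid_attachment_errors():
    z = np.linspace(0, 300, 10)
    stem = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    with pytest.raises(IndexError):
        leaf_angles(stem, stem, attachment=99)


def test_record_round_trip_and_missing_values(tmp_path):
    rec = TraitRecord(plant_height=400.0, leaves=[
        LeafTraits(leaf_length=200.0, leaf_width=np.nan, leaf_area=np.nan,
                   inclination_deg=40.0, azimuth_deg=10.0,
                   top_height=150.0, growth_height=60.0),
    ])
    path = tmp_path / "traits.csv"
    rec.to_csv(str(path))
    back = TraitRecord.from_csv(str(path))
    assert back.plant_height == 400.0
    assert np.isnan(back.leaves[0].leaf_width)      # NA stays NA, never 0
    assert back.leaves[0].leaf_length == 200.0


def test_rigid_invariance_of_traits():
    """A z-rotation plus translation shifts azimuth by the rotation angle
    and leaves every other trait unchanged (within numerical noise)."""
    base = run_recovery(31, point_density=0.3)
    rec0 = base["record"]
    angle = 40.0
    a = np.radians(angle)
    R = np.array([[np.cos(a), -np.sin(a), 0],
                  [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
    t = np.array([500.0, -200.0, 0.0])
    # re-extract from the rigidly moved cloud + skeleton
    spec = base["spec"]
    from shootpheno import (apply_scale, denoise_region_growth,
                            estimate_scale, extract_skeleton,
                            remove_pot_and_ground)
    from shootpheno.synth import generate_shoot
    cloud, truth = generate_shoot(spec)
    moved = cloud.transformed(R, t)
    clean, _ = denoise_region_growth(moved)
    metric = apply_scale(clean, estimate_scale(clean).tau)
    shoot, soil_z = remove_pot_and_ground(metric)
    skel = extract_skeleton(shoot)
    shifted = ColoredPointCloud(shoot.points - [0, 0, soil_z], shoot.colors,
                                frame_note="metric")
    rec1 = extract_all(shifted,
                       skel.transformed(np.eye(3), np.array([0, 0, -soil_z])),
                       TraitConfig(soil_z=0.0))
    assert rec1.plant_height == pytest.approx(rec0.plant_height, rel=0.01)
    assert len(rec1.leaves) == len(rec0.leaves)
    for a0, a1 in zip(rec0.leaves, rec1.leaves):
        assert a1.leaf_length == pytest.approx(a0.leaf_length, rel=0.05)
        daz = (a1.azimuth_deg - a0.azimuth_deg - angle + 180) % 360 - 180
        assert abs(daz) < 3.0


def test_tilted_shoot_height_matches_upright_twin():
    """A 15-degree lean is removed by stem verticalization."""
    from shootpheno import extract_skeleton
    from shootpheno.synth import generate_shoot, random_spec

    spec = random_spec("v5", seed=32, point_density=0.3)
    cloud, truth = generate_shoot(spec)
    # strip pot/ground/noise by generator label: the pot is no longer
    # upright after the tilt, so color-based rim stripping does not apply
    shoot = cloud.select((truth.labels >= 2) & ~truth.noise_mask)
    a = np.radians(15.0)
    R = np.array([[1, 0, 0],
                  [0, np.cos(a), -np.sin(a)],
                  [0, np.sin(a), np.cos(a)]])
    h_up = plant_height(shoot, extract_skeleton(shoot))
    tilted = shoot.transformed(R, np.zeros(3))
    h_tilt = plant_height(tilted, extract_skeleton(tilted))
    assert h_tilt == pytest.approx(h_up, rel=0.01)


def test_recovery_battery_leaf_statistics(recovery_battery):
    """Length, top height and growth height recovered across 20 shoots."""
    from tests.conftest import leaf_errors
    errs, heights, miscounts = leaf_errors(recovery_battery)
    assert miscounts <= 1
    # lengths: unbiased and accurate in aggregate
    assert abs(np.nanmean(errs["length"])) <= 0.03
    assert np.nanmedian(np.abs(errs["length"])) <= 0.03
    # vertical positions track the truth to a few millimetres
    assert np.nanmedian(np.abs(errs["top"])) <= 5.0
    assert np.nanmedian(np.abs(errs["growth"])) <= 5.0
    # ordering by growth height is respected
    for b in recovery_battery:
        gh = [lf.growth_height for lf in b["record"].leaves]
        assert gh == sorted(gh)
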