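"""Shared fixtures: generated shoots and full-pipeline recovery runs.

The expensive twenty-shoot recovery battery is computed once per session
and shared between the skeleton, traits and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from shootpheno import (
    TraitConfig, apply_scale, denoise_region_growth, estimate_scale,
    extract_skeleton, extract_all, remove_pot_and_ground, truth_to_table,
)
from shootpheno.cloud import ColoredPointCloud
from shootpheno.synth import generate_shoot, random_spec

BATTERY_SEEDS = list(range(1, 21))


def run_recovery(seed: int, **spec_overrides):
    """Full pipeline on one randomized V5 shoot; returns recovery bundle."""
    spec = random_spec("v5", seed=seed, **spec_overrides)
    cloud, truth = generate_shoot(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, removed = denoise_region_growth(cloud)
        est = estimate_scale(clean)
        metric = apply_scale(clean, est.tau)
        shoot, soil_z = remove_pot_and_ground(metric)
        skel = extract_skeleton(shoot)
        shifted = ColoredPointCloud(
            shoot.points - [0, 0, soil_z], shoot.colors, frame_note="metric"
        )
        skel_shifted = skel.transformed(np.eye(3), np.array([0, 0, -soil_z]))
        record = extract_all(shifted, skel_shifted, TraitConfig(soil_z=0.0))
    return {
        "spec": spec,
        "cloud": cloud,
        "truth": truth,
        "truth_table": truth_to_table(truth),
        "skeleton": skel,
        "record": record,
        "tau": est.tau,
        "removed": removed,
    }


@pytest.fixture(scope="session")
def v5_shoot():
    """One deterministic V5 shoot cloud with truth (raw, unprocessed)."""
    spec = random_spec("v5", seed=1)
    cloud, truth = generate_shoot(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def small_shoot():
    """A lighter shoot for mechanics-level tests."""
    spec = random_spec("v5", seed=7, point_density=0.25)
    cloud, truth = generate_shoot(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def recovery_battery():
    """Full-pipeline recovery on twenty randomized V5 shoots."""
    return [run_recovery(seed) for seed in BATTERY_SEEDS]


def leaf_errors(battery):
    """Pool per-leaf relative/angular errors over shoots with matched counts."""
    errs = {k: [] for k in
            ("length", "width", "area", "incl", "az", "top", "growth")}
    heights = []
    miscounts = 0
    for b in battery:
        rec, tt = b["record"], b["truth_table"]
        heights.append(rec.plant_height / b["truth"].plant_height - 1)
        if len(rec.leaves) != len(tt.leaves):
            miscounts += 1
            continue
        for ext, tr in zip(rec.leaves, tt.leaves):
            errs["length"].append(ext.leaf_length / tr.leaf_length - 1)
            errs["width"].append(ext.leaf_width / tr.leaf_width - 1)
            errs["area"].append(ext.leaf_area / tr.leaf_area - 1)
            errs["incl"].append(ext.inclination_deg - tr.inclination_deg)
            errs["az"].append(
                (ext.azimuth_deg - tr.azimuth_deg + 180) % 360 - 180
            )
            errs["top"].append(ext.top_height - tr.top_height)
            errs["growth"].append(ext.growth_height - tr.growth_height)
    return ({k: np.asarray(v) for k, v in errs.items()},
            np.asarray(heights), miscounts)
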