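"""Parametric maize-shoot point clouds with analytic ground truth.

Emulates what multi-view-stereo photogrammetry delivers for a potted shoot:
a dense colored cloud at an unknown global scale containing the green plant,
a uniformly colored terracotta pot (the metric marker), dark soil/ground,
and gray back-of-leaf noise patches.  Every downstream stage (denoising,
scale calibration, registration, skeletonization, trait extraction) is
validated against the closed-form truth produced here.

Leaf model
----------
Each midrib is a planar, arc-length-parameterized circular arc in the
vertical plane at the leaf's azimuth: the tangent angle from vertical grows
linearly from the base inclination ``gamma0`` to ``gamma0 + droop`` at the
tip.  The blade is a flat strip swept perpendicular to that plane with a
tapering width profile ``w(u) = W * (27/4) u (1-u)^2`` (maximum ``W`` at
u = 1/3).  Because the sweep direction is orthogonal to the midrib plane,
surface area is exactly ``∫ w(s) ds`` — no quadrature error in the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import beta as _sp_beta

# organ labels in ShootTruth.labels
POT, GROUND, STEM = 0, 1, 2
LEAF_BASE = 10  # leaf i -> LEAF_BASE + i

LEAF_GREEN = np.array([50, 160, 55])
STEM_GREEN = np.array([45, 140, 50])
POT_COLOR = np.array([180, 90, 60])
SOIL_COLOR = np.array([60, 45, 30])

# beta(1.5, 1.8)-shaped width profile: w(u) = W * u^p (1-u)^q / norm with
# p = 0.5, q = 0.8 -- fast collar widening, maximum near u = 0.38, long
# gentle taper with a short acuminate tip (width ~0.2 W at 95% of length),
# as on real maize blades.  Its exact integral is B(p+1, q+1) / norm.
_TAPER_P = 0.5
_TAPER_Q = 0.8
_TAPER_UMAX = _TAPER_P / (_TAPER_P + _TAPER_Q)
_TAPER_NORM = _TAPER_UMAX**_TAPER_P * (1.0 - _TAPER_UMAX) ** _TAPER_Q
_TAPER_INTEGRAL = float(_sp_beta(_TAPER_P + 1.0, _TAPER_Q + 1.0)) / _TAPER_NORM


class DegenerateSamplingError(ValueError):
    """Requested point density leaves a leaf with fewer than 50 points."""


@dataclass
class LeafSpec:
    """One leaf: attachment on the stem plus midrib/blade geometry.

    Angles in degrees; lengths in millimetres.  ``inclination_deg`` is the
    base tangent's angle from the vertical stem axis; ``droop_deg`` is the
    total tangent rotation from base to tip (gravitational droop).
    """

    attachment_height: float      # mm above soil surface
    azimuth_deg: float            # [0, 360), CCW from +x
    inclination_deg: float        # (0, 90)
    midrib_length: float          # mm, arc length
    max_width: float              # mm
    droop_deg: float = 65.0
    width_profile: str = "tapered"   # "tapered" | "rectangular"

    def validate(self) -> None:
        if not (0 < self.inclination_deg < 90):
            raise ValueError("inclination must lie in (0, 90) degrees")
        if not (0 <= self.azimuth_deg < 360):
            raise ValueError("azimuth must lie in [0, 360)")
        if min(self.midrib_length, self.max_width) <= 0:
            raise ValueError("leaf lengths must be positive")
        if self.width_profile not in ("tapered", "rectangular"):
            raise ValueError(f"unknown width_profile {self.width_profile!r}")


@dataclass
class ShootSpec:
    """Full shoot + pot + acquisition-artifact parameters."""

    leaves: list[LeafSpec]
    plant_height: float = 401.0   # mm, soil surface to stem/tassel top
    stem_diameter: float = 16.0   # mm
    pot_radius: float = 150.0     # mm ("30 cm diameter" pots)
    pot_height: float = 250.0     # mm ("25 cm deep" pots)
    point_density: float = 0.5    # points per mm^2 of surface
    noise_fraction: float = 0.10  # fraction of leaf points echoed as gray noise
    jitter_sd: float = 0.5        # mm, isotropic Gaussian
    scale_factor: float = 1.0     # applied to all coordinates at the end
    seed: int = 0

    def validate(self) -> None:
        for name in ("plant_height", "stem_diameter", "pot_radius",
                     "pot_height", "point_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.noise_fraction <= 1):
            raise ValueError("noise_fraction must lie in [0, 1]")
        if self.jitter_sd < 0 or self.scale_factor <= 0:
            raise ValueError("jitter_sd >= 0 and scale_factor > 0 required")
        for leaf in self.leaves:
            leaf.validate()


@dataclass
class LeafTruth:
    """Closed-form per-leaf truth (millimetres / degrees, metric frame)."""

    length: float
    width: float
    area: float
    azimuth_deg: float
    inclination_deg: float        # base tangent angle from vertical
    base_tangent_deg: float       # mean tangent over the first 10% of arc
    top_height: float             # mm above soil
    growth_height: float          # attachment height above soil
    midrib: np.ndarray = field(repr=False, default=None)  # (200,3) mm polyline


@dataclass
class ShootTruth:
    """Analytic ground truth plus per-point generator labels."""

    leaves: list[LeafTruth]
    plant_height: float
    pot_radius: float
    scale_factor: float
    soil_z: float                 # mm (pre-scale frame)
    labels: np.ndarray = field(repr=False, default=None)      # int per point
    noise_mask: np.ndarray = field(repr=False, default=None)  # bool per point


# ---------------------------------------------------------------------------
# midrib geometry (closed form)

def _midrib_frame(azimuth_deg: float):
    az = np.radians(azimuth_deg)
    u_az = np.array([np.cos(az), np.sin(az), 0.0])     # in-plane horizontal
    e_perp = np.array([-np.sin(az), np.cos(az), 0.0])  # blade sweep direction
    return u_az, e_perp


def _midrib_hz(s: np.ndarray, gamma0: float, kappa: float):
    """Horizontal offset and height of the arc at arc length s."""
    s = np.asarray(s, dtype=float)
    if abs(kappa) < 1e-12:
        return s * np.sin(gamma0), s * np.cos(gamma0)
    g = gamma0 + kappa * s
    h = (np.cos(gamma0) - np.cos(g)) / kappa
    z = (np.sin(g) - np.sin(gamma0)) / kappa
    return h, z


def _arch_rise(gamma0: float, kappa: float, length: float) -> float:
    """Maximum height of the midrib above its base (tangent crosses horizontal)."""
    if kappa < 1e-12:
        return length * np.cos(gamma0)
    s_star = (np.pi / 2 - gamma0) / kappa
    s_star = min(max(s_star, 0.0), length)
    return _midrib_hz(np.array([s_star]), gamma0, kappa)[1][0]


def _width_at(u: np.ndarray, max_width: float, profile: str) -> np.ndarray:
    if profile == "rectangular":
        return np.full_like(np.asarray(u, dtype=float), max_width)
    u = np.asarray(u, dtype=float)
    return max_width * u**_TAPER_P * (1 - u) ** _TAPER_Q / _TAPER_NORM


def leaf_truth(leaf: LeafSpec, soil_z: float, stem_radius: float) -> LeafTruth:
    """Closed-form truth for one leaf (in the unscaled mm frame)."""
    g0 = np.radians(leaf.inclination_deg)
    kappa = np.radians(leaf.droop_deg) / leaf.midrib_length
    L = leaf.midrib_length
    if leaf.width_profile == "rectangular":
        area = leaf.max_width * L
    else:
        area = leaf.max_width * L * _TAPER_INTEGRAL
    rise = _arch_rise(g0, kappa, L)
    # mean unit tangent over [0, 0.1L] is the chord direction: angle
    # gamma0 + kappa * 0.05 L for a constant-curvature arc
    base_tan = leaf.inclination_deg + np.degrees(kappa * 0.05 * L)
    u_az, _ = _midrib_frame(leaf.azimuth_deg)
    s = np.linspace(0.0, L, 200)
    h, z = _midrib_hz(s, g0, kappa)
    attach = np.array([0.0, 0.0, soil_z + leaf.attachment_height]) + stem_radius * u_az
    midrib = attach[None, :] + h[:, None] * u_az[None, :]
    midrib[:, 2] += z
    return LeafTruth(
        length=L,
        width=leaf.max_width,
        area=area,
        azimuth_deg=leaf.azimuth_deg,
        inclination_deg=leaf.inclination_deg,
        base_tangent_deg=base_tan,
        top_height=leaf.attachment_height + rise,
        growth_height=leaf.attachment_height,
        midrib=midrib,
    )


# ---------------------------------------------------------------------------
# surface samplers

def _sample_cylinder(rng, radius, z0, z1, density, color, color_var):
    area = 2 * np.pi * radius * (z1 - z0)
    n = max(int(round(area * density)), 8)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z0, z1, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    normals = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    cols = np.clip(
        color[None, :] + rng.integers(-color_var, color_var + 1, (n, 3)), 0, 255
    )
    return pts, cols, normals


def _sample_annulus(rng, r0, r1, z, density, color, color_var):
    area = np.pi * (r1**2 - r0**2)
    n = max(int(round(area * density)), 8)
    r = np.sqrt(rng.uniform(r0**2, r1**2, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n, z)])
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    cols = np.clip(
        color[None, :] + rng.integers(-color_var, color_var + 1, (n, 3)), 0, 255
    )
    return pts, cols, normals


def _sample_leaf(rng, leaf: LeafSpec, soil_z: float, stem_radius: float,
                 density: float):
    g0 = np.radians(leaf.inclination_deg)
    L = leaf.midrib_length
    kappa = np.radians(leaf.droop_deg) / L
    truth = leaf_truth(leaf, soil_z, stem_radius)
    n = int(round(truth.area * density))
    if n < 50:
        raise DegenerateSamplingError(
            f"leaf at azimuth {leaf.azimuth_deg:.0f} deg would receive only "
            f"{n} points (< 50); raise point_density"
        )
    # area-uniform sampling: s from the width profile's inverse CDF, v uniform
    grid_u = np.linspace(0.0, 1.0, 1025)
    w = _width_at(grid_u, leaf.max_width, leaf.width_profile)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    cdf /= cdf[-1]
    u = np.interp(rng.uniform(0, 1, n), cdf, grid_u)
    s = u * L
    wu = _width_at(u, leaf.max_width, leaf.width_profile)
    v = rng.uniform(-0.5, 0.5, n) * wu
    u_az, e_perp = _midrib_frame(leaf.azimuth_deg)
    h, z = _midrib_hz(s, g0, kappa)
    attach = np.array([0.0, 0.0, soil_z + leaf.attachment_height]) + stem_radius * u_az
    pts = attach[None, :] + h[:, None] * u_az[None, :] + v[:, None] * e_perp[None, :]
    pts[:, 2] += z
    gamma = g0 + kappa * s
    # surface normal of the swept strip: t x e_perp
    normals = (np.sin(gamma)[:, None] * np.array([0.0, 0.0, 1.0])[None, :]
               - np.cos(gamma)[:, None] * u_az[None, :])
    cols = np.clip(
        LEAF_GREEN[None, :] + rng.integers(-15, 16, (n, 3)), 0, 255
    )
    return pts, cols, normals, truth


def generate_shoot(spec: ShootSpec):
    """Sample a shoot cloud and return it with its analytic truth.

    Returns
    -------
    (ColoredPointCloud, ShootTruth)
        Cloud coordinates are ``spec.scale_factor`` times the metric
        geometry; truth lengths stay in millimetres.  ``truth.labels`` and
        ``truth.noise_mask`` index the returned cloud point-for-point.
    """
    from .cloud import ColoredPointCloud
    from .denoise import GRAY_PALETTE

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    soil_z = spec.pot_height
    stem_r = spec.stem_diameter / 2

    parts_pts, parts_cols, parts_normals, parts_labels = [], [], [], []

    def add(pts, cols, normals, label):
        parts_pts.append(pts)
        parts_cols.append(cols)
        parts_normals.append(normals)
        parts_labels.append(np.full(len(pts), label, dtype=int))

    # pot wall, soil surface, ground annulus
    add(*_sample_cylinder(rng, spec.pot_radius, 0.0, spec.pot_height,
                          spec.point_density, POT_COLOR, 5), POT)
    add(*_sample_annulus(rng, stem_r, spec.pot_radius * 0.98, soil_z,
                         spec.point_density, SOIL_COLOR, 5), GROUND)
    add(*_sample_annulus(rng, spec.pot_radius * 1.1, spec.pot_radius * 1.5,
                         0.0, spec.point_density, SOIL_COLOR, 5), GROUND)
    # stem from soil to plant top
    add(*_sample_cylinder(rng, stem_r, soil_z, soil_z + spec.plant_height,
                          spec.point_density, STEM_GREEN, 10), STEM)

    leaf_truths = []
    leaf_start = len(np.concatenate(parts_labels)) if parts_labels else 0
    for i, leaf in enumerate(spec.leaves):
        pts, cols, normals, tr = _sample_leaf(
            rng, leaf, soil_z, stem_r, spec.point_density
        )
        add(pts, cols, normals, LEAF_BASE + i)
        leaf_truths.append(tr)

    pts = np.vstack(parts_pts)
    cols = np.vstack(parts_cols).astype(np.uint8)
    normals = np.vstack(parts_normals)
    labels = np.concatenate(parts_labels)
    noise_mask = np.zeros(len(pts), dtype=bool)

    # gray back-of-leaf noise: echo a fraction of leaf points behind the blade
    leaf_idx = np.flatnonzero(labels >= LEAF_BASE)
    n_noise = int(round(spec.noise_fraction * len(leaf_idx)))
    if n_noise > 0:
        src = rng.choice(leaf_idx, size=n_noise, replace=False)
        offset = rng.uniform(1.0, 3.0, n_noise)
        npts = pts[src] - normals[src] * offset[:, None]
        palette = np.asarray(GRAY_PALETTE)
        pal = palette[rng.integers(0, len(palette), n_noise)]
        ncols = np.clip(pal + rng.integers(-8, 9, (n_noise, 3)), 0, 255)
        pts = np.vstack([pts, npts])
        cols = np.vstack([cols, ncols.astype(np.uint8)])
        normals = np.vstack([normals, normals[src]])
        labels = np.concatenate([labels, labels[src]])
        noise_mask = np.concatenate(
            [noise_mask, np.ones(n_noise, dtype=bool)]
        )

    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sd, pts.shape)

    pts = pts * spec.scale_factor

    arch_tops = [t.top_height for t in leaf_truths]
    truth = ShootTruth(
        leaves=leaf_truths,
        plant_height=max([spec.plant_height] + arch_tops),
        pot_radius=spec.pot_radius,
        scale_factor=spec.scale_factor,
        soil_z=soil_z,
        labels=labels,
        noise_mask=noise_mask,
    )
    cloud = ColoredPointCloud(pts, cols, frame_note="raw-scale")
    return cloud, truth


# ---------------------------------------------------------------------------
# presets and randomized study specs

_STAGES = {
    # plant height (mm), leaf count, midrib length range, width range
    "v5": dict(height=401.0, n_leaves=5, length=(180, 320), width=(35, 55)),
    "v15": dict(height=1800.0, n_leaves=12, length=(500, 900), width=(70, 100)),
    "r1": dict(height=2011.0, n_leaves=13, length=(550, 950), width=(75, 105)),
}


def random_spec(stage: str = "v5", seed: int = 0, **overrides) -> ShootSpec:
    """Randomized shoot of a given growth stage (v5, v15 or r1).

    Phyllotaxy is distichous (alternating ~180 deg azimuths with scatter),
    attachments spread over the lower two thirds of the stem so the stem /
    tassel tip stays the highest structure, as in real maize.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(_STAGES)}")
    p = _STAGES[stage]
    rng = np.random.default_rng(seed)
    height = p["height"] * rng.uniform(0.92, 1.08)
    n = p["n_leaves"]
    base_az = rng.uniform(0, 360)
    leaves = []
    attach_fracs = np.linspace(0.15, 0.62, n) + rng.uniform(-0.02, 0.02, n)
    for i in range(n):
        az = (base_az + 180.0 * i + rng.uniform(-20, 20)) % 360.0
        leaves.append(
            LeafSpec(
                attachment_height=float(attach_fracs[i] * height),
                azimuth_deg=float(az),
                inclination_deg=float(rng.uniform(25, 50)),
                midrib_length=float(rng.uniform(*p["length"])),
                max_width=float(rng.uniform(*p["width"])),
                droop_deg=float(rng.uniform(50, 80)),
            )
        )
    spec = ShootSpec(leaves=leaves, plant_height=float(height),
                     seed=int(rng.integers(0, 2**31 - 1)))
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


def preset_spec(name: str, seed: int = 0, **overrides) -> ShootSpec:
    """Canonical growth-stage preset (deterministic geometry for a seed)."""
    return random_spec(name, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# truth -> trait table

def truth_to_table(truth: ShootTruth):
    """Map analytic truth into the TraitRecord shape of the traits module."""
    from .traits import LeafTraits, TraitRecord

    leaves = [
        LeafTraits(
            leaf_length=t.length,
            leaf_width=t.width,
            leaf_area=t.area,
            inclination_deg=t.base_tangent_deg,
            azimuth_deg=t.azimuth_deg,
            top_height=t.top_height,
            growth_height=t.growth_height,
        )
        for t in sorted(truth.leaves, key=lambda t: t.growth_height)
    ]
    return TraitRecord(plant_height=truth.plant_height, leaves=leaves)


def spec_to_json(spec: ShootSpec) -> str:
    return json.dumps(asdict(spec), indent=2)


def spec_from_json(text: str) -> ShootSpec:
    d = json.loads(text)
    d["leaves"] = [LeafSpec(**l) for l in d["leaves"]]
    return ShootSpec(**d)


def truth_to_json(truth: ShootTruth) -> str:
    d = {
        "plant_height": truth.plant_height,
        "pot_radius": truth.pot_radius,
        "scale_factor": truth.scale_factor,
        "soil_z": truth.soil_z,
        "leaves": [
            {k: v for k, v in asdict(t).items() if k != "midrib"}
            for t in truth.leaves
        ],
    }
    return json.dumps(d, indent=2)
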