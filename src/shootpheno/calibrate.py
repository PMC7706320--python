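"""Metric scale calibration from the pot marker.

Photogrammetric clouds come at an arbitrary global scale.  The pot the
shoot grows in has a known radius ``R`` (default 150 mm for 30-cm pots),
so fitting circles to horizontal slices of the color-segmented pot wall
yields the cloud-unit radius ``R_mvs`` and the scale factor

    tau = R / R_mvs

averaged over three slices (bottom / middle / top of the pot).  Multiplying
the cloud by tau puts it in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud
from .denoise import _delta_c
from .synth import POT_COLOR

SLICE_FRACTIONS = (0.15, 0.50, 0.85)   # bottom, middle, top of the pot wall
SLICE_THICKNESS_FRACTION = 0.06
TAPER_WARN_FRACTION = 0.05


class PotNotFoundError(ValueError):
    """Too few pot-colored points to calibrate."""


@dataclass
class ScaleEstimate:
    """Result of pot-based scale estimation."""

    tau: float
    slice_radii: list          # fitted radii, cloud units
    pot_radius_true: float     # mm
    residuals: list            # per-slice RMS radial residual, cloud units
    used_middle_only: bool = False


def segment_pot(
    cloud: ColoredPointCloud,
    pot_color=tuple(POT_COLOR),
    tolerance: float = 60.0,
):
    """Select the pot by color, then keep the largest connected component.

    Color matching uses the same redmean metric as the denoiser; the
    component step (neighbor radius = 3x mean point spacing) discards
    isolated stragglers that happen to match the pot color.

    Returns ``(pot_cloud, indices)`` into the input cloud.
    """
    if len(cloud) == 0:
        raise PotNotFoundError("empty cloud")
    c = cloud.colors.astype(float)
    target = np.broadcast_to(np.asarray(pot_color, dtype=float), c.shape)
    match = np.flatnonzero(_delta_c(c, target) <= tolerance)
    if len(match) < 100:
        raise PotNotFoundError(
            f"only {len(match)} points match the pot color (need >= 100)"
        )
    pts = cloud.points[match]
    sub = cloud.select(match)
    radius = 3.0 * sub.mean_spacing()
    tree = cKDTree(pts)
    graph = tree.sparse_distance_matrix(tree, radius, output_type="coo_matrix")
    n_comp, comp = connected_components(graph.tocsr(), directed=False)
    if n_comp > 1:
        keep = comp == np.bincount(comp).argmax()
        match = match[keep]
    return cloud.select(match), match


def fit_circle_slice(
    pot: ColoredPointCloud, z_center: float, thickness: float
):
    """Algebraic (Kasa) least-squares circle fit to one horizontal slab.

    Points with ``|z - z_center| <= thickness/2`` are projected to the xy
    plane and the linear system for center ``(a, b)`` and radius ``r`` is
    solved:  ``x^2 + y^2 = 2ax + 2by + (r^2 - a^2 - b^2)``.

    Returns ``(radius, center_xy, rms_residual)``.
    """
    z = pot.points[:, 2]
    mask = np.abs(z - z_center) <= thickness / 2.0
    if mask.sum() < 20:
        raise ValueError(
            f"slab at z={z_center:g} holds {int(mask.sum())} points (< 20)"
        )
    xy = pot.points[mask, :2]
    return kasa_circle(xy)


def kasa_circle(xy: np.ndarray):
    """Kasa algebraic circle fit on (n,2) points."""
    xy = np.asarray(xy, dtype=float)
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate circle fit: points are collinear")
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if r2 <= 0:
        raise ValueError("degenerate circle fit: non-positive radius")
    r = float(np.sqrt(r2))
    center = np.array([a, bb])
    resid = np.linalg.norm(xy - center, axis=1) - r
    return r, center, float(np.sqrt(np.mean(resid**2)))


def estimate_scale(
    cloud: ColoredPointCloud,
    pot_radius_true: float = 150.0,
    pot_color=tuple(POT_COLOR),
    tolerance: float = 60.0,
) -> ScaleEstimate:
    """Estimate the metric scale factor tau = R / mean(R_mvs) from the pot.

    Circles are fitted at 15 / 50 / 85 % of the pot segment's z extent with
    slab thickness 6 % of pot height; tau uses the unweighted mean of the
    fitted radii.  If the three radii disagree by more than 5 % (tapering
    pot), the middle slice alone is used and a warning is issued.  Failed
    slices fall back to the remaining ones.
    """
    pot, _ = segment_pot(cloud, pot_color, tolerance)
    z = pot.points[:, 2]
    z0, z1 = z.min(), z.max()
    height = z1 - z0
    thickness = height * SLICE_THICKNESS_FRACTION
    radii, resids = [], []
    for frac in SLICE_FRACTIONS:
        try:
            r, _, rms = fit_circle_slice(pot, z0 + frac * height, thickness)
            radii.append(r)
            resids.append(rms)
        except ValueError as exc:
            warnings.warn(f"pot slice at fraction {frac} failed: {exc}")
    if not radii:
        raise PotNotFoundError("all pot slices failed to fit")
    used_middle = False
    use_radii = radii
    if len(radii) == 3:
        spread = (max(radii) - min(radii)) / np.mean(radii)
        if spread > TAPER_WARN_FRACTION:
            warnings.warn(
                f"pot slice radii disagree by {spread:.1%} (tapered pot?); "
                "using the middle slice only"
            )
            use_radii = [radii[1]]
            used_middle = True
    tau = float(pot_radius_true / np.mean(use_radii))
    return ScaleEstimate(
        tau=tau,
        slice_radii=[float(r) for r in radii],
        pot_radius_true=float(pot_radius_true),
        residuals=[float(r) for r in resids],
        used_middle_only=used_middle,
    )


def apply_scale(cloud: ColoredPointCloud, tau: float) -> ColoredPointCloud:
    """Multiply coordinates by tau and mark the cloud metric."""
    if tau <= 0:
        raise ValueError("scale factor must be positive")
    return replace(cloud, points=cloud.points * tau, frame_note="metric")
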