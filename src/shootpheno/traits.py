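"""Architectural trait extraction from skeleton + metric cloud.

Eight phenotypes: plant height, and per leaf the length, maximum width,
blade area, inclination angle, azimuthal angle, top height and growth
(attachment) height.  Width and area come from virtual ring cuts: at
nodes spread evenly along the leaf skeleton, cloud points in a thin slab
perpendicular to the local tangent are collected, cleaned of crossing
organs by nearest-neighbor clustering, and the cut-line width is the
extent of the points along their total-least-squares principal line;
blade area is the trapezoid sum of consecutive cut widths over their arc
separations plus triangular end caps tapering to zero at the chain ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud
from .skeleton import Skeleton, chain_arc_length, resample_chain

_COLUMNS = [
    "row_type", "leaf_index", "plant_height_mm", "leaf_length_mm",
    "leaf_width_mm", "leaf_area_mm2", "inclination_deg", "azimuth_deg",
    "top_height_mm", "growth_height_mm",
]


@dataclass
class LeafTraits:
    leaf_length: float = np.nan
    leaf_width: float = np.nan       # NaN = missing, never zero
    leaf_area: float = np.nan
    inclination_deg: float = np.nan
    azimuth_deg: float = np.nan
    top_height: float = np.nan
    growth_height: float = np.nan


@dataclass
class TraitRecord:
    plant_height: float
    leaves: list = field(default_factory=list)   # LeafTraits, growth height asc

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "row_type": "shoot", "leaf_index": pd.NA,
            "plant_height_mm": self.plant_height,
        }]
        for i, lf in enumerate(self.leaves):
            rows.append({
                "row_type": "leaf", "leaf_index": i,
                "leaf_length_mm": lf.leaf_length,
                "leaf_width_mm": lf.leaf_width,
                "leaf_area_mm2": lf.leaf_area,
                "inclination_deg": lf.inclination_deg,
                "azimuth_deg": lf.azimuth_deg,
                "top_height_mm": lf.top_height,
                "growth_height_mm": lf.growth_height,
            })
        return pd.DataFrame(rows, columns=_COLUMNS)

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TraitRecord":
        df = pd.read_csv(path_or_buf)
        shoot = df[df.row_type == "shoot"].iloc[0]
        leaves = [
            LeafTraits(
                leaf_length=row.leaf_length_mm,
                leaf_width=row.leaf_width_mm,
                leaf_area=row.leaf_area_mm2,
                inclination_deg=row.inclination_deg,
                azimuth_deg=row.azimuth_deg,
                top_height=row.top_height_mm,
                growth_height=row.growth_height_mm,
            )
            for row in df[df.row_type == "leaf"].itertuples()
        ]
        return cls(plant_height=float(shoot.plant_height_mm), leaves=leaves)


@dataclass
class RingCut:
    node: np.ndarray
    tangent: np.ndarray
    radius: float
    length: float
    arc_position: float            # mm from chain start
    cut_points: np.ndarray = None  # kept cluster, in-plane 2D coords
    spacing: float = 1.0           # mean cloud point spacing, mm
    width: float = np.nan
    valid: bool = True


@dataclass
class TraitConfig:
    n_nodes: int = 8               # ring cuts per leaf, within [5, 8]
    width_prior: float = 40.0      # mm; ~average leaf width (ring radius = 1.5x)
    auto_width: bool = True        # one refinement pass with measured median width
    trim_fraction: float = 0.05    # chain fraction excluded at each end
    resample_points: int = 60
    soil_z: float | None = None    # mm; stem-chain base used when None
    stem_clearance: float = 12.0   # mm; leaf-base angles measured outside
                                   # this distance from the stem chain

    def __post_init__(self) -> None:
        if not (5 <= self.n_nodes <= 8):
            raise ValueError("n_nodes must lie in [5, 8]")
        if self.width_prior <= 0:
            raise ValueError("width_prior must be positive")


# ---------------------------------------------------------------------------
# canonical (stem-vertical) frame

def stem_axis(stem_chain: np.ndarray) -> np.ndarray:
    """Dominant direction of the stem chain, oriented upward."""
    x = stem_chain - stem_chain.mean(axis=0)
    _, _, Vt = np.linalg.svd(x, full_matrices=False)
    v = Vt[0]
    return v if v[2] >= 0 else -v


def verticalizing_rotation(stem_chain: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying the stem axis onto +z."""
    v = stem_axis(stem_chain)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(v @ z, -1.0, 1.0))
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(math.acos(c)) * K + (1 - c) * (K @ K)


def plant_height(
    cloud: ColoredPointCloud,
    skeleton: Skeleton,
    soil_z: float | None = None,
) -> float:
    """Soil surface to the arch of the uppermost structure, stem verticalized.

    The maximum is taken over the stem chain and each leaf chain's highest
    point (its arch), so tips hanging below their arch never raise the
    value.  Soil level defaults to the stem chain's base z.
    """
    if skeleton.stem is None or len(skeleton.stem) < 2:
        raise ValueError("skeleton has no stem chain")
    R = verticalizing_rotation(skeleton.stem)
    skel = skeleton.transformed(R, np.zeros(3))
    soil = float(skel.stem[:, 2].min()) if soil_z is None else float(soil_z)
    top = skel.stem[:, 2].max()
    for chain in skel.leaves:
        top = max(top, chain[:, 2].max())
    return float(top - soil)


def leaf_length(chain: np.ndarray) -> float:
    """Arc length of the (refined, resampled) leaf skeleton."""
    return chain_arc_length(chain)


def _base_direction(chain: np.ndarray, window: float = 0.10) -> np.ndarray:
    """Mean tangent over the first ``window`` of arc length (= chord)."""
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    target = window * arc[-1]
    k = int(np.searchsorted(arc, target))
    k = max(k, 1)
    d = chain[k] - chain[0]
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate leaf base")
    return d / n


def _blade_base_angles(blade: np.ndarray, stem_chain: np.ndarray,
                       r_stem: float, chord: int = 3):
    """Base inclination, azimuth and collar height from the blade chain.

    Tangent directions are taken as chords over +-``chord`` resampled
    points (wide baselines suppress per-point chain noise); their
    angle-from-vertical is fitted linearly in arc length over the
    15-55 % window — exact for a constant-curvature droop — and evaluated
    at 5 % of the blade arc measured from the stem surface.  The collar
    offset is the measured distance of the chain start from a smoothed
    (quadratic-in-z) stem axis, minus the stem radius, divided by the sine
    of the base angle (straight-exit model).  Azimuth is the
    horizontal-magnitude-weighted mean bearing of the window chords.

    Returns ``(inclination_deg, azimuth_deg, collar_z)``.
    """
    k = chord
    if len(blade) < 2 * k + 4:
        d = _base_direction(blade)
        incl = math.degrees(math.acos(float(np.clip(d[2], -1.0, 1.0))))
        az = math.degrees(math.atan2(d[1], d[0])) % 360.0
        return incl, az, float(blade[0, 2]), 0.0
    seg = np.linalg.norm(np.diff(blade, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    idx = np.arange(k, len(blade) - k)
    v = blade[idx + k] - blade[idx - k]
    vlen = np.linalg.norm(v, axis=1)
    vlen[vlen == 0] = 1.0
    ang = np.degrees(np.arccos(np.clip(v[:, 2] / vlen, -1.0, 1.0)))
    sm = s[idx]
    win = (sm >= 0.15 * L) & (sm <= 0.55 * L)
    if win.sum() < 4:
        win = slice(None)
    slope, intercept = np.polyfit(sm[win], ang[win], 1)
    sin_g = max(math.sin(math.radians(np.clip(intercept, 5.0, 175.0))), 0.3)
    # smoothed stem axis at the blade-start height
    if len(stem_chain) >= 4:
        px = np.polyfit(stem_chain[:, 2], stem_chain[:, 0], 2)
        py = np.polyfit(stem_chain[:, 2], stem_chain[:, 1], 2)
        axis_xy = np.array([np.polyval(px, blade[0, 2]),
                            np.polyval(py, blade[0, 2])])
    else:
        axis_xy = stem_chain[:, :2].mean(axis=0)
    d0 = float(np.linalg.norm(blade[0, :2] - axis_xy))
    s_off = max(d0 - r_stem, 0.0) / sin_g
    eval_s = 0.05 * (L + s_off) - s_off
    incl = float(slope * eval_s + intercept)
    az = math.degrees(math.atan2(float(v[win][:, 1].sum()),
                                 float(v[win][:, 0].sum()))) % 360.0
    cos_g = math.cos(math.radians(np.clip(intercept, 5.0, 175.0)))
    collar_z = float(blade[0, 2] - s_off * cos_g)
    return incl, az, collar_z, s_off


def estimate_stem_radius(cloud_pts: np.ndarray, stem_chain: np.ndarray,
                         search: float = 12.0) -> float:
    """Median distance to the stem polyline of points within ``search`` mm."""
    dense = stem_chain
    if len(stem_chain) >= 2:
        seg = np.linalg.norm(np.diff(stem_chain, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(seg)])
        tgt = np.linspace(0, u[-1], max(4 * len(stem_chain), 8))
        dense = np.column_stack(
            [np.interp(tgt, u, stem_chain[:, d]) for d in range(3)]
        )
    dist, _ = cKDTree(dense).query(cloud_pts)
    near = dist[dist <= search]
    return float(np.median(near)) if len(near) else 0.5 * search


def trim_to_blade(leaf_chain: np.ndarray, stem_chain: np.ndarray,
                  clearance: float) -> np.ndarray:
    """Drop leaf-chain points within ``clearance`` of the stem chain.

    The topologized leaf chain starts at its stem junction, so its first
    segment runs radially out of the stem cylinder; base angles must be
    measured on the blade proper, beyond the stem surface.
    """
    dense = stem_chain
    if len(stem_chain) >= 2:
        seg = np.linalg.norm(np.diff(stem_chain, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(seg)])
        tgt = np.linspace(0, u[-1], max(4 * len(stem_chain), 8))
        dense = np.column_stack(
            [np.interp(tgt, u, stem_chain[:, d]) for d in range(3)]
        )
    dist, _ = cKDTree(dense).query(leaf_chain)
    outside = np.flatnonzero(dist > clearance)
    if len(outside) < 2:
        return leaf_chain
    return leaf_chain[outside[0]:]


def leaf_angles(
    leaf_chain: np.ndarray,
    stem_chain: np.ndarray,
    attachment: int,
    soil_z: float | None = None,
    stem_clearance: float = 0.0,
    r_stem: float | None = None,
):
    """(inclination, azimuth, top height, growth height) in the vertical frame.

    Inclination is the angle between the leaf-base tangent (the fitted
    tangent-angle profile evaluated at 5 % of the blade arc from the stem
    surface) and the upward stem axis; azimuth is that direction's xy
    bearing, CCW from +x in [0, 360).  ``r_stem`` defaults to 60 % of the
    clearance when no measured stem radius is supplied.
    """
    if not (0 <= attachment < len(stem_chain)):
        raise IndexError(f"attachment index {attachment} out of range")
    base = leaf_chain
    if stem_clearance > 0:
        base = trim_to_blade(leaf_chain, stem_chain, stem_clearance)
    if r_stem is None:
        r_stem = 0.6 * stem_clearance
    inclination, azimuth, collar_z, _ = _blade_base_angles(
        base, stem_chain, r_stem)
    soil = float(stem_chain[:, 2].min()) if soil_z is None else float(soil_z)
    top_height = float(leaf_chain[:, 2].max() - soil)
    # the extrapolated collar tracks the attachment more faithfully than
    # the junction sample, which MST quantization places up to a sample
    # radius away along the stem
    if stem_clearance > 0 and len(base) < len(leaf_chain):
        growth_height = float(collar_z - soil)
    else:
        growth_height = float(stem_chain[attachment][2] - soil)
    return inclination, azimuth, top_height, growth_height


# ---------------------------------------------------------------------------
# ring cuts

def cut_rings(
    chain: np.ndarray,
    cloud: ColoredPointCloud,
    n_nodes: int = 8,
    width_prior: float = 40.0,
    spacing: float | None = None,
    trim_fraction: float = 0.05,
    tree: cKDTree | None = None,
) -> list:
    """Virtual ring cuts at evenly spaced nodes along a resampled leaf chain.

    Ring radius r = 1.5x the prior average leaf width; slab length
    l = 2x the cloud's mean neighbor spacing.  Points in each slab are
    single-linkage clustered at cut distance 3x spacing and only the most
    populous cluster is kept, discarding overcut points from crossing
    organs.  Rings with fewer than 5 slab points are marked invalid.
    """
    if spacing is None:
        spacing = cloud.mean_spacing()
    if tree is None:
        tree = cKDTree(cloud.points)
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    fracs = np.linspace(trim_fraction, 1.0 - trim_fraction, n_nodes)
    r = 1.5 * width_prior
    l = 2.0 * spacing

    def one_ring(s):
        i = min(int(np.searchsorted(arc, s)), len(chain) - 1)
        node = chain[i]
        lo, hi = max(i - 1, 0), min(i + 1, len(chain) - 1)
        t = chain[hi] - chain[lo]
        t = t / max(np.linalg.norm(t), 1e-12)
        cand = np.array(tree.query_ball_point(node, math.hypot(r, 2.0 * l)),
                        dtype=int)
        ring = RingCut(node=node, tangent=t, radius=r, length=l,
                       arc_position=float(s), spacing=spacing)
        if len(cand) == 0:
            ring.valid = False
            return ring
        d = cloud.points[cand] - node
        axial = d @ t
        inplane = d - np.outer(axial, t)
        rad = np.linalg.norm(inplane, axis=1)
        in_ring = (np.abs(axial) <= l / 2.0) & (rad <= r)
        if in_ring.sum() < 5:
            ring.valid = False
            return ring
        # single-linkage clustering at cut 3x spacing.  Connectivity is
        # evaluated on a thicker support slab (|axial| <= 2l) so that the
        # sparse 1-D gap statistics of the thin measurement slab cannot
        # fragment the blade cross-section; only thin-slab points of the
        # most populous component are measured.
        support = (np.abs(axial) <= 2.0 * l) & (rad <= r)
        pts3 = cloud.points[cand[support]]
        sub = cKDTree(pts3)
        graph = sub.sparse_distance_matrix(sub, 3.0 * spacing,
                                           output_type="coo_matrix")
        _, comp = connected_components(graph.tocsr(), directed=False)
        best = np.bincount(comp).argmax()
        # the cut line is measured on the cluster points within +-l of
        # axial distance: wide enough to tame the edge-gap noise of the
        # extent estimate, narrow enough that the width profile's gradient
        # along the blade cannot inflate the cross-section
        keep = (comp == best) & (np.abs(axial[support]) <= l)
        kept3 = pts3[keep]
        if (in_ring[support] & keep).sum() < 5 or len(kept3) < 5:
            ring.valid = False
            return ring
        # project kept cluster into the cut plane (2D basis orthogonal to t)
        b1 = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(b1) < 1e-8:
            b1 = np.cross(t, [1.0, 0.0, 0.0])
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(t, b1)
        rel = kept3 - node
        ring.cut_points = np.column_stack([rel @ b1, rel @ b2])
        return ring

    def usable(ring):
        return ring.valid and np.isfinite(ring_width(ring))

    rings = []
    for f in fracs:
        ring = one_ring(f * total)
        if not usable(ring):
            # contamination is local: a small shift along the chain often
            # clears the crossing organ
            for ds in (0.025 * total, -0.025 * total):
                s2 = min(max(f * total + ds, 0.0), total)
                alt = one_ring(s2)
                if usable(alt):
                    ring = alt
                    break
        if not usable(ring):
            ring.valid = False
        rings.append(ring)
    return rings


def ring_width(ring: RingCut) -> float:
    """Cut-line width: extent along the total-least-squares principal line.

    The raw extent of n uniform samples underestimates the true segment
    length by a factor (n-1)/(n+1), so the order-statistics correction
    (n+1)/(n-1) is applied.
    """
    if not ring.valid or ring.cut_points is None or len(ring.cut_points) < 2:
        return np.nan
    # the skeleton node lies on the midrib, so the cut line is constrained
    # through the node (coordinate origin): direction = principal axis of
    # the second moment about the node, with one residual-trimmed refit.
    # This keeps a touching neighbor organ from rotating the fit.
    pts = ring.cut_points
    band = 2.0 * ring.spacing
    _, _, Vt = np.linalg.svd(pts, full_matrices=False)
    for _ in range(2):
        res = pts @ Vt[1]
        inlier = np.abs(res) <= band
        if inlier.sum() < 2:
            break
        _, _, Vt = np.linalg.svd(pts[inlier], full_matrices=False)
    res = pts @ Vt[1]
    proj = pts[np.abs(res) <= band] @ Vt[0]
    n = len(proj)
    if n < 2:
        return np.nan
    lo, hi = float(proj.min()), float(proj.max())
    width = hi - lo
    if n >= 5:
        # order-statistics correction for the extent of uniform samples;
        # tiny cuts are taken at face value
        width *= (n + 1) / (n - 1)
    width = min(width, 2.0 * ring.radius)
    # a clean cut is centred on the node; a strongly one-sided segment is
    # contamination from a neighboring organ the clustering kept
    if abs((hi + lo) / 2.0) > max(0.2 * (hi - lo), 1.5 * ring.spacing):
        return np.nan
    return float(width)


def _filtered_ring_widths(rings: list) -> list:
    """(arc_position, width) pairs after a neighbor-consistency cap.

    The blade width profile is smooth, so a cut that exceeds both of its
    valid neighbors by more than a couple of point spacings is an organ
    contact the clustering and centring checks both missed; it is capped
    at the neighbor maximum plus that margin.  Other widths pass raw.
    """
    spacing = max((r.spacing for r in rings if r.valid), default=1.0)
    vals = [(r.arc_position, ring_width(r)) for r in rings if r.valid]
    vals = [(s, w) for s, w in vals if np.isfinite(w)]
    if len(vals) < 3:
        return vals
    out = []
    for i, (s, w) in enumerate(vals):
        nbrs = [vals[j][1] for j in (i - 1, i + 1) if 0 <= j < len(vals)]
        cap = max(nbrs) + 2.0 * spacing
        out.append((s, float(min(w, cap))))
    return out


def leaf_width(rings: list) -> float:
    """Leaf width = the longest fitted cut line over valid rings (NaN if none)."""
    widths = [ring_width(r) for r in rings if r.valid]
    widths = [w for w in widths if np.isfinite(w)]
    return max(widths) if widths else np.nan


def _robust_leaf_width(rings: list) -> float:
    """Pipeline variant of :func:`leaf_width` on consistency-capped widths."""
    vals = _filtered_ring_widths(rings)
    return max(w for _, w in vals) if vals else np.nan


def leaf_area(rings: list, chain: np.ndarray, collar_offset: float = 0.0) -> float:
    """Trapezoid-sum blade area over consecutive valid rings plus end caps.

    The base cap tapers linearly from the first ring back to zero width at
    the collar (``collar_offset`` of arc before the chain start); the tip
    cap tapers to the zero-width point extrapolated from the last two ring
    widths, never farther than 20 % of the chain beyond its end.  Returns
    NaN with fewer than two valid rings.
    """
    valid = _filtered_ring_widths(rings)
    if len(valid) < 2:
        return np.nan
    total = chain_arc_length(chain)
    area = 0.0
    for (s0, w0), (s1, w1) in zip(valid[:-1], valid[1:]):
        area += 0.5 * (w0 + w1) * (s1 - s0)
    s_first, w_first = valid[0]
    s_prev, w_prev = valid[-2]
    s_last, w_last = valid[-1]
    area += 0.5 * w_first * (s_first + max(collar_offset, 0.0))
    tip_run = total - s_last
    if w_prev > w_last > 0:
        extrap = w_last * (s_last - s_prev) / (w_prev - w_last)
        tip_run = min(max(tip_run, extrap), total - s_last + 0.2 * total)
    area += 0.5 * w_last * max(tip_run, 0.0)
    return float(area)


# ---------------------------------------------------------------------------
# assembly

def extract_all(
    cloud: ColoredPointCloud,
    skeleton: Skeleton,
    config: TraitConfig | None = None,
) -> TraitRecord:
    """Full eight-trait record from a metric shoot cloud and its skeleton.

    The cloud and skeleton are first rotated into the stem-vertical frame.
    Missing per-leaf values propagate as NaN, never zero.  Leaves are
    ordered by growth height.
    """
    config = config or TraitConfig()
    if skeleton.stem is None or len(skeleton.stem) < 2:
        raise ValueError("skeleton has no stem chain")
    R = verticalizing_rotation(skeleton.stem)
    cl = cloud.transformed(R, np.zeros(3))
    sk = skeleton.transformed(R, np.zeros(3))
    soil = config.soil_z
    height = plant_height(cl, sk, soil)
    spacing = cl.mean_spacing() if len(cl) > 1 else 1.0

    # ring cuts are measured on the stem-free cloud: near the collar the
    # cut plane crosses the stem cylinder, which would weld onto the blade
    # cross-section and inflate the fitted cut line
    seg = np.linalg.norm(np.diff(sk.stem, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0, u[-1], max(4 * len(sk.stem), 8))
    dense_stem = np.column_stack(
        [np.interp(tgt, u, sk.stem[:, d]) for d in range(3)]
    )
    d_stem, _ = cKDTree(dense_stem).query(cl.points)
    blade_cloud = cl.select(d_stem > config.stem_clearance)
    tree = cKDTree(blade_cloud.points)

    def measure(chain_rs, prior):
        rings = cut_rings(chain_rs, blade_cloud, config.n_nodes, prior,
                          spacing, config.trim_fraction, tree)
        return rings, _robust_leaf_width(rings)

    leaves = []
    resampled = [resample_chain(c, config.resample_points) for c in sk.leaves]
    # ring cuts and angles live on the blade: the chain segment outside the
    # stem cylinder (the junction-to-stem-surface stub would pollute them)
    blades = [trim_to_blade(c, sk.stem, config.stem_clearance)
              for c in resampled]
    widths0 = []
    for blade in blades:
        _, w = measure(blade, config.width_prior)
        widths0.append(w)
    prior = config.width_prior
    if config.auto_width:
        finite = [w for w in widths0 if np.isfinite(w)]
        if finite:
            prior = float(np.median(finite))
    r_stem = estimate_stem_radius(cl.points, sk.stem,
                                  search=config.stem_clearance)
    soil_val = float(sk.stem[:, 2].min()) if soil is None else float(soil)
    for i, chain_rs in enumerate(resampled):
        blade = blades[i]
        rings, w = measure(blade, prior)
        incl, az, collar_z, s_off = _blade_base_angles(blade, sk.stem, r_stem)
        top = float(chain_rs[:, 2].max() - soil_val)
        growth = float(collar_z - soil_val)
        # midrib length measured from the collar: blade chain arc plus
        # the collar offset (tip truncation is a known small negative bias)
        length = leaf_length(blade) + max(s_off, 0.0)
        leaves.append(LeafTraits(
            leaf_length=length,
            leaf_width=w,
            leaf_area=leaf_area(rings, blade, s_off),
            inclination_deg=incl,
            azimuth_deg=az,
            top_height=top,
            growth_height=growth,
        ))
    leaves.sort(key=lambda lf: lf.growth_height)
    return TraitRecord(plant_height=height, leaves=leaves)
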