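"""Curve-skeleton extraction for maize shoots.

The shoot-only cloud (pot and ground removed) is collapsed onto its
medial curves by Laplacian contraction on a k-NN graph: each iteration
solves the sparse least-squares system balancing a smoothing term
``W_L * L X`` against a positional attraction term ``W_H * (X - X_prev)``,
with the smoothing weight growing geometrically until the point set is
quasi-one-dimensional.  The contracted set is then topologized by
farthest-point sampling plus a Euclidean minimum spanning tree: the path
from the lowest node to the highest node is the stem, the remaining
branches become leaf chains.  Chains are finally recentred against the
original cloud (tangent-plane disk centroids) and resampled at uniform
arc length with a natural cubic spline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud


@dataclass
class ContractionParams:
    initial_laplace_weight: float = 1.0
    attraction_weight: float = 1.0
    weight_growth: float = 2.0
    max_contraction_iters: int = 10
    topology_sample_radius: float = 10.0   # mm, ~internode scale
    knn: int = 12
    linearity_target: float = 0.05
    downsample_voxel: float = 4.0          # mm; 0 disables

    def __post_init__(self) -> None:
        if min(self.initial_laplace_weight, self.attraction_weight,
               self.weight_growth, self.topology_sample_radius) <= 0:
            raise ValueError("contraction parameters must be positive")
        if self.weight_growth <= 1:
            raise ValueError("weight_growth must exceed 1")


@dataclass
class Skeleton:
    """Per-organ ordered polylines: one stem chain plus one chain per leaf.

    ``stem`` is ordered bottom-to-top, every leaf base-to-tip, and
    ``attachments[i]`` is the stem-chain index where leaf ``i`` joins.
    """

    stem: np.ndarray
    leaves: list = field(default_factory=list)
    attachments: list = field(default_factory=list)

    @property
    def chains(self) -> list:
        out = [("stem", self.stem)]
        out += [(f"leaf_{i}", c) for i, c in enumerate(self.leaves)]
        return out

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Skeleton":
        R = np.asarray(R, float)
        t = np.asarray(t, float).reshape(3)
        return Skeleton(
            stem=self.stem @ R.T + t,
            leaves=[c @ R.T + t for c in self.leaves],
            attachments=list(self.attachments),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "stem": self.stem.tolist(),
                "leaves": [c.tolist() for c in self.leaves],
                "attachments": [int(a) for a in self.attachments],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Skeleton":
        d = json.loads(text)
        return cls(
            stem=np.asarray(d["stem"], float),
            leaves=[np.asarray(c, float) for c in d["leaves"]],
            attachments=list(d["attachments"]),
        )


def voxel_downsample(points: np.ndarray, voxel: float) -> np.ndarray:
    """Centroid-per-voxel downsampling (deterministic)."""
    if voxel <= 0:
        return points
    keys = np.floor(points / voxel).astype(np.int64)
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    n = inv.max() + 1
    sums = np.zeros((n, 3))
    counts = np.bincount(inv, minlength=n).astype(float)
    for d in range(3):
        sums[:, d] = np.bincount(inv, weights=points[:, d], minlength=n)
    return sums / counts[:, None]


def _knn_laplacian(points: np.ndarray, k: int) -> sparse.csr_matrix:
    """Symmetrized uniform-weight graph Laplacian L = D - W."""
    n = len(points)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k + 1, n))
    rows = np.repeat(np.arange(n), idx.shape[1] - 1)
    cols = idx[:, 1:].ravel()
    W = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)
    deg = np.asarray(W.sum(axis=1)).ravel()
    return sparse.diags(deg) - W.tocsr()


def _linearity(points: np.ndarray, k: int = 10) -> float:
    """Median over points of (lam1 + lam2) / lam3 of the k-NN covariance."""
    n = len(points)
    tree = cKDTree(points)
    sub = points if n <= 4000 else points[:: n // 4000 + 1]
    _, idx = tree.query(sub, k=min(k + 1, n))
    nb = points[idx]
    c = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", c, c) / nb.shape[1]
    lam = np.linalg.eigvalsh(cov)
    return float(np.median((lam[:, 0] + lam[:, 1]) / np.maximum(lam[:, 2], 1e-30)))


def contract_cloud(
    cloud: ColoredPointCloud | np.ndarray,
    params: ContractionParams | None = None,
) -> np.ndarray:
    """Contract a shoot-only cloud onto curve-like loci.

    Returns the contracted point set (same cardinality as the working set;
    the cloud is voxel-downsampled first when ``downsample_voxel`` > 0).
    """
    params = params or ContractionParams()
    pts = cloud.points if isinstance(cloud, ColoredPointCloud) else np.asarray(cloud, float)
    X = voxel_downsample(pts, params.downsample_voxel)
    if len(X) < params.knn + 2:
        raise ValueError("too few points to contract")
    L = _knn_laplacian(X, params.knn)
    wl = params.initial_laplace_weight
    wh = params.attraction_weight
    for it in range(params.max_contraction_iters):
        A = (wl * wl) * (L.T @ L) + (wh * wh) * sparse.eye(len(X), format="csr")
        try:
            solver = splu(A.tocsc())
            X = np.column_stack(
                [solver.solve((wh * wh) * X[:, d]) for d in range(3)]
            )
        except RuntimeError as exc:   # pragma: no cover - solver failure
            raise RuntimeError(f"contraction solve failed at iteration {it}: {exc}")
        if _linearity(X) < params.linearity_target:
            break
        wl *= params.weight_growth
    return X


# ---------------------------------------------------------------------------
# topology

def _farthest_point_sampling(points: np.ndarray, radius: float) -> np.ndarray:
    """Greedy FPS until every point is within ``radius`` of a sample."""
    n = len(points)
    start = int(np.argmin(points[:, 2]))
    dist = np.linalg.norm(points - points[start], axis=1)
    chosen = [start]
    while dist.max() > radius:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return points[np.array(chosen)]


def topologize(
    contracted: np.ndarray,
    sample_radius: float = 10.0,
    min_branch_samples: int = 3,
    expected_leaves: int | None = None,
) -> Skeleton:
    """Build a labeled stem/leaf skeleton from a contracted point set.

    Samples the contracted set by farthest-point sampling, spans the
    samples with a Euclidean minimum spanning tree, takes the tree path
    from the lowest to the highest sample as the stem, and turns every
    remaining branch into a leaf chain rooted at its stem junction.
    Branches shorter than ``min_branch_samples`` samples are treated as
    contraction debris and dropped.
    """
    samples = _farthest_point_sampling(np.asarray(contracted, float), sample_radius)
    n = len(samples)
    if n < 2:
        raise ValueError("contracted set too small to topologize")
    d2 = np.linalg.norm(samples[:, None] - samples[None, :], axis=2)
    mst = minimum_spanning_tree(d2).tocoo()
    adj = [[] for _ in range(n)]
    for i, j in zip(mst.row, mst.col):
        adj[i].append(j)
        adj[j].append(i)

    root = int(np.argmin(samples[:, 2]))
    # BFS parents from root
    parent = np.full(n, -1)
    order = [root]
    seen = np.zeros(n, bool)
    seen[root] = True
    for u in order:
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                order.append(v)

    def path_to_root(v):
        path = [v]
        while parent[path[-1]] != -1:
            path.append(parent[path[-1]])
        return path[::-1]

    # the stem is the highest-reaching root path that stays straight: a
    # path continuing into a leaf bends sharply at the junction and into
    # the arch, so its deviation from its own best-fit line is large.
    # This criterion also tolerates a leaning plant.
    z_range = samples[:, 2].max() - samples[:, 2].min()
    straight_tol = max(2.0 * sample_radius, 0.05 * z_range)

    def path_straightness(idx_path):
        pts = samples[np.array(idx_path)]
        c = pts - pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(c, full_matrices=False)
        resid = c - np.outer(c @ Vt[0], Vt[0])
        return float(np.linalg.norm(resid, axis=1).max())

    order_z = np.argsort(samples[:, 2])[::-1]
    top = None
    for cand in order_z[: max(12, n // 10)]:
        path = path_to_root(int(cand))
        if len(path) >= 3 and path_straightness(path) <= straight_tol:
            top = int(cand)
            break
    if top is None:
        # fallback: highest sample within a vertical column above the root
        gate = max(0.15 * z_range, 3.0 * sample_radius)
        xy_dist = np.linalg.norm(samples[:, :2] - samples[root, :2], axis=1)
        column = np.flatnonzero(xy_dist <= gate)
        top = int(column[np.argmax(samples[column, 2])])
    stem_idx = path_to_root(top)
    on_stem = np.zeros(n, bool)
    on_stem[stem_idx] = True

    # each off-stem subtree becomes one leaf chain: junction -> deepest node
    leaves = []
    attach = []
    for si, s in enumerate(stem_idx):
        for v in adj[s]:
            if on_stem[v] or parent[v] != s:
                continue
            # collect subtree under v
            sub = [v]
            for u in sub:
                for w in adj[u]:
                    if w != parent[u] and not on_stem[w]:
                        sub.append(w)
            if len(sub) < min_branch_samples:
                continue
            # deepest node by tree distance from the junction
            depth = {s: 0.0}
            best, best_d = v, 0.0
            stack = [(v, float(d2[s, v]))]
            while stack:
                u, du = stack.pop()
                depth[u] = du
                if du > best_d:
                    best, best_d = u, du
                for w in adj[u]:
                    if w != parent[u] and not on_stem[w]:
                        stack.append((w, du + float(d2[u, w])))
            chain = [best]
            while chain[-1] != s:
                chain.append(parent[chain[-1]])
            chain = chain[::-1]      # junction -> tip
            leaves.append(samples[np.array(chain)])
            attach.append(si)

    if expected_leaves is not None and len(leaves) > expected_leaves + 3:
        warnings.warn(
            f"over-segmentation: {len(leaves)} branches for "
            f"{expected_leaves} expected leaves"
        )
    # order leaves by attachment height
    order_ix = np.argsort([samples[stem_idx[a]][2] for a in attach]) if attach else []
    leaves = [leaves[i] for i in order_ix]
    attach = [attach[i] for i in order_ix]
    return Skeleton(stem=samples[np.array(stem_idx)], leaves=leaves,
                    attachments=attach)


# ---------------------------------------------------------------------------
# refinement against the original cloud

def _tangents(chain: np.ndarray) -> np.ndarray:
    t = np.gradient(chain, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return t / n


def _recenter_chain(chain, tree, cloud_pts, disk_radius, slab_half):
    tang = _tangents(chain)
    out = chain.copy()
    misses = 0
    for i, (p, t) in enumerate(zip(chain, tang)):
        cand = tree.query_ball_point(p, disk_radius)
        if not cand:
            misses += 1
            continue
        d = cloud_pts[cand] - p
        axial = d @ t
        mask = np.abs(axial) <= slab_half
        if not mask.any():
            misses += 1
            continue
        target = p + d[mask].mean(axis=0)
        step = target - p
        norm = np.linalg.norm(step)
        if norm > disk_radius:
            step *= disk_radius / norm
        out[i] = p + step
    return out, misses


def _extend_chain_tip(chain, tree, cloud_pts, radius, max_steps=60):
    """Grow the chain's tip outward while cloud support continues.

    Contraction shrinks free chain ends (stem apex, leaf tips).  The tip
    advances to the centroid of cloud points ahead of it along a smoothed
    direction estimate; it stops when forward support vanishes (the blade
    tip or stem cap) or the step direction breaks down.
    """
    out = list(chain)
    t = out[-1] - out[-2]
    t = t / max(np.linalg.norm(t), 1e-12)
    # a contracted end shrinks by at most a modest fraction of the chain;
    # capping the added arc keeps a bad step from walking onto another organ
    budget = 0.35 * float(
        np.linalg.norm(np.diff(np.asarray(chain), axis=0), axis=1).sum()
    )
    added = 0.0
    for _ in range(max_steps):
        tip = out[-1]
        cand = tree.query_ball_point(tip, 1.2 * radius)
        if not cand:
            break
        d = cloud_pts[cand] - tip
        axial = d @ t
        ahead = axial > 0.15 * radius
        if ahead.sum() < 2:
            break
        adv = d[ahead].mean(axis=0)
        if adv @ t < 0.05 * radius:
            break
        t_new = adv / np.linalg.norm(adv)
        if t_new @ t < 0.5:   # direction break: stop rather than curl
            break
        added += float(np.linalg.norm(adv))
        if added > budget:
            break
        out.append(tip + adv)
        t = 0.6 * t + 0.4 * t_new
        t /= np.linalg.norm(t)
    return np.asarray(out)


def refine_skeleton(
    skeleton: Skeleton,
    cloud: ColoredPointCloud,
    sample_radius: float = 10.0,
    extend_tips: bool = True,
    n_passes: int = 2,
    stem_exclusion_radius: float = 12.0,
) -> Skeleton:
    """Recenter chain points onto the cloud and extend shrunken tips.

    Every skeleton point moves to the centroid of cloud points inside a
    disk of radius 1.5x ``sample_radius`` lying in the plane normal to the
    local tangent (slab half-thickness = ``sample_radius`` / 2); the update
    is capped at the disk radius and empty disks leave points unchanged.
    Laplacian contraction shortens chain ends, so tips are then grown
    outward along the tangent while cylinder-of-support continues.

    Leaf chains are refined against the cloud with points within
    ``stem_exclusion_radius`` of the stem chain excluded, so the stem
    cylinder cannot drag leaf bases toward the axis.
    """
    pts = cloud.points
    tree = cKDTree(pts)
    disk = 1.5 * sample_radius
    slab = sample_radius / 2.0
    misses = 0

    def refine(chain, tr, p):
        nonlocal misses
        c, m = _recenter_chain(chain, tr, p, disk, slab)
        if extend_tips:
            c = _extend_chain_tip(c, tr, p, sample_radius)
        for _ in range(n_passes - 1):
            c, m = _recenter_chain(c, tr, p, disk, slab)
        misses += m
        return c

    stem = refine(skeleton.stem, tree, pts)

    # blade-only cloud for leaf refinement
    seg = np.linalg.norm(np.diff(stem, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0, u[-1], max(4 * len(stem), 8))
    dense_stem = np.column_stack(
        [np.interp(tgt, u, stem[:, d]) for d in range(3)]
    )
    d_stem, _ = cKDTree(dense_stem).query(pts)
    blade_pts = pts[d_stem > stem_exclusion_radius]
    blade_tree = cKDTree(blade_pts) if len(blade_pts) else tree
    if not len(blade_pts):
        blade_pts = pts

    leaves = [refine(c, blade_tree, blade_pts) for c in skeleton.leaves]
    if misses:
        warnings.warn(f"{misses} skeleton points had empty refinement disks")
    return Skeleton(stem=stem, leaves=leaves,
                    attachments=list(skeleton.attachments))


# ---------------------------------------------------------------------------
# spline resampling

def resample_chain(chain: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a polyline at uniform arc length via a natural cubic spline.

    Falls back to linear interpolation below 4 input points.  Endpoints
    are preserved exactly.
    """
    chain = np.asarray(chain, float)
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    # drop consecutive duplicates
    keep = np.ones(len(chain), bool)
    keep[1:] = np.linalg.norm(np.diff(chain, axis=0), axis=1) > 1e-12
    chain = chain[keep]
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if len(chain) < 4:
        warnings.warn("chain has < 4 points; linear resampling used")
        tgt = np.linspace(0, u[-1], n_out)
        return np.column_stack(
            [np.interp(tgt, u, chain[:, d]) for d in range(3)]
        )
    spline = CubicSpline(u, chain, axis=0, bc_type="natural")
    dense = np.linspace(0, u[-1], max(20 * len(chain), 20 * n_out))
    dp = spline(dense)
    ds = np.linalg.norm(np.diff(dp, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(ds)])
    tgt = np.linspace(0, arc[-1], n_out)
    params = np.interp(tgt, arc, dense)
    out = spline(params)
    out[0], out[-1] = chain[0], chain[-1]
    return out


def chain_arc_length(chain: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(chain, float), axis=0), axis=1).sum())


def extract_skeleton(
    cloud: ColoredPointCloud,
    params: ContractionParams | None = None,
    expected_leaves: int | None = None,
) -> Skeleton:
    """Contract + topologize + refine in one call (shoot-only cloud)."""
    params = params or ContractionParams()
    contracted = contract_cloud(cloud, params)
    skel = topologize(contracted, params.topology_sample_radius,
                      expected_leaves=expected_leaves)
    return refine_skeleton(skel, cloud, params.topology_sample_radius)
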