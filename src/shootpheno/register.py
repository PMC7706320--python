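"""Rigid registration of truncated tall-shoot halves.

Shoots taller than the acquisition device are cut and imaged in two
passes sharing at least two complete leaves; the basal cloud ``P`` is the
reference and the upper cloud ``Q`` is moved.  Iterative closest point
minimizes the mean squared correspondence energy

    E(R, T) = (1/N_P) * sum_i || p_i - R q_i - T ||^2

by alternating nearest-neighbor correspondence (each P point to its
nearest transformed Q point) with the closed-form SVD (Kabsch/Umeyama
without scale) solution on those pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud


class EnergyIncreaseError(RuntimeError):
    """ICP energy increased between iterations (never expected)."""


@dataclass
class RigidTransform:
    """Rotation + translation mapping Q into P's frame: x -> R x + T."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    T: np.ndarray = field(default_factory=lambda: np.zeros(3))
    final_energy: float = np.nan
    iterations: int = 0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if np.linalg.norm(self.R.T @ self.R - np.eye(3)) > 1e-8:
            raise ValueError("R is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-8:
            raise ValueError("R is not a proper rotation (det != +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.R.T + self.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(R=self.R.T, T=-self.R.T @ self.T)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(R=self.R @ other.R, T=self.R @ other.T + self.T)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.T
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(R=m[:3, :3], T=m[:3, 3])


def _solve_rigid(p: np.ndarray, q: np.ndarray):
    """Closed-form least-squares rotation/translation mapping q onto p."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (q - qc).T @ (p - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, pc - R @ qc


def principal_axis_init(
    P_crop: ColoredPointCloud, Q_crop: ColoredPointCloud
) -> RigidTransform:
    """Initial transform aligning Q's overlap crop onto P's.

    Aligns centroids and the dominant principal axes of the two crops
    (sign chosen by third-moment agreement), standing in for the manual
    overlap-leaf selection of an interactive workflow.
    """
    def frame(pts):
        c = pts.mean(axis=0)
        x = pts - c
        _, _, Vt = np.linalg.svd(x, full_matrices=False)
        axes = Vt.copy()
        for i in range(3):
            if np.sum((x @ axes[i]) ** 3) < 0:
                axes[i] = -axes[i]
        if np.linalg.det(axes) < 0:
            axes[2] = -axes[2]
        return c, axes.T  # columns are axes

    cp, Ap = frame(P_crop.points)
    cq, Aq = frame(Q_crop.points)
    R = Ap @ Aq.T
    return RigidTransform(R=R, T=cp - R @ cq)


def icp_register(
    P: ColoredPointCloud,
    Q: ColoredPointCloud,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_factor: float = 3.0,
) -> RigidTransform:
    """Register Q onto P by trimmed iterative closest point.

    Correspondences farther than ``trim_factor`` times the median pair
    distance are excluded from the solve (robustness under partial
    overlap); the reported energy is the full Eq-style mean over all P
    points.  The energy trace is asserted non-increasing.
    """
    if len(P) == 0 or len(Q) == 0:
        raise ValueError("both clouds must be non-empty")
    t = init or RigidTransform()
    tree_q = cKDTree(Q.points)
    p = P.points

    def correspond(transform):
        q_moved = transform.apply(Q.points)
        tree = cKDTree(q_moved)
        d, j = tree.query(p)
        return d, Q.points[j]

    d, q_sel = correspond(t)
    energy = float(np.mean(d**2))
    trace = [energy]
    it = 0
    for it in range(1, max_iter + 1):
        if trim_factor is not None and len(d) > 10:
            med = np.median(d)
            keep = d <= trim_factor * max(med, 1e-12)
        else:
            keep = slice(None)
        R, T = _solve_rigid(p[keep], q_sel[keep])
        cand = RigidTransform(R=R, T=T)
        d_new, q_new = correspond(cand)
        e_new = float(np.mean(d_new**2))
        if e_new > energy * (1.0 + 1e-9) + 1e-15:
            raise EnergyIncreaseError(
                f"energy rose from {energy:.6g} to {e_new:.6g} at iteration {it}"
            )
        converged = energy - e_new < tol * max(energy, 1e-30)
        t, d, q_sel, energy = cand, d_new, q_new, e_new
        trace.append(energy)
        if converged or energy == 0.0:
            break
    t.final_energy = energy
    t.iterations = it
    t.trace = trace
    return t


def merge_registered(
    P: ColoredPointCloud,
    Q: ColoredPointCloud,
    t: RigidTransform,
    duplicate_radius: float | None = None,
) -> ColoredPointCloud:
    """Union of P and transformed Q, dropping transformed-Q duplicates.

    A transformed Q point within ``duplicate_radius`` of any P point is
    considered re-imaged overlap and removed; default radius is 1.5x the
    mean point spacing of P.
    """
    if duplicate_radius is None:
        duplicate_radius = 1.5 * P.mean_spacing()
    q_moved = Q.transformed(t.R, t.T)
    tree = cKDTree(P.points)
    d, _ = tree.query(q_moved.points)
    keep = d > duplicate_radius
    return P.concat(q_moved.select(keep))
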