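"""Pipeline orchestration, acquisition-geometry planning and provenance.

The processing chain mirrors the acquisition workflow: denoise the raw
cloud, calibrate it to millimetres from the pot, optionally register the
two halves of a truncated tall shoot, strip the pot and ground, extract
the curve skeleton and compute the trait record.  Every intermediate is
written next to the output and logged with the hashes of its inputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibrate import apply_scale, estimate_scale, segment_pot
from .cloud import ColoredPointCloud
from .denoise import DenoiseParams, NoiseColorList, denoise_region_growth
from .io_formats import read_cloud, write_cloud
from .register import RigidTransform, icp_register, merge_registered
from .skeleton import ContractionParams, extract_skeleton
from .traits import TraitConfig, TraitRecord, extract_all

ROTATION_RANGE_DEG = 400.0    # > 360 so first and last images overlap
MAX_ROTATION_SPEED = 6.0      # deg/s: one circle per minute, motor stability
MIN_CAPTURE_INTERVAL = 1.0    # s


class AcquisitionConstraintError(ValueError):
    pass


@dataclass
class AcquisitionPlan:
    phi: float
    v: float
    t: float
    n_per_layer: int
    n_cameras: int = 2

    @property
    def images_total(self) -> int:
        return self.n_per_layer * self.n_cameras

    @property
    def seconds_per_layer(self) -> float:
        return self.phi / self.v


def images_per_layer(phi: float, v: float, t: float) -> int:
    """Images captured per camera layer: floor(phi / (v t)).

    ``t`` must be at least 1 s (camera write-out) and ``v`` at most
    6 deg/s (one rotation per minute, for motor stability).
    """
    if phi <= 0 or v <= 0:
        raise AcquisitionConstraintError("phi and v must be positive")
    if t < MIN_CAPTURE_INTERVAL:
        raise AcquisitionConstraintError(
            f"capture interval t={t} s below the {MIN_CAPTURE_INTERVAL} s minimum"
        )
    if v > MAX_ROTATION_SPEED:
        raise AcquisitionConstraintError(
            f"rotation speed v={v} deg/s above the {MAX_ROTATION_SPEED} deg/s limit"
        )
    return int(np.floor(phi / (v * t)))


def make_plan(phi: float = ROTATION_RANGE_DEG, v: float = 6.0, t: float = 2.0,
              n_cameras: int = 2) -> AcquisitionPlan:
    return AcquisitionPlan(phi=phi, v=v, t=t,
                           n_per_layer=images_per_layer(phi, v, t),
                           n_cameras=n_cameras)


# ---------------------------------------------------------------------------
# pot/ground removal

def remove_pot_and_ground(
    cloud: ColoredPointCloud,
    pot_color=None,
    tolerance: float = 60.0,
    rim_margin: float = 3.0,
):
    """Shoot-only cloud: drop the pot segment and everything at/below its rim.

    Returns ``(shoot_cloud, soil_z)`` where ``soil_z`` is the pot rim
    height (the soil surface sits at the rim of a filled pot).
    """
    from .synth import POT_COLOR

    if pot_color is None:
        pot_color = tuple(POT_COLOR)
    _, pot_idx = segment_pot(cloud, pot_color, tolerance)
    rim_z = float(cloud.points[pot_idx, 2].max())
    keep = np.ones(len(cloud), dtype=bool)
    keep[pot_idx] = False
    keep &= cloud.points[:, 2] > rim_z + rim_margin
    return cloud.select(keep), rim_z


# ---------------------------------------------------------------------------
# config + provenance

@dataclass
class PipelineConfig:
    input_path: str = ""
    upper_path: str = ""            # second segment of a truncated tall shoot
    init_transform_path: str = ""   # 4x4 row-major text matrix for ICP init
    out_dir: str = "run"
    pot_radius_mm: float = 150.0
    pot_color: tuple = (180, 90, 60)
    pot_color_tolerance: float = 60.0
    seed: int = 0
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    noise_colors: NoiseColorList = field(default_factory=NoiseColorList)
    contraction: ContractionParams = field(default_factory=ContractionParams)
    traits: TraitConfig = field(default_factory=TraitConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class _Provenance:
    def __init__(self, out_dir: str, config: PipelineConfig):
        self.records = []
        self.out_dir = out_dir
        self.config = config
        self.t0 = time.time()
        self.warnings: list[str] = []

    def log(self, stage: str, outputs: list[str], inputs: list[str],
            **extra) -> None:
        self.records.append({
            "stage": stage,
            "elapsed_s": round(time.time() - self.t0, 3),
            "inputs": {os.path.basename(p): _sha256(p) for p in inputs
                       if os.path.exists(p)},
            "outputs": [os.path.basename(p) for p in outputs],
            **extra,
        })

    def write(self, status: str) -> str:
        path = os.path.join(self.out_dir, "provenance.json")
        with open(path, "w") as fh:
            json.dump({
                "status": status,
                "config": _jsonable(self.config.to_dict()),
                "stages": self.records,
                "warnings": self.warnings,
            }, fh, indent=2)
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> TraitRecord:
    """Execute denoise -> calibrate -> [register] -> skeleton -> traits.

    Writes every intermediate artifact and a provenance log into
    ``config.out_dir``; raises on the first hard error after persisting the
    partial artifacts and the log.
    """
    if not config.input_path or not os.path.exists(config.input_path):
        raise FileNotFoundError(f"input cloud not found: {config.input_path}")
    if config.upper_path and not os.path.exists(config.upper_path):
        raise FileNotFoundError(f"upper cloud not found: {config.upper_path}")
    os.makedirs(config.out_dir, exist_ok=True)
    prov = _Provenance(config.out_dir, config)
    out = lambda name: os.path.join(config.out_dir, name)

    stage = "read"
    try:
        cloud = read_cloud(config.input_path)
        upper = read_cloud(config.upper_path) if config.upper_path else None

        stage = "denoise"
        clean, removed = denoise_region_growth(
            cloud, config.noise_colors, config.denoise
        )
        write_cloud(clean, out("denoised.ply"))
        np.savetxt(out("removed_indices.csv"), removed, fmt="%d",
                   header="removed_index", comments="")
        prov.log(stage, [out("denoised.ply")], [config.input_path],
                 removed=len(removed))

        if upper is not None:
            stage = "denoise_upper"
            upper, _ = denoise_region_growth(
                upper, config.noise_colors, config.denoise
            )
            stage = "register"
            init = RigidTransform()
            if config.init_transform_path:
                init = RigidTransform.from_matrix(
                    np.loadtxt(config.init_transform_path)
                )
            t = icp_register(clean, upper, init=init)
            clean = merge_registered(clean, upper, t)
            write_cloud(clean, out("merged.ply"))
            with open(out("icp.json"), "w") as fh:
                json.dump({"matrix": t.matrix.tolist(),
                           "final_energy": t.final_energy,
                           "iterations": t.iterations}, fh, indent=2)
            prov.log(stage, [out("merged.ply"), out("icp.json")],
                     [out("denoised.ply"), config.upper_path],
                     iterations=t.iterations)

        stage = "calibrate"
        est = estimate_scale(clean, config.pot_radius_mm, config.pot_color,
                             config.pot_color_tolerance)
        metric = apply_scale(clean, est.tau)
        write_cloud(metric, out("metric.ply"))
        with open(out("scale.json"), "w") as fh:
            json.dump(_jsonable(asdict(est)), fh, indent=2)
        prov.log(stage, [out("metric.ply"), out("scale.json")],
                 [out("denoised.ply")], tau=est.tau)

        stage = "skeleton"
        shoot, soil_z = remove_pot_and_ground(
            metric, config.pot_color, config.pot_color_tolerance
        )
        skel = extract_skeleton(shoot, config.contraction)
        with open(out("skeleton.json"), "w") as fh:
            fh.write(skel.to_json())
        prov.log(stage, [out("skeleton.json")], [out("metric.ply")],
                 n_leaves=len(skel.leaves))

        stage = "traits"
        tconf = config.traits
        # shift so the soil surface (pot rim) is z = 0, then measure
        shoot_shift = ColoredPointCloud(
            shoot.points - [0, 0, soil_z], shoot.colors,
            shoot.normals, frame_note="metric",
        )
        skel_shift = skel.transformed(np.eye(3), np.array([0, 0, -soil_z]))
        tconf.soil_z = 0.0
        record = extract_all(shoot_shift, skel_shift, tconf)
        record.to_csv(out("traits.csv"))
        prov.log(stage, [out("traits.csv")], [out("skeleton.json")])
    except Exception as exc:
        prov.warnings.append(f"stage '{stage}' failed: {exc}")
        prov.write(f"failed at {stage}")
        raise
    prov.write("ok")
    return record
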