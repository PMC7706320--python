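"""Point-cloud file I/O (PLY / PCD / XYZRGB) and the shoot catalog.

Written PLY is always ASCII for diffability; binary_little_endian PLY is
accepted on read.  PCD follows v0.7 with the packed-float ``rgb`` field.
The catalog is a flat CSV, one row per shoot, keyed by
(experiment, plot, shoot_id); the experiment/plot/shoot tree is derived
from the columns, never stored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud import ColoredPointCloud

__all__ = [
    "CloudParseError",
    "CatalogConflictError",
    "read_cloud",
    "write_cloud",
    "CatalogEntry",
    "catalog_upsert",
    "catalog_rollup",
]

HEADER_COMMENT = "coordinate frame: z-up, millimetres after calibration"


class CloudParseError(ValueError):
    """Malformed point-cloud file; the message names the offending line."""


class CatalogConflictError(ValueError):
    """Upsert would silently change an immutable catalog field."""


# ---------------------------------------------------------------------------
# PLY

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh):
    magic = fh.readline().strip()
    if magic != b"ply":
        raise CloudParseError("line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []  # (name, dtype code) of element vertex
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise CloudParseError(f"line {lineno}: unexpected EOF in PLY header")
        toks = raw.decode("ascii", "replace").split()
        if not toks:
            continue
        if toks[0] == "comment":
            continue
        if toks[0] == "format":
            fmt = toks[1]
        elif toks[0] == "element":
            in_vertex = toks[1] == "vertex"
            if in_vertex:
                n_vertex = int(toks[2])
        elif toks[0] == "property":
            if in_vertex:
                if toks[1] == "list":
                    raise CloudParseError(
                        f"line {lineno}: list property on vertex unsupported"
                    )
                if toks[1] not in _PLY_DTYPES:
                    raise CloudParseError(
                        f"line {lineno}: unknown PLY type '{toks[1]}'"
                    )
                props.append((toks[2], _PLY_DTYPES[toks[1]]))
        elif toks[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise CloudParseError(f"unsupported PLY format '{fmt}'")
    if n_vertex is None:
        raise CloudParseError("PLY header has no vertex element")
    return fmt, n_vertex, props, lineno


def _read_ply(path: str) -> ColoredPointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, header_lines = _parse_ply_header(fh)
        names = [p[0] for p in props]
        dtype = np.dtype([(nm, "<" + code) for nm, code in props])
        if fmt == "ascii":
            rows = []
            for i in range(n):
                raw = fh.readline()
                if not raw:
                    raise CloudParseError(
                        f"line {header_lines + i + 1}: expected {n} vertex "
                        f"records, file ended after {i}"
                    )
                toks = raw.split()
                if len(toks) != len(props):
                    raise CloudParseError(
                        f"line {header_lines + i + 1}: expected "
                        f"{len(props)} fields, got {len(toks)}"
                    )
                rows.append(tuple(float(t) for t in toks))
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype)
        else:
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise CloudParseError("binary PLY vertex data truncated")
            data = np.frombuffer(buf, dtype=dtype, count=n)
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise CloudParseError(f"PLY vertex element lacks '{axis}' property")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    if not all(c in names for c in ("red", "green", "blue")):
        raise CloudParseError("PLY has no color (red/green/blue) — pipeline requires color")
    cols = np.column_stack([data["red"], data["green"], data["blue"]])
    if cols.dtype.kind == "f":
        # 0-1 float colors rescaled to 0-255, round half up
        if len(cols) and cols.max() <= 1.0:
            cols = np.floor(cols * 255.0 + 0.5)
        else:
            cols = np.floor(cols + 0.5)
    cols = np.clip(cols, 0, 255).astype(np.uint8)
    normals = None
    if all(c in names for c in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(
            np.float64
        )
        ln = np.linalg.norm(normals, axis=1)
        ln[ln == 0] = 1.0
        normals = normals / ln[:, None]
    return ColoredPointCloud(pts, cols, normals)


def _write_ply(cloud: ColoredPointCloud, path: str) -> None:
    has_n = cloud.normals is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {HEADER_COMMENT}\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        if has_n:
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        fh.write("end_header\n")
        for i in range(len(cloud)):
            x, y, z = cloud.points[i]
            r, g, b = cloud.colors[i]
            line = f"{x:.6f} {y:.6f} {z:.6f} {r} {g} {b}"
            if has_n:
                nx, ny, nz = cloud.normals[i]
                line += f" {nx:.6f} {ny:.6f} {nz:.6f}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# PCD (v0.7, ascii, FIELDS x y z rgb with PCL packed-float rgb)

def _pack_rgb(colors: np.ndarray) -> np.ndarray:
    packed = (
        colors[:, 0].astype(np.uint32) << 16
        | colors[:, 1].astype(np.uint32) << 8
        | colors[:, 2].astype(np.uint32)
    )
    return packed.view(np.float32)


def _unpack_rgb(rgb_f: np.ndarray) -> np.ndarray:
    packed = np.ascontiguousarray(rgb_f, dtype=np.float32).view(np.uint32)
    return np.column_stack(
        [(packed >> 16) & 255, (packed >> 8) & 255, packed & 255]
    ).astype(np.uint8)


def _read_pcd(path: str) -> ColoredPointCloud:
    fields = None
    n = None
    data_mode = None
    with open(path, "r") as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            toks = line.split()
            if not toks or toks[0] == "#":
                continue
            key = toks[0].upper()
            if key == "FIELDS":
                fields = [t.lower() for t in toks[1:]]
            elif key == "POINTS":
                n = int(toks[1])
            elif key == "DATA":
                data_mode = toks[1]
                break
        if data_mode != "ascii":
            raise CloudParseError(f"line {lineno}: only DATA ascii PCD supported")
        if fields is None or n is None:
            raise CloudParseError("PCD header missing FIELDS or POINTS")
        for f in ("x", "y", "z"):
            if f not in fields:
                raise CloudParseError(f"PCD missing field '{f}'")
        if "rgb" not in fields:
            raise CloudParseError("PCD has no 'rgb' field — pipeline requires color")
        rows = []
        for i in range(n):
            line = fh.readline()
            lineno += 1
            if not line:
                raise CloudParseError(f"line {lineno}: truncated PCD data")
            toks = line.split()
            if len(toks) != len(fields):
                raise CloudParseError(
                    f"line {lineno}: expected {len(fields)} fields, got {len(toks)}"
                )
            rows.append([float(t) for t in toks])
    arr = np.asarray(rows, dtype=np.float64).reshape(n, len(fields))
    ix, iy, iz = (fields.index(a) for a in ("x", "y", "z"))
    pts = arr[:, [ix, iy, iz]]
    cols = _unpack_rgb(arr[:, fields.index("rgb")].astype(np.float32))
    return ColoredPointCloud(pts, cols)


def _write_pcd(cloud: ColoredPointCloud, path: str) -> None:
    rgb = _pack_rgb(cloud.colors)
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write(f"# .PCD v0.7 - Point Cloud Data file format\n# {HEADER_COMMENT}\n")
        fh.write("VERSION 0.7\nFIELDS x y z rgb\nSIZE 4 4 4 4\n")
        fh.write("TYPE F F F F\nCOUNT 1 1 1 1\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {n}\nDATA ascii\n")
        for p, c in zip(cloud.points, rgb):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c:.9e}\n")


# ---------------------------------------------------------------------------
# XYZRGB text

def _read_xyzrgb(path: str) -> ColoredPointCloud:
    pts, cols = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            if len(toks) != 6:
                raise CloudParseError(
                    f"line {lineno}: expected 6 columns (x y z r g b), got {len(toks)}"
                )
            pts.append([float(t) for t in toks[:3]])
            cols.append([float(t) for t in toks[3:]])
    if not pts:
        raise CloudParseError("empty XYZRGB file")
    cols = np.asarray(cols)
    if cols.max() <= 1.0 and not np.allclose(cols, np.round(cols)):
        cols = np.floor(cols * 255.0 + 0.5)
    return ColoredPointCloud(np.asarray(pts), np.clip(cols, 0, 255).astype(np.uint8))


def _write_xyzrgb(cloud: ColoredPointCloud, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {HEADER_COMMENT}\n")
        for p, c in zip(cloud.points, cloud.colors):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}\n")


_FORMATS = {"ply", "pcd", "xyzrgb"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format '{fmt}' (choose from {sorted(_FORMATS)})")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    if ext in ("txt", "xyz"):
        return "xyzrgb"
    raise ValueError(f"cannot infer cloud format from extension '.{ext}'")


def read_cloud(path: str, format: str | None = None) -> ColoredPointCloud:
    """Read a colored point cloud, preserving point order.

    Colors are normalized to integer 0-255 regardless of source encoding
    (0-1 floats are rescaled with round-half-up).
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    return _read_xyzrgb(path)


def write_cloud(cloud: ColoredPointCloud, path: str, format: str | None = None) -> None:
    """Write a cloud; re-readable with lossless colors and <=1e-4 coordinate error."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    else:
        _write_xyzrgb(cloud, path)


# ---------------------------------------------------------------------------
# Catalog

_KEY = ["experiment", "plot", "shoot_id"]
_IMMUTABLE = ["cultivar", "acquisition_date"]
_ROLES = ["raw_cloud", "denoised_cloud", "skeleton", "traits"]


@dataclass
class CatalogEntry:
    """One shoot in the 3-level experiment/plot/shoot catalog."""

    experiment: str
    plot: str
    shoot_id: str
    cultivar: str = ""
    growth_stage: str = ""
    acquisition_date: str = ""
    file_paths: dict = field(default_factory=dict)
    treatments: str = ""       # free text: fertilizer / water regime
    acquired_by: str = ""

    def to_row(self) -> dict:
        row = {
            "experiment": self.experiment,
            "plot": self.plot,
            "shoot_id": self.shoot_id,
            "cultivar": self.cultivar,
            "growth_stage": self.growth_stage,
            "acquisition_date": self.acquisition_date,
            "treatments": self.treatments,
            "acquired_by": self.acquired_by,
        }
        for role in _ROLES:
            row[f"path_{role}"] = self.file_paths.get(role, "")
        return row


def _load_catalog(path: str) -> pd.DataFrame:
    if os.path.exists(path):
        return pd.read_csv(path, dtype=str).fillna("")
    cols = CatalogEntry("", "", "").to_row().keys()
    return pd.DataFrame(columns=list(cols))


def catalog_upsert(path: str, entry: CatalogEntry) -> pd.DataFrame:
    """Insert or replace an entry keyed on (experiment, plot, shoot_id).

    Replacing an existing row with conflicting immutable fields (cultivar,
    acquisition date) raises :class:`CatalogConflictError`.  The catalog
    stays sorted by key.
    """
    df = _load_catalog(path)
    row = entry.to_row()
    mask = pd.Series(True, index=df.index)
    for k in _KEY:
        mask &= df[k] == row[k]
    if mask.any():
        old = df[mask].iloc[0]
        for f in _IMMUTABLE:
            if old[f] and row[f] and old[f] != row[f]:
                raise CatalogConflictError(
                    f"{f} conflict for key {tuple(row[k] for k in _KEY)}: "
                    f"'{old[f]}' vs '{row[f]}'"
                )
        df = df[~mask]
    df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    df = df.sort_values(_KEY).reset_index(drop=True)
    df.to_csv(path, index=False)
    return df


def catalog_rollup(path: str) -> dict:
    """Roll-up statistics: plot/shoot totals and per-growth-stage counts."""
    df = _load_catalog(path)
    return {
        "n_experiments": int(df["experiment"].nunique()),
        "n_plots": int(df[["experiment", "plot"]].drop_duplicates().shape[0]),
        "n_shoots": int(df.shape[0]),
        "per_stage": {
            str(k): int(v)
            for k, v in df.groupby("growth_stage").size().items()
            if str(k)
        },
    }
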