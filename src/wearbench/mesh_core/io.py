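"""Mesh and raster-grid file I/O.

PLY is the canonical format: an extra ``uchar region`` vertex property
(0=other, 1=occlusal, 2=buccal, 3=lingual) carries region labels losslessly.
STL and OBJ carry geometry only; labels travel in a sidecar CSV with columns
``vertex_index,region``. STL has no vertex identity, so vertices are welded
within 1e-9 mm on read.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .types import REGIONS, REGION_CODES, RasterGrid, SurfaceScan, ValidationError

__all__ = ["read_scan", "write_scan", "read_labels_csv", "write_labels_csv",
           "read_raster_csv", "write_raster_csv", "FormatError"]

_WELD_TOL_MM = 1e-9


class FormatError(ValueError):
    """Raised when a mesh file cannot be parsed as the named standard."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in {"ply", "stl", "obj"}:
        raise FormatError(f"unsupported mesh format: {fmt!r}")
    return fmt


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    raw = path.read_bytes()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise FormatError(f"{path} is not a PLY file")
    header = raw[: end + len(b"end_header\n")].decode("ascii", errors="replace")
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    elements: list[tuple[str, int, list]] = []
    for line in header.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property" and elements:
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1][2].append(("scalar", parts[1], parts[2]))
    if fmt not in {"ascii", "binary_little_endian"}:
        raise FormatError(f"unsupported PLY format {fmt!r}")

    verts = faces = None
    region_codes = None
    if fmt == "ascii":
        tokens = body.decode("ascii", errors="replace").split("\n")
        cursor = 0
        for name, count, props in elements:
            rows = tokens[cursor: cursor + count]
            cursor += count
            if name == "vertex":
                cols = [p[2] for p in props if p[0] == "scalar"]  # ("scalar", dtype, name)
                data = np.array([r.split() for r in rows], dtype=float)
                if data.shape != (count, len(cols)):
                    raise FormatError("PLY vertex rows malformed")
                ix = {c: i for i, c in enumerate(cols)}
                try:
                    verts = data[:, [ix["x"], ix["y"], ix["z"]]]
                except KeyError as e:
                    raise FormatError(f"PLY missing vertex coordinate {e}") from None
                if "region" in ix:
                    region_codes = data[:, ix["region"]].astype(int)
            elif name == "face":
                face_rows = []
                for r in rows:
                    nums = r.split()
                    n = int(nums[0])
                    if n != 3:
                        raise FormatError("only triangular PLY faces are supported")
                    face_rows.append([int(x) for x in nums[1:4]])
                faces = np.array(face_rows, dtype=np.int64).reshape(-1, 3)
    else:  # binary little endian
        offset = 0
        for name, count, props in elements:
            if all(p[0] == "scalar" for p in props):
                dt = np.dtype([(p[2], "<" + _PLY_DTYPES[p[1]]) for p in props])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                if name == "vertex":
                    verts = np.column_stack(
                        [arr["x"], arr["y"], arr["z"]]
                    ).astype(float)
                    if "region" in dt.names:
                        region_codes = arr["region"].astype(int)
            else:
                rows = []
                for _ in range(count):
                    cnt_dt = _PLY_DTYPES[props[0][1]]  # ("list", count_dtype, idx_dtype, name)
                    (n,) = np.frombuffer(body, dtype="<" + cnt_dt, count=1, offset=offset)
                    offset += np.dtype(cnt_dt).itemsize
                    idx_dt = _PLY_DTYPES[props[0][2]]
                    vals = np.frombuffer(body, dtype="<" + idx_dt, count=int(n), offset=offset)
                    offset += np.dtype(idx_dt).itemsize * int(n)
                    if int(n) != 3:
                        raise FormatError("only triangular PLY faces are supported")
                    rows.append(vals)
                if name == "face":
                    faces = np.array(rows, dtype=np.int64).reshape(-1, 3)
    if verts is None or faces is None:
        raise FormatError(f"{path} lacks vertex or face elements")
    return verts, faces, region_codes


def _write_ply(scan: SurfaceScan, path: Path) -> None:
    codes = np.array([REGION_CODES[r] for r in scan.region_labels], dtype=np.uint8)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment wearbench surface scan\n")
        fh.write(f"element vertex {scan.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar region\n")
        fh.write(f"element face {scan.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), c in zip(scan.vertices, codes):
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} {c}\n")
        for a, b, c in scan.faces:
            fh.write(f"3 {a} {b} {c}\n")


# --------------------------------------------------------------------------
# OBJ
# --------------------------------------------------------------------------

def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as e:
        raise FormatError(f"{path} is not a text OBJ file: {e}") from None
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise FormatError(f"malformed OBJ vertex line: {line!r}")
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) for tok in parts[1:]]
            if len(idx) != 3:
                raise FormatError("only triangular OBJ faces are supported")
            faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
    if not verts or not faces:
        raise FormatError(f"{path} contains no usable OBJ geometry")
    return np.array(verts, dtype=float), np.array(faces, dtype=np.int64)


def _write_obj(scan: SurfaceScan, path: Path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# wearbench surface scan\n")
        for x, y, z in scan.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in scan.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


# --------------------------------------------------------------------------
# STL
# --------------------------------------------------------------------------

def _read_stl(path: Path) -> np.ndarray:
    """Return the (m, 3, 3) triangle corner soup (no vertex identity in STL)."""
    raw = path.read_bytes()
    if raw[:5] == b"solid" and b"facet" in raw[:4096]:
        tris = []
        cur: list[list[float]] = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                cur.append([float(x) for x in parts[1:4]])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
        if not tris:
            raise FormatError(f"{path}: no facets found in ASCII STL")
        return np.array(tris, dtype=float)
    if len(raw) < 84:
        raise FormatError(f"{path} is too short to be a binary STL")
    (n,) = struct.unpack("<I", raw[80:84])
    expected = 84 + n * 50
    if n == 0 or len(raw) < expected:
        raise FormatError(f"{path}: binary STL empty or truncated")
    rec = np.frombuffer(raw, dtype=np.dtype("<12f4, <u2"), count=n, offset=84)
    data = rec["f0"].reshape(n, 4, 3)[:, 1:, :]  # drop the stored facet normal
    return data.astype(float)


def _weld(tri_soup: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate triangle-soup corners within the welding tolerance."""
    pts = tri_soup.reshape(-1, 3)
    key = np.round(pts / _WELD_TOL_MM).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = pts[first]
    faces = inverse.reshape(-1, 3)
    return verts, faces


def _write_stl(scan: SurfaceScan, path: Path) -> None:
    normals = scan.face_normals()
    a, b, c = scan.triangle_corners()
    with open(path, "w", encoding="ascii") as fh:
        fh.write("solid wearbench\n")
        for n, pa, pb, pc in zip(normals, a, b, c):
            fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            fh.write("    outer loop\n")
            for p in (pa, pb, pc):
                fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid wearbench\n")


# --------------------------------------------------------------------------
# Sidecar labels
# --------------------------------------------------------------------------

def read_labels_csv(path, n_vertices: int) -> np.ndarray:
    """Read a ``vertex_index,region`` table; unlisted vertices become "other"."""
    labels = np.full(n_vertices, "other", dtype="<U8")
    seen = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or (lineno == 0 and line.lower().startswith("vertex_index")):
                continue
            idx_s, region = [t.strip() for t in line.split(",")[:2]]
            idx = int(idx_s)
            if idx < 0 or idx >= n_vertices:
                raise ValidationError(
                    f"label row {lineno}: vertex index {idx} out of range (n={n_vertices})"
                )
            if region not in REGIONS:
                raise ValidationError(f"label row {lineno}: unknown region {region!r}")
            labels[idx] = region
            seen += 1
    if seen > n_vertices:
        raise ValidationError(f"label table has {seen} rows for {n_vertices} vertices")
    return labels


def write_labels_csv(scan: SurfaceScan, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("vertex_index,region\n")
        for i, r in enumerate(scan.region_labels):
            fh.write(f"{i},{r}\n")


# --------------------------------------------------------------------------
# Public mesh API
# --------------------------------------------------------------------------

def read_scan(path, format: str | None = None, labels_path=None) -> SurfaceScan:
    """Read a surface scan (PLY/STL/OBJ), with labels embedded or in a sidecar.

    PLY labels come from an embedded ``region`` vertex property; for STL/OBJ
    (or a PLY without that property) pass ``labels_path`` to a
    ``vertex_index,region`` CSV. Unlabeled vertices get region "other".
    For STL, duplicated corners are welded within 1e-9 mm *before* labeling,
    so sidecar indices refer to the welded vertex order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    region_codes = None
    if fmt == "ply":
        verts, faces, region_codes = _read_ply(path)
    elif fmt == "obj":
        verts, faces = _read_obj(path)
    else:
        verts, faces = _weld(_read_stl(path))
    if labels_path is not None:
        labels = read_labels_csv(labels_path, len(verts))
    elif region_codes is not None:
        if region_codes.min() < 0 or region_codes.max() >= len(REGIONS):
            raise FormatError("PLY region codes out of range 0..3")
        labels = np.array(REGIONS, dtype="<U8")[region_codes]
    else:
        labels = None
    return SurfaceScan(verts, faces, labels)


def write_scan(scan: SurfaceScan, path, format: str | None = None,
               labels_path=None) -> None:
    """Write a scan to PLY (labels embedded), or OBJ/STL (+ optional sidecar)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(scan, path)
    elif fmt == "obj":
        _write_obj(scan, path)
    else:
        _write_stl(scan, path)
    if labels_path is not None:
        write_labels_csv(scan, labels_path)


# --------------------------------------------------------------------------
# Raster grids
# --------------------------------------------------------------------------

def write_raster_csv(grid: RasterGrid, path) -> None:
    """Write the long-form ``x_um,y_um,z_mm`` representation (missing cells skipped)."""
    x, y = grid.node_xy_mm()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x_um,y_um,z_mm\n")
        for iy in range(grid.shape[0]):
            for ix in range(grid.shape[1]):
                z = grid.heights[iy, ix]
                if np.isfinite(z):
                    fh.write(f"{x[ix] * 1e3:.6f},{y[iy] * 1e3:.6f},{z:.9f}\n")


def read_raster_csv(path) -> RasterGrid:
    """Read a long-form ``x_um,y_um,z_mm`` grid; spacing inferred from coordinates."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.size == 0:
        raise ValidationError(f"{path}: empty raster table")
    xs = np.unique(np.round(data["x_um"], 6))
    ys = np.unique(np.round(data["y_um"], 6))
    if len(xs) < 2 or len(ys) < 2:
        raise ValidationError("raster grid needs at least 2 distinct x and y values")
    x_step = float(np.min(np.diff(xs)))
    y_step = float(np.min(np.diff(ys)))
    nx = int(round((xs[-1] - xs[0]) / x_step)) + 1
    ny = int(round((ys[-1] - ys[0]) / y_step)) + 1
    heights = np.full((ny, nx), np.nan)
    ix = np.round((data["x_um"] - xs[0]) / x_step).astype(int)
    iy = np.round((data["y_um"] - ys[0]) / y_step).astype(int)
    heights[iy, ix] = data["z_mm"]
    return RasterGrid(x_step, y_step, heights, origin_mm=(xs[0] * 1e-3, ys[0] * 1e-3))
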