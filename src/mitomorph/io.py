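"""File formats: star-dialect particle tables, STL meshes + attribute
sidecars, and per-tomogram context-record CSVs.

The star dialect supported here is the single-block ``data_``/``loop_`` table
used by subtomogram-averaging packages, with ``_rlnCoordinateX/Y/Z`` (pixels)
and ``_rlnAngleRot/Tilt/Psi`` (degrees) columns; coordinates are converted to
Angstrom at ingest using the caller-supplied pixel size.  Optics/CTF blocks
are ignored.  Meshes travel as STL (ASCII or binary) plus a CSV sidecar keyed
by triangle index that carries the named label sets; normals and areas are
always recomputed from the geometry, never trusted from the file.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .surfaces import TriangleSurface

logger = logging.getLogger(__name__)

PARTICLE_COLUMNS = {
    "tomogram_id": "_rlnTomoName",
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
}
TRUTH_COLUMN = "_mmTruthLabel"

CONTEXT_COLUMNS = [
    "particle_id", "center_to_omm", "angle_x", "angle_y", "angle_z",
    "nearest_triangle_id", "exit_to_omm", "orientation_class",
]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


# ---------------------------------------------------------------------------
# star-dialect particle tables


def _parse_star_block(text: str) -> pd.DataFrame:
    lines = [ln.strip() for ln in text.splitlines()]
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("data_"):
            continue
        if ln == "loop_":
            if cols:  # second block: the particle table is the first loop only
                break
            in_loop = True
            continue
        if in_loop and ln.startswith("_"):
            cols.append(ln.split()[0])
            continue
        if in_loop and cols:
            parts = ln.split()
            if parts[0].startswith("_"):
                break
            rows.append(parts)
    if not cols:
        raise SchemaError("no loop_ block with column declarations found")
    if rows and any(len(r) != len(cols) for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != len(cols))
        raise SchemaError(f"row {bad} has {len(rows[bad])} fields, expected {len(cols)}")
    return pd.DataFrame(rows, columns=cols)


def read_particles(path, pixel_size: float) -> pd.DataFrame:
    """Read a star-dialect particle table into an Angstrom-unit DataFrame.

    Returns columns ``tomogram_id, x, y, z, rot, tilt, psi`` (+ ``truth_label``
    when present); ``x/y/z`` are multiplied by ``pixel_size`` (A/px), angles
    pass through in degrees, row order is preserved.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    raw = _parse_star_block(Path(path).read_text())
    out = {}
    for name, star_name in PARTICLE_COLUMNS.items():
        if star_name not in raw.columns:
            if name == "tomogram_id":
                out[name] = ["tomo"] * len(raw)
                continue
            raise SchemaError(f"missing required column {star_name}")
        out[name] = raw[star_name]
    df = pd.DataFrame(out)
    for col in ("x", "y", "z", "rot", "tilt", "psi"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            bad = next(i for i, v in enumerate(df[col]) if not _is_number(v))
            raise SchemaError(f"non-numeric value in {col!r} at row {bad}") from exc
    if not np.all(np.isfinite(df[["x", "y", "z", "rot", "tilt", "psi"]].to_numpy())):
        raise SchemaError("non-finite coordinate or angle in particle table")
    df[["x", "y", "z"]] *= pixel_size
    if TRUTH_COLUMN in raw.columns:
        df["truth_label"] = raw[TRUTH_COLUMN].to_numpy()
    return df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_particles(table: pd.DataFrame, path, pixel_size: float = 1.0) -> None:
    """Write a particle table in the star dialect; coordinates are divided by
    ``pixel_size`` back into pixels so a read/write cycle is the identity."""
    cols = list(PARTICLE_COLUMNS.values())
    has_truth = "truth_label" in table.columns
    if has_truth:
        cols.append(TRUTH_COLUMN)
    lines = ["data_particles", "", "loop_"]
    lines += [f"{c} #{i + 1}" for i, c in enumerate(cols)]
    for _, row in table.iterrows():
        vals = [
            str(row["tomogram_id"]),
            *(f"{row[c] / pixel_size:.6f}" for c in ("x", "y", "z")),
            *(f"{row[c]:.6f}" for c in ("rot", "tilt", "psi")),
        ]
        if has_truth:
            vals.append(str(row["truth_label"]))
        lines.append(" ".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def particle_positions(table: pd.DataFrame) -> np.ndarray:
    return table[["x", "y", "z"]].to_numpy(dtype=float)


def particle_angles(table: pd.DataFrame) -> np.ndarray:
    return table[["rot", "tilt", "psi"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# STL meshes + attribute sidecar


def read_surface(stl_path, sidecar_path=None, surface_id: str = "OMM",
                 tomogram_id: str = "tomo") -> TriangleSurface:
    """Load an STL mesh (ASCII or binary) and optional label sidecar.

    Per-triangle centroid/normal/area are derived from the geometry;
    zero-area triangles are dropped with a logged count; closed surfaces get
    their normals oriented outward.
    """
    path = Path(stl_path)
    data = path.read_bytes()
    if data[:5] == b"solid" and b"facet" in data[:500]:
        verts, faces = _read_stl_ascii(data.decode("ascii", errors="replace"))
    else:
        verts, faces = _read_stl_binary(data)
    surf = TriangleSurface(verts, faces, surface_id=surface_id, tomogram_id=tomogram_id)
    dropped = surf.drop_degenerate()
    if dropped:
        logger.warning("dropped %d zero-area triangles from %s", dropped, path.name)
    surf.orient_outward()
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path)
        if "triangle_id" not in side.columns:
            raise SchemaError("sidecar must have a triangle_id column")
        for col in side.columns:
            if col == "triangle_id":
                continue
            mask = np.zeros(surf.n_triangles, dtype=bool)
            marked = side.loc[side[col].astype(bool), "triangle_id"].to_numpy(int)
            mask[marked] = True
            surf.set_label(col, mask)
    return surf


def _read_stl_ascii(text: str):
    verts = []
    for ln in text.splitlines():
        ln = ln.strip()
        if ln.startswith("vertex"):
            verts.append([float(t) for t in ln.split()[1:4]])
    v = np.asarray(verts, dtype=float)
    if len(v) == 0 or len(v) % 3:
        raise SchemaError("truncated ASCII STL: vertex count not a multiple of 3")
    return _dedupe_vertices(v)


def _read_stl_binary(data: bytes):
    if len(data) < 84:
        raise SchemaError("binary STL shorter than its header")
    (n_tri,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * n_tri
    if len(data) < expected:
        raise SchemaError(f"truncated binary STL: {len(data)} bytes, expected {expected}")
    rec = np.frombuffer(data, dtype=np.dtype(
        [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]), count=n_tri, offset=84)
    return _dedupe_vertices(rec["v"].reshape(-1, 3).astype(float))


def _dedupe_vertices(flat: np.ndarray):
    uniq, inverse = np.unique(flat.round(decimals=6), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return uniq, faces


def write_surface(surface: TriangleSurface, stl_path, sidecar_path=None,
                  binary: bool = True) -> None:
    tri = surface.vertices[surface.faces].astype(np.float32)
    if binary:
        buf = bytearray(b"\0" * 80)
        buf += struct.pack("<I", surface.n_triangles)
        rec = np.zeros(surface.n_triangles, dtype=np.dtype(
            [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
        rec["normal"] = surface.normals.astype(np.float32)
        rec["v"] = tri
        buf += rec.tobytes()
        Path(stl_path).write_bytes(bytes(buf))
    else:
        lines = [f"solid {surface.surface_id}"]
        for n, t in zip(surface.normals, tri):
            lines.append(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {surface.surface_id}")
        Path(stl_path).write_text("\n".join(lines) + "\n")
    if sidecar_path is not None:
        side = pd.DataFrame({"triangle_id": np.arange(surface.n_triangles)})
        for name, mask in surface.labels.items():
            side[name] = np.asarray(mask, dtype=int)
        side.to_csv(sidecar_path, index=False)


# ---------------------------------------------------------------------------
# context-record CSVs


def write_context_records(records: pd.DataFrame, path) -> None:
    """One CSV per tomogram, one row per ribosome, stable column order."""
    missing = [c for c in CONTEXT_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"context records missing columns {missing}")
    records[CONTEXT_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_context_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CONTEXT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"context CSV missing columns {missing}")
    return df
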