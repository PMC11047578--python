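"""Tube-mesh reconstruction of vessel lumens around centerlines.

Each centerline point gets a right-handed orthonormal frame (tangent
dir, normals nx, ny) built by rotation-minimizing parallel transport
(double-reflection), a ring of k vertices at radius r = sqrt(A/pi), and
consecutive rings are stitched into a triangle band by pairing each
vertex with the Euclidean-nearest vertex of the next ring (constant
circumferential offset; ties break to the lower index).  Per-vertex
scalars from mapped solver fields are baked per time frame, with vertex
positions recomputed from the instantaneous area, and the animated mesh
is exported as legacy-VTK / PLY files plus a PVD-style series index.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class FrameField:
    """Orthonormal (nx, ny, dir) triad at every centerline point."""

    dir: np.ndarray   # (n, 3) unit tangents
    nx: np.ndarray    # (n, 3)
    ny: np.ndarray    # (n, 3)


def transport_frames(segment) -> FrameField:
    """Rotation-minimizing frames along a centerline segment.

    Tangents are central differences (one-sided at the ends); the
    initial normal is an arbitrary perpendicular and is propagated by
    the double-reflection method, which keeps twist minimal (zero on
    planar curves).
    """
    pts = np.asarray(segment.positions if hasattr(segment, "positions")
                     else segment, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    d = np.diff(pts, axis=0)
    seglen = np.linalg.norm(d, axis=1)
    bad = np.nonzero(seglen < 1e-12)[0]
    if bad.size:
        raise ValueError(f"coincident consecutive points at index {bad[0]}")

    tang = np.empty_like(pts)
    tang[0] = d[0]
    tang[-1] = d[-1]
    if n > 2:
        tang[1:-1] = pts[2:] - pts[:-2]
    tang /= np.linalg.norm(tang, axis=1)[:, None]

    # initial perpendicular: axis least aligned with the first tangent
    t0 = tang[0]
    e = np.zeros(3)
    e[np.argmin(np.abs(t0))] = 1.0
    nx0 = e - (e @ t0) * t0
    nx0 /= np.linalg.norm(nx0)

    nx = np.empty_like(pts)
    nx[0] = nx0
    for i in range(n - 1):
        # double-reflection (Wang et al. 2008)
        v1 = pts[i + 1] - pts[i]
        c1 = v1 @ v1
        rL = nx[i] - (2.0 / c1) * (v1 @ nx[i]) * v1
        tL = tang[i] - (2.0 / c1) * (v1 @ tang[i]) * v1
        v2 = tang[i + 1] - tL
        c2 = v2 @ v2
        if c2 < 1e-30:
            nx[i + 1] = rL
        else:
            nx[i + 1] = rL - (2.0 / c2) * (v2 @ rL) * v2
        # re-orthonormalize against accumulated drift
        nx[i + 1] -= (nx[i + 1] @ tang[i + 1]) * tang[i + 1]
        nx[i + 1] /= np.linalg.norm(nx[i + 1])

    ny = np.cross(tang, nx)
    return FrameField(dir=tang, nx=nx, ny=ny)


def ring_vertices(point, frame_nx, frame_ny, area, k=16):
    """k ring vertices at radius sqrt(A/pi) around one centerline point,
    at angles 2*pi*l/k in the (nx, ny) plane."""
    if k < 3:
        raise ValueError("need k >= 3 ring vertices")
    if area <= 0:
        raise ValueError("area must be positive")
    r = np.sqrt(area / np.pi)
    ang = 2.0 * np.pi * np.arange(k) / k
    return (np.asarray(point, dtype=float)
            + r * (np.cos(ang)[:, None] * np.asarray(frame_nx)
                   + np.sin(ang)[:, None] * np.asarray(frame_ny)))


@dataclass
class TubeMesh:
    """Open triangle tube: k vertices per ring, 2k(N-1) faces."""

    vertices: np.ndarray          # (k*N, 3)
    faces: np.ndarray             # (F, 3) int
    k: int
    n_rings: int
    scalars: dict = field(default_factory=dict)     # name -> (k*N,)
    ring_index: np.ndarray = None  # (k*N, 2): (ring i, slot l)

    def edge_census(self):
        """Map edge -> number of incident faces."""
        census = {}
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                census[key] = census.get(key, 0) + 1
        return census


def _ring_offsets(rings, k):
    """Nearest-vertex pairing offset between consecutive rings.

    Ring i vertex l pairs with ring i+1 vertex (l + off) mod k; ``off``
    is the Euclidean-nearest match for l = 0, ties to the lower index.
    Non-monotonic per-vertex nearest matches (twist beyond half a slot)
    trigger a warning and the constant-offset fallback.
    """
    offsets = []
    for ra, rb in zip(rings[:-1], rings[1:]):
        d0 = np.linalg.norm(rb - ra[0], axis=1)
        off = int(np.argmin(d0))      # argmin takes the lowest index on ties
        # check that every vertex's nearest neighbour agrees with the offset
        for l in range(1, len(ra)):
            m = int(np.argmin(np.linalg.norm(rb - ra[l], axis=1)))
            if m != (l + off) % k:
                warnings.warn("non-monotonic nearest-vertex pairing; "
                              "falling back to constant offset")
                break
        offsets.append(off)
    return offsets


def triangulate_tube(rings, scalars=None) -> TubeMesh:
    """Stitch ordered vertex rings (equal k) into a watertight open tube.

    Between rings i and i+1 every vertex Q_{i,l} pairs with the nearest
    vertex Q_{i+1,m}; the band closes with wraparound at l = k-1 and is
    wound consistently outward.
    """
    rings = [np.asarray(r, dtype=float) for r in rings]
    if len(rings) < 2:
        raise ValueError("need at least 2 rings")
    k = len(rings[0])
    if any(len(r) != k for r in rings):
        raise ValueError("all rings must have the same vertex count k")

    offsets = _ring_offsets(rings, k)
    verts = np.concatenate(rings)
    ring_index = np.array([(i, l) for i in range(len(rings)) for l in range(k)])
    faces = []
    for i, off in enumerate(offsets):
        base_a = i * k
        base_b = (i + 1) * k
        for l in range(k):
            l1 = (l + 1) % k
            m = (l + off) % k
            m1 = (l1 + off) % k
            a0, a1 = base_a + l, base_a + l1
            b0, b1 = base_b + m, base_b + m1
            faces.append((a0, a1, b0))
            faces.append((a1, b1, b0))
    faces = np.asarray(faces, dtype=np.int64)

    # consistent outward winding: flip if face normals point inward
    centers = np.array([r.mean(axis=0) for r in rings])
    f0 = faces[0]
    v0, v1, v2 = verts[f0]
    normal = np.cross(v1 - v0, v2 - v0)
    outward = v0 - centers[0]
    if normal @ outward < 0:
        faces = faces[:, [0, 2, 1]]

    mesh = TubeMesh(vertices=verts, faces=faces, k=k, n_rings=len(rings),
                    ring_index=ring_index)
    if scalars:
        for name, per_ring in scalars.items():
            mesh.scalars[name] = np.repeat(np.asarray(per_ring, float), k)
    return mesh


def tube_mesh_from_segment(segment, areas=None, k=16,
                           scalars=None) -> TubeMesh:
    """Convenience: frames + rings + triangulation for one segment.

    ``areas`` (mm^2 per point) defaults to pi*r^2 from the centerline
    radii; ``scalars`` maps field name -> per-point values.
    """
    frames = transport_frames(segment)
    if areas is None:
        areas = np.pi * np.asarray(segment.radii) ** 2
    rings = [ring_vertices(p, frames.nx[i], frames.ny[i], areas[i], k)
             for i, p in enumerate(segment.positions)]
    return triangulate_tube(rings, scalars=scalars)


@dataclass
class DynamicMesh:
    """Time series of tube meshes with identical connectivity."""

    times: np.ndarray
    frames: list                  # list[TubeMesh]
    color_range: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) != len(self.frames):
            raise ValueError("one mesh per time sample required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")


def bake_scalar_series(segment, mapped, field_name, k=16, n_frames=None,
                       colormap="viridis", dynamic_radius=True) -> DynamicMesh:
    """Build an animated tube mesh for one segment from mapped fields.

    Ring radii are recomputed per frame from the instantaneous area
    A(s,t) (static reference geometry optional); every ring's vertices
    carry the scalar of their centerline point at that time.
    """
    if field_name not in mapped.fields:
        raise ValueError(f"field {field_name!r} missing from mapped data; "
                         f"have {sorted(mapped.fields)}")
    times = mapped.times
    idx = (np.linspace(0, len(times) - 1, n_frames).round().astype(int)
           if n_frames else np.arange(len(times)))
    frames_field = transport_frames(segment)
    A_mm2 = mapped.fields["A"] / 1e-6        # m^2 -> mm^2
    values = mapped.fields[field_name]
    meshes = []
    for t_i in idx:
        areas = (A_mm2[t_i] if dynamic_radius
                 else np.pi * np.asarray(segment.radii) ** 2)
        rings = [ring_vertices(p, frames_field.nx[i], frames_field.ny[i],
                               areas[i], k)
                 for i, p in enumerate(segment.positions)]
        mesh = triangulate_tube(rings, scalars={field_name: values[t_i]})
        meshes.append(mesh)
    vmin = float(values[idx].min())
    vmax = float(values[idx].max())
    return DynamicMesh(times=times[idx], frames=meshes,
                       color_range={"field": field_name, "min": vmin,
                                    "max": vmax, "colormap": colormap})


# ---------------------------------------------------------------------------
# exporters (plain-text, byte-deterministic)


def _fmt(x):
    return f"{x:.9g}"


def write_vtk_polydata(mesh: TubeMesh, path):
    """Legacy-VTK ASCII PolyData with per-vertex scalars."""
    lines = ["# vtk DataFile Version 3.0", "vasculate tube mesh", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(mesh.vertices)} double"]
    for v in mesh.vertices:
        lines.append(" ".join(_fmt(c) for c in v))
    nf = len(mesh.faces)
    lines.append(f"POLYGONS {nf} {4 * nf}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if mesh.scalars:
        lines.append(f"POINT_DATA {len(mesh.vertices)}")
        for name, vals in mesh.scalars.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_fmt(v) for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_ply(mesh: TubeMesh, path):
    """ASCII PLY with per-vertex scalar properties."""
    names = sorted(mesh.scalars)
    header = ["ply", "format ascii 1.0",
              f"element vertex {len(mesh.vertices)}",
              "property double x", "property double y", "property double z"]
    header += [f"property double {n}" for n in names]
    header += [f"element face {len(mesh.faces)}",
               "property list uchar int vertex_indices", "end_header"]
    lines = list(header)
    cols = [mesh.vertices[:, i] for i in range(3)]
    cols += [mesh.scalars[n] for n in names]
    for row in zip(*cols):
        lines.append(" ".join(_fmt(v) for v in row))
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_dynamic_mesh(dyn: DynamicMesh, out_dir, basename="frame",
                        fmt="vtk"):
    """Write one mesh file per frame plus a PVD-style XML index and a
    JSON color-range sidecar; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writer = write_vtk_polydata if fmt == "vtk" else write_ply
    entries = []
    for i, (t, mesh) in enumerate(zip(dyn.times, dyn.frames)):
        name = f"{basename}_{i:04d}.{fmt}"
        writer(mesh, out / name)
        entries.append((float(t), name))
    xml = ['<?xml version="1.0"?>',
           '<VTKFile type="Collection" version="0.1">', "  <Collection>"]
    for t, name in entries:
        xml.append(f'    <DataSet timestep="{_fmt(t)}" file="{name}"/>')
    xml += ["  </Collection>", "</VTKFile>"]
    (out / "series.pvd").write_text("\n".join(xml) + "\n")
    (out / "color_range.json").write_text(
        json.dumps(dyn.color_range, indent=2, sort_keys=True) + "\n")
    return out / "series.pvd"
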