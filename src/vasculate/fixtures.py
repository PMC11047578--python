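"""Synthetic inputs: voxel phantoms, noisy centerlines, toy networks.

Everything the test surface needs is generated here, reproducibly from
(parameters, seed): straight/Y/helix tube phantoms with analytic ground
truth, quantization-noise centerlines, a planar toy looped network
reminiscent of the circle of Willis (two inlet branches fed by one
root, joined through a pair of communicating segments, four RCR
terminals) with optional inlet-branch stenosis, and inflow waveforms.

The toy network's dimensions (root radius 4 mm, branch radii 2-3 mm,
communicating radii 1 mm, lengths 20-60 mm) and its wall/terminal
parameters are fixture constants chosen to be physiologically plausible
for a cerebral-scale network; they are not patient values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .centerline import CenterlineSegment, assemble_network
from .hemo1d import FluidProps, SimConfig, StenosisElement
from .skeleton import VoxelVolume
from .units import MMHG


@dataclass
class PhantomSpec:
    """Parameters of a voxel phantom; ``seed`` fixes all randomness."""

    kind: str = "tube"            # tube | Y | helix | loop-network
    length: float = 40.0          # voxels along the axis
    radius: float = 3.0           # tube radius, voxels
    spacing: float = 1.0          # mm per voxel
    helix_radius: float = 10.0    # mm
    helix_pitch: float = 5.0      # mm per turn
    turns: float = 2.0
    noise: float = 0.0            # centerline jitter amplitude, mm
    seed: int = 0


def _paint_capsule(vol, p0, p1, radius):
    """Set voxels within ``radius`` of segment p0-p1 (index space)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int),
                    np.array(vol.shape) - 1)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                        indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    d = p1 - p0
    L2 = max(d @ d, 1e-30)
    tt = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
    dist = np.linalg.norm(pts - (p0 + tt[:, None] * d), axis=1)
    sel = pts[dist <= radius].astype(int)
    vol[sel[:, 0], sel[:, 1], sel[:, 2]] = True


def make_tube_phantom(spec: PhantomSpec | None = None, **kw):
    """Binary tube phantom plus analytic ground truth.

    Returns (VoxelVolume, truth dict).  ``truth`` carries the axis
    points (world mm), the tube radius (mm) and, for helices, the
    analytic curvature kappa = R/(R^2 + c^2).
    """
    spec = spec or PhantomSpec(**kw)
    if kw and spec is not None and not isinstance(spec, PhantomSpec):
        raise TypeError("pass a PhantomSpec or keyword arguments, not both")
    if spec.radius < 2:
        raise ValueError("tube radius below 2 voxels: thinning unreliable")
    if spec.length <= 0:
        raise ValueError("zero-length phantom requested")

    margin = int(spec.radius) + 3
    if spec.kind == "tube":
        n_axis = int(spec.length) + 2 * margin
        side = 2 * margin + 1
        vol = np.zeros((side, side, n_axis), dtype=bool)
        c = margin
        _paint_capsule(vol, (c, c, margin), (c, c, margin + spec.length - 1),
                       spec.radius)
        axis = np.stack([np.full(int(spec.length), c),
                         np.full(int(spec.length), c),
                         margin + np.arange(int(spec.length))], axis=1)
        truth = {"axis_mm": axis * spec.spacing, "radius_mm":
                 spec.radius * spec.spacing, "curvature": 0.0}
    elif spec.kind == "Y":
        n = int(spec.length) + 2 * margin
        side = n
        vol = np.zeros((side, side, n), dtype=bool)
        c = side // 2
        zj = margin + int(spec.length * 0.45)
        top = n - margin
        dx = int(spec.length * 0.3)
        _paint_capsule(vol, (c, c, margin), (c, c, zj), spec.radius)
        _paint_capsule(vol, (c, c, zj), (c - dx, c, top), spec.radius)
        _paint_capsule(vol, (c, c, zj), (c + dx, c, top), spec.radius)
        truth = {"bifurcation_idx": (c, c, zj),
                 "radius_mm": spec.radius * spec.spacing}
    elif spec.kind == "helix":
        R = spec.helix_radius / spec.spacing       # voxels
        cpar = spec.helix_pitch / (2 * math.pi * spec.spacing)
        tmax = 2 * math.pi * spec.turns
        ts = np.linspace(0, tmax, int(20 * spec.turns * math.pi))
        pts = np.stack([R * np.cos(ts), R * np.sin(ts), cpar * ts], axis=1)
        lo = pts.min(axis=0) - spec.radius - 3
        pts -= lo
        shape = tuple((pts.max(axis=0) + spec.radius + 4).astype(int))
        vol = np.zeros(shape, dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            _paint_capsule(vol, a, b, spec.radius)
        c_mm = spec.helix_pitch / (2 * math.pi)
        truth = {"axis_mm": pts * spec.spacing,
                 "radius_mm": spec.radius * spec.spacing,
                 "curvature": spec.helix_radius / (spec.helix_radius ** 2 + c_mm ** 2)}
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    return VoxelVolume(vol, spacing=(spec.spacing,) * 3), truth


def helix_points(n=120, radius=10.0, pitch=5.0, turns=2.0, tube_radius=1.5):
    """Exact helix samples (n, 4: x, y, z, r) with analytic curvature."""
    c = pitch / (2 * math.pi)
    ts = np.linspace(0, 2 * math.pi * turns, n)
    pts = np.stack([radius * np.cos(ts), radius * np.sin(ts), c * ts,
                    np.full(n, tube_radius)], axis=1)
    kappa = radius / (radius ** 2 + c ** 2)
    return pts, kappa


def make_noisy_centerline(points, amplitude=0.5, seed=0, quantize=None):
    """Jitter (and optionally round) exact centerline samples.

    ``points`` is (n, 4) x,y,z,r; uniform noise in [-amplitude,
    amplitude] is added per coordinate; ``quantize`` rounds positions to
    that grid pitch (mm), emulating voxel quantization.  Seed-reproducible.
    """
    if amplitude < 0:
        raise ValueError("noise amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    pts = np.asarray(points, dtype=float).copy()
    if amplitude > 0:
        pts[:, :3] += rng.uniform(-amplitude, amplitude, size=(len(pts), 3))
    if quantize:
        pts[:, :3] = np.round(pts[:, :3] / quantize) * quantize
    return pts


def default_inflow_waveform(T=1.0, stroke_volume=12.0, n=200):
    """Half-sine systolic inflow: Q > 0 over [0, 0.35 T], zero diastole.

    Returns (t, q) with t in s, q in ml/s, sampled at n+1 points and
    scaled so the trapezoidal integral equals ``stroke_volume`` (ml)
    exactly.
    """
    if T <= 0:
        raise ValueError("period must be positive")
    if stroke_volume <= 0:
        raise ValueError("stroke volume must be positive")
    t = np.linspace(0.0, T, n + 1)
    q = np.where(t <= 0.35 * T, np.sin(np.pi * t / (0.35 * T)), 0.0)
    q = np.clip(q, 0.0, None)
    q *= stroke_volume / np.trapezoid(q, t)
    return t, q


def area_severity_from_nascet(nascet: float) -> float:
    """Map a NASCET (diameter) severity to area severity 1-(1-n)^2."""
    if not (0 <= nascet < 1):
        raise ValueError("NASCET severity must be in [0, 1)")
    return 1.0 - (1.0 - nascet) ** 2


def _straight_segment(p0, p1, radius, dl=2.0, arterial_index=0):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    L = float(np.linalg.norm(p1 - p0))
    s = np.arange(0.0, L, dl)
    if L - s[-1] > 1e-9:
        s = np.append(s, L)
    else:
        s[-1] = L
    d = (p1 - p0) / L
    return CenterlineSegment(positions=p0 + s[:, None] * d,
                             radii=np.full(len(s), float(radius)),
                             arc_positions=s, grid_width=dl,
                             arterial_index=arterial_index)


# fixture constants of the toy looped network (mm, SI for 0D elements).
# Communicating radius 1.5 mm is ACA/ACoA scale; the distal beds get
# twice the MCA terminal resistance (smaller territories), which leaves
# the midline junction free to float between the two sides so a
# unilateral inlet stenosis drives genuine retrograde collateral flow.
COW_RADII = {"root": 4.0, "ica": 3.0, "mca": 2.0, "comm": 1.5, "dist": 2.0}
COW_TERMINAL_MCA = {"kind": "rcr", "R1": 4.0e8, "R2": 2.46e9, "C": 3.5e-10,
                    "P_out": 5.0 * MMHG}
COW_TERMINAL_DIST = {"kind": "rcr", "R1": 8.0e8, "R2": 4.92e9, "C": 1.75e-10,
                     "P_out": 5.0 * MMHG}
COW_WALL = {"E": 400e3, "h0_ratio": 0.15, "sigma": 0.5}
COW_STROKE_VOLUME = 12.0     # ml over a 1 s cycle
SEVERITY_PRESETS = {"CS": area_severity_from_nascet(0.70), "VRCA": 0.90}


def make_toy_cow(severity: float = 0.0, symmetric: bool = True,
                 preset: str | None = None):
    """Toy looped (circle-of-Willis-like) network plus solver config.

    Two inlet branches fed by one root are joined by left/right
    communicating segments meeting at a midline junction that feeds two
    distal terminals; stenosis of the given area ``severity`` sits
    mid-way along the left inlet branch.  Severity presets: ``CS``
    (70% NASCET diameter severity) and ``VRCA`` (90% area severity).

    Returns (network, SimConfig, names) where names maps descriptive
    segment names to ids.
    """
    if preset is not None:
        severity = SEVERITY_PRESETS[preset]
    if not (0.0 <= severity < 1.0):
        raise ValueError("severity must be in [0, 1)")

    r = COW_RADII
    r_ica_right = r["ica"] if symmetric else 0.9 * r["ica"]
    P = {
        "IN": (0.0, -20.0, 0.0), "J0": (0.0, 0.0, 0.0),
        "JL": (-24.0, 32.0, 0.0), "JR": (24.0, 32.0, 0.0),
        "JM": (0.0, 50.0, 0.0),
        "T1": (-48.0, 64.0, 0.0), "T2": (48.0, 64.0, 0.0),
        "T3": (-20.0, 84.641016, 0.0), "T4": (20.0, 84.641016, 0.0),
    }
    segs = {
        0: _straight_segment(P["IN"], P["J0"], r["root"], arterial_index=0),
        1: _straight_segment(P["J0"], P["JL"], r["ica"], arterial_index=1),
        2: _straight_segment(P["J0"], P["JR"], r_ica_right, arterial_index=2),
        3: _straight_segment(P["JL"], P["T1"], r["mca"], arterial_index=3),
        4: _straight_segment(P["JR"], P["T2"], r["mca"], arterial_index=4),
        5: _straight_segment(P["JL"], P["JM"], r["comm"], arterial_index=5),
        6: _straight_segment(P["JR"], P["JM"], r["comm"], arterial_index=6),
        7: _straight_segment(P["JM"], P["T3"], r["dist"], arterial_index=7),
        8: _straight_segment(P["JM"], P["T4"], r["dist"], arterial_index=8),
    }
    junctions = {
        0: [(0, "end"), (1, "start"), (2, "start")],
        1: [(1, "end"), (3, "start"), (5, "start")],
        2: [(2, "end"), (4, "start"), (6, "start")],
        3: [(5, "end"), (6, "end"), (7, "start"), (8, "start")],
    }
    terminals = {
        1: {"segment": 3, "end": "end", "model": dict(COW_TERMINAL_MCA)},
        2: {"segment": 4, "end": "end", "model": dict(COW_TERMINAL_MCA)},
        3: {"segment": 7, "end": "end", "model": dict(COW_TERMINAL_DIST)},
        4: {"segment": 8, "end": "end", "model": dict(COW_TERMINAL_DIST)},
    }
    stenoses = []
    if severity > 0:
        stenoses.append(StenosisElement(
            segment=1, position=20.0, r0=r["ica"],
            As_over_A0=1.0 - severity, Ls=10.0))
    net = assemble_network(segs, junctions, inlet=(0, "start"),
                           terminals=terminals, stenoses=stenoses)

    t, q = default_inflow_waveform(T=1.0, stroke_volume=COW_STROKE_VOLUME)
    cfg = SimConfig(fluid=FluidProps(), E=COW_WALL["E"], h0_ratio=COW_WALL["h0_ratio"],
                    sigma=COW_WALL["sigma"], inflow_t=t, inflow_q=q, period=1.0,
                    ds=1.0, cfl=0.8)
    names = {"root": 0, "left_inlet": 1, "right_inlet": 2, "left_mca": 3,
             "right_mca": 4, "left_comm": 5, "right_comm": 6,
             "left_dist": 7, "right_dist": 8}
    return net, cfg, names


def make_tube_network(length_mm=100.0, radius_mm=3.0, terminal=None,
                      split_at=None, E=400e3, h0_mm=0.3, sigma=0.5,
                      inflow=None, period=1.0):
    """Single straight tube network (optionally split by a degree-2
    junction at ``split_at`` mm) with one terminal; returns
    (network, SimConfig)."""
    terminal = terminal or {"kind": "rcr", "R1": 4.0e8, "R2": 3.18e9,
                            "C": 3.0e-10, "P_out": 5.0 * MMHG}
    if split_at is None:
        segs = {0: _straight_segment((0, 0, 0), (0, 0, length_mm), radius_mm)}
        junctions = {}
        term = {1: {"segment": 0, "end": "end", "model": terminal}}
    else:
        segs = {0: _straight_segment((0, 0, 0), (0, 0, split_at), radius_mm,
                                     arterial_index=0),
                1: _straight_segment((0, 0, split_at), (0, 0, length_mm),
                                     radius_mm, arterial_index=1)}
        junctions = {0: [(0, "end"), (1, "start")]}
        term = {1: {"segment": 1, "end": "end", "model": terminal}}
    net = assemble_network(segs, junctions, inlet=(0, "start"), terminals=term)
    if inflow is None:
        t, q = default_inflow_waveform(T=period, stroke_volume=6.0)
    else:
        t, q = inflow
    cfg = SimConfig(E=E, h0=h0_mm, sigma=sigma, inflow_t=t, inflow_q=q,
                    period=period)
    return net, cfg
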