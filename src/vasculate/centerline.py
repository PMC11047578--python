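"""Centerline smoothing, resampling, and network assembly.

Voxel skeleton segments carry quantization noise that corrupts local
radius and curvature estimates.  Each labeled segment is therefore fit
with penalized degree-5 B-splines (one per coordinate and one for the
radius) under combined 3rd- and 4th-derivative roughness penalties,
with the penalty weights selected by the Akaike information criterion.
The smooth curve is then resampled at a uniform arc-length grid width
(default 2 mm) and the resampled segments are assembled into a
validated :class:`VascularNetwork` ready for the 1D solver.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

DEFAULT_GRID_WIDTH_MM = 2.0
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 2, 13))


# ---------------------------------------------------------------------------
# smooth curves


@dataclass
class SmoothCurve:
    """Penalized-spline space curve x(u), y(u), z(u) with radius r(u).

    ``u`` is the chord-length fit parameter on [0, U]; arc length is
    obtained by quadrature of the parametric speed.
    """

    splines: list                 # [BSpline x, y, z, r]
    domain: tuple                 # (0, U)
    lambda3: float
    lambda4: float
    aic: float

    def position(self, u):
        u = np.asarray(u, dtype=float)
        return np.stack([self.splines[i](u) for i in range(3)], axis=-1)

    def radius(self, u):
        return self.splines[3](np.asarray(u, dtype=float))

    def derivative(self, u, nu=1):
        u = np.asarray(u, dtype=float)
        return np.stack([self.splines[i](u, nu=nu) for i in range(3)], axis=-1)

    def speed(self, u):
        return np.linalg.norm(self.derivative(u, 1), axis=-1)

    def curvature(self, u):
        d1 = self.derivative(u, 1)
        d2 = self.derivative(u, 2)
        cross = np.cross(d1, d2)
        return np.linalg.norm(cross, axis=-1) / np.linalg.norm(d1, axis=-1) ** 3

    def arc_length(self, u0=None, u1=None, epsrel=1e-6):
        a = self.domain[0] if u0 is None else u0
        b = self.domain[1] if u1 is None else u1
        val, _ = quad(lambda t: float(self.speed(t)), a, b,
                      epsabs=1e-12, epsrel=epsrel, limit=200)
        return val


def _basis_and_penalties(u, n_interior_every=3):
    """Clamped degree-5 B-spline design matrix plus 3rd/4th-derivative
    Gram (penalty) matrices on the chord parameter grid ``u``."""
    n = len(u)
    k = 5
    interior = u[3:n - 3:n_interior_every] if n > 6 else np.array([])
    t = np.concatenate([[u[0]] * (k + 1), interior, [u[-1]] * (k + 1)])
    nb = len(t) - k - 1
    B = BSpline.design_matrix(u, t, k).toarray()

    # Gauss-Legendre per knot span, exact for the polynomial integrands
    gx, gw = np.polynomial.legendre.leggauss(5)
    spans = np.unique(t)
    ident = np.eye(nb)
    basis = BSpline(t, ident, k)
    P = {}
    for d in (3, 4):
        G = np.zeros((nb, nb))
        for a, b in zip(spans[:-1], spans[1:]):
            if b <= a:
                continue
            xs = 0.5 * (b - a) * gx + 0.5 * (a + b)
            ws = 0.5 * (b - a) * gw
            D = basis(xs, nu=d)          # (npts, nb)
            G += (D * ws[:, None]).T @ D
        P[d] = G
    return B, P[3], P[4], t, k


def fit_spline_sfm(nodes, lambda_grid=DEFAULT_LAMBDA_GRID, full_grid=False):
    """Fit a smoothed space curve to ordered (x, y, z, r) skeleton nodes.

    Each channel is a degree-5 penalized least-squares B-spline with
    roughness penalty ``lam3 * int(f''')^2 + lam4 * int(f'''')^2``; the
    penalty weights are selected from ``lambda_grid`` (diagonal
    lam3 == lam4 search by default, full 2D grid optionally) by
    minimizing AIC = n*ln(RSS/n) + 2*edf summed over the four channels,
    with edf the trace of the smoother matrix.
    """
    data = _nodes_to_array(nodes)
    n = len(data)
    if n < 7:
        raise ValueError(f"need at least 7 nodes for a degree-5 fit, got {n}")
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0 or (lambda_grid <= 0).any():
        raise ValueError("lambda_grid must be positive and nonempty")

    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(data[:, :3], axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("nodes are coincident: zero chord length")
    u = chord

    B, P3, P4, t, k = _basis_and_penalties(u)
    BtB = B.T @ B
    Bty = B.T @ data          # (nb, 4)

    pairs = ([(l, l) for l in lambda_grid] if not full_grid
             else [(l3, l4) for l3 in lambda_grid for l4 in lambda_grid])

    best = None
    for lam3, lam4 in pairs:
        M = BtB + lam3 * P3 + lam4 * P4
        try:
            Minv_BtB = np.linalg.solve(M, BtB)
            coef = np.linalg.solve(M, Bty)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular penalized fit at lambda=({lam3}, {lam4})")
        edf = float(np.trace(Minv_BtB))
        resid = data - B @ coef
        rss = np.sum(resid ** 2, axis=0)
        aic = float(np.sum(n * np.log(np.maximum(rss, 1e-30) / n)) + 2 * 4 * edf)
        if best is None or aic < best[0]:
            best = (aic, lam3, lam4, coef)

    aic, lam3, lam4, coef = best
    splines = [BSpline(t, coef[:, c].copy(), k) for c in range(4)]
    return SmoothCurve(splines=splines, domain=(float(u[0]), float(u[-1])),
                       lambda3=float(lam3), lambda4=float(lam4), aic=aic)


def _nodes_to_array(nodes):
    if isinstance(nodes, np.ndarray):
        arr = np.asarray(nodes, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("node array must be (n, 4): x, y, z, r")
        return arr
    rows = []
    for nd in nodes:
        if hasattr(nd, "position"):
            rows.append([*np.asarray(nd.position, float), float(nd.radius)])
        else:
            rows.append([float(v) for v in nd])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# resampled centerline segments


@dataclass
class CenterlinePoint:
    position: np.ndarray     # (3,) mm
    radius: float            # mm


@dataclass
class CenterlineSegment:
    """Smoothed centerline resampled on a uniform arc-length grid."""

    positions: np.ndarray            # (n, 3) mm
    radii: np.ndarray                # (n,) mm
    arc_positions: np.ndarray        # (n,) mm along the curve, 0 .. L
    grid_width: float                # requested grid width (mm)
    arterial_index: int = 0
    endpoints: dict = field(default_factory=dict)   # 'start'/'end' -> attachment id

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        if len(self.positions) < 2:
            raise ValueError("centerline segment needs at least 2 points")
        if (self.radii <= 0).any():
            raise ValueError("centerline radii must be positive")

    @property
    def points(self):
        return [CenterlinePoint(p, r) for p, r in zip(self.positions, self.radii)]

    @property
    def length(self) -> float:
        return float(self.arc_positions[-1])

    def end_position(self, end: str) -> np.ndarray:
        return self.positions[0] if end == "start" else self.positions[-1]


def resample_curve(curve: SmoothCurve, dl: float = DEFAULT_GRID_WIDTH_MM,
                   arterial_index: int = 0) -> CenterlineSegment:
    """Resample a smooth curve at arc lengths 0, dl, 2*dl, ..., L.

    The final point (arc length L) is always included.  The arc-length
    map s(u) is computed by adaptive quadrature of the parametric speed
    (relative tolerance 1e-6) and inverted on a dense monotone table.
    """
    if dl <= 0:
        raise ValueError("grid width dl must be positive")
    u0, u1 = curve.domain
    L = curve.arc_length()
    if L <= 0:
        raise ValueError("curve has zero length")
    if dl >= L:
        warnings.warn(f"grid width {dl} mm >= curve length {L:.3g} mm; "
                      "returning a 2-point segment")
        s_targets = np.array([0.0, L])
    else:
        s_targets = np.arange(0.0, L, dl)
        if L - s_targets[-1] > 1e-9 * max(L, 1.0):
            s_targets = np.append(s_targets, L)
        else:
            s_targets[-1] = L

    # dense cumulative arc length (composite Simpson), scaled to the
    # adaptive-quadrature total so endpoints are exact
    m = 4097
    ug = np.linspace(u0, u1, m)
    sp = curve.speed(ug)
    from scipy.integrate import cumulative_simpson
    S = np.concatenate([[0.0], cumulative_simpson(sp, x=ug)])
    S *= L / S[-1]
    u_of_s = np.interp(s_targets, S, ug)
    u_of_s[0], u_of_s[-1] = u0, u1       # endpoints exact

    pos = curve.position(u_of_s)
    rad = curve.radius(u_of_s)
    return CenterlineSegment(positions=pos, radii=rad, arc_positions=s_targets,
                             grid_width=float(dl), arterial_index=arterial_index)


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class VascularNetwork:
    """Centerline segments + junctions + boundary attachments.

    ``junctions`` maps junction id -> list of (segment id, 'start'|'end');
    ``terminals`` maps terminal id -> dict with keys ``segment``, ``end``
    and ``model`` (the attached 0D element parameters); ``stenoses`` is a
    list of stenosis descriptors bound to a segment arc position.
    """

    segments: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)
    inlet: tuple = None                      # (segment id, end)
    terminals: dict = field(default_factory=dict)
    stenoses: list = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        attach = self._attachment_of_ends()
        for sid in self.segments:
            a = attach[(sid, "start")]
            b = attach[(sid, "end")]
            g.add_edge(a, b, segment=sid)
        return g

    def _attachment_of_ends(self):
        attach = {}
        for jid, ends in self.junctions.items():
            for sid, end in ends:
                attach[(sid, end)] = f"junction:{jid}"
        if self.inlet is not None:
            attach[tuple(self.inlet)] = "inlet"
        for tid, spec in self.terminals.items():
            attach[(spec["segment"], spec["end"])] = f"terminal:{tid}"
        return attach

    def cycle_count(self) -> int:
        """Dimension of the cycle space of the network multigraph (E - V + C)."""
        import networkx as nx

        mg = self.to_networkx()
        c = nx.number_connected_components(mg)
        return mg.number_of_edges() - mg.number_of_nodes() + c

    def to_dict(self) -> dict:
        return {
            "segments": {
                str(sid): {
                    "positions": seg.positions.tolist(),
                    "radii": seg.radii.tolist(),
                    "arc_positions": seg.arc_positions.tolist(),
                    "grid_width": seg.grid_width,
                    "arterial_index": seg.arterial_index,
                    "endpoints": seg.endpoints,
                }
                for sid, seg in self.segments.items()
            },
            "junctions": {str(j): [[sid, end] for sid, end in ends]
                          for j, ends in self.junctions.items()},
            "inlet": list(self.inlet) if self.inlet else None,
            "terminals": {str(t): spec for t, spec in self.terminals.items()},
            "stenoses": [st if isinstance(st, dict) else dataclasses.asdict(st)
                         for st in self.stenoses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularNetwork":
        segments = {}
        for sid, s in d["segments"].items():
            seg = CenterlineSegment(
                positions=np.asarray(s["positions"]),
                radii=np.asarray(s["radii"]),
                arc_positions=np.asarray(s["arc_positions"]),
                grid_width=s["grid_width"],
                arterial_index=s["arterial_index"],
                endpoints=dict(s.get("endpoints", {})),
            )
            segments[int(sid)] = seg
        junctions = {int(j): [(int(sid), end) for sid, end in ends]
                     for j, ends in d["junctions"].items()}
        inlet = tuple([int(d["inlet"][0]), d["inlet"][1]]) if d.get("inlet") else None
        terminals = {int(t): dict(spec) for t, spec in d.get("terminals", {}).items()}
        return cls(segments=segments, junctions=junctions, inlet=inlet,
                   terminals=terminals, stenoses=list(d.get("stenoses", [])))


def assemble_network(segments, junctions, inlet, terminals, stenoses=(),
                     snap_tol_factor=1.5) -> VascularNetwork:
    """Validate and assemble segments into a :class:`VascularNetwork`.

    Junction endpoints are snapped to their common centroid when every
    incident endpoint lies within ``snap_tol_factor * grid_width`` of
    it; a larger spread is an error.  Every segment end must be attached
    to exactly one junction, the inlet, or a terminal, and the network
    graph must be connected.
    """
    segments = dict(segments)
    junctions = {j: [(sid, end) for sid, end in ends] for j, ends in junctions.items()}
    terminals = dict(terminals)

    attachments = {}

    def _attach(key, what):
        sid, end = key
        if sid not in segments:
            raise ValueError(f"{what} references unknown segment {sid}")
        if end not in ("start", "end"):
            raise ValueError(f"{what}: end must be 'start' or 'end', got {end!r}")
        if key in attachments:
            raise ValueError(f"segment end {key} attached to both "
                             f"{attachments[key]} and {what}")
        attachments[key] = what

    if inlet is None:
        raise ValueError("network needs exactly one inlet")
    _attach(tuple(inlet), "inlet")
    for jid, ends in junctions.items():
        if len(ends) < 2:
            raise ValueError(f"junction {jid} has fewer than 2 incident ends")
        for key in ends:
            _attach(tuple(key), f"junction {jid}")
    for tid, spec in terminals.items():
        _attach((spec["segment"], spec["end"]), f"terminal {tid}")

    dangling = [
        (sid, end) for sid in segments for end in ("start", "end")
        if (sid, end) not in attachments
    ]
    if dangling:
        raise ValueError(f"dangling segment ends: {dangling}")

    # snap junction endpoints to their common centroid
    for jid, ends in junctions.items():
        pts = np.array([segments[sid].end_position(end) for sid, end in ends])
        centroid = pts.mean(axis=0)
        dmax = np.linalg.norm(pts - centroid, axis=1).max()
        tol = snap_tol_factor * max(segments[sid].grid_width for sid, _ in ends)
        if dmax > tol:
            raise ValueError(
                f"junction {jid}: endpoint spread {dmax:.3g} mm exceeds "
                f"snap tolerance {tol:.3g} mm")
        for sid, end in ends:
            seg = segments[sid]
            if end == "start":
                seg.positions[0] = centroid
            else:
                seg.positions[-1] = centroid

    for sid, seg in segments.items():
        seg.endpoints = {}
    for key, what in attachments.items():
        sid, end = key
        segments[sid].endpoints[end] = what

    for st in stenoses:
        st_seg = st["segment"] if isinstance(st, dict) else st.segment
        if st_seg not in segments:
            raise ValueError(f"stenosis references unknown segment {st_seg}")

    net = VascularNetwork(segments=segments, junctions=junctions,
                          inlet=tuple(inlet), terminals=terminals,
                          stenoses=list(stenoses))
    import networkx as nx

    if not nx.is_connected(nx.Graph(net.to_networkx())):
        raise ValueError("network graph is disconnected")
    return net
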