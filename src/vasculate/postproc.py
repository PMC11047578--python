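"""Velocity, wall shear stress, and 1D-to-3D field mapping.

WSS is a post-processing quantity: assuming a cylindrical cross section
and a parabolic (Hagen-Poiseuille) velocity profile, the cross-section
mean velocity V = Q/A gives the profile U(r) = 2 V (1 - r^2/R^2) and the
wall shear stress tau_w = 4 mu V / R.  TAWSS is the cycle average of
|tau_w|.  Note the 1D momentum friction coefficient K_R defaults to the
flatter 22*pi*nu profile while this module assumes Poiseuille; the two
assumptions are exposed independently and deliberately not reconciled.

Solver fields on the ds grid are mapped to centerline points on the dl
grid by linear interpolation in arc length, so results ride on the 3D
geometry with the shared arterial index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import MM


def mean_velocity(Q, A):
    """Cross-section mean velocity V = Q/A (unit-consistent)."""
    A = np.asarray(A, dtype=float)
    if (A <= 0).any():
        raise ValueError("area must be positive")
    out = np.asarray(Q, dtype=float) / A
    return out if out.ndim else float(out)


def velocity_profile(V, R, r):
    """Poiseuille profile U(r) = 2 V (1 - r^2/R^2), 0 <= r <= R."""
    V = np.asarray(V, dtype=float)
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    if (r > R).any() or (r < 0).any():
        raise ValueError("radial offset must satisfy 0 <= r <= R")
    out = 2.0 * V * (1.0 - r ** 2 / R ** 2)
    return out if out.ndim else float(out)


def wss(V, R, mu):
    """Wall shear stress tau_w = 4 mu V / R (sign follows V)."""
    R = np.asarray(R, dtype=float)
    if (R <= 0).any():
        raise ValueError("radius must be positive")
    out = 4.0 * mu * np.asarray(V, dtype=float) / R
    return out if out.ndim else float(out)


def tawss(tau_series, times, period, signed=False):
    """Time-averaged WSS over one cycle, (1/T) int |tau_w| dt (trapezoid).

    The series must span the full period; the first sample is reused at
    t = T when the series stops short of it (periodic closure).  With
    ``signed=True`` the plain mean is returned instead of the mean
    magnitude.
    """
    tau = np.asarray(tau_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(tau):
        raise ValueError("series and times must have equal length")
    span = times[-1] - times[0]
    if span <= 0 or span > period * (1 + 1e-9):
        raise ValueError("series must span (up to) exactly one period")
    if span < period * (1 - 1e-9):
        # periodic closure
        times = np.append(times, times[0] + period)
        tau = np.append(tau, tau[:1], axis=0)
    vals = tau if signed else np.abs(tau)
    return np.trapezoid(vals, times, axis=0) / period


@dataclass
class WSSField:
    """Per-node velocity/WSS and per-segment TAWSS for one segment."""

    s: np.ndarray            # node arc positions, m
    times: np.ndarray        # s
    V: np.ndarray            # (n_t, n_s) m/s
    R: np.ndarray            # (n_t, n_s) m, instantaneous radius
    tau_w: np.ndarray        # (n_t, n_s) Pa
    tawss: np.ndarray        # (n_s,) Pa
    tawss_mean: float        # segment-mean TAWSS, Pa


def wss_field(solution, sid, mu, use_reference_radius=False,
              r0=None) -> WSSField:
    """Derive V, tau_w and TAWSS for one solved segment.

    The WSS radius is taken from the instantaneous area, R = sqrt(A/pi),
    unless ``use_reference_radius`` (then ``r0`` in mm, scalar or
    per-node, is used).
    """
    seg = solution.segments[sid]
    A, Q = seg["A"], seg["Q"]
    V = Q / A
    if use_reference_radius:
        if r0 is None:
            raise ValueError("use_reference_radius requires r0")
        R = np.broadcast_to(np.asarray(r0, dtype=float) * MM, A.shape)
    else:
        R = np.sqrt(A / np.pi)
    tau = 4.0 * mu * V / R
    ta = tawss(tau, solution.times, solution.period)
    return WSSField(s=seg["s"], times=solution.times, V=V, R=R, tau_w=tau,
                    tawss=ta, tawss_mean=float(np.mean(ta)))


@dataclass
class MappedField:
    """Solver fields carried onto the 3D centerline points of a segment."""

    positions: np.ndarray     # (n_p, 3) mm
    arc_positions: np.ndarray  # (n_p,) mm
    times: np.ndarray          # s
    fields: dict               # name -> (n_t, n_p) SI values
    arterial_index: int = 0


def map_solution_to_centerline(solution, segment, sid=None,
                               extra_fields=None) -> MappedField:
    """Interpolate solver A/P/Q (and any extra per-node fields) from the
    ds grid onto the centerline's dl points, matching arterial index.

    Endpoints map exactly; an arc-length mismatch above 5% between the
    solver tube and the centerline is an error.
    """
    sid = segment.arterial_index if sid is None else sid
    if sid not in solution.segments:
        raise ValueError(f"arterial index {sid} not present in the solution")
    seg = solution.segments[sid]
    s_solver = seg["s"] / MM                        # mm
    L_solver = s_solver[-1] - s_solver[0]
    L_center = segment.length
    if abs(L_solver - L_center) > 0.05 * max(L_center, 1e-12):
        raise ValueError(
            f"arc-length mismatch: solver {L_solver:.3g} mm vs centerline "
            f"{L_center:.3g} mm exceeds 5%")
    # affine arc map so both endpoints coincide exactly
    s_target = segment.arc_positions * (L_solver / L_center) + s_solver[0]

    fields = {}
    names = {"A": seg["A"], "P": seg["P"], "Q": seg["Q"]}
    if extra_fields:
        names.update(extra_fields)
    for name, arr in names.items():
        out = np.empty((arr.shape[0], len(s_target)))
        for k in range(arr.shape[0]):
            out[k] = np.interp(s_target, s_solver, arr[k])
        fields[name] = out
    return MappedField(positions=segment.positions,
                       arc_positions=segment.arc_positions,
                       times=solution.times, fields=fields,
                       arterial_index=sid)
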