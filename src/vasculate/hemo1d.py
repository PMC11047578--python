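"""1D pulse-wave network solver with 0D terminal elements.

Major arteries are axisymmetric compliant tubes governed by the
cross-sectionally averaged continuity and momentum equations

    dA/dt + dQ/dz = 0
    dQ/dt + d(Q^2/A)/dz + (A/rho) dP/dz + K_R Q/A = 0

closed by the elastic tube law

    P - P0 = beta (sqrt(A/A0) - 1),   beta = E h0 / (r0 (1 - sigma^2)).

The interior scheme is the two-step (Richtmyer) Lax-Wendroff method in
conservative form with flux F = (Q, Q^2/A + beta A^(3/2)/(3 rho sqrt(A0)))
and sources for wall friction and reference-geometry taper.  Segment
ends are coupled through Riemann invariants (W+- = u +- 4(c - c0)) to
junctions (mass conservation + pressure continuity, scalar Newton),
prescribed-inflow inlets, RCR Windkessel or non-reflecting terminals,
and Young-type stenosis pressure-drop interfaces.

Everything inside this module is SI (m, s, Pa, m^3/s); the network
geometry it consumes is millimetres and is converted on entry.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import MM, MM2, MMHG, ML_S

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# material models


@dataclass
class WallModel:
    """Elastic wall of one vessel: linear-elastic thin shell.

    E in Pa; h0, r0 in mm; P0 in Pa.  beta = E h0 / (r0 (1 - sigma^2))
    is in Pa because only the ratio h0/r0 enters.
    """

    E: float                 # Young's modulus, Pa
    h0: float                # wall thickness, mm
    r0: float                # reference radius, mm
    sigma: float = 0.5       # Poisson ratio
    P0: float = 85.0 * MMHG  # reference pressure, Pa

    def __post_init__(self):
        if self.E <= 0 or self.h0 <= 0 or self.r0 <= 0:
            raise ValueError("E, h0, r0 must be positive")
        if not (0 <= self.sigma < 1):
            raise ValueError("Poisson ratio must be in [0, 1)")

    @property
    def A0(self) -> float:
        """Reference area, mm^2."""
        return math.pi * self.r0 ** 2

    @property
    def beta(self) -> float:
        """Stiffness E h0 / (r0 (1 - sigma^2)), Pa."""
        return self.E * self.h0 / (self.r0 * (1.0 - self.sigma ** 2))


@dataclass
class FluidProps:
    """Blood rheology and the 1D friction coefficient."""

    rho: float = 1060.0      # kg/m^3
    mu: float = 0.004        # Pa s
    profile: str = "flat"    # 'flat' (K_R = 22 pi nu) or 'poiseuille' (8 pi nu)
    K_R: float | None = None  # m^2/s; overrides profile when given

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")
        if self.K_R is None:
            factor = {"flat": 22.0, "poiseuille": 8.0}[self.profile]
            self.K_R = factor * math.pi * self.nu

    @property
    def nu(self) -> float:
        return self.mu / self.rho


def tube_law(A, wall: WallModel):
    """Pressure from area: P = P0 + beta (sqrt(A/A0) - 1).

    ``A`` must be in the same units as ``wall.A0`` (mm^2); only the
    ratio enters.
    """
    A = np.asarray(A, dtype=float)
    if (A <= 0).any():
        raise ValueError("area must be positive")
    out = wall.P0 + wall.beta * (np.sqrt(A / wall.A0) - 1.0)
    return out if out.ndim else float(out)


def tube_law_inv(P, wall: WallModel):
    """Area from pressure, exact inverse of :func:`tube_law`."""
    P = np.asarray(P, dtype=float)
    root = (P - wall.P0) / wall.beta + 1.0
    if (root <= 0).any():
        raise ValueError("pressure below collapse limit P0 - beta")
    out = wall.A0 * root ** 2
    return out if out.ndim else float(out)


def wave_speed(A, wall: WallModel, fluid: FluidProps):
    """Local pulse-wave speed c = sqrt(beta sqrt(A) / (2 rho sqrt(A0))).

    At A = A0 this is the Moens-Korteweg speed
    sqrt(E h0 / (2 rho r0 (1 - sigma^2))).
    """
    A = np.asarray(A, dtype=float)
    if (A <= 0).any():
        raise ValueError("area must be positive")
    out = np.sqrt(wall.beta / (2.0 * fluid.rho)) * (A / wall.A0) ** 0.25
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# 0D elements


@dataclass
class WindkesselState:
    """RCR (resistor-capacitor-resistor) lumped distal bed."""

    R1: float                # proximal resistance, Pa s/m^3
    R2: float                # distal resistance, Pa s/m^3
    C: float                 # compliance, m^3/Pa
    P_out: float = 5.0 * MMHG   # venous pressure, Pa
    P_c: float = None        # capacitor pressure, Pa

    def __post_init__(self):
        if min(self.R1, self.R2, self.C) <= 0:
            raise ValueError("R1, R2, C must be positive")
        if self.P_c is None:
            self.P_c = self.P_out


def windkessel_step(Q_in: float, wk: WindkesselState, dt: float) -> float:
    """Advance the capacitor pressure one implicit-Euler step and return
    the terminal (inlet-side) pressure P = P_c + R1 Q_in."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    wk.P_c = (wk.P_c + dt / wk.C * (Q_in + wk.P_out / wk.R2)) / (1.0 + dt / (wk.R2 * wk.C))
    return wk.P_c + wk.R1 * Q_in


@dataclass
class StenosisElement:
    """Young-type empirical stenosis: viscous + turbulent + inertial
    pressure drop applied as an internal interface (P jump, Q continuous).
    """

    segment: int             # network segment id
    position: float          # arc position along the segment, mm
    r0: float                # nominal (healthy) radius at the site, mm
    As_over_A0: float        # minimal area fraction As/A0 (1 - severity)
    Ls: float = 10.0         # stenosis length, mm
    Kv: float | None = None  # viscous coefficient; default Young empirical
    Kt: float = 1.52         # turbulent coefficient
    Ku: float = 1.2          # inertial coefficient

    def __post_init__(self):
        if not (0.0 < self.As_over_A0 <= 1.0):
            raise ValueError("As/A0 must be in (0, 1]")
        if self.Ls <= 0 or self.r0 <= 0:
            raise ValueError("Ls and r0 must be positive")
        if self.Kv is None:
            self.Kv = 32.0 * (self.Ls / (2.0 * self.r0)) / self.As_over_A0 ** 2

    @property
    def severity(self) -> float:
        return 1.0 - self.As_over_A0

    @property
    def A0_sten(self) -> float:
        """Nominal area, mm^2."""
        return math.pi * self.r0 ** 2


def stenosis_pressure_drop(Q: float, dQdt: float, sten: StenosisElement,
                           fluid: FluidProps) -> float:
    """Pressure drop (Pa) across the stenosis for flow Q (m^3/s)."""
    A0 = sten.A0_sten * MM2
    As = A0 * sten.As_over_A0
    if As <= 0:
        raise ValueError("stenotic area must be positive")
    r0 = sten.r0 * MM
    Ls = sten.Ls * MM
    visc = sten.Kv * fluid.mu / (2.0 * r0 * A0) * Q
    turb = sten.Kt * fluid.rho / (2.0 * A0 ** 2) * (A0 / As - 1.0) ** 2 * Q * abs(Q)
    inert = sten.Ku * fluid.rho * Ls / A0 * dQdt
    return visc + turb + inert


def _stenosis_dpdq(Q: float, sten: StenosisElement, fluid: FluidProps,
                   dt: float) -> float:
    """d(deltaP)/dQ when dQ/dt is backward-differenced over dt."""
    A0 = sten.A0_sten * MM2
    As = A0 * sten.As_over_A0
    r0 = sten.r0 * MM
    Ls = sten.Ls * MM
    return (sten.Kv * fluid.mu / (2.0 * r0 * A0)
            + sten.Kt * fluid.rho / A0 ** 2 * (A0 / As - 1.0) ** 2 * abs(Q)
            + sten.Ku * fluid.rho * Ls / (A0 * dt))


# ---------------------------------------------------------------------------
# discretized vessel state and the interior scheme


@dataclass
class VesselState:
    """Solver state of one discretized tube (SI units)."""

    s_grid: np.ndarray       # node arc positions, m
    A: np.ndarray            # m^2
    Q: np.ndarray            # m^3/s
    P: np.ndarray            # Pa
    t: float = 0.0


class _Piece:
    """One contiguous solver tube (a network segment or a stenosis half)."""

    __slots__ = ("seg_id", "s0", "n", "ds", "A", "Q", "beta", "A0", "sqA0",
                 "c0", "P0", "rho", "KR", "uniform")

    def __init__(self, seg_id, s0_mm, length_m, r0_mm_nodes, E, h0_mm, sigma,
                 P0, fluid, ds_target):
        n_int = max(2, int(round(length_m / ds_target)))
        self.seg_id = seg_id
        self.s0 = s0_mm                       # offset along parent segment, mm
        self.n = n_int + 1
        self.ds = length_m / n_int
        r0 = np.asarray(r0_mm_nodes, dtype=float) * MM   # m
        h0 = h0_mm * MM
        self.A0 = math.pi * r0 ** 2
        self.beta = E * h0 / (r0 * (1.0 - sigma ** 2))
        self.sqA0 = np.sqrt(self.A0)
        self.c0 = np.sqrt(self.beta / (2.0 * fluid.rho))
        self.P0 = P0
        self.rho = fluid.rho
        self.KR = fluid.K_R
        self.A = self.A0.copy()
        self.Q = np.zeros(self.n)
        self.uniform = bool(np.allclose(self.beta, self.beta[0])
                            and np.allclose(self.A0, self.A0[0]))

    # -- local fields ------------------------------------------------------
    def pressure(self):
        return self.P0 + self.beta * (np.sqrt(self.A / self.A0) - 1.0)

    def celerity(self):
        return self.c0 * (self.A / self.A0) ** 0.25

    def max_eigen(self):
        return float(np.max(np.abs(self.Q / self.A) + self.celerity()))

    # -- characteristic extraction ----------------------------------------
    def outgoing(self, side: str, dt: float) -> float:
        """Outgoing Riemann invariant at the boundary, interpolated at the
        foot of the characteristic one time level back."""
        A, Q = self.A, self.Q
        if side == "end":
            i, j = self.n - 1, self.n - 2
            sgn = 1.0
        else:
            i, j = 0, 1
            sgn = -1.0
        ui = float(Q[i] / A[i])
        ci = float(self.c0[i]) * float(A[i] / self.A0[i]) ** 0.25
        lam = sgn * ui + ci                     # speed of the outgoing wave
        x = max(0.0, min(1.0, lam * dt / self.ds))
        uj = float(Q[j] / A[j])
        cj = float(self.c0[j]) * float(A[j] / self.A0[j]) ** 0.25
        Wi = ui + sgn * 4.0 * (ci - float(self.c0[i]))
        Wj = uj + sgn * 4.0 * (cj - float(self.c0[j]))
        return (1.0 - x) * Wi + x * Wj

    def end_consts(self, side: str):
        i = self.n - 1 if side == "end" else 0
        return (float(self.beta[i]), float(self.A0[i]), float(self.c0[i]),
                float(self.A[i]))

    def set_boundary(self, side: str, A: float, Q: float):
        i = self.n - 1 if side == "end" else 0
        self.A[i] = A
        self.Q[i] = Q


def _flux2(A, Q, beta, sqA0, rho):
    return Q * Q / A + beta * A * np.sqrt(A) / (3.0 * rho * sqA0)


def _interior_step(piece: _Piece, dt: float):
    """Richtmyer two-step Lax-Wendroff update of the interior nodes."""
    A, Q = piece.A, piece.Q
    ds, rho, KR = piece.ds, piece.rho, piece.KR
    beta, A0, sqA0 = piece.beta, piece.A0, piece.sqA0

    F2 = _flux2(A, Q, beta, sqA0, rho)
    lam = dt / ds

    bh = 0.5 * (beta[:-1] + beta[1:])
    A0h = 0.5 * (A0[:-1] + A0[1:])
    sqA0h = np.sqrt(A0h)

    Am = 0.5 * (A[:-1] + A[1:])
    Qm = 0.5 * (Q[:-1] + Q[1:])
    S2m = -KR * Qm / Am
    if not piece.uniform:
        db = (beta[1:] - beta[:-1]) / ds
        dA0 = (A0[1:] - A0[:-1]) / ds
        A32 = Am * np.sqrt(Am)
        Tb = -(2.0 / 3.0) * A32 / (rho * sqA0h) + Am / rho
        TA0 = bh * A32 / (3.0 * rho * A0h * sqA0h)
        S2m = S2m + Tb * db + TA0 * dA0

    Ah = Am - 0.5 * lam * (Q[1:] - Q[:-1])
    Qh = Qm - 0.5 * lam * (F2[1:] - F2[:-1]) + 0.5 * dt * S2m
    if (Ah <= 0).any():
        raise RuntimeError("collapse: nonpositive area at half step; "
                           "reduce dt or stiffen the wall")

    F2h = _flux2(Ah, Qh, bh, sqA0h, rho)
    S2h = -KR * Qh / Ah
    if not piece.uniform:
        A32h = Ah * np.sqrt(Ah)
        Tbh = -(2.0 / 3.0) * A32h / (rho * sqA0h) + Ah / rho
        TA0h = bh * A32h / (3.0 * rho * A0h * sqA0h)
        S2h = S2h + Tbh * db + TA0h * dA0

    A[1:-1] -= lam * (Qh[1:] - Qh[:-1])
    Q[1:-1] -= lam * (F2h[1:] - F2h[:-1])
    Q[1:-1] += dt * 0.5 * (S2h[1:] + S2h[:-1])
    if (A[1:-1] <= 0).any():
        raise RuntimeError("collapse: nonpositive area after step; "
                           "reduce dt or stiffen the wall")


def advance_step(state: VesselState, wall: WallModel, fluid: FluidProps,
                 dt: float, cfl_limit: float = 1.0) -> VesselState:
    """Advance the interior nodes of a single uniform tube by ``dt``.

    Boundary nodes are left untouched (they belong to the coupling
    layer).  Raises on CFL violation or collapse.
    """
    ds = float(state.s_grid[1] - state.s_grid[0])
    piece = _Piece.__new__(_Piece)
    piece.seg_id = None
    piece.s0 = 0.0
    piece.n = len(state.A)
    piece.ds = ds
    piece.A0 = np.full(piece.n, wall.A0 * MM2)
    piece.beta = np.full(piece.n, wall.beta)
    piece.sqA0 = np.sqrt(piece.A0)
    piece.rho = fluid.rho
    piece.KR = fluid.K_R
    piece.c0 = np.sqrt(piece.beta / (2.0 * fluid.rho))
    piece.P0 = wall.P0
    piece.A = state.A
    piece.Q = state.Q
    piece.uniform = True

    lam_max = piece.max_eigen()
    if dt * lam_max / ds > cfl_limit + 1e-12:
        raise ValueError(
            f"CFL violation: dt={dt:.3e} s exceeds limit; "
            f"suggest dt <= {cfl_limit * ds / lam_max:.3e} s")
    _interior_step(piece, dt)
    state.P = piece.pressure()
    state.t += dt
    return state


# ---------------------------------------------------------------------------
# boundary couplings


_MASS_TOL = 5e-18        # m^3/s  (= 5e-12 ml/s)
_U_TOL = 1e-12           # m/s
_MAX_NEWTON = 50


class _Inlet:
    def __init__(self, piece, side, q_of_t):
        self.piece, self.side, self.q_of_t = piece, side, q_of_t

    def solve(self, t_new, dt):
        p, side = self.piece, self.side
        W = p.outgoing(side, dt)
        beta, A0, c0, A = p.end_consts(side)
        Qt = self.q_of_t(t_new)
        sgn = 1.0 if side == "start" else -1.0   # inflow direction
        # unknown A: sgn*Qt/A = u, with u -+ 4(c-c0) = W
        for _ in range(_MAX_NEWTON):
            c = c0 * (A / A0) ** 0.25
            if side == "start":
                f = sgn * Qt / A - 4.0 * (c - c0) - W
                df = -sgn * Qt / A ** 2 - c / A
            else:
                f = sgn * Qt / A + 4.0 * (c - c0) - W
                df = -sgn * Qt / A ** 2 + c / A
            if abs(f) < _U_TOL:
                break
            A -= f / df
            if A <= 0:
                A = 0.1 * A0
        p.set_boundary(side, A, sgn * Qt)
        return 0.0


class _NonReflecting:
    def __init__(self, piece, side):
        self.piece, self.side = piece, side

    def solve(self, t_new, dt):
        p, side = self.piece, self.side
        W = p.outgoing(side, dt)
        beta, A0, c0, _ = p.end_consts(side)
        # incoming invariant pinned to its rest value (0)
        c = c0 + (W if side == "end" else -W) / 8.0
        u = W / 2.0
        A = A0 * (c / c0) ** 4
        p.set_boundary(side, A, u * A)
        return 0.0


class _Terminal:
    def __init__(self, piece, side, wk: WindkesselState):
        self.piece, self.side, self.wk = piece, side, wk
        self.volume = 0.0
        self._q_prev = 0.0

    def solve(self, t_new, dt):
        p, side, wk = self.piece, self.side, self.wk
        W = p.outgoing(side, dt)
        beta, A0, c0, A = p.end_consts(side)
        sgn = 1.0 if side == "end" else -1.0     # outflow = sgn * Q
        rho = p.rho
        denom = 1.0 + dt / (wk.R2 * wk.C)
        dpc_dq = (dt / wk.C) / denom
        for _ in range(_MAX_NEWTON):
            c = c0 * (A / A0) ** 0.25
            u = W - 4.0 * (c - c0) if side == "end" else W + 4.0 * (c - c0)
            Qout = sgn * u * A
            Pc_new = (wk.P_c + dt / wk.C * (Qout + wk.P_out / wk.R2)) / denom
            P = p.P0 + beta * (math.sqrt(A / A0) - 1.0)
            f = P - Pc_new - wk.R1 * Qout
            dqda = (u - c) if side == "end" else (u + c)
            df = rho * c * c / A - (wk.R1 + dpc_dq) * sgn * dqda
            if abs(f) < 1e-9 * max(abs(P), 1.0):
                break
            A -= f / df
            if A <= 0:
                A = 0.1 * A0
        wk.P_c = Pc_new
        p.set_boundary(side, A, u * A)
        q_new = Qout
        self.volume += 0.5 * (self._q_prev + q_new) * dt
        self._q_prev = q_new
        return 0.0


class _Junction:
    """Static-pressure junction: one scalar Newton unknown (the common
    pressure); each incident area follows from the local tube law."""

    def __init__(self, ends, mode="static"):
        self.ends = ends          # list of (piece, side)
        self.mode = mode
        self.last_defect = 0.0

    def solve(self, t_new, dt):
        consts = []
        for piece, side in self.ends:
            W = piece.outgoing(side, dt)
            beta, A0, c0, A = piece.end_consts(side)
            sgn = 1.0 if side == "end" else -1.0
            consts.append((piece, side, W, beta, A0, c0, sgn, piece.rho, piece.P0))
        # initial guess: mean of current end pressures
        P = 0.0
        for piece, side, W, beta, A0, c0, sgn, rho, P0 in consts:
            _, _, _, A = piece.end_consts(side)
            P += P0 + beta * (math.sqrt(A / A0) - 1.0)
        P /= len(consts)

        total_mode = self.mode == "total"
        f = 0.0
        for it in range(_MAX_NEWTON):
            f = 0.0
            df = 0.0
            sols = []
            for piece, side, W, beta, A0, c0, sgn, rho, P0 in consts:
                Ps = P
                if total_mode:
                    # static pressure from total: fixed-point on u
                    Ps = P
                    for _ in range(30):
                        root = (Ps - P0) / beta + 1.0
                        root = max(root, 1e-6)
                        A = A0 * root * root
                        c = c0 * (A / A0) ** 0.25
                        u = W - sgn * 4.0 * (c - c0)
                        Ps_new = P - 0.5 * rho * u * u
                        if abs(Ps_new - Ps) < 1e-10:
                            Ps = Ps_new
                            break
                        Ps = Ps_new
                root = (Ps - P0) / beta + 1.0
                if root <= 0:
                    raise RuntimeError("collapse at junction: pressure below "
                                       "the tube-law limit")
                A = A0 * root * root
                c = c0 * (A / A0) ** 0.25
                u = W - sgn * 4.0 * (c - c0)
                Q = u * A
                f += sgn * Q
                dqda = u - sgn * c
                df += sgn * dqda * A / (rho * c * c)
                sols.append((piece, side, A, Q))
            if abs(f) < _MASS_TOL:
                break
            P -= f / df
        self.last_defect = abs(f)
        for piece, side, A, Q in sols:
            piece.set_boundary(side, A, Q)
        return abs(f)


class _StenosisFace:
    """Internal interface: Q continuous, P jumps by the Young drop."""

    def __init__(self, up_piece, down_piece, element: StenosisElement,
                 fluid: FluidProps):
        self.up, self.down = up_piece, down_piece
        self.elem = element
        self.fluid = fluid
        self.q_prev = 0.0
        self.last_defect = 0.0

    def solve(self, t_new, dt):
        up, dn = self.up, self.down
        Wp = up.outgoing("end", dt)
        Wm = dn.outgoing("start", dt)
        bL, A0L, c0L, AL = up.end_consts("end")
        bR, A0R, c0R, AR = dn.end_consts("start")
        rho = up.rho
        for _ in range(_MAX_NEWTON):
            cL = c0L * (AL / A0L) ** 0.25
            cR = c0R * (AR / A0R) ** 0.25
            uL = Wp - 4.0 * (cL - c0L)
            uR = Wm + 4.0 * (cR - c0R)
            QL = uL * AL
            QR = uR * AR
            Qb = 0.5 * (QL + QR)
            dqdt = (Qb - self.q_prev) / dt
            dP = stenosis_pressure_drop(Qb, dqdt, self.elem, self.fluid)
            dPdQ = _stenosis_dpdq(Qb, self.elem, self.fluid, dt)
            PL = up.P0 + bL * (math.sqrt(AL / A0L) - 1.0)
            PR = dn.P0 + bR * (math.sqrt(AR / A0R) - 1.0)
            g1 = QL - QR
            g2 = PL - PR - dP
            if abs(g1) < _MASS_TOL and abs(g2) < 1e-9 * max(abs(PL), 1.0):
                break
            dQL = uL - cL
            dQR = uR + cR
            j11, j12 = dQL, -dQR
            j21 = rho * cL * cL / AL - dPdQ * 0.5 * dQL
            j22 = -rho * cR * cR / AR - dPdQ * 0.5 * dQR
            det = j11 * j22 - j12 * j21
            AL -= (g1 * j22 - g2 * j12) / det
            AR -= (g2 * j11 - g1 * j21) / det
            if AL <= 0:
                AL = 0.1 * A0L
            if AR <= 0:
                AR = 0.1 * A0R
        self.last_defect = abs(QL - QR)
        self.q_prev = 0.5 * (QL + QR)
        up.set_boundary("end", AL, QL)
        dn.set_boundary("start", AR, QR)
        return self.last_defect


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class SimConfig:
    """Configuration for :func:`simulate` (wall, fluid, inflow, numerics)."""

    fluid: FluidProps = field(default_factory=FluidProps)
    E: float = 400e3              # Pa, global Young's modulus
    h0: float = 0.3               # mm, global wall thickness
    h0_ratio: float | None = None  # if set, h0 = h0_ratio * local r0
    sigma: float = 0.5
    P0: float = 85.0 * MMHG       # Pa, reference pressure
    wall_per_segment: dict = field(default_factory=dict)  # seg id -> overrides
    inflow_t: np.ndarray = None   # s, one period
    inflow_q: np.ndarray = None   # ml/s
    period: float = 1.0           # s
    ds: float = 1.0               # mm, solver grid width
    cfl: float = 0.5
    max_cycles: int = 20
    conv_tol: float = 1e-3
    n_output: int = 100           # samples per cycle
    junction_mode: str = "static"   # 'static' or 'total' pressure continuity

    def q_inlet(self, t: float) -> float:
        """Periodic inflow, SI (m^3/s)."""
        tt = t % self.period
        return float(np.interp(tt, self.inflow_t, self.inflow_q)) * ML_S


@dataclass
class SolutionField:
    """Converged-cycle output: per-segment A/P/Q time series (SI)."""

    times: np.ndarray                 # s, within the cycle
    segments: dict                    # seg id -> dict(s, A, P, Q) SI
    period: float
    converged: bool
    n_cycles: int
    conservation: dict
    final_state: dict = field(default_factory=dict)

    def seg(self, sid):
        return self.segments[sid]

    def mean_flow(self, sid) -> np.ndarray:
        """Cycle-mean flow along the segment, m^3/s."""
        q = self.segments[sid]["Q"]
        span = float(self.times[-1] - self.times[0])
        return np.trapezoid(q, self.times, axis=0) / span


def _wall_for(cfg: SimConfig, sid):
    w = dict(E=cfg.E, h0=cfg.h0, h0_ratio=cfg.h0_ratio, sigma=cfg.sigma)
    w.update(cfg.wall_per_segment.get(sid, {}))
    return w


def _build_pieces(network, cfg: SimConfig):
    """Discretize network segments into solver pieces, splitting at
    stenoses, and wire up all couplings."""
    sten_by_seg = {}
    for st in network.stenoses:
        elem = st if isinstance(st, StenosisElement) else StenosisElement(**st)
        sten_by_seg.setdefault(elem.segment, []).append(elem)

    pieces_of_seg = {}
    end_piece = {}          # (seg id, 'start'|'end') -> (piece, side)
    all_pieces = []
    faces = []
    ds_target = cfg.ds * MM

    for sid, seg in network.segments.items():
        w = _wall_for(cfg, sid)
        L = seg.length
        cuts = sorted(min(max(e.position, 2.0 * cfg.ds), L - 2.0 * cfg.ds)
                      for e in sten_by_seg.get(sid, []))
        bounds = [0.0] + cuts + [L]
        segs_pieces = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_int = max(2, int(round((b - a) / cfg.ds)))
            s_nodes = np.linspace(a, b, n_int + 1)
            r_nodes = np.interp(s_nodes, seg.arc_positions, seg.radii)
            h0 = w["h0"] if w["h0_ratio"] is None else None
            if h0 is None:
                h0_nodes_eff = w["h0_ratio"] * r_nodes
                # taper-aware: per-node h0 folds into beta via r0; emulate by
                # building beta directly with an effective constant h over r
                piece = _Piece(sid, a, (b - a) * MM, r_nodes, w["E"], 1.0,
                               w["sigma"], cfg.P0, cfg.fluid, ds_target)
                piece.beta = (w["E"] * (h0_nodes_eff * MM)
                              / (r_nodes * MM * (1.0 - w["sigma"] ** 2)))
                piece.c0 = np.sqrt(piece.beta / (2.0 * cfg.fluid.rho))
                piece.uniform = bool(np.allclose(piece.beta, piece.beta[0])
                                     and np.allclose(piece.A0, piece.A0[0]))
            else:
                piece = _Piece(sid, a, (b - a) * MM, r_nodes, w["E"], h0,
                               w["sigma"], cfg.P0, cfg.fluid, ds_target)
            segs_pieces.append(piece)
            all_pieces.append(piece)
        pieces_of_seg[sid] = segs_pieces
        end_piece[(sid, "start")] = (segs_pieces[0], "start")
        end_piece[(sid, "end")] = (segs_pieces[-1], "end")
        for elem, up, dn in zip(sten_by_seg.get(sid, []), segs_pieces[:-1],
                                segs_pieces[1:]):
            faces.append(_StenosisFace(up, dn, elem, cfg.fluid))

    couplings = list(faces)
    sid, end = network.inlet
    couplings.append(_Inlet(*end_piece[(sid, end)], cfg.q_inlet))

    junctions = []
    for jid, ends in network.junctions.items():
        j = _Junction([end_piece[(s, e)] for s, e in ends],
                      mode=cfg.junction_mode)
        junctions.append(j)
        couplings.append(j)

    terminals = {}
    for tid, spec in network.terminals.items():
        model = spec.get("model", {})
        piece, side = end_piece[(spec["segment"], spec["end"])]
        if model.get("kind", "rcr") == "nonreflecting":
            couplings.append(_NonReflecting(piece, side))
        else:
            wk = WindkesselState(R1=model["R1"], R2=model["R2"], C=model["C"],
                                 P_out=model.get("P_out", 5.0 * MMHG))
            term = _Terminal(piece, side, wk)
            terminals[tid] = term
            couplings.append(term)
    return all_pieces, pieces_of_seg, couplings, junctions, terminals, faces


def simulate(network, cfg: SimConfig, init_state: dict | None = None) -> SolutionField:
    """Run cardiac cycles until the pressure field is cycle-periodic.

    Convergence: max over nodes and sample times of |P_k - P_(k-1)|
    relative to max |P_k| below ``cfg.conv_tol`` (cap ``max_cycles``;
    a capped run is returned flagged, with a warning).
    """
    (pieces, pieces_of_seg, couplings, junctions, terminals,
     faces) = _build_pieces(network, cfg)

    if init_state:
        for p in pieces:
            key = (p.seg_id, round(p.s0, 6))
            if key in init_state.get("pieces", {}):
                A, Q = init_state["pieces"][key]
                if len(A) == p.n:
                    p.A[:] = A
                    # rescale stored area toward the (possibly remodeled)
                    # local reference so warm starts stay consistent
                    p.Q[:] = Q
        for tid, pc in init_state.get("P_c", {}).items():
            if tid in terminals:
                terminals[tid].wk.P_c = pc
    else:
        # distribute the mean inflow over terminals by conductance for a
        # near-steady Windkessel start
        qm = float(np.trapezoid(cfg.inflow_q, cfg.inflow_t)) / cfg.period * ML_S
        if terminals:
            g = {tid: 1.0 / (t.wk.R1 + t.wk.R2) for tid, t in terminals.items()}
            gs = sum(g.values())
            for tid, term in terminals.items():
                qt = qm * g[tid] / gs
                term.wk.P_c = term.wk.P_out + qt * term.wk.R2

    n_out = cfg.n_output
    prev_sample = None
    converged = False
    max_defect = 0.0
    t = 0.0
    n_cycles = 0
    conservation = {}
    # eigenvalue rate max(|u|+c)/ds seen so far; systole speeds waves up,
    # so the first cycle gets extra headroom and later cycles reuse the
    # observed peak.  A mid-cycle CFL bust restarts the cycle with a
    # larger margin.
    rate_hist = 0.0
    margin = 1.6

    for cycle in range(cfg.max_cycles):
        rate_now = max(p.max_eigen() / p.ds for p in pieces)
        snapshot = ([(p.A.copy(), p.Q.copy()) for p in pieces],
                    {tid: term.wk.P_c for tid, term in terminals.items()},
                    [f.q_prev for f in faces], t)
        while True:
            rate_use = max(rate_now * margin, rate_hist * 1.15)
            dt = cfg.cfl / rate_use
            n_steps = max(n_out, int(math.ceil(cfg.period / dt)))
            dt = cfg.period / n_steps
            sample_every = n_steps / n_out
            next_sample = 0.0
            samples = {sid: [] for sid in pieces_of_seg}
            sample_times = []

            inlet_vol = 0.0
            q_in_prev = cfg.q_inlet(t)
            for term in terminals.values():
                term.volume = 0.0
            stored0 = sum(np.trapezoid(p.A, dx=p.ds) for p in pieces)

            cfl_bust = False
            rate_seen = rate_now
            for k in range(n_steps):
                if k >= next_sample:
                    sample_times.append(t - cycle * cfg.period)
                    for sid, plist in pieces_of_seg.items():
                        samples[sid].append(
                            (np.concatenate([p.A for p in plist]),
                             np.concatenate([p.Q for p in plist])))
                    next_sample += sample_every
                t_new = t + dt
                step_rate = max(p.max_eigen() / p.ds for p in pieces)
                rate_seen = max(rate_seen, step_rate)
                if dt * step_rate > 1.0 + 1e-9:
                    cfl_bust = True
                    break
                for p in pieces:
                    _interior_step(p, dt)
                for cpl in couplings:
                    d = cpl.solve(t_new, dt)
                    if d > max_defect:
                        max_defect = d
                q_in = cfg.q_inlet(t_new)
                inlet_vol += 0.5 * (q_in_prev + q_in) * dt
                q_in_prev = q_in
                t = t_new
            rate_hist = max(rate_hist, rate_seen)
            if not cfl_bust:
                break
            # roll back and redo the cycle with a wider margin
            margin *= 1.5
            if margin > 20.0:
                raise ValueError(
                    "CFL margin exhausted: wave speeds keep outrunning the "
                    f"step; suggest dt <= {1.0 / rate_seen:.3e} s")
            states, pcs, qprevs, t = snapshot
            for p, (A, Q) in zip(pieces, states):
                p.A[:], p.Q[:] = A, Q
            for tid, pc in pcs.items():
                terminals[tid].wk.P_c = pc
            for f, qp in zip(faces, qprevs):
                f.q_prev = qp

        n_cycles = cycle + 1
        for p in pieces:
            if np.isnan(p.A).any() or np.isnan(p.Q).any():
                raise RuntimeError(
                    f"instability (NaN) in segment {p.seg_id} at t={t:.4f} s")

        stored1 = sum(np.trapezoid(p.A, dx=p.ds) for p in pieces)
        term_vol = {tid: term.volume for tid, term in terminals.items()}
        balance = inlet_vol - sum(term_vol.values()) - (stored1 - stored0)
        conservation = {
            "inlet_volume_m3": inlet_vol,
            "terminal_volumes_m3": term_vol,
            "stored_delta_m3": stored1 - stored0,
            "balance_rel": abs(balance) / max(inlet_vol, 1e-30),
            "max_junction_defect_m3s": max_defect,
        }

        sample_P = {}
        for sid, snaps in samples.items():
            plist = pieces_of_seg[sid]
            P0s = np.concatenate([p.P0 + np.zeros(p.n) for p in plist])
            betas = np.concatenate([p.beta for p in plist])
            A0s = np.concatenate([p.A0 for p in plist])
            Aarr = np.stack([s[0] for s in snaps])
            sample_P[sid] = P0s + betas * (np.sqrt(Aarr / A0s) - 1.0)
        if prev_sample is not None:
            num = max(np.max(np.abs(sample_P[sid] - prev_sample[sid]))
                      for sid in sample_P)
            den = max(np.max(np.abs(sample_P[sid])) for sid in sample_P)
            if num / den < cfg.conv_tol:
                converged = True
        prev_sample = sample_P
        last_samples, last_times = samples, sample_times
        if converged:
            break

    if not converged:
        warnings.warn(f"cycle-to-cycle convergence not reached in "
                      f"{cfg.max_cycles} cycles")

    seg_out = {}
    for sid, snaps in last_samples.items():
        plist = pieces_of_seg[sid]
        s_mm = np.concatenate([p.s0 + np.arange(p.n) * p.ds / MM for p in plist])
        Aarr = np.stack([s[0] for s in snaps])
        Qarr = np.stack([s[1] for s in snaps])
        seg_out[sid] = {
            "s": s_mm * MM,                      # m
            "A": Aarr, "Q": Qarr,
            "P": prev_sample[sid],
        }
    final_state = {
        "pieces": {(p.seg_id, round(p.s0, 6)): (p.A.copy(), p.Q.copy())
                   for p in pieces},
        "P_c": {tid: term.wk.P_c for tid, term in terminals.items()},
    }
    return SolutionField(times=np.asarray(last_times), segments=seg_out,
                         period=cfg.period, converged=converged,
                         n_cycles=n_cycles, conservation=conservation,
                         final_state=final_state)
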