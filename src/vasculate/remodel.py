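"""Arterial remodeling toward homeostatic wall shear stress.

Arteries adapt their caliber so that wall shear stress returns to a
set-point when flow changes.  Since tau_w = 4 mu Q / (pi r^3) for
Poiseuille flow at fixed Q, the constant-WSS fixed point scales as
r* = r (tau/tau*)^(1/3); the outer loop below applies that update with
under-relaxation omega (exponent omega/3) to each adaptive segment,
re-simulating the network between updates, until the time-averaged WSS
matches the target within tolerance.

The reference radius r0 (hence A0) is adapted; wall thickness h0 is
kept fixed unless ``scale_h0`` is set.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .hemo1d import simulate
from .postproc import wss_field

log = logging.getLogger(__name__)


@dataclass
class RemodelConfig:
    """Outer-loop parameters for WSS-homeostasis remodeling."""

    segments: list                     # adaptive segment ids
    targets: dict | str = "baseline"   # seg id -> Pa, or "baseline"
    omega: float = 0.5                 # relaxation in (0, 1]
    tol: float = 0.05                  # relative TAWSS error
    max_iter: int = 12
    scale_h0: bool = False             # also scale wall thickness with r
    step_clip: tuple = (0.7, 1.5)      # per-iteration radius factor bounds

    def __post_init__(self):
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def iterate_radii(eval_tawss, radii, targets, omega=0.5, tol=0.05,
                  max_iter=30, step_clip=(0.5, 2.0)):
    """Core fixed-point loop on a plain radius vector.

    ``eval_tawss(radii) -> tawss array``; radii are updated by
    r <- r * (tau/target)^(omega/3), clipped per step, until the max
    relative error drops below ``tol``.  Returns (radii, trace); raises
    if the error grows three iterations in a row.
    """
    radii = np.asarray(radii, dtype=float).copy()
    targets = np.asarray(targets, dtype=float)
    if (targets <= 0).any():
        raise ValueError("targets must be positive")
    trace = []
    prev_err = np.inf
    n_grow = 0
    for it in range(max_iter + 1):
        tau = np.asarray(eval_tawss(radii), dtype=float)
        err = np.abs(tau - targets) / targets
        trace.append({"iteration": it, "radii": radii.copy(),
                      "tawss": tau.copy(), "max_rel_error": float(err.max())})
        if err.max() < tol:
            return radii, trace
        if it == max_iter:
            break
        if err.max() >= prev_err:
            n_grow += 1
            if n_grow >= 3:
                raise RuntimeError(
                    f"remodeling diverged: error grew 3 consecutive "
                    f"iterations (last {err.max():.3g}); trace has "
                    f"{len(trace)} entries")
        else:
            n_grow = 0
        prev_err = err.max()
        factor = np.clip((tau / targets) ** (omega / 3.0), *step_clip)
        radii = np.maximum(radii * factor, 1e-9)
    log.warning("remodeling hit the iteration cap at error %.3g",
                trace[-1]["max_rel_error"])
    return radii, trace


def _segment_tawss(solution, sids, mu):
    return np.array([wss_field(solution, sid, mu).tawss_mean for sid in sids])


def remodel_to_target_wss(network, sim_config, remodel: RemodelConfig,
                          baseline_network=None):
    """Adapt the radii of designated segments until TAWSS hits target.

    With ``targets="baseline"`` the targets are the segment-mean TAWSS
    of a reference run: ``baseline_network`` if given, else the same
    network with its stenoses removed.  Returns (adapted network,
    trace, final solution); the trace is one dict per outer iteration
    per segment (iteration, segment, radius scale, TAWSS, target,
    relative error).
    """
    sids = list(remodel.segments)
    mu = sim_config.fluid.mu

    if remodel.targets == "baseline":
        ref = baseline_network
        if ref is None:
            ref = copy.deepcopy(network)
            ref.stenoses = []
        ref_sol = simulate(ref, sim_config)
        targets = _segment_tawss(ref_sol, sids, mu)
    else:
        targets = np.array([float(remodel.targets[s]) for s in sids])
    if (targets <= 0).any():
        raise ValueError("baseline/target TAWSS must be positive for "
                         "adaptive segments")

    net = copy.deepcopy(network)
    scale = np.ones(len(sids))
    trace = []
    prev_err = np.inf
    n_grow = 0
    warm = None
    sol = None
    for it in range(remodel.max_iter + 1):
        sol = simulate(net, sim_config, init_state=warm)
        warm = sol.final_state
        tau = _segment_tawss(sol, sids, mu)
        err = np.abs(tau - targets) / targets
        for j, sid in enumerate(sids):
            trace.append({"iteration": it, "segment": sid,
                          "radius_scale": float(scale[j]),
                          "tawss": float(tau[j]), "target": float(targets[j]),
                          "rel_error": float(err[j])})
        if err.max() < remodel.tol:
            return net, trace, sol
        if it == remodel.max_iter:
            break
        if err.max() >= prev_err:
            n_grow += 1
            if n_grow >= 3:
                raise RuntimeError(
                    "remodeling diverged: error grew 3 consecutive outer "
                    "iterations; inspect the trace")
        else:
            n_grow = 0
        prev_err = err.max()

        factor = np.clip((tau / targets) ** (remodel.omega / 3.0),
                         *remodel.step_clip)
        for j, sid in enumerate(sids):
            seg = net.segments[sid]
            seg.radii = np.maximum(seg.radii * factor[j], 1e-6)
            scale[j] *= factor[j]
            if remodel.scale_h0:
                ov = dict(sim_config.wall_per_segment.get(sid, {}))
                h0 = ov.get("h0", sim_config.h0)
                if sim_config.h0_ratio is None:
                    ov["h0"] = h0 * factor[j]
                    sim_config.wall_per_segment[sid] = ov
            # keep the warm-start areas consistent with the new reference
            for key in list(warm["pieces"]):
                if key[0] == sid:
                    A, Q = warm["pieces"][key]
                    warm["pieces"][key] = (A * factor[j] ** 2, Q)
    log.warning("remodeling hit the outer-iteration cap at error %.3g",
                trace[-1]["rel_error"] if trace else float("nan"))
    return net, trace, sol
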