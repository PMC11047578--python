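"""File I/O: volumes, skeletons, networks, solver configs, solutions.

Volumes are accepted as NIfTI (via nibabel) or ``.npy`` arrays, or as a
raw binary file next to a JSON header (``shape``, ``dtype``,
``spacing``, ``origin``).  Skeletons and networks are documented JSON;
solutions are written as per-segment CSV tables plus an ``.npz``
container for round-tripping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .centerline import VascularNetwork
from .hemo1d import FluidProps, SimConfig, SolutionField
from .skeleton import Skeleton, SkeletonNode, VoxelVolume
from .units import MM, MMHG, ML_S


def load_volume(path) -> VoxelVolume:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj) > 0
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return VoxelVolume(data, spacing=spacing)
    if path.suffix == ".npy":
        return VoxelVolume(np.load(path) > 0)
    if path.suffix == ".json":
        hdr = json.loads(path.read_text())
        raw = np.fromfile(path.with_suffix(".raw"), dtype=hdr.get("dtype", "uint8"))
        data = raw.reshape(hdr["shape"]) > 0
        return VoxelVolume(data, spacing=tuple(hdr.get("spacing", (1, 1, 1))),
                           origin=tuple(hdr.get("origin", (0, 0, 0))))
    raise ValueError(f"unsupported volume format: {path}")


def save_skeleton(skeleton: Skeleton, path):
    d = {
        "nodes": [{"id": n.index, "x": n.position[0], "y": n.position[1],
                   "z": n.position[2], "r": n.radius, "kind": n.kind,
                   "label": skeleton.segment_labels.get(n.index)}
                  for n in skeleton.nodes],
        "edges": [[int(i), int(j)] for i, j in skeleton.edges],
        "segments": {str(k): [int(i) for i in v]
                     for k, v in skeleton.segments.items()},
        "metadata": skeleton.metadata,
    }
    Path(path).write_text(json.dumps(d, indent=1) + "\n")


def load_skeleton(path) -> Skeleton:
    d = json.loads(Path(path).read_text())
    nodes = [SkeletonNode(n["id"], np.array([n["x"], n["y"], n["z"]]),
                          radius=n["r"], kind=n["kind"]) for n in d["nodes"]]
    sk = Skeleton(nodes=nodes, edges=[tuple(e) for e in d["edges"]],
                  segments={int(k): v for k, v in d.get("segments", {}).items()},
                  segment_labels={n["id"]: n["label"] for n in d["nodes"]
                                  if n.get("label") is not None},
                  metadata=d.get("metadata", {}))
    sk.recompute_degrees()
    return sk


def save_network(network: VascularNetwork, path):
    Path(path).write_text(json.dumps(network.to_dict(), indent=1) + "\n")


def load_network(path) -> VascularNetwork:
    return VascularNetwork.from_dict(json.loads(Path(path).read_text()))


def load_sim_config(path) -> SimConfig:
    """Build a SimConfig from a YAML/JSON file.

    Schema (all blocks optional, with defaults):
      fluid:  {rho, mu, profile, K_R}
      wall:   {E, h0, h0_ratio, sigma, P0_mmhg, per_segment: {id: {...}}}
      inflow: {preset: halfsine, period, stroke_volume_ml}  or  {t: [...], q_mlps: [...]}
      solver: {ds, cfl, max_cycles, conv_tol, n_output, junction_mode}
    """
    path = Path(path)
    raw = (yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml")
           else json.loads(path.read_text()))
    fluid = FluidProps(**raw.get("fluid", {}))
    wall = dict(raw.get("wall", {}))
    per_seg = {int(k): v for k, v in wall.pop("per_segment", {}).items()}
    p0 = wall.pop("P0_mmhg", 85.0) * MMHG

    inflow = raw.get("inflow", {})
    period = float(inflow.get("period", 1.0))
    if "t" in inflow:
        t = np.asarray(inflow["t"], dtype=float)
        q = np.asarray(inflow["q_mlps"], dtype=float)
    else:
        from .fixtures import default_inflow_waveform

        t, q = default_inflow_waveform(
            T=period, stroke_volume=float(inflow.get("stroke_volume_ml", 12.0)))
    solver = raw.get("solver", {})
    return SimConfig(fluid=fluid, P0=p0, wall_per_segment=per_seg,
                     inflow_t=t, inflow_q=q, period=period,
                     **{k: wall[k] for k in ("E", "h0", "h0_ratio", "sigma")
                        if k in wall},
                     **{k: solver[k] for k in
                        ("ds", "cfl", "max_cycles", "conv_tol", "n_output",
                         "junction_mode") if k in solver})


def save_solution(solution: SolutionField, out_dir):
    """Write per-segment CSV tables (mm / ml/s / mmHg) and an .npz
    container; returns the output directory."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    npz = {"times": solution.times, "period": solution.period,
           "converged": solution.converged, "n_cycles": solution.n_cycles}
    for sid, seg in solution.segments.items():
        npz[f"s_{sid}"] = seg["s"]
        for f in ("A", "P", "Q"):
            npz[f"{f}_{sid}"] = seg[f]
        rows = []
        for k, t in enumerate(solution.times):
            for j, s in enumerate(seg["s"]):
                rows.append((t, s / MM, seg["A"][k, j] / 1e-6,
                             seg["P"][k, j] / MMHG, seg["Q"][k, j] / ML_S))
        pd.DataFrame(rows, columns=["t_s", "s_mm", "A_mm2", "P_mmhg",
                                    "Q_mlps"]).to_csv(
            out / f"segment_{sid}.csv", index=False)
    np.savez(out / "solution.npz", **npz)
    (out / "conservation.json").write_text(json.dumps(
        {k: (v if not isinstance(v, dict) else v)
         for k, v in _jsonable(solution.conservation).items()}, indent=1) + "\n")
    return out


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[str(k)] = _jsonable(v)
        elif isinstance(v, (np.floating, np.integer)):
            out[str(k)] = float(v)
        else:
            out[str(k)] = v
    return out


def load_solution(path) -> SolutionField:
    """Rebuild a SolutionField from a run directory or .npz file."""
    path = Path(path)
    if path.is_dir():
        path = path / "solution.npz"
    z = np.load(path, allow_pickle=False)
    sids = sorted({int(k.split("_", 1)[1]) for k in z.files
                   if k.startswith("A_")})
    segments = {sid: {"s": z[f"s_{sid}"], "A": z[f"A_{sid}"],
                      "P": z[f"P_{sid}"], "Q": z[f"Q_{sid}"]}
                for sid in sids}
    return SolutionField(times=z["times"], segments=segments,
                         period=float(z["period"]),
                         converged=bool(z["converged"]),
                         n_cycles=int(z["n_cycles"]), conservation={})
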