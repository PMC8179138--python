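"""File formats: perturbation TSV, multi-model PDB trajectories, configs.

Perturbation series travel as TSV with a mandatory header
(window_index, lambda, frame, delta_U_kcal_mol).  Trajectories are written
as multi-model PDB (one MODEL per frame, via gemmi) plus a TSV sidecar with
per-frame unit orientation vectors; region geometry and temperature ride
along as ``#key value`` comment lines at the top of the sidecar.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .fep import PerturbationSeries
from .hydration import Frame, Trajectory

PERTURBATION_COLUMNS = ("window_index", "lambda", "frame", "delta_U_kcal_mol")
ORIENTATION_COLUMNS = ("frame", "water_id", "ux", "uy", "uz")

_WATER_RES = "HOH"
_SOLUTE_RES = "LIG"


def write_perturbation_tsv(
    series_list: list[PerturbationSeries], path: str | Path, temperature: float | None = None
) -> None:
    """Write per-window energy differences; temperature goes in a comment."""
    path = Path(path)
    temp = temperature
    if temp is None and series_list:
        temp = series_list[0].temperature
    with path.open("w") as fh:
        fh.write(f"#temperature_K\t{temp}\n")
        fh.write("\t".join(PERTURBATION_COLUMNS) + "\n")
        for s in series_list:
            for frame, du in enumerate(s.delta_u):
                fh.write(f"{s.window_index}\t{s.lam:.10g}\t{frame}\t{du:.10g}\n")


def read_perturbation_tsv(path: str | Path) -> list[PerturbationSeries]:
    """Read and validate a perturbation TSV, grouped by window.

    Malformed rows are rejected with their 1-based line number; duplicate
    (window, frame) pairs and missing columns are errors.
    """
    path = Path(path)
    temperature = 300.0
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            key, _, val = line[1:].partition("\t")
            if key.strip() == "temperature_K":
                temperature = float(val)
        else:
            break
    if body_start >= len(lines):
        raise ValueError(f"{path}: no header row")
    header = lines[body_start].rstrip("\n").split("\t")
    missing = [c for c in PERTURBATION_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in PERTURBATION_COLUMNS}
    rows = []
    for lineno, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        try:
            rows.append(
                (
                    int(cells[idx["window_index"]]),
                    float(cells[idx["lambda"]]),
                    int(cells[idx["frame"]]),
                    float(cells[idx["delta_U_kcal_mol"]]),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["window_index", "lambda", "frame", "delta_u"])
    dup = df.duplicated(subset=["window_index", "frame"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (window, frame) = "
            f"({int(first.window_index)}, {int(first.frame)})"
        )
    out = []
    for w, g in df.groupby("window_index", sort=True):
        g = g.sort_values("frame")
        out.append(
            PerturbationSeries(
                window_index=int(w),
                lam=float(g["lambda"].iloc[0]),
                delta_u=g["delta_u"].to_numpy(),
                temperature=temperature,
            )
        )
    return out


def write_trajectory_pdb(
    traj: Trajectory, pdb_path: str | Path, orientation_tsv_path: str | Path
) -> None:
    """Multi-model PDB (one MODEL per frame) plus orientation sidecar TSV."""
    st = gemmi.Structure()
    st.name = "thermoprof trajectory"
    for i, frame in enumerate(traj.frames):
        model = gemmi.Model(i + 1)
        if frame.solute_positions is not None and len(frame.solute_positions):
            chain = gemmi.Chain("A")
            res = gemmi.Residue()
            res.name = _SOLUTE_RES
            res.seqid = gemmi.SeqId(1, " ")
            for k, p in enumerate(frame.solute_positions):
                atom = gemmi.Atom()
                atom.name = f"C{k + 1}"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*p)
                res.add_atom(atom)
            chain.add_residue(res)
            model.add_chain(chain)
        wchain = gemmi.Chain("W")
        for wid, p in zip(frame.water_ids, frame.positions):
            res = gemmi.Residue()
            res.name = _WATER_RES
            res.seqid = gemmi.SeqId(int(wid) + 1, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "O"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(*p)
            res.add_atom(atom)
            wchain.add_residue(res)
        model.add_chain(wchain)
        st.add_model(model)
    st.write_pdb(str(pdb_path))

    with Path(orientation_tsv_path).open("w") as fh:
        fh.write(f"#region_center\t{traj.region_center[0]:.10g}\t"
                 f"{traj.region_center[1]:.10g}\t{traj.region_center[2]:.10g}\n")
        fh.write(f"#region_radius\t{traj.region_radius:.10g}\n")
        fh.write(f"#temperature_K\t{traj.temperature:.10g}\n")
        fh.write("\t".join(ORIENTATION_COLUMNS) + "\n")
        for i, frame in enumerate(traj.frames):
            for wid, u in zip(frame.water_ids, frame.orientations):
                fh.write(
                    f"{i}\t{int(wid)}\t{u[0]:.10g}\t{u[1]:.10g}\t{u[2]:.10g}\n"
                )


def read_trajectory_pdb(
    pdb_path: str | Path, orientation_tsv_path: str | Path
) -> Trajectory:
    """Read a multi-model PDB with its orientation sidecar into a Trajectory.

    Frames align by MODEL order.  Every water in every frame must have an
    orientation row; vectors are re-normalised when within 1e-3 of unit norm
    and rejected otherwise.
    """
    meta = {"region_center": np.zeros(3), "region_radius": None, "temperature": 300.0}
    lines = Path(orientation_tsv_path).read_text().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if parts[0] == "region_center":
                meta["region_center"] = np.array([float(x) for x in parts[1:4]])
            elif parts[0] == "region_radius":
                meta["region_radius"] = float(parts[1])
            elif parts[0] == "temperature_K":
                meta["temperature"] = float(parts[1])
        else:
            body.append(line)
    ori = pd.read_csv(
        _io.StringIO("\n".join(body)), sep="\t", dtype={"frame": int, "water_id": int}
    )
    missing = [c for c in ORIENTATION_COLUMNS if c not in ori.columns]
    if missing:
        raise ValueError(f"{orientation_tsv_path}: missing column(s) {missing}")
    ori_map = {
        (int(r.frame), int(r.water_id)): np.array([r.ux, r.uy, r.uz])
        for r in ori.itertuples()
    }
    n_ori_frames = ori["frame"].nunique() if len(ori) else 0

    st = gemmi.read_structure(str(pdb_path))
    if len(st) != n_ori_frames and len(ori):
        raise ValueError(
            f"frame-count mismatch: {len(st)} PDB models vs "
            f"{n_ori_frames} frames in the orientation file"
        )
    frames = []
    max_r = 0.0
    for i, model in enumerate(st):
        wids, pos, oris = [], [], []
        solute = []
        for chain in model:
            for res in chain:
                if res.name == _WATER_RES:
                    wid = res.seqid.num - 1
                    a = res[0]
                    key = (i, wid)
                    if key not in ori_map:
                        raise ValueError(
                            f"missing orientation row for frame {i}, water_id {wid}"
                        )
                    u = ori_map[key]
                    norm = np.linalg.norm(u)
                    if abs(norm - 1.0) > 1e-3:
                        raise ValueError(
                            f"orientation of frame {i}, water_id {wid} has "
                            f"norm {norm:.4f}, not a unit vector"
                        )
                    wids.append(wid)
                    pos.append([a.pos.x, a.pos.y, a.pos.z])
                    oris.append(u / norm)
                elif res.name == _SOLUTE_RES:
                    for a in res:
                        solute.append([a.pos.x, a.pos.y, a.pos.z])
        pos_arr = np.array(pos, dtype=float).reshape(-1, 3)
        if len(pos_arr):
            r = np.linalg.norm(pos_arr - meta["region_center"], axis=1)
            max_r = max(max_r, float(r.max()))
        frames.append(
            Frame(
                water_ids=np.array(wids, dtype=int),
                positions=pos_arr,
                orientations=np.array(oris, dtype=float).reshape(-1, 3),
                solute_positions=np.array(solute, dtype=float).reshape(-1, 3)
                if solute
                else None,
            )
        )
    radius = meta["region_radius"]
    if radius is None:
        radius = max_r + 1e-6 if max_r > 0 else 1.0
    return Trajectory(
        frames=frames,
        region_center=meta["region_center"],
        region_radius=radius,
        temperature=meta["temperature"],
    )
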