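"""Plain-text I/O: extended-XYZ trajectories, energy logs, window manifests."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SlabTrajectory
from .wham import UmbrellaWindow


def write_xyz(traj: SlabTrajectory, path: str | Path) -> None:
    """Write a trajectory as extended-XYZ frames.

    The comment line carries the orthorhombic box (``Lattice=``) and the
    frame time in ps; the per-bead columns are chain id, residue index
    and x/y/z in nm.
    """
    bx, by, bz = traj.box
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(
                f'Lattice="{bx:g} 0 0 0 {by:g} 0 0 0 {bz:g}" '
                f"Properties=chain:I:1:residue:I:1:pos:R:3 time={t:g}\n"
            )
            for cid, rid, (x, y, z) in zip(
                traj.chain_id, traj.residue_index, frame
            ):
                fh.write(f"{cid} {rid} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path) -> SlabTrajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    Bead masses are not stored in the format; they are set to 1 Da, so
    mass-weighted analyses need a trajectory built in-memory instead.
    """
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    box = None
    chain_id = residue_index = None
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        lat = comment.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
        t = float(comment.split("time=")[1].split()[0])
        rows = [lines[i + 2 + k].split() for k in range(n)]
        chain_id = np.array([int(r[0]) for r in rows])
        residue_index = np.array([int(r[1]) for r in rows])
        frames.append([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
        times.append(t)
        i += 2 + n
    return SlabTrajectory(
        frames=np.asarray(frames),
        times=np.asarray(times),
        box=box,
        chain_id=chain_id,
        residue_index=residue_index,
        masses=np.ones(chain_id.size),
        temperature=float("nan"),
    )


def write_energy_log(traj: SlabTrajectory, path: str | Path) -> None:
    """CSV energy log: step,time_ps,E_pot,E_kin,T_inst."""
    log = traj.energy_log
    if log is None:
        raise ValueError("trajectory has no energy log")
    log[["step", "time_ps", "E_pot", "E_kin", "T_inst"]].to_csv(
        path, index=False
    )


def write_energy_breakdown(traj: SlabTrajectory, path: str | Path) -> None:
    """CSV per-frame energy decomposition:
    frame,hydrophobic,electrostatic,cation_pi,bonded,total."""
    log = traj.energy_log
    if log is None:
        raise ValueError("trajectory has no energy log")
    out = log[["hydrophobic", "electrostatic", "cation_pi", "bonded"]].copy()
    out.insert(0, "frame", np.arange(len(out)))
    out["total"] = log["E_pot"]
    out.to_csv(path, index=False)


def read_window_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Read umbrella windows from a manifest (one window file per line,
    relative paths resolved against the manifest's directory)."""
    mpath = Path(path)
    windows = []
    for line in mpath.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p = Path(line)
        if not p.is_absolute():
            p = mpath.parent / p
        windows.append(UmbrellaWindow.read_csv(p))
    if not windows:
        raise ValueError(f"manifest {path} lists no window files")
    return windows


def write_pmf_csv(pmf, path: str | Path) -> None:
    """CSV PMF: r_nm,pmf_kj_mol,err_kj_mol."""
    err = pmf.error if pmf.error is not None else np.full_like(pmf.grid, np.nan)
    pd.DataFrame(
        {"r_nm": pmf.grid, "pmf_kj_mol": pmf.free_energy, "err_kj_mol": err}
    ).to_csv(path, index=False)
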