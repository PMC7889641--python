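"""Langevin dynamics in periodic boxes and direct-coexistence slab runs.

The production integrator is a BAOAB-split Langevin scheme (exact
Ornstein-Uhlenbeck substep, friction gamma = 1/relaxation time).  Slab
systems for direct coexistence are built by placing chains as
self-avoiding random walks inside a central slab of an elongated box and
briefly relaxing overlaps with a capped steepest descent; a Berendsen
weak-coupling barostat is available as an optional pre-equilibration
stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .constants import BAR, KB
from .forcefield import BoundSystem, ForceField, InteractionScaling, apply_regime
from .params import ChainTopology, ResidueParamSet


@dataclass
class SystemState:
    """Instantaneous state of a multi-chain bead system."""

    positions: np.ndarray  # (N, 3) nm, wrapped into the box
    velocities: np.ndarray  # (N, 3) nm/ps
    box: np.ndarray  # (3,) nm, orthorhombic edges
    chain_id: np.ndarray  # (N,) int
    residue_index: np.ndarray  # (N,) int, 0-based within chain
    time: float = 0.0  # ps

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.box.copy(),
            self.chain_id.copy(),
            self.residue_index.copy(),
            self.time,
        )


@dataclass
class SlabTrajectory:
    """Thinned frames of an NVT production run plus run metadata."""

    frames: np.ndarray  # (F, N, 3) nm
    times: np.ndarray  # (F,) ps
    box: np.ndarray  # (3,) nm
    chain_id: np.ndarray
    residue_index: np.ndarray
    masses: np.ndarray  # (N,) Da
    temperature: float  # K (thermostat target)
    scaling: InteractionScaling | None = None
    seed: int | None = None
    timestep_fs: float | None = None
    energy_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, N, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


def _as_chain_list(
    topologies: Sequence[ChainTopology] | ChainTopology,
    counts: Sequence[int] | int,
) -> list[tuple[ChainTopology, int]]:
    if isinstance(topologies, ChainTopology):
        topologies = [topologies]
        counts = [counts]  # type: ignore[list-item]
    return [(t, int(c)) for t, c in zip(topologies, counts)]


def init_slab(
    topologies: Sequence[ChainTopology] | ChainTopology,
    counts: Sequence[int] | int,
    box: Sequence[float],
    params: ResidueParamSet,
    *,
    slab_fraction: float = 0.25,
    temperature: float = 300.0,
    min_sep_factor: float = 0.7,
    rng_seed: int = 0,
    max_retries: int = 200,
) -> SystemState:
    """Place chains as self-avoiding random walks inside a central slab.

    The slab occupies ``slab_fraction`` of the box's long axis, centered;
    the two transverse directions are filled periodically.  Inter-bead
    separations are kept above ``min_sep_factor`` times the smallest bead
    diameter.  Velocities are drawn from the Maxwell-Boltzmann
    distribution at ``temperature``.  Deterministic for a fixed seed.
    """
    chains = _as_chain_list(topologies, counts)
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive edge lengths")
    axis = int(np.argmax(box))
    if not 0 < slab_fraction <= 1:
        raise ValueError("slab_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)

    sig_min = min(params[r].sigma for t, _ in chains for r in t.sequence)
    min_sep = min_sep_factor * sig_min
    lo = 0.5 * box[axis] * (1.0 - slab_fraction)
    hi = 0.5 * box[axis] * (1.0 + slab_fraction)

    cell = max(min_sep, 1e-6)
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def cell_of(p: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(np.floor(p[d] / cell)) for d in range(3))

    def clashes(p: np.ndarray) -> bool:
        cx, cy, cz = cell_of(p)
        for ix in (cx - 1, cx, cx + 1):
            for iy in (cy - 1, cy, cy + 1):
                for iz in (cz - 1, cz, cz + 1):
                    nc = (
                        ix % max(int(box[0] / cell), 1),
                        iy % max(int(box[1] / cell), 1),
                        iz % max(int(box[2] / cell), 1),
                    )
                    for q in grid.get(nc, ()):
                        d = p - q
                        d -= box * np.rint(d / box)
                        if d @ d < min_sep * min_sep:
                            return True
        return False

    def register(p: np.ndarray) -> None:
        key = (
            cell_of(p)[0] % max(int(box[0] / cell), 1),
            cell_of(p)[1] % max(int(box[1] / cell), 1),
            cell_of(p)[2] % max(int(box[2] / cell), 1),
        )
        grid.setdefault(key, []).append(p)

    all_pos: list[np.ndarray] = []
    chain_id: list[np.ndarray] = []
    residue_index: list[np.ndarray] = []
    masses: list[np.ndarray] = []
    cid = 0
    for topo, count in chains:
        L = len(topo)
        marr = params.arrays_for(topo.sequence)["mass"]
        for _ in range(count):
            placed = None
            for _attempt in range(max_retries):
                pts = np.empty((L, 3))
                p = rng.uniform(0.0, 1.0, 3) * box
                p[axis] = rng.uniform(lo, hi)
                if clashes(p):
                    continue
                pts[0] = p
                ok = True
                for i in range(1, L):
                    placed_bead = False
                    for _b in range(60):
                        v = rng.normal(size=3)
                        v *= topo.r0 / np.linalg.norm(v)
                        q = pts[i - 1] + v
                        qa = q[axis]
                        if qa < lo - topo.r0 or qa > hi + topo.r0:
                            continue
                        qw = np.mod(q, box)
                        qw[axis] = q[axis]  # long axis is never wrapped here
                        if clashes(qw):
                            continue
                        # earlier beads of the chain are not in the grid yet
                        if i >= 2:
                            d = pts[:i - 1] - q
                            d -= box * np.rint(d / box)
                            if np.min((d**2).sum(axis=1)) < min_sep * min_sep:
                                continue
                        pts[i] = q
                        placed_bead = True
                        break
                    if not placed_bead:
                        ok = False
                        break
                if ok:
                    placed = pts
                    break
            if placed is None:
                raise RuntimeError(
                    "could not place chains at the requested density; "
                    "use a larger box or slab_fraction"
                )
            for i in range(L):
                register(np.mod(placed[i], box))
            all_pos.append(placed)
            chain_id.append(np.full(L, cid))
            residue_index.append(np.arange(L))
            masses.append(marr)
            cid += 1

    positions = np.mod(np.concatenate(all_pos), box)
    mass = np.concatenate(masses)
    vel = rng.normal(size=positions.shape) * np.sqrt(
        KB * temperature / mass
    )[:, None]
    vel -= np.average(vel, axis=0, weights=mass)
    return SystemState(
        positions=positions,
        velocities=vel,
        box=box,
        chain_id=np.concatenate(chain_id),
        residue_index=np.concatenate(residue_index),
        time=0.0,
    )


def relax_overlaps(
    state: SystemState,
    system: BoundSystem,
    *,
    n_iter: int = 300,
    max_move: float = 0.05,
    force_tol: float = 50.0,
) -> SystemState:
    """Capped steepest-descent relaxation to remove placement overlaps."""
    out = state.copy()
    box = out.box
    _kernels.relax(
        out.positions,
        box,
        *system._kernel_args(box),
        n_iter,
        max_move,
        force_tol,
    )
    return out


def _check_dt(system: BoundSystem, dt_ps: float) -> None:
    w = system.max_bond_frequency()
    if w > 0 and dt_ps > 0.1 * 2.0 * math.pi / w:
        raise ValueError(
            f"dt = {dt_ps * 1e3:.1f} fs unstable for the stiffest spring "
            f"(limit {0.1 * 2e3 * math.pi / w:.1f} fs)"
        )


def langevin_run(
    state: SystemState,
    system: BoundSystem,
    temperature: float,
    *,
    dt_fs: float = 10.0,
    friction_time_ps: float = 5.0,
    n_steps: int = 100_000,
    thin: int = 1000,
    rng_seed: int = 0,
    zero_com: bool = True,
    return_state: bool = False,
):
    """NVT Langevin production run; returns the thinned trajectory.

    Frames and energy-log rows are recorded every ``thin`` steps.  Runs
    are exactly reproducible for a fixed seed (single-threaded kernels).
    """
    dt = dt_fs * 1e-3
    _check_dt(system, dt)
    if n_steps < thin:
        raise ValueError("n_steps must be >= thin")
    st = state.copy()
    n_frames = n_steps // thin
    frames = np.empty((n_frames, system.n_beads, 3))
    frame_times = np.empty(n_frames)
    elog = np.empty((n_frames, 9))
    box = st.box.astype(float)
    status, nf = _kernels.run_langevin(
        st.positions,
        st.velocities,
        box,
        system.mass,
        system.sigma,
        system.lam,
        system.charge,
        system.catflag,
        system.excl_next,
        system.chain_id,
        system.charged_idx,
        system.bonds_i,
        system.bonds_j,
        system.bonds_r0,
        system.bonds_k,
        system.ff.eps,
        system.ff.scaling.hydro_scale,
        system.ff.scaling.cation_pi_eps,
        system.ff.hydro_cutoff,
        system.kel,
        system.inv_debye,
        system.effective_elec_cutoff(box),
        system.ff.skin,
        KB * temperature,
        KB,
        1.0 / friction_time_ps,
        dt,
        int(n_steps),
        int(thin),
        int(rng_seed),
        frames,
        frame_times,
        elog,
        float(np.min(system.sigma)),
        st.time,
        zero_com,
    )
    if status == 1:
        raise RuntimeError(
            f"integration unstable after {nf} recorded frames "
            "(per-step displacement exceeded half a bead diameter); "
            "relax the initial configuration or reduce dt"
        )
    if status == 2:
        raise RuntimeError(f"non-finite potential energy at frame {nf}")
    log = pd.DataFrame(
        elog[:nf],
        columns=[
            "step",
            "time_ps",
            "hydrophobic",
            "electrostatic",
            "cation_pi",
            "bonded",
            "E_pot",
            "E_kin",
            "T_inst",
        ],
    )
    traj = SlabTrajectory(
        frames=frames[:nf],
        times=frame_times[:nf],
        box=box.copy(),
        chain_id=st.chain_id.copy(),
        residue_index=st.residue_index.copy(),
        masses=system.mass.copy(),
        temperature=temperature,
        scaling=system.ff.scaling,
        seed=rng_seed,
        timestep_fs=dt_fs,
        energy_log=log,
    )
    if return_state:
        st.positions = np.mod(st.positions, box)
        st.time = state.time + n_steps * dt
        return traj, st
    return traj


def npt_equilibrate(
    state: SystemState,
    system: BoundSystem,
    temperature: float,
    pressure_bar: float = 1.0,
    tau_p_ps: float = 5.0,
    n_steps: int = 10_000,
    *,
    dt_fs: float = 10.0,
    friction_time_ps: float = 5.0,
    compressibility_per_bar: float = 0.2,
    n_inner: int = 20,
    rng_seed: int = 0,
) -> SystemState:
    """Berendsen weak-coupling NPT pre-equilibration (isotropic scaling).

    The instantaneous pressure P = (2 E_kin + virial) / (3 V) is coupled
    to ``pressure_bar`` with time constant ``tau_p_ps``; volume updates
    every ``n_inner`` Langevin steps.  ``tau_p_ps = inf`` leaves the
    volume unchanged.  The compressibility default is deliberately large:
    for weak coupling only the ratio kappa/tau_p sets the relaxation
    rate, and coarse-grained systems tolerate fast box relaxation.
    """
    dt = dt_fs * 1e-3
    _check_dt(system, dt)
    st = state.copy()
    p0 = pressure_bar * BAR
    mu_min, mu_max = 0.98, 1.02
    n_outer = max(n_steps // n_inner, 1)
    min_box = 2.0 * max(system.ff.hydro_cutoff, 1.0)
    for k in range(n_outer):
        traj, st = langevin_run(
            st,
            system,
            temperature,
            dt_fs=dt_fs,
            friction_time_ps=friction_time_ps,
            n_steps=n_inner,
            thin=n_inner,
            rng_seed=rng_seed + 7919 * k,
            zero_com=False,
            return_state=True,
        )
        comps, _forces, vir = system.energy_breakdown(st.positions, st.box)
        ekin = float(traj.energy_log["E_kin"].iloc[-1])
        vol = float(np.prod(st.box))
        p_inst = (2.0 * ekin + vir) / (3.0 * vol)
        if math.isinf(tau_p_ps):
            continue
        mu3 = 1.0 - compressibility_per_bar / BAR * (n_inner * dt / tau_p_ps) * (
            p0 - p_inst
        )
        mu = np.clip(mu3, mu_min**3, mu_max**3) ** (1.0 / 3.0)
        st.box = st.box * mu
        st.positions = np.mod(st.positions * mu, st.box)
        if np.min(st.box) < min_box:
            raise RuntimeError(
                f"box collapsed below twice the interaction cutoff "
                f"(edge {np.min(st.box):.2f} nm); check pressure/temperature"
            )
    return st


def default_slab_box(
    chains: list[tuple[ChainTopology, int]],
    params: ResidueParamSet,
    *,
    slab_density_mg_ml: float = 350.0,
    slab_fraction: float = 0.25,
    aspect: float = 4.0,
) -> np.ndarray:
    """Elongated box sized so the central slab holds all chains at the
    target dense-phase density."""
    from .constants import DA_PER_NM3_IN_MG_PER_ML

    mass = sum(
        params.arrays_for(t.sequence)["mass"].sum() * c for t, c in chains
    )
    v_slab = mass * DA_PER_NM3_IN_MG_PER_ML / slab_density_mg_ml
    volume = v_slab / slab_fraction
    s = (volume / aspect) ** (1.0 / 3.0)
    return np.array([s, s, aspect * s])


def run_direct_coexistence(
    topologies: Sequence[ChainTopology] | ChainTopology,
    counts: Sequence[int] | int,
    params: ResidueParamSet,
    scaling: InteractionScaling | str,
    temperatures: Sequence[float],
    *,
    protein_class: str = "fus_like",
    box: Sequence[float] | None = None,
    slab_fraction: float = 0.25,
    slab_density_mg_ml: float = 350.0,
    n_steps: int = 100_000,
    dt_fs: float = 10.0,
    friction_time_ps: float = 5.0,
    thin: int = 1000,
    rng_seed: int = 0,
    relax_iters: int = 300,
    npt_steps: int = 0,
    ff_kwargs: dict | None = None,
) -> dict[float, SlabTrajectory]:
    """Direct-coexistence pipeline: init slab -> relax -> (optional NPT)
    -> NVT production, for each temperature of the ladder.

    ``scaling`` may be an :class:`InteractionScaling` or a regime name
    (``low``/``moderate``/``high``), resolved with ``protein_class``.
    Returns a dict keyed by temperature.
    """
    chains = _as_chain_list(topologies, counts)
    if isinstance(scaling, str):
        scaling = apply_regime(scaling, protein_class)
    ff = ForceField(params=params, scaling=scaling, **(ff_kwargs or {}))
    if box is None:
        box = default_slab_box(
            chains,
            params,
            slab_density_mg_ml=slab_density_mg_ml,
            slab_fraction=slab_fraction,
        )
    out: dict[float, SlabTrajectory] = {}
    for it, temp in enumerate(temperatures):
        seed = rng_seed + 1009 * it
        state = init_slab(
            [t for t, _ in chains],
            [c for _, c in chains],
            box,
            params,
            slab_fraction=slab_fraction,
            temperature=temp,
            rng_seed=seed,
        )
        system = ff.bind(chains, positions=state.positions, box=state.box)
        state = relax_overlaps(state, system, n_iter=relax_iters)
        if npt_steps:
            state = npt_equilibrate(
                state, system, temp, n_steps=npt_steps, rng_seed=seed + 1
            )
        out[float(temp)] = langevin_run(
            state,
            system,
            temp,
            dt_fs=dt_fs,
            friction_time_ps=friction_time_ps,
            n_steps=n_steps,
            thin=thin,
            rng_seed=seed + 2,
        )
    return out
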