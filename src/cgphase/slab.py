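"""Direct-coexistence slab analysis: density profiles, coexistence
densities, LLPS classification, critical-point fits and phase-diagram
scans.

Coexistence densities are read from the time-averaged mass-density
profile along the slab axis after recentring every frame on the dense
slab; the profile is fit with a symmetric double-hyperbolic-tangent
step.  The critical point is obtained by fitting the dense/dilute
density difference to the scaling law ``delta_rho = A (1 - T/Tc)^beta``
(3D Ising beta = 0.325) jointly with the law of rectilinear diameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .constants import DA_PER_NM3_IN_MG_PER_ML
from .dynamics import SlabTrajectory, run_direct_coexistence

ISING_BETA = 0.325
DILUTE_FLOOR_MG_ML = 1e-3


@dataclass
class DensityProfile:
    """Time-averaged mass density along the slab axis."""

    centers: np.ndarray  # bin centers, nm
    density: np.ndarray  # mg/mL per bin
    axis: int
    n_frames: int
    bin_volume: float  # nm^3

    @property
    def total_mass_da(self) -> float:
        return float(
            self.density.sum() * self.bin_volume / DA_PER_NM3_IN_MG_PER_ML
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_nm": self.centers, "density_mg_ml": self.density}
        )


@dataclass
class CoexistencePoint:
    """Dilute/dense coexistence densities at one temperature."""

    temperature: float  # K
    rho_dilute: float  # mg/mL
    rho_dense: float  # mg/mL
    interface_width: float  # nm
    d_rho_dilute: float = 0.0
    d_rho_dense: float = 0.0
    from_fallback: bool = False

    def __post_init__(self) -> None:
        if self.rho_dense < self.rho_dilute - 1e-9 or self.rho_dilute < -1e-9:
            raise ValueError("need rho_dense >= rho_dilute >= 0")


@dataclass
class CriticalFit:
    """Critical-point fit result."""

    tc: float  # K
    amplitude: float  # mg/mL
    rho_c: float  # mg/mL
    diameter_slope: float  # mg/mL per K
    beta: float
    residuals: np.ndarray
    tc_ci: tuple[float, float] | None = None


def density_profile(
    traj: SlabTrajectory,
    axis: int | None = None,
    n_bins: int = 60,
    equil_fraction: float = 0.3,
) -> DensityProfile:
    """Mass-density profile along the long axis, recentred per frame.

    Each frame is shifted so the mass-weighted circular mean of the axial
    coordinate (the dense slab's center of mass under periodicity) sits
    at the box center, then bead masses are histogrammed.  The integral
    of the profile equals the total system mass exactly.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if not 0 <= equil_fraction < 1:
        raise ValueError("equil_fraction must be in [0, 1)")
    if axis is None:
        axis = int(np.argmax(traj.box))
    first = int(math.ceil(equil_fraction * traj.n_frames))
    frames = traj.frames[first:]
    if frames.shape[0] == 0:
        raise ValueError("no frames left after the equilibration cut")
    L = float(traj.box[axis])
    m = traj.masses
    hist = np.zeros(n_bins)
    edges = np.linspace(0.0, L, n_bins + 1)
    for fr in frames:
        z = np.mod(fr[:, axis], L)
        theta = 2.0 * np.pi * z / L
        com = np.arctan2(
            np.average(np.sin(theta), weights=m),
            np.average(np.cos(theta), weights=m),
        )
        shift = com * L / (2.0 * np.pi)
        zc = np.mod(z - shift + 0.5 * L, L)
        hist += np.histogram(zc, bins=edges, weights=m)[0]
    hist /= frames.shape[0]
    other = [d for d in range(3) if d != axis]
    bin_volume = (L / n_bins) * float(traj.box[other[0]] * traj.box[other[1]])
    density = hist / bin_volume * DA_PER_NM3_IN_MG_PER_ML
    centers = 0.5 * (edges[:-1] + edges[1:]) - 0.5 * L
    return DensityProfile(
        centers=centers,
        density=density,
        axis=axis,
        n_frames=frames.shape[0],
        bin_volume=bin_volume,
    )


def _double_tanh(z, rho_dil, rho_den, half_width, iface):
    return rho_dil + 0.5 * (rho_den - rho_dil) * (
        np.tanh((z + half_width) / iface) - np.tanh((z - half_width) / iface)
    )


def coexistence_densities(
    profile: DensityProfile, temperature: float = float("nan")
) -> CoexistencePoint:
    """Extract coexistence densities from a recentred slab profile.

    Fits a symmetric double-tanh step; the reported densities are plateau
    averages over bins at least two interface widths away from the two
    interfaces.  On fit failure falls back to central-20% / outer-20% bin
    averages (flagged on the returned point).
    """
    z = profile.centers
    rho = profile.density
    L = z[-1] - z[0]
    n = z.size
    central = rho[np.abs(z) <= 0.1 * L]
    outer = rho[np.abs(z) >= 0.4 * L]
    guess = [
        max(float(outer.mean()), 0.0),
        float(central.mean()),
        0.15 * L,
        0.05 * L,
    ]
    rho_max = float(rho.max())
    try:
        popt, _ = curve_fit(
            _double_tanh,
            z,
            rho,
            p0=guess,
            bounds=(
                [0.0, 0.0, 0.01 * L, 1e-3],
                [2.0 * rho_max + 1e-9, 2.0 * rho_max + 1e-9, 0.49 * L, 0.5 * L],
            ),
            maxfev=5000,
        )
        rho_dil_fit, rho_den_fit, hw, iface = popt
        # the tanh tail decays as exp(-2 z/iface): 2.5/4 interface widths
        # keep plateau contamination below ~1%
        dense_sel = np.abs(z) < hw - 2.5 * iface
        dil_sel = np.abs(z) > hw + 4.0 * iface
        if dense_sel.sum() < 2:
            # interface too wide for a clean plateau: average the most
            # central bins instead of trusting an unconstrained fit value
            dense_sel = np.abs(z) <= np.sort(np.abs(z))[3]
        if dil_sel.sum() < 2:
            dil_sel = np.abs(z) >= np.sort(np.abs(z))[-4]
        rho_den = float(rho[dense_sel].mean())
        rho_dil = float(rho[dil_sel].mean())
        d_den = float(rho[dense_sel].std() / math.sqrt(dense_sel.sum()))
        d_dil = float(rho[dil_sel].std() / math.sqrt(dil_sel.sum()))
        fallback = False
    except RuntimeError:
        rho_den = float(central.mean())
        rho_dil = float(outer.mean())
        d_den = float(central.std() / math.sqrt(central.size))
        d_dil = float(outer.std() / math.sqrt(outer.size))
        iface = float("nan")
        fallback = True
    rho_dil = max(rho_dil, 0.0)
    if rho_den < rho_dil:
        rho_den, rho_dil = rho_dil, rho_den
    return CoexistencePoint(
        temperature=temperature,
        rho_dilute=rho_dil,
        rho_dense=rho_den,
        interface_width=float(iface),
        d_rho_dilute=d_dil,
        d_rho_dense=d_den,
        from_fallback=fallback,
    )


def classify_llps(
    point: CoexistencePoint,
    ratio_threshold: float = 10.0,
    floor: float = DILUTE_FLOOR_MG_ML,
) -> bool:
    """True iff rho_dense / max(rho_dilute, floor) >= ratio_threshold.

    Inclusive at the threshold; the floor keeps empty dilute phases from
    dividing by zero.
    """
    return point.rho_dense / max(point.rho_dilute, floor) >= ratio_threshold


def _critical_sse(tc, T, drho, diam, beta):
    x = np.maximum(1.0 - T / tc, 0.0) ** beta
    denom = float(x @ x)
    if denom == 0.0:
        return np.inf, 0.0, 0.0, 0.0, None
    A = float(drho @ x) / denom
    r1 = drho - A * x
    X = np.column_stack([np.ones_like(T), tc - T])
    coef, *_ = np.linalg.lstsq(X, diam, rcond=None)
    r2 = diam - X @ coef
    return float(r1 @ r1 + r2 @ r2), A, coef[0], coef[1], np.concatenate([r1, r2])


def fit_critical_point(
    points: Sequence[CoexistencePoint],
    *,
    beta: float = ISING_BETA,
    n_boot: int = 200,
    rng_seed: int = 0,
) -> CriticalFit:
    """Joint fit of the coexistence-curve scaling law and the law of
    rectilinear diameters; Tc uncertainty by bootstrap over points.

    Needs at least three subcritical points.  The fit is one-dimensional
    in Tc: for fixed Tc the amplitude and the diameter line are linear
    least squares.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 coexistence points")
    T = np.array([p.temperature for p in points], dtype=float)
    drho = np.array([p.rho_dense - p.rho_dilute for p in points], dtype=float)
    diam = np.array([0.5 * (p.rho_dense + p.rho_dilute) for p in points], dtype=float)
    if np.all(drho == 0):
        raise ValueError("all density differences are zero; no coexistence")

    t_hi = float(T.max())
    span = max(float(T.max() - T.min()), 1.0)

    def fit_once(Ts, ds, ms):
        def obj(tc):
            return _critical_sse(tc, Ts, ds, ms, beta)[0]

        res = minimize_scalar(
            obj,
            bounds=(t_hi + 1e-6, t_hi + 3.0 * span),
            method="bounded",
            options={"xatol": 1e-4},
        )
        return float(res.x)

    tc = fit_once(T, drho, diam)
    _, A, rho_c, slope, resid = _critical_sse(tc, T, drho, diam, beta)

    ci = None
    if n_boot >= 2:
        rng = np.random.default_rng(rng_seed)
        boots = []
        tries = 0
        while len(boots) < n_boot and tries < 20 * n_boot:
            tries += 1
            idx = rng.integers(0, len(points), len(points))
            if np.unique(T[idx]).size < 3:
                continue
            boots.append(fit_once(T[idx], drho[idx], diam[idx]))
        if len(boots) >= 2:
            # basic (reverse-percentile) interval: better calibrated than the
            # raw percentile interval for this skewed, bias-prone estimator
            q_lo, q_hi = np.percentile(boots, [2.5, 97.5])
            ci = (2.0 * tc - q_hi, 2.0 * tc - q_lo)
    return CriticalFit(
        tc=tc,
        amplitude=A,
        rho_c=rho_c,
        diameter_slope=slope,
        beta=beta,
        residuals=resid,
        tc_ci=ci,
    )


def scan_phase_diagram(
    entries: Iterable[dict],
    params,
    *,
    n_seeds: int = 3,
    rng_seed: int = 0,
    ratio_threshold: float = 10.0,
    equil_fraction: float = 0.5,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run reduced direct-coexistence simulations over a condition grid
    and classify each cell as phase-separated or not.

    Each entry is a dict with keys ``protein`` (label), ``topology``,
    ``count``, ``regime`` (label), ``scaling`` (InteractionScaling or
    regime name), ``temperature`` and optionally ``protein_class`` and
    ``box``.  The LLPS call per cell is a majority vote over ``n_seeds``
    independent runs (single-run calls are flagged low-confidence in the
    output).  Returns a tidy table with columns protein, regime, T,
    rho_dilute, rho_dense, llps, n_seeds, votes.
    """
    sim_kwargs = dict(sim_kwargs or {})
    overridable = (
        "n_steps", "thin", "dt_fs", "slab_fraction", "slab_density_mg_ml",
        "friction_time_ps",
    )
    rows = []
    for ie, entry in enumerate(entries):
        kwargs = dict(sim_kwargs)
        kwargs.update({k: entry[k] for k in overridable if k in entry})
        votes = 0
        dils, dens = [], []
        for s in range(n_seeds):
            trajs = run_direct_coexistence(
                entry["topology"],
                entry["count"],
                params,
                entry["scaling"],
                [entry["temperature"]],
                protein_class=entry.get("protein_class", "fus_like"),
                box=entry.get("box"),
                rng_seed=rng_seed + 7919 * ie + 104729 * s,
                **kwargs,
            )
            traj = trajs[float(entry["temperature"])]
            prof = density_profile(traj, equil_fraction=equil_fraction)
            point = coexistence_densities(prof, entry["temperature"])
            votes += int(classify_llps(point, ratio_threshold))
            dils.append(point.rho_dilute)
            dens.append(point.rho_dense)
        rows.append(
            {
                "protein": entry["protein"],
                "regime": entry["regime"],
                "T": entry["temperature"],
                "rho_dilute": float(np.mean(dils)),
                "rho_dense": float(np.mean(dens)),
                "llps": votes * 2 > n_seeds,
                "n_seeds": n_seeds,
                "votes": votes,
                "low_confidence": n_seeds < 3,
            }
        )
    return pd.DataFrame(rows)
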