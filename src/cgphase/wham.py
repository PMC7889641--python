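"""Weighted-histogram (WHAM) reconstruction of potentials of mean force
from umbrella-sampling windows, with Bayesian-bootstrap error bands.

Each window holds scalar reaction-coordinate samples collected under a
harmonic bias ``w_k(x) = k/2 (x - c_k)^2``.  The standard self-consistent
WHAM equations are iterated on a uniform grid until the window free
energies stop changing; the PMF is ``-kB T ln rho(x)``, zeroed over a
reference range (by default the largest 10% of the grid, where pair PMFs
are expected to level off).  Statistical errors follow the Bayesian
bootstrap: whole windows are reweighted with flat-Dirichlet weights and
WHAM is re-solved per replicate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic bias."""

    center: float  # nm
    k_bias: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # nm
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k_bias <= 0:
            raise ValueError("bias force constant must be > 0")
        if self.samples.size < 1:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    def write_csv(self, path: str | Path) -> None:
        lines = ["center_nm,k_kj_mol_nm2,temperature_K"]
        lines.append(f"{self.center:g},{self.k_bias:g},{self.temperature:g}")
        lines.extend(f"{x:.8g}" for x in self.samples)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "UmbrellaWindow":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 3 or lines[0].split(",")[0] != "center_nm":
            raise ValueError(f"{path}: not a window file")
        center, k, temp = map(float, lines[1].split(","))
        samples = np.array([float(x) for x in lines[2:] if x.strip()])
        return cls(center=center, k_bias=k, samples=samples, temperature=temp)


@dataclass
class PMFProfile:
    """Free-energy profile on a grid with an error band."""

    grid: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol, NaN where no window has support
    error: np.ndarray | None = None  # kJ/mol, +- per grid point
    reference_range: tuple[float, float] | None = None
    n_iterations: int = 0
    residual_history: np.ndarray | None = None


def _check_overlap(windows: Sequence[UmbrellaWindow]) -> None:
    """Detect islands: groups of windows whose sample supports do not
    overlap with the rest."""
    spans = [(w.samples.min(), w.samples.max()) for w in windows]
    order = np.argsort([s[0] for s in spans])
    islands: list[list[int]] = [[int(order[0])]]
    hi = spans[order[0]][1]
    for idx in order[1:]:
        lo, up = spans[idx]
        if lo > hi:
            islands.append([int(idx)])
        else:
            islands[-1].append(int(idx))
        hi = max(hi, up)
    if len(islands) > 1:
        raise ValueError(
            "umbrella windows form non-overlapping islands "
            f"(by input order): {islands}"
        )


def _wham_core(
    counts: np.ndarray,  # (K, B) histogram per window
    n_eff: np.ndarray,  # (K,) effective sample counts
    bias: np.ndarray,  # (K, B) bias energy at bin centers, kJ/mol
    kT: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Self-consistent WHAM iteration in log space.

    Returns (log density per bin, window free energies f_k, iterations,
    residual history)."""
    K, B = counts.shape
    total = counts.sum(axis=0)  # (B,)
    log_total = np.where(total > 0, np.log(np.maximum(total, 1e-300)), -np.inf)
    f = np.zeros(K)
    log_n = np.log(n_eff)
    neg_bias_kT = -bias / kT  # (K, B)
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_k [ log N_k + f_k/kT - w_k/kT ]
        log_den = logsumexp(log_n[:, None] + f[:, None] / kT + neg_bias_kT, axis=0)
        log_rho = log_total - log_den
        # new f_k: -kT * logsumexp_bins [ log rho - w_k/kT ]
        f_new = -kT * logsumexp(log_rho[None, :] + neg_bias_kT, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        history.append(resid)
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {history[-1]:.3g} kJ/mol)"
        )
    log_den = logsumexp(log_n[:, None] + f[:, None] / kT + neg_bias_kT, axis=0)
    log_rho = log_total - log_den
    return log_rho, f, it, np.asarray(history)


def _prepare(windows, grid_spacing, grid):
    if not windows:
        raise ValueError("no umbrella windows")
    _check_overlap(windows)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    if grid is None:
        n_bins = max(int(math.ceil((hi - lo) / grid_spacing)), 10)
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        grid = np.asarray(grid, dtype=float)
        dz = grid[1] - grid[0]
        edges = np.concatenate([grid - 0.5 * dz, [grid[-1] + 0.5 * dz]])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    *,
    grid: np.ndarray | None = None,
    grid_spacing: float = 0.005,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    burn_in_fraction: float = 0.1,
    reference_fraction: float = 0.1,
    min_bin_count: float = 5.0,
    _window_weights: np.ndarray | None = None,
) -> PMFProfile:
    """Reconstruct the unbiased PMF from umbrella windows.

    The first ``burn_in_fraction`` of each window's samples is dropped as
    equilibration.  The PMF is zeroed over the largest
    ``reference_fraction`` of the grid (where it has support).  Windows
    may be given in any order; the result is order-invariant.
    """
    temps = {round(w.temperature, 6) for w in windows}
    if len(temps) > 1:
        raise ValueError("all windows must share one temperature")
    kT = KB * next(iter(windows)).temperature

    trimmed = []
    for w in windows:
        n0 = int(burn_in_fraction * w.samples.size)
        s = w.samples[n0:]
        if s.size == 0:
            raise ValueError("burn-in removed all samples from a window")
        trimmed.append(
            UmbrellaWindow(w.center, w.k_bias, s, w.temperature)
        )
    edges, centers = _prepare(trimmed, grid_spacing, grid)
    K = len(trimmed)
    B = centers.size
    counts = np.empty((K, B))
    n_eff = np.empty(K)
    bias = np.empty((K, B))
    for k, w in enumerate(trimmed):
        counts[k] = np.histogram(w.samples, bins=edges)[0]
        n_eff[k] = counts[k].sum()
        bias[k] = 0.5 * w.k_bias * (centers - w.center) ** 2
    if _window_weights is not None:
        ww = np.asarray(_window_weights, dtype=float) * K
        counts = counts * ww[:, None]
        n_eff = n_eff * ww
        keep = n_eff > 0
        counts, n_eff, bias = counts[keep], n_eff[keep], bias[keep]

    log_rho, f, n_iter, history = _wham_core(
        counts, n_eff, bias, kT, tol, max_iter
    )
    pmf = np.where(np.isfinite(log_rho), -kT * log_rho, np.nan)
    # bins visited only a handful of times carry no usable free-energy
    # information and would produce spurious minima at the support edges
    pmf[counts.sum(axis=0) < min_bin_count] = np.nan
    # reference-zero over the largest-r part of the grid with support
    n_ref = max(int(reference_fraction * B), 1)
    ref_sel = np.zeros(B, dtype=bool)
    ref_sel[-n_ref:] = True
    ref_vals = pmf[ref_sel & np.isfinite(pmf)]
    if ref_vals.size == 0:
        ref_vals = pmf[np.isfinite(pmf)][-n_ref:]
    pmf = pmf - float(np.mean(ref_vals))
    return PMFProfile(
        grid=centers,
        free_energy=pmf,
        reference_range=(float(centers[-n_ref]), float(centers[-1])),
        n_iterations=n_iter,
        residual_history=history,
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    rng_seed: int = 0,
    *,
    grid: np.ndarray | None = None,
    grid_spacing: float = 0.005,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    burn_in_fraction: float = 0.1,
    max_failure_fraction: float = 0.2,
) -> PMFProfile:
    """Bayesian-bootstrap error band for the WHAM PMF.

    Per replicate, whole windows are reweighted by flat Dirichlet
    weights and WHAM is re-solved; the band is the pointwise standard
    deviation across replicates.  Seed-deterministic.  Raises if more
    than ``max_failure_fraction`` of replicates fail to converge.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = wham_solve(
        windows,
        grid=grid,
        grid_spacing=grid_spacing,
        tol=tol,
        max_iter=max_iter,
        burn_in_fraction=burn_in_fraction,
    )
    rng = np.random.default_rng(rng_seed)
    reps = []
    failures = 0
    for _ in range(n_boot):
        weights = rng.dirichlet(np.ones(len(windows)))
        try:
            rep = wham_solve(
                windows,
                grid=base.grid,
                tol=tol,
                max_iter=max_iter,
                burn_in_fraction=burn_in_fraction,
                _window_weights=weights,
            )
            reps.append(rep.free_energy)
        except (RuntimeError, ValueError):
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge"
        )
    stack = np.vstack(reps)
    import warnings

    with warnings.catch_warnings():
        # grid points supported by no replicate give all-NaN columns
        warnings.simplefilter("ignore", RuntimeWarning)
        band = np.nanstd(stack, axis=0)
    return PMFProfile(
        grid=base.grid,
        free_energy=base.free_energy,
        error=band,
        reference_range=base.reference_range,
        n_iterations=base.n_iterations,
        residual_history=base.residual_history,
    )


def well_depth(
    pmf: PMFProfile,
    reference_range: tuple[float, float] | None = None,
    *,
    search_range: tuple[float, float] | None = None,
) -> tuple[float, float, bool]:
    """Depth and location of the PMF minimum relative to a reference.

    depth = min(PMF) - mean(PMF over the reference range); negative depth
    means net attraction.  ``search_range`` optionally restricts the
    minimum search to an interior interval (e.g. the contact region of a
    pair PMF, away from the noisier support edges).  Returns
    (depth, location, at_edge) where ``at_edge`` flags a minimum on the
    first or last searched grid point.
    """
    g = pmf.grid
    F = pmf.free_energy
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("PMF has no finite values")
    if reference_range is None:
        reference_range = pmf.reference_range
    if reference_range is None:
        n_ref = max(int(0.1 * g.size), 1)
        reference_range = (float(g[-n_ref]), float(g[-1]))
    lo, hi = reference_range
    ref_sel = finite & (g >= lo) & (g <= hi)
    if not ref_sel.any():
        raise ValueError("reference range has no finite PMF values")
    ref = float(F[ref_sel].mean())
    search = finite.copy()
    if search_range is not None:
        search &= (g >= search_range[0]) & (g <= search_range[1])
        if not search.any():
            raise ValueError("search range has no finite PMF values")
    idx_f = np.flatnonzero(search)
    imin = idx_f[np.argmin(F[idx_f])]
    depth = float(F[imin] - ref)
    at_edge = imin == idx_f[0] or imin == idx_f[-1]
    return depth, float(g[imin]), bool(at_edge)
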