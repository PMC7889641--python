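"""Synthetic-data generators standing in for the study's raw inputs.

These produce (i) analytic salt-dependent toy pair potentials with the
qualitative trends seen in all-atom pair PMFs — oppositely charged pairs
weaken with added salt, uncharged/hydrophobic pairs strengthen
(salting-out), arginine-arginine-like pairs switch from repulsive to
attractive, cation-aromatic hybrids dip and recover; (ii) Metropolis
samples from biased (umbrella) 1-D potentials; (iii) the study's
peptide sequences; (iv) coexistence points on a critical scaling curve;
(v) labeled near-circular droplet masks.  All generators are pure
functions of their parameters and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .constants import COULOMB_KJ_NM, KB
from .forcefield import debye_length
from .params import read_fasta
from .slab import CoexistencePoint
from .wham import UmbrellaWindow


@dataclass(frozen=True)
class ToyPairClass:
    """Analytic amino-acid pair class for salt-trend studies.

    ``coulomb_pref`` is the screened-Coulomb prefactor in kJ nm/mol
    (sign carries the charge product; the 1/(4 pi eps0 epsr) factor is
    already folded in).  The hydrophobic part is a Gaussian well whose
    depth grows linearly with salt at rate ``salting_out`` (kJ/mol per
    mol/L).  A r^-12 core keeps the potential bounded below.
    """

    name: str
    coulomb_pref: float  # kJ nm / mol
    well_depth0: float  # kJ/mol, depth at 0 M (>= 0)
    salting_out: float  # kJ/mol per mol/L (>= 0)
    well_center: float = 0.45  # nm
    well_width: float = 0.12  # nm
    rep_sigma: float = 0.33  # nm
    rep_eps: float = 1.0  # kJ/mol

    def __post_init__(self) -> None:
        if self.well_width <= 0 or self.rep_sigma <= 0:
            raise ValueError("widths must be > 0")
        if self.salting_out < 0:
            raise ValueError("salting-out coefficient must be >= 0")


_KEL_80 = COULOMB_KJ_NM / 80.0  # one unit-charge pair in water

TOY_CLASSES: dict[str, ToyPairClass] = {
    # cation-anion: Coulomb attraction that salt screens away; the net
    # trend is monotone weakening, so no salting-out term here
    "charged_opposite": ToyPairClass(
        "charged_opposite", -_KEL_80, well_depth0=1.5, salting_out=0.0
    ),
    # Arg-Arg-like: bare repulsion, pi-driven well grows with salt
    "charged_like_pi": ToyPairClass(
        "charged_like_pi", +_KEL_80, well_depth0=0.5, salting_out=1.2
    ),
    # uncharged pair strengthened by salting-out
    "hydrophobic": ToyPairClass(
        "hydrophobic", 0.0, well_depth0=3.0, salting_out=1.5
    ),
    # cation-aromatic: screened electrostatic part plus salting-out well
    "cation_pi_hybrid": ToyPairClass(
        "cation_pi_hybrid", -1.6 * _KEL_80, well_depth0=2.5, salting_out=1.2
    ),
}


def toy_pair_potential(
    r: float | np.ndarray,
    cls: ToyPairClass | str,
    salt: float,
    *,
    temperature: float = 298.15,
) -> float | np.ndarray:
    """Closed-form toy pair potential U(r) in kJ/mol at a salt
    concentration in mol/L."""
    if isinstance(cls, str):
        cls = TOY_CLASSES[cls]
    if salt < 0:
        raise ValueError("salt concentration must be >= 0")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    ld = debye_length(salt, temperature)
    inv_ld = 0.0 if math.isinf(ld) else 1.0 / ld
    core = cls.rep_eps * (cls.rep_sigma / r) ** 12
    coul = cls.coulomb_pref * np.exp(-r * inv_ld) / r
    depth = cls.well_depth0 + cls.salting_out * salt
    well = -depth * np.exp(-((r - cls.well_center) ** 2) / (2.0 * cls.well_width**2))
    out = core + coul + well
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _metropolis(xg, ug, center, k_bias, kT, n_samples, thin, burn, step, seed, lo, hi):
    np.random.seed(seed)
    x = min(max(center, lo), hi)
    u = np.interp(x, xg, ug) + 0.5 * k_bias * (x - center) ** 2
    out = np.empty(n_samples)
    n_acc = 0
    total = n_samples * thin + burn
    for i in range(total):
        xp = x + step * np.random.normal()
        if lo <= xp <= hi:
            up = np.interp(xp, xg, ug) + 0.5 * k_bias * (xp - center) ** 2
            du = up - u
            if du <= 0.0 or np.random.random() < np.exp(-du / kT):
                x = xp
                u = up
                n_acc += 1
        if i >= burn and (i - burn) % thin == thin - 1:
            out[(i - burn) // thin] = x
    return out, n_acc / total


def sample_windows_from_potential(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    *,
    k_bias: float = 6000.0,
    n_per_window: int = 5000,
    temperature: float = 298.15,
    rng_seed: int = 0,
    thin: int = 10,
    burn: int = 2000,
    support: tuple[float, float] | None = None,
) -> list[UmbrellaWindow]:
    """Metropolis-sample umbrella windows from an arbitrary 1-D potential.

    The potential is tabulated on a fine grid (piecewise-linear
    interpolant) and sampled from exp(-(U + bias)/kBT); samples are
    thinned to near-independence.  Deterministic for a fixed seed.
    """
    centers = np.sort(np.asarray(centers, dtype=float))
    kT = KB * temperature
    sd = math.sqrt(kT / k_bias)
    if support is None:
        lo = max(1e-3, centers[0] - 8.0 * sd)
        hi = centers[-1] + 8.0 * sd
    else:
        lo, hi = support
    xg = np.linspace(lo, hi, 4001)
    ug = np.asarray(potential(xg), dtype=float)
    if not np.all(np.isfinite(ug)):
        raise ValueError("potential must be finite over the sampling support")
    windows = []
    for i, c in enumerate(centers):
        samples, acc = _metropolis(
            xg,
            ug,
            float(c),
            float(k_bias),
            kT,
            int(n_per_window),
            int(thin),
            int(burn),
            1.5 * sd,
            int(rng_seed) + 65537 * i,
            lo,
            hi,
        )
        if acc == 0.0:
            raise RuntimeError(
                f"zero Metropolis acceptance in window at {c} nm; "
                "check the bias force constant"
            )
        windows.append(
            UmbrellaWindow(
                center=float(c),
                k_bias=float(k_bias),
                samples=samples,
                temperature=temperature,
            )
        )
    return windows


def sample_umbrella_windows(
    cls: ToyPairClass | str,
    salt: float,
    centers: Sequence[float] | None = None,
    k_bias: float = 6000.0,
    n_per_window: int = 5000,
    temperature: float = 298.15,
    rng_seed: int = 0,
    **kwargs,
) -> list[UmbrellaWindow]:
    """Umbrella windows over a toy pair potential at a salt concentration.

    Defaults mirror the usual pair-PMF protocol: ~30 windows spaced at
    0.05 nm from 0.1 to 1.6 nm, bias constant 6000 kJ mol^-1 nm^-2.
    """
    if centers is None:
        centers = np.arange(0.1, 1.6001, 0.05)
    return sample_windows_from_potential(
        lambda x: toy_pair_potential(x, cls, salt, temperature=temperature),
        centers,
        k_bias=k_bias,
        n_per_window=n_per_window,
        temperature=temperature,
        rng_seed=rng_seed,
        **kwargs,
    )


#: Deterministic 100-residue test sequence: a sticky prion-like-domain
#: caricature -- Tyr-rich on a Gly/Ser backbone with one Arg per repeat,
#: hence slightly net-positive.  Aromatic stickiness dominates its
#: cohesion while the arginines make the Coulomb scaling chi a genuine
#: (repulsive) lever and give the cation-pi term partners at low salt.
PLD_LIKE_UNIT = "YGSYSGYGSRYGSYGGYGSS"


def make_sequence(
    kind: str,
    fasta_path: str | Path | None = None,
    *,
    res: str | None = None,
    n: int | None = None,
) -> str:
    """Return a study sequence.

    kinds: ``PR25`` (13 Arg / 12 Pro alternating, Arg at both termini),
    ``FUS_PLD`` (residues 1-163 of a user-supplied full FUS FASTA),
    ``FUS_full`` (the supplied FASTA as-is), ``PLD_like`` (deterministic
    100-residue test sequence), ``homopolymer`` (``res`` repeated ``n``
    times).
    """
    kind_l = kind.lower()
    if kind_l == "pr25":
        seq = "RP" * 12 + "R"
        return seq
    if kind_l == "pld_like":
        return PLD_LIKE_UNIT * 5
    if kind_l == "homopolymer":
        if not res or not n:
            raise ValueError("homopolymer needs res= and n=")
        return res.upper() * int(n)
    if kind_l in ("fus_pld", "fus_full"):
        if fasta_path is None:
            raise ValueError(
                f"{kind} requires a user-supplied FASTA of full-length FUS "
                "(UniProt accession K7DPS7, 526 residues)"
            )
        name, seq = read_fasta(fasta_path)[0]
        if kind_l == "fus_pld":
            if len(seq) < 163:
                raise ValueError(
                    f"FASTA record {name!r} has {len(seq)} residues; "
                    "the prion-like domain needs residues 1-163"
                )
            return seq[:163]
        return seq
    raise ValueError(f"unknown sequence kind {kind!r}")


def synth_coexistence_points(
    tc: float,
    amplitude: float,
    beta: float,
    temps: Sequence[float],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    *,
    rho_c: float = 300.0,
    diameter_slope: float = 1.0,
) -> list[CoexistencePoint]:
    """Coexistence points on an exact critical scaling curve.

    delta_rho = amplitude (1 - T/Tc)^beta split symmetrically around the
    rectilinear diameter rho_c + slope (Tc - T); multiplicative Gaussian
    noise of relative width ``noise_sd`` is added to each density.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(temps >= tc):
        raise ValueError("all temperatures must be below Tc")
    rng = np.random.default_rng(rng_seed)
    drho = amplitude * (1.0 - temps / tc) ** beta
    diam = rho_c + diameter_slope * (tc - temps)
    dense = diam + 0.5 * drho
    dilute = diam - 0.5 * drho
    if np.any(dilute < 0):
        raise ValueError(
            "parameters give negative dilute densities; reduce amplitude "
            "or raise rho_c"
        )
    if noise_sd > 0:
        dense = dense * (1.0 + noise_sd * rng.standard_normal(temps.size))
        dilute = dilute * (1.0 + noise_sd * rng.standard_normal(temps.size))
        dilute = np.clip(dilute, 0.0, None)
        dense = np.maximum(dense, dilute)
    return [
        CoexistencePoint(
            temperature=float(t),
            rho_dilute=float(lo),
            rho_dense=float(hi),
            interface_width=float("nan"),
        )
        for t, lo, hi in zip(temps, dilute, dense)
    ]


def synth_droplet_mask(
    radii_px: Sequence[float],
    positions: Sequence[tuple[float, float]],
    image_size: tuple[int, int] = (512, 512),
    boundary_noise: float = 0.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Labeled raster of (optionally noisy-edged) disks.

    ``boundary_noise`` is the relative amplitude of a smooth random
    radial perturbation.  Returns (uint16 label mask, ground-truth table
    with label, center, radius, area and the analytic circularity).
    Droplets must lie inside the frame and must not touch.
    """
    radii = np.asarray(radii_px, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if radii.size != pos.shape[0]:
        raise ValueError("radii and positions disagree in length")
    rng = np.random.default_rng(rng_seed)
    h, w = image_size
    margin = radii * (1.0 + 3.0 * boundary_noise) + 1.0
    if np.any(pos[:, 0] - margin < 0) or np.any(pos[:, 0] + margin > h) or np.any(
        pos[:, 1] - margin < 0
    ) or np.any(pos[:, 1] + margin > w):
        raise ValueError("droplets must lie fully inside the frame")
    for i in range(radii.size):
        for j in range(i + 1, radii.size):
            gap = np.linalg.norm(pos[i] - pos[j]) - (margin[i] + margin[j])
            if gap <= 0:
                raise ValueError(f"droplets {i + 1} and {j + 1} overlap")
    mask = np.zeros((h, w), dtype=np.uint16)
    rows = []
    yy, xx = np.mgrid[0:h, 0:w]
    for lab, (r0, (cy, cx)) in enumerate(zip(radii, pos), start=1):
        dy = yy - cy
        dx = xx - cx
        dist = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        r_theta = np.full_like(dist, r0)
        modes = []
        if boundary_noise > 0:
            for m in range(2, 6):
                a = rng.normal() * boundary_noise * r0 / m
                ph = rng.uniform(0, 2 * np.pi)
                r_theta = r_theta + a * np.cos(m * theta + ph)
                modes.append((m, a, ph))
        inside = dist <= r_theta
        mask[inside] = lab
        # analytic area/perimeter of r(theta) = r0 + sum a_m cos(m theta + ph)
        area = math.pi * r0**2 + 0.5 * math.pi * sum(a**2 for _, a, _ in modes)
        perim = 2 * math.pi * r0
        if modes:
            # arc length to second order in the perturbation
            perim += (math.pi / (2 * r0)) * sum(
                (m**2 + 0) * a**2 for m, a, _ in modes
            )
        rows.append(
            {
                "label": lab,
                "center_y": cy,
                "center_x": cx,
                "radius_px": r0,
                "area_px2": area,
                "circularity": min(4 * math.pi * area / perim**2, 1.0),
            }
        )
    return mask, pd.DataFrame(rows)
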