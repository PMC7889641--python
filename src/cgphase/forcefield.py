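"""The reparameterized residue-level energy model.

Nonbonded pair interactions combine three terms:

* an Ashbaugh-Hatch hydrophobic term: a Lennard-Jones potential whose
  attractive branch is scaled by the pair hydrophobicity
  ``lambda_ij = hydro_scale * (lambda_i + lambda_j) / 2`` (with each
  residue's lambda reduced by 30% when it sits in a globular region,
  i.e. is buried), and whose repulsive core is lifted so that
  ``lambda_ij = 0`` gives a purely repulsive interaction;
* a Debye-Hueckel screened Coulomb term multiplied by the salt-regime
  parameter ``chi``;
* an optional extra Lennard-Jones well on cation x aromatic pairs that
  stands in for the enhanced cation-pi attraction at low salt.

Salt regimes are encoded as presets on :class:`InteractionScaling`:
low salt = chi 4 with the cation-pi term on, moderate = chi 2, high =
chi 1 with the hydrophobic term scaled up by 10% (FUS-like sequences)
or 30% (arginine/proline repeat peptides), where the cation-pi
attraction is subsumed by the hydrophobic up-scaling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import constants as _sc
from scipy.spatial import cKDTree

from . import _kernels
from .constants import COULOMB_KJ_NM, EPS_AH, KB
from .params import BURIED_LAMBDA_SCALE, ChainTopology, ResidueParamSet

#: Default depth of the extra cation-pi well, kJ/mol.
DEFAULT_CATION_PI_EPS = 3.0

#: Pair distances below this (nm) are treated as unphysical overlaps.
HARD_CORE_FLOOR = 0.1


@dataclass(frozen=True)
class InteractionScaling:
    """Salt-regime knobs of the energy model.

    chi multiplies the Coulomb term; hydro_scale multiplies the pair
    hydrophobicity lambda_ij; cation_pi_eps (kJ/mol) is the extra well
    depth on {R,K} x {F,W,Y} pairs (0 disables); debye_length is in nm
    (``math.inf`` for unscreened Coulomb).
    """

    chi: float = 1.0
    hydro_scale: float = 1.0
    cation_pi_eps: float = 0.0
    debye_length: float = 1.0
    rel_permittivity: float = 80.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if self.hydro_scale <= 0:
            raise ValueError("hydro_scale must be > 0")
        if self.cation_pi_eps < 0:
            raise ValueError("cation_pi_eps must be >= 0")
        if not (self.debye_length > 0):
            raise ValueError("debye_length must be > 0 (inf allowed)")
        if self.rel_permittivity <= 0 or self.temperature <= 0:
            raise ValueError("rel_permittivity and temperature must be > 0")


@dataclass(frozen=True)
class PairEnergyBreakdown:
    """Diagnostic decomposition of one pair interaction, kJ/mol."""

    hydrophobic: float
    electrostatic: float
    cation_pi: float

    @property
    def total(self) -> float:
        return self.hydrophobic + self.electrostatic + self.cation_pi


def debye_length(
    ionic_strength: float,
    temperature: float = 298.15,
    rel_permittivity: float = 80.0,
) -> float:
    """Debye screening length in nm for an ionic strength in mol/L.

    kappa^-1 = sqrt(eps0 epsr kB T / (2 NA e^2 I)); returns ``inf`` at
    I = 0 (unscreened Coulomb limit).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return math.inf
    i_si = ionic_strength * 1000.0  # mol/m^3
    lam = math.sqrt(
        _sc.epsilon_0
        * rel_permittivity
        * _sc.k
        * temperature
        / (2.0 * _sc.N_A * _sc.e**2 * i_si)
    )
    return lam * 1e9


#: Debye length used by the high-salt preset, nm.  At >3 M the physical
#: screening length is ~0.17 nm; chi = 1 with a dilute-regime Debye length
#: would leave densely charged sequences (13 Arg in PR25) dominated by
#: residual Coulomb repulsion, which contradicts the premise of the
#: high-salt regime that electrostatics are screened out.
HIGH_SALT_DEBYE_NM = 0.3

_REGIMES = {
    ("low", "fus_like"): dict(chi=4.0, hydro_scale=1.0, cation_pi=True, debye=1.0),
    ("low", "pr_like"): dict(chi=4.0, hydro_scale=1.0, cation_pi=True, debye=1.0),
    ("moderate", "fus_like"): dict(chi=2.0, hydro_scale=1.0, cation_pi=False, debye=1.0),
    ("moderate", "pr_like"): dict(chi=2.0, hydro_scale=1.0, cation_pi=False, debye=1.0),
    ("high", "fus_like"): dict(
        chi=1.0, hydro_scale=1.1, cation_pi=False, debye=HIGH_SALT_DEBYE_NM
    ),
    ("high", "pr_like"): dict(
        chi=1.0, hydro_scale=1.3, cation_pi=False, debye=HIGH_SALT_DEBYE_NM
    ),
}


def apply_regime(
    regime: str,
    protein_class: str = "fus_like",
    *,
    cation_pi_eps: float = DEFAULT_CATION_PI_EPS,
    debye_length_nm: float | None = None,
    temperature: float = 300.0,
    rel_permittivity: float = 80.0,
) -> InteractionScaling:
    """Interaction scaling preset for a salt regime.

    low -> chi 4, cation-pi on; moderate -> chi 2; high -> chi 1 with the
    hydrophobic contribution raised by 10% (fus_like) or 30% (pr_like)
    and a molar-regime Debye length (0.3 nm).  ``debye_length_nm``
    overrides the preset's screening length.
    """
    key = (regime, protein_class)
    if key not in _REGIMES:
        raise ValueError(
            f"unknown regime/class {key!r}; regimes: low, moderate, high; "
            "classes: fus_like, pr_like"
        )
    preset = _REGIMES[key]
    return InteractionScaling(
        chi=preset["chi"],
        hydro_scale=preset["hydro_scale"],
        cation_pi_eps=cation_pi_eps if preset["cation_pi"] else 0.0,
        debye_length=preset["debye"] if debye_length_nm is None else debye_length_nm,
        rel_permittivity=rel_permittivity,
        temperature=temperature,
    )


def _ah_terms(r, sij, lij, eps, rc):
    if r >= rc:
        return 0.0
    s6 = (sij / r) ** 6
    lj = 4.0 * eps * (s6 * s6 - s6)
    c6 = (sij / rc) ** 6
    ljc = 4.0 * eps * (c6 * c6 - c6)
    if r <= 2.0 ** (1.0 / 6.0) * sij:
        return lj + (1.0 - lij) * eps - lij * ljc
    return lij * (lj - ljc)


def pair_energy(
    r: float,
    res_i: str,
    res_j: str,
    params: ResidueParamSet,
    scaling: InteractionScaling,
    buried_i: bool = False,
    buried_j: bool = False,
    *,
    eps: float = EPS_AH,
    hydro_cutoff: float = 2.0,
    elec_cutoff: float | None = None,
) -> PairEnergyBreakdown:
    """Energy decomposition of a single residue pair at separation r (nm)."""
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    pi = params[res_i]
    pj = params[res_j]
    sij = 0.5 * (pi.sigma + pj.sigma)
    li = pi.lambda_h * (BURIED_LAMBDA_SCALE if buried_i else 1.0)
    lj = pj.lambda_h * (BURIED_LAMBDA_SCALE if buried_j else 1.0)
    lij = scaling.hydro_scale * 0.5 * (li + lj)
    e_h = _ah_terms(r, sij, lij, eps, hydro_cutoff)

    if elec_cutoff is None:
        elec_cutoff = min(3.5 * scaling.debye_length, 3.5)
    qq = pi.charge * pj.charge
    e_el = 0.0
    if qq != 0.0 and scaling.chi > 0.0 and r < elec_cutoff:
        pref = scaling.chi * qq * COULOMB_KJ_NM / scaling.rel_permittivity
        inv_ld = 0.0 if math.isinf(scaling.debye_length) else 1.0 / scaling.debye_length
        e_el = pref * math.exp(-r * inv_ld) / r - pref * math.exp(
            -elec_cutoff * inv_ld
        ) / elec_cutoff

    e_cp = 0.0
    cross = (pi.is_cation and pj.is_aromatic) or (pj.is_cation and pi.is_aromatic)
    if scaling.cation_pi_eps > 0.0 and cross and r < hydro_cutoff:
        s6 = (sij / r) ** 6
        c6 = (sij / hydro_cutoff) ** 6
        e_cp = 4.0 * scaling.cation_pi_eps * (
            (s6 * s6 - s6) - (c6 * c6 - c6)
        )
    return PairEnergyBreakdown(e_h, e_el, e_cp)


@dataclass
class ForceField:
    """Residue parameter set plus interaction scaling and numerical knobs.

    ``bind`` attaches the force field to a concrete multi-chain system,
    producing the flat per-bead arrays the kernels consume.
    """

    params: ResidueParamSet
    scaling: InteractionScaling
    eps: float = EPS_AH
    hydro_cutoff: float = 2.0
    elec_cutoff_factor: float = 3.5
    elec_cutoff_cap: float = 3.5
    en_cutoff: float = 0.9  # elastic-network spring range inside globular regions, nm
    en_k: float = 500.0  # elastic-network spring constant, kJ mol^-1 nm^-2
    skin: float = 0.3  # Verlet-list skin, nm

    @property
    def elec_cutoff(self) -> float:
        if math.isinf(self.scaling.debye_length):
            return self.elec_cutoff_cap
        return min(self.elec_cutoff_factor * self.scaling.debye_length,
                   self.elec_cutoff_cap)

    def with_scaling(self, scaling: InteractionScaling) -> "ForceField":
        return replace(self, scaling=scaling)

    def bind(
        self,
        chains: Sequence[tuple[ChainTopology, int]],
        positions: np.ndarray | None = None,
        box: np.ndarray | None = None,
    ) -> "BoundSystem":
        """Expand ``(topology, count)`` pairs into a :class:`BoundSystem`.

        ``positions``/``box`` are only needed when any chain has globular
        regions: the elastic network that keeps those regions compact is
        built from distances in the supplied configuration.
        """
        return BoundSystem(self, list(chains), positions, box)


class BoundSystem:
    """A force field bound to a concrete set of chains (flat bead arrays)."""

    def __init__(
        self,
        ff: ForceField,
        chains: list[tuple[ChainTopology, int]],
        positions: np.ndarray | None = None,
        box: np.ndarray | None = None,
    ):
        if not chains:
            raise ValueError("no chains")
        self.ff = ff
        self.chains = chains
        mass, charge, sigma, lam, cat, aro = [], [], [], [], [], []
        chain_id, residue_index = [], []
        excl_next = []
        bonds_i: list[int] = []
        bonds_j: list[int] = []
        bonds_r0: list[float] = []
        bonds_k: list[float] = []
        glob_ranges: list[tuple[int, int]] = []  # bead index ranges, globular
        offset = 0
        cid = 0
        for topo, count in chains:
            arr = ff.params.arrays_for(topo.sequence)
            gmask = topo.globular_mask()
            L = len(topo)
            lam_eff = arr["lambda_h"] * np.where(gmask, BURIED_LAMBDA_SCALE, 1.0)
            for _ in range(count):
                mass.append(arr["mass"])
                charge.append(arr["charge"])
                sigma.append(arr["sigma"])
                lam.append(lam_eff)
                cat.append(arr["is_cation"])
                aro.append(arr["is_aromatic"])
                chain_id.append(np.full(L, cid))
                residue_index.append(np.arange(L))
                e = np.zeros(L, dtype=bool)
                e[: L - 1] = True
                excl_next.append(e)
                for i, j in topo.bonds:
                    bonds_i.append(offset + i)
                    bonds_j.append(offset + j)
                    bonds_r0.append(topo.r0)
                    bonds_k.append(topo.bond_k)
                for start, end, kind in topo.regions:
                    if kind == "globular":
                        glob_ranges.append((offset + start - 1, offset + end))
                offset += L
                cid += 1
        self.n_beads = offset
        self.mass = np.concatenate(mass)
        self.charge = np.concatenate(charge)
        self.sigma = np.concatenate(sigma)
        self.lam = np.concatenate(lam)
        self.chain_id = np.concatenate(chain_id).astype(np.int64)
        self.residue_index = np.concatenate(residue_index).astype(np.int64)
        self.excl_next = np.concatenate(excl_next)
        catflag = np.zeros(offset, dtype=np.int64)
        catflag[np.concatenate(cat)] = 1
        catflag[np.concatenate(aro)] = 2
        self.catflag = catflag
        self.charged_idx = np.flatnonzero(self.charge != 0.0).astype(np.int64)

        if glob_ranges:
            if positions is None or box is None:
                raise ValueError(
                    "chains with globular regions need positions and box at "
                    "bind time to build the intra-region elastic network"
                )
            for a, b in glob_ranges:
                sub = np.asarray(positions[a:b], dtype=float)
                for i in range(sub.shape[0]):
                    for j in range(i + 2, sub.shape[0]):
                        d = sub[i] - sub[j]
                        d -= box * np.rint(d / box)
                        r = float(np.linalg.norm(d))
                        if r < ff.en_cutoff:
                            bonds_i.append(a + i)
                            bonds_j.append(a + j)
                            bonds_r0.append(r)
                            bonds_k.append(ff.en_k)
        self.bonds_i = np.asarray(bonds_i, dtype=np.int64)
        self.bonds_j = np.asarray(bonds_j, dtype=np.int64)
        self.bonds_r0 = np.asarray(bonds_r0, dtype=float)
        self.bonds_k = np.asarray(bonds_k, dtype=float)

    # -- scalar kernel parameters -------------------------------------
    @property
    def kel(self) -> float:
        s = self.ff.scaling
        return s.chi * COULOMB_KJ_NM / s.rel_permittivity

    @property
    def inv_debye(self) -> float:
        ld = self.ff.scaling.debye_length
        return 0.0 if math.isinf(ld) else 1.0 / ld

    def effective_elec_cutoff(self, box: np.ndarray) -> float:
        """Electrostatic cutoff, reduced if the box is too small for the
        minimum-image convention at the nominal cutoff."""
        rc = self.ff.elec_cutoff
        limit = 0.5 * float(np.min(box)) - self.ff.skin - 1e-9
        return max(min(rc, limit), 0.5)

    def max_bond_frequency(self) -> float:
        """Largest harmonic angular frequency (1/ps), for dt stability checks."""
        if self.bonds_i.size == 0:
            return 0.0
        mu = 1.0 / (
            1.0 / self.mass[self.bonds_i] + 1.0 / self.mass[self.bonds_j]
        )
        return float(np.sqrt(np.max(self.bonds_k / mu)))

    def _kernel_args(self, box: np.ndarray):
        ff = self.ff
        s = ff.scaling
        return (
            self.excl_next,
            self.chain_id,
            self.charged_idx,
            self.bonds_i,
            self.bonds_j,
            self.bonds_r0,
            self.bonds_k,
            self.sigma,
            self.lam,
            self.charge,
            self.catflag,
            ff.eps,
            s.hydro_scale,
            s.cation_pi_eps,
            ff.hydro_cutoff,
            self.kel,
            self.inv_debye,
            self.effective_elec_cutoff(box),
        )

    def check_overlaps(self, positions: np.ndarray, box: np.ndarray) -> None:
        wrapped = np.mod(positions, box)
        tree = cKDTree(wrapped, boxsize=box)
        for i, j in sorted(map(sorted, tree.query_pairs(HARD_CORE_FLOOR))):
            if j == i + 1 and self.excl_next[i]:
                continue
            raise ValueError(
                f"beads {i} and {j} overlap below the hard-core floor "
                f"({HARD_CORE_FLOOR} nm)"
            )

    def energy_breakdown(
        self, positions: np.ndarray, box: np.ndarray, check_overlap: bool = False
    ) -> tuple[dict[str, float], np.ndarray, float]:
        """Return (component energies, forces, virial)."""
        positions = np.ascontiguousarray(positions, dtype=float)
        box = np.ascontiguousarray(box, dtype=float)
        if check_overlap:
            self.check_overlaps(positions, box)
        forces, e_h, e_el, e_cp, e_b, vir = _kernels.energy_forces(
            positions, box, *self._kernel_args(box)
        )
        comps = {
            "hydrophobic": e_h,
            "electrostatic": e_el,
            "cation_pi": e_cp,
            "bonded": e_b,
            "total": e_h + e_el + e_cp + e_b,
        }
        return comps, forces, vir

    def energy_forces(
        self, positions: np.ndarray, box: np.ndarray, check_overlap: bool = False
    ) -> tuple[float, np.ndarray]:
        comps, forces, _ = self.energy_breakdown(positions, box, check_overlap)
        return comps["total"], forces


def system_energy_forces(
    positions: np.ndarray,
    box: np.ndarray,
    topologies: Iterable[ChainTopology | tuple[ChainTopology, int]],
    params: ResidueParamSet,
    scaling: InteractionScaling,
    **ff_kwargs,
) -> tuple[float, np.ndarray]:
    """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm).

    ``topologies`` is either one ChainTopology per chain or
    ``(topology, count)`` pairs.  Results are independent of neighbor-list
    bookkeeping: the pair list is built fresh at the interaction cutoffs.
    """
    chains: list[tuple[ChainTopology, int]] = []
    for t in topologies:
        if isinstance(t, ChainTopology):
            chains.append((t, 1))
        else:
            chains.append((t[0], int(t[1])))
    ff = ForceField(params=params, scaling=scaling, **ff_kwargs)
    system = ff.bind(chains, positions=positions, box=np.asarray(box, dtype=float))
    return system.energy_forces(
        np.asarray(positions, dtype=float),
        np.asarray(box, dtype=float),
        check_overlap=True,
    )
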