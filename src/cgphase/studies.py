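"""Frozen desk-scale study definitions for the salt-regime phase scan.

These are reduced direct-coexistence systems sized so a full reentrance
scan runs on one CPU in minutes: chains are shorter and fewer than in a
production condensate simulation, the Langevin coupling is weak (50 ps)
to accelerate configurational sampling (the equilibrium ensemble is
unchanged), the initial slab is built loose (250 mg/mL) so that
conditions that should not phase-separate melt within the run, and each
condition is decided by a majority vote over independent seeds.  Scan
temperatures sit between the melting points of the conditions that must
and must not phase-separate, estimated beforehand from temperature
ladders of the same reduced systems — the usual direct-coexistence
practice of simulating just below the relevant critical points.
"""
from __future__ import annotations

from .params import build_topology
from .synthetic import make_sequence

#: Langevin relaxation time used for the reduced scans, ps.
SCAN_FRICTION_TIME_PS = 50.0
SCAN_N_STEPS = 120_000
SCAN_THIN = 2_500
SCAN_SLAB_FRACTION = 0.45
SCAN_SLAB_DENSITY_MG_ML = 250.0
SCAN_EQUIL_FRACTION = 0.6

#: Scan temperature for the FUS-like system, K.
FUS_LIKE_T = 330.0
#: Scan temperature for the PR25 system, K.
PR25_T = 140.0


def fus_like_entries(temperature: float = FUS_LIKE_T) -> list[dict]:
    """Reduced FUS-like scan: 10 chains of a 60-residue aromatic-rich,
    slightly net-positive prion-like-domain caricature across the three
    salt regimes.

    Expected pattern (reentrance): low -> LLPS, moderate -> no LLPS,
    high -> LLPS.
    """
    seq = make_sequence("PLD_like")[:60]
    topo = build_topology(seq, name="pld_like_60")
    return [
        dict(
            protein="fus_like",
            topology=topo,
            count=10,
            regime=regime,
            scaling=regime,
            protein_class="fus_like",
            temperature=temperature,
        )
        for regime in ("low", "moderate", "high")
    ]


def pr25_entries(temperature: float = PR25_T) -> list[dict]:
    """Reduced arginine/proline-repeat scan: 20 PR25 peptides at low and
    high salt.  Expected pattern: low -> no LLPS (Arg-Arg repulsion),
    high -> LLPS (screened charges plus 30% stronger hydrophobicity).

    Unlike the FUS-like scan this one starts from a regular dense slab:
    the condition that must not phase-separate melts by outright
    Coulomb repulsion, and a loose start at the low scan temperature
    would risk freezing multi-droplet configurations instead."""
    topo = build_topology(make_sequence("PR25"), name="PR25")
    return [
        dict(
            protein="PR25",
            topology=topo,
            count=20,
            regime=regime,
            scaling=regime,
            protein_class="pr_like",
            temperature=temperature,
            n_steps=80_000,
            slab_fraction=0.35,
            slab_density_mg_ml=350.0,
        )
        for regime in ("low", "high")
    ]


def scan_kwargs() -> dict:
    """Simulation keyword arguments shared by the reduced scans."""
    return dict(
        n_steps=SCAN_N_STEPS,
        thin=SCAN_THIN,
        slab_fraction=SCAN_SLAB_FRACTION,
        slab_density_mg_ml=SCAN_SLAB_DENSITY_MG_ML,
        friction_time_ps=SCAN_FRICTION_TIME_PS,
    )


EXPECTED_PATTERN = {
    ("fus_like", "low"): True,
    ("fus_like", "moderate"): False,
    ("fus_like", "high"): True,
    ("PR25", "low"): False,
    ("PR25", "high"): True,
}
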