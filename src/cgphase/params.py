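"""Residue parameter tables, FASTA ingestion and chain topology construction.

The model keeps one bead per amino acid.  Each residue carries a mass (Da),
a signed charge (elementary charges), a bead diameter sigma (nm) and a
hydrophobicity lambda on a 0-1 scale; arginine/lysine are flagged cationic
and Phe/Trp/Tyr aromatic, which is what the cation-pi term of the force
field keys on.  Chains are annotated with disordered and globular regions;
globular residues are the ones whose hydrophobicity is scaled down by 30%
to account for burial.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
CATIONIC = frozenset("RK")
AROMATIC = frozenset("FWY")

#: Factor applied to the hydrophobicity of residues inside globular regions.
BURIED_LAMBDA_SCALE = 0.7


@dataclass(frozen=True)
class ResidueParams:
    """Parameters of a single residue bead."""

    mass: float  # Da
    charge: float  # elementary charges
    sigma: float  # nm
    lambda_h: float  # dimensionless, 0-1
    is_cation: bool
    is_aromatic: bool


class ResidueParamSet:
    """Per-amino-acid parameter table for the twenty canonical residues.

    Validates completeness and value ranges on construction; lookup is by
    one-letter code.
    """

    def __init__(self, table: dict[str, ResidueParams]):
        missing = [r for r in CANONICAL_RESIDUES if r not in table]
        if missing:
            raise ValueError(
                f"residue parameter table is missing residue(s): {', '.join(missing)}"
            )
        extra = [r for r in table if r not in CANONICAL_RESIDUES]
        if extra:
            raise ValueError(f"non-canonical residue row(s): {', '.join(extra)}")
        for res, p in table.items():
            if not 0.0 <= p.lambda_h <= 1.0:
                raise ValueError(
                    f"lambda for residue {res} is {p.lambda_h}, outside [0, 1]"
                )
            if p.sigma <= 0:
                raise ValueError(f"sigma for residue {res} must be positive")
            if p.mass <= 0:
                raise ValueError(f"mass for residue {res} must be positive")
            if res != "H" and p.charge not in (-1.0, 0.0, 1.0):
                raise ValueError(
                    f"charge for residue {res} must be -1, 0 or +1 (got {p.charge})"
                )
        self._table = dict(table)

    def __getitem__(self, res: str) -> ResidueParams:
        try:
            return self._table[res]
        except KeyError:
            raise KeyError(f"unknown residue code {res!r}") from None

    def __contains__(self, res: str) -> bool:
        return res in self._table

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueParamSet) and self._table == other._table

    def residues(self) -> list[str]:
        return sorted(self._table)

    def arrays_for(self, sequence: str) -> dict[str, np.ndarray]:
        """Vectorized parameter lookup for a residue string."""
        rows = [self[r] for r in sequence]
        return {
            "mass": np.array([p.mass for p in rows]),
            "charge": np.array([p.charge for p in rows]),
            "sigma": np.array([p.sigma for p in rows]),
            "lambda_h": np.array([p.lambda_h for p in rows]),
            "is_cation": np.array([p.is_cation for p in rows], dtype=bool),
            "is_aromatic": np.array([p.is_aromatic for p in rows], dtype=bool),
        }

    def with_charge(self, res: str, charge: float) -> "ResidueParamSet":
        """Return a copy with one residue's charge replaced (e.g. His +1)."""
        p = self[res]
        table = dict(self._table)
        table[res] = ResidueParams(
            p.mass, float(charge), p.sigma, p.lambda_h, p.is_cation, p.is_aromatic
        )
        return ResidueParamSet(table)

    def write_table(self, path: str | Path) -> None:
        lines = ["res\tmass\tcharge\tsigma\tlambda"]
        for res in sorted(self._table):
            p = self._table[res]
            lines.append(
                f"{res}\t{p.mass:g}\t{p.charge:g}\t{p.sigma:g}\t{p.lambda_h:g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def load_residue_params(
    table_path: str | Path | None = None, *, his_charge: float = 0.0
) -> ResidueParamSet:
    """Load a residue parameter table (tab-separated, header
    ``res mass charge sigma lambda``).

    With no path the bundled default table is used (the Kapcha-Rossky-derived
    hydrophobicity-scale parameter set standard for this residue-level model
    family).  ``his_charge`` switches histidine to +1 for low-pH work; the
    default keeps it neutral, appropriate near pH 7.
    """
    if table_path is None:
        text = (
            resources.files("cgphase").joinpath("data/hps_params.tsv").read_text()
        )
    else:
        text = Path(table_path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty residue parameter table")
    header = lines[0].split()
    expected = ["res", "mass", "charge", "sigma", "lambda"]
    if header != expected:
        raise ValueError(
            f"bad residue table header {header!r}; expected {expected!r}"
        )
    table: dict[str, ResidueParams] = {}
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 5:
            raise ValueError(f"malformed residue row: {ln!r}")
        res = parts[0].upper()
        mass, charge, sigma, lam = map(float, parts[1:])
        table[res] = ResidueParams(
            mass=mass,
            charge=charge,
            sigma=sigma,
            lambda_h=lam,
            is_cation=res in CATIONIC,
            is_aromatic=res in AROMATIC,
        )
    ps = ResidueParamSet(table)
    if his_charge:
        ps = ps.with_charge("H", his_charge)
    return ps


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file into ``(name, sequence)`` pairs.

    Sequences are uppercased; any letter outside the twenty canonical
    one-letter codes raises with the record name and 1-based offset.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out: list[tuple[str, str]] = []
    allowed = set(CANONICAL_RESIDUES)
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"record {rec.id!r}: illegal residue {ch!r} at position {i + 1}"
                )
        out.append((rec.id, seq))
    return out


@dataclass
class ChainTopology:
    """Sequence plus bonded structure and region annotations for one chain.

    ``bonds`` connect consecutive residues (0-based indices) with harmonic
    springs of rest length ``r0`` (nm) and constant ``bond_k``
    (kJ mol^-1 nm^-2).  ``regions`` are (start, end, kind) triples in
    1-based inclusive residue coordinates tiling [1, L]; kind is either
    ``"disordered"`` or ``"globular"``.
    """

    name: str
    sequence: str
    r0: float
    bond_k: float
    regions: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L < 1:
            raise ValueError("empty sequence")
        bad = [c for c in self.sequence if c not in CANONICAL_RESIDUES]
        if bad:
            raise ValueError(f"non-canonical residues in sequence: {sorted(set(bad))}")
        if self.r0 < 0 or self.bond_k < 0:
            raise ValueError("r0 and bond_k must be non-negative")
        self._validate_regions()

    def _validate_regions(self) -> None:
        L = len(self.sequence)
        if not self.regions:
            self.regions = [(1, L, "disordered")]
        regs = sorted(self.regions)
        pos = 1
        for start, end, kind in regs:
            if kind not in ("disordered", "globular"):
                raise ValueError(f"unknown region kind {kind!r}")
            if start < 1 or end > L or end < start:
                raise ValueError(f"region ({start}, {end}) outside [1, {L}]")
            if start < pos:
                raise ValueError(f"overlapping regions at residue {start}")
            if start > pos:
                raise ValueError(f"regions do not tile the chain: gap before {start}")
            pos = end + 1
        if pos != L + 1:
            raise ValueError(f"regions do not tile the chain: gap after {pos - 1}")
        self.regions = regs

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        """Consecutive-residue bond list, 0-based."""
        return [(i, i + 1) for i in range(len(self.sequence) - 1)]

    def globular_mask(self) -> np.ndarray:
        """Boolean per-residue mask, True inside globular regions (0-based)."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for start, end, kind in self.regions:
            if kind == "globular":
                mask[start - 1 : end] = True
        return mask

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "name": self.name,
                "sequence": self.sequence,
                "r0": self.r0,
                "bond_k": self.bond_k,
                "regions": [list(r) for r in self.regions],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ChainTopology":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            name=d["name"],
            sequence=d["sequence"],
            r0=d["r0"],
            bond_k=d["bond_k"],
            regions=[tuple(r) for r in d["regions"]],
        )


def build_topology(
    sequence: str,
    globular_ranges: Iterable[tuple[int, int]] | None = None,
    r0: float = 0.38,
    *,
    bond_k: float = 1000.0,
    name: str = "chain",
) -> ChainTopology:
    """Build a chain topology from a sequence and optional globular ranges.

    ``globular_ranges`` are 1-based inclusive; everything not covered is
    marked disordered.  The chain gets L-1 consecutive harmonic bonds at
    rest length ``r0`` nm.
    """
    sequence = sequence.upper()
    L = len(sequence)
    ranges = sorted(tuple(r) for r in (globular_ranges or []))
    regions: list[tuple[int, int, str]] = []
    pos = 1
    for start, end in ranges:
        if start < 1 or end > L:
            raise ValueError(f"globular range ({start}, {end}) exceeds chain [1, {L}]")
        if start < pos:
            raise ValueError(f"overlapping globular ranges at residue {start}")
        if start > pos:
            regions.append((pos, start - 1, "disordered"))
        regions.append((start, end, "globular"))
        pos = end + 1
    if pos <= L:
        regions.append((pos, L, "disordered"))
    return ChainTopology(
        name=name, sequence=sequence, r0=r0, bond_k=bond_k, regions=regions
    )
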