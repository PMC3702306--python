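"""Residue mass tables and neutral/ionic mass arithmetic.

Three conventions are supported:

``monoisotopic``
    Lightest-isotope residue masses; the default for theoretical fragment
    ladders and precursor m/z, since instrument-reported values track
    monoisotopic theory within the stated product tolerances.
``average``
    Abundance-weighted mean residue masses.
``paper_legend``
    Average residue masses rounded to 2 decimals with a nominal 80.00 Da
    phosphate, the convention used in hand-checked spectrum-legend
    arithmetic (e.g. S + P = 87.08 + 97.12 = 184.20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TableKind",
    "MassTable",
    "Modification",
    "Peptide",
    "build_mass_table",
    "load_mass_table",
    "phospho",
    "peptide_neutral_mass",
    "mz",
    "STANDARD_RESIDUES",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses, Da.
_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average residue masses, Da.
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

_PROTON = 1.007276  # charge carrier, not 1.008


class TableKind(str, Enum):
    monoisotopic = "monoisotopic"
    average = "average"
    paper_legend = "paper_legend"


@dataclass(frozen=True)
class MassTable:
    """Residue masses plus the constants needed for fragment-ion arithmetic.

    ``z_dot_constant`` is the neutral-mass offset of a z• radical fragment
    over its residue sum (H2O − NH3 + H); ``phospho_delta`` the HPO3
    addition on S/T/Y.
    """

    kind: TableKind
    residue_mass: Mapping[str, float]
    water: float
    ammonia: float
    proton: float
    z_dot_constant: float
    phospho_delta: float

    def __post_init__(self) -> None:
        missing = [r for r in STANDARD_RESIDUES if r not in self.residue_mass]
        if missing:
            raise ValueError(f"mass table missing residues: {missing}")
        bad = [r for r, m in self.residue_mass.items() if not m > 0]
        if bad:
            raise ValueError(f"non-positive residue masses: {bad}")

    def mass_of(self, residue: str) -> float:
        try:
            return self.residue_mass[residue]
        except KeyError:
            raise ValueError(f"residue {residue!r} not in {self.kind.value} table") from None

    def sum_residues(self, sequence: str) -> float:
        return sum(self.mass_of(r) for r in sequence)


@dataclass(frozen=True)
class Modification:
    """A covalent mass delta at a 1-based position within a peptide."""

    name: str
    delta: float
    allowed_residues: frozenset[str]
    position: int

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("modification delta must be nonzero")
        if self.position < 1:
            raise ValueError("modification position is 1-based")


def phospho(position: int, delta: float | None = None) -> Modification:
    """Phosphorylation (+HPO3) on S, T or Y at ``position`` (1-based).

    ``delta`` defaults to the monoisotopic 79.96633 Da; pass the table's
    ``phospho_delta`` to stay consistent with another convention.
    """
    d = 79.966331 if delta is None else delta
    return Modification("phospho", d, frozenset("STY"), position)


@dataclass(frozen=True)
class Peptide:
    """A peptide located in its parent protein (1-based, inclusive coords)."""

    sequence: str
    protein_id: str = ""
    protein_start: int = 1
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
        if self.protein_start < 1:
            raise ValueError("protein_start is 1-based")
        positions = [m.position for m in self.modifications]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate modification positions")
        for m in self.modifications:
            if m.position > len(self.sequence):
                raise ValueError(
                    f"modification at {m.position} beyond peptide length {len(self.sequence)}"
                )
            r = self.sequence[m.position - 1]
            if m.allowed_residues and r not in m.allowed_residues:
                raise ValueError(f"{m.name} not allowed on residue {r} at {m.position}")

    def __len__(self) -> int:
        return len(self.sequence)

    def protein_coord(self, position: int) -> int:
        """Map a 1-based peptide position to its protein residue coordinate."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(f"position {position} outside peptide")
        return self.protein_start + position - 1

    @property
    def protein_end(self) -> int:
        return self.protein_start + len(self.sequence) - 1

    def with_modifications(self, mods: Iterable[Modification]) -> "Peptide":
        return replace(self, modifications=tuple(mods))

    def site_label(self, position: int) -> str:
        """Protein-coordinate residue label, e.g. ``S320``."""
        return f"{self.sequence[position - 1]}{self.protein_coord(position)}"


def build_mass_table(kind: TableKind | str) -> MassTable:
    """Return the complete mass table for one of the three conventions."""
    try:
        kind = TableKind(kind)
    except ValueError:
        raise ValueError(
            f"unknown mass table kind {kind!r}; expected one of "
            f"{[k.value for k in TableKind]}"
        ) from None
    if kind is TableKind.monoisotopic:
        return MassTable(
            kind=kind,
            residue_mass=dict(_MONO),
            water=18.010565,
            ammonia=17.026549,
            proton=_PROTON,
            z_dot_constant=18.010565 - 17.026549 + 1.007825,
            phospho_delta=79.966331,
        )
    if kind is TableKind.average:
        return MassTable(
            kind=kind,
            residue_mass=dict(_AVG),
            water=18.01528,
            ammonia=17.03052,
            proton=_PROTON,
            z_dot_constant=18.01528 - 17.03052 + 1.00794,
            phospho_delta=79.9799,
        )
    return MassTable(
        kind=TableKind.paper_legend,
        residue_mass={r: round(m, 2) for r, m in _AVG.items()},
        water=18.02,
        ammonia=17.03,
        proton=_PROTON,
        z_dot_constant=1.99,
        phospho_delta=80.00,
    )


def load_mass_table(path: str | Path, base: TableKind | str = TableKind.monoisotopic) -> MassTable:
    """Load a mass table from a plain-text ``key = value`` file.

    Recognised keys: ``kind`` (base convention to start from), ``water``,
    ``ammonia``, ``proton``, ``z_dot_constant``, ``phospho_delta`` and
    ``residue.X`` for single-letter residue overrides. Unlisted values fall
    back to the built-in table for the base convention.
    """
    overrides: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        overrides[key] = value
    kind = overrides.pop("kind", None)
    table = build_mass_table(kind if kind is not None else base)
    residues = dict(table.residue_mass)
    scalars: dict[str, float] = {}
    for key, value in overrides.items():
        if key.startswith("residue."):
            residues[key.split(".", 1)[1]] = float(value)
        elif key in ("water", "ammonia", "proton", "z_dot_constant", "phospho_delta"):
            scalars[key] = float(value)
        else:
            raise ValueError(f"unknown mass-table key {key!r} in {path}")
    return replace(table, residue_mass=residues, **scalars)


def peptide_neutral_mass(peptide: Peptide, table: MassTable) -> float:
    """Neutral (uncharged) peptide mass: residues + water + modification deltas."""
    return (
        table.sum_residues(peptide.sequence)
        + table.water
        + sum(m.delta for m in peptide.modifications)
    )


def mz(neutral: float, z: int, table: MassTable) -> float:
    """m/z of a neutral mass protonated ``z`` times."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral + z * table.proton) / z
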