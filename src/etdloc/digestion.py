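"""In-silico tryptic digestion and phosphoform enumeration.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline. Peptides with up to ``max_missed_cleavages`` internal uncut K/R
sites are enumerated, mirroring a conventional database-search space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .masses import (
    MassTable,
    Modification,
    Peptide,
    STANDARD_RESIDUES,
    mz,
    peptide_neutral_mass,
    phospho,
)

__all__ = [
    "Protein",
    "DigestParams",
    "cleavage_sites",
    "digest",
    "enumerate_phosphoforms",
    "find_peptide",
]


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"protein {self.id!r}: non-standard residues {sorted(bad)}")


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 1
    max_length: int = 100

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValueError("max_missed_cleavages must be in 0..5")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("require 1 <= min_length <= max_length")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between residues i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(protein: Protein, params: DigestParams = DigestParams()) -> list[Peptide]:
    """Fully tryptic peptides of ``protein`` within the length/missed limits.

    Returned peptides carry 1-based ``protein_start`` coordinates and are
    ordered by start, then length.
    """
    seq = protein.sequence
    # segment boundaries: cut positions plus both termini
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides: list[Peptide] = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(bounds))):
            sub = seq[bounds[a] : bounds[b]]
            if params.min_length <= len(sub) <= params.max_length:
                peptides.append(
                    Peptide(sub, protein_id=protein.id, protein_start=bounds[a] + 1)
                )
    peptides.sort(key=lambda p: (p.protein_start, len(p.sequence)))
    return peptides


def enumerate_phosphoforms(peptide: Peptide, n_phospho: int, delta: float | None = None) -> list[Peptide]:
    """All placements of exactly ``n_phospho`` phosphates on S/T/Y.

    Returns one peptide per combination, ordered by ascending position
    tuple; empty when the peptide has fewer than ``n_phospho`` acceptor
    residues. ``n_phospho = 0`` returns the peptide itself.
    """
    if n_phospho < 0:
        raise ValueError("n_phospho must be >= 0")
    if n_phospho == 0:
        return [peptide]
    sites = [i + 1 for i, r in enumerate(peptide.sequence) if r in "STY"]
    forms = []
    for combo in itertools.combinations(sites, n_phospho):
        mods = peptide.modifications + tuple(phospho(p, delta) for p in combo)
        forms.append(peptide.with_modifications(mods))
    return forms


def find_peptide(
    protein: Protein,
    precursor_mz: float,
    z: int,
    tol: float,
    table: MassTable,
    params: DigestParams = DigestParams(),
    n_phospho: int = 1,
) -> list[Peptide]:
    """Digest ``protein`` and return the phosphoforms (0..n_phospho sites)
    whose [M+zH]z+ m/z falls within ``tol`` of ``precursor_mz``, sorted by
    absolute m/z error.
    """
    if tol <= 0:
        raise ValueError("precursor tolerance must be positive")
    matches: list[tuple[float, Peptide]] = []
    for pep in digest(protein, params):
        for k in range(n_phospho + 1):
            for form in enumerate_phosphoforms(pep, k, delta=table.phospho_delta):
                err = mz(peptide_neutral_mass(form, table), z, table) - precursor_mz
                if abs(err) <= tol:
                    matches.append((abs(err), form))
    matches.sort(key=lambda t: (t[0], t[1].protein_start, t[1].sequence,
                                tuple(m.position for m in t[1].modifications)))
    return [p for _, p in matches]
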