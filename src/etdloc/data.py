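"""Bundled Fra-2 example data.

The example reproduces the published localization of ERK2-directed
phosphorylation on the Fra-2 tryptic peptide SSSSGDQSSDSLNSPTLLAL
(protein residues 307–326, so peptide position 14 is S320 and position
16 is T322). No Fra-2 construct sequence was deposited with the original
experiment, so the carrier protein here is synthetic: a simple repeat
scaffold with the real 20-mer grafted at its C terminus behind a lysine,
making it a genuine tryptic product at the documented coordinates.

Of the two bundled ETD spectra only four peak m/z values are
experimentally observed (c13 = 1269.7 and c15 = 1534.8 in the first
spectrum; c13 = 1269.6 and c16 = 1634.7 in the second); the remaining
series peaks are synthetic, computed from fragment theory consistent
with each spectrum's apparent mass calibration and rounded to 0.1 m/z
like the observed values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .masses import Peptide, phospho

__all__ = [
    "FRA2_PEPTIDE_SEQUENCE",
    "FRA2_PROTEIN_START",
    "fra2_peptide",
    "fra2_fasta_path",
    "fra2_mgf_path",
]

FRA2_PEPTIDE_SEQUENCE = "SSSSGDQSSDSLNSPTLLAL"
FRA2_PROTEIN_START = 307  # peptide position 14 -> protein residue S320


def fra2_peptide(phospho_position: int | None = None) -> Peptide:
    """The example 20-mer at its protein coordinates, optionally
    phosphorylated at a 1-based peptide position (14 = S320, 16 = T322)."""
    mods = (phospho(phospho_position),) if phospho_position else ()
    return Peptide(FRA2_PEPTIDE_SEQUENCE, protein_id="FRA2_SYNTHETIC",
                   protein_start=FRA2_PROTEIN_START, modifications=mods)


def _data_path(name: str) -> Path:
    return Path(resources.files("etdloc") / "data" / name)


def fra2_fasta_path() -> Path:
    """Synthetic carrier protein FASTA (326 residues; 20-mer at 307–326)."""
    return _data_path("fra2_synthetic.fasta")


def fra2_mgf_path() -> Path:
    """Two ETD spectra of the m/z 1023.5 (2+) phosphopeptide precursor."""
    return _data_path("fra2_etd_spectra.mgf")
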