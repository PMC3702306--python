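"""Format plumbing: FASTA and MGF reading/writing, tabular exports, plots.

FASTA goes through Bio.SeqIO and MGF through pyteomics.mgf; this module
only adapts those records to the package's domain types and raises
errors that name the offending file and record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .digestion import Protein
from .fragmentation import FragmentIon
from .localization import MatchResult, SiteAssignment, Spectrum
from .masses import MassTable, Peptide, peptide_neutral_mass

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "peptides_to_tsv",
    "ladder_to_tsv",
    "assignments_to_tsv",
    "assignments_to_json",
    "plot_annotated_spectrum",
]


def read_fasta(path: str | Path) -> list[Protein]:
    """All records of a (possibly line-wrapped, multi-record) FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            proteins.append(Protein(rec.id, str(rec.seq).upper(), rec.description))
        except ValueError as e:
            raise ValueError(f"{path}: record {rec.id!r}: {e}") from e
    if not proteins:
        raise ValueError(f"{path}: no FASTA records found")
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = p.description if p.description.startswith(p.id) else f"{p.id} {p.description}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Spectra from an MGF file; requires PEPMASS and CHARGE per record.

    The common "2+" charge dialect is accepted (pyteomics parses it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MGF file not found: {path}")
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"index={i}"))
            if "pepmass" not in params:
                raise ValueError(f"{path}: spectrum {title!r}: missing PEPMASS")
            pepmass = params["pepmass"]
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charges = params.get("charge")
            if not charges:
                raise ValueError(f"{path}: spectrum {title!r}: missing CHARGE")
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            meta = {k: str(v) for k, v in params.items()
                    if k not in ("pepmass", "charge", "title")}
            try:
                spectra.append(
                    Spectrum(title, precursor_mz, int(charges[0]),
                             mz[order], inten[order], meta)
                )
            except ValueError as e:
                raise ValueError(f"{path}: spectrum {title!r}: {e}") from e
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips m/z to 6 decimals."""
    entries = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": round(float(s.precursor_mz), 6),
            "charge": f"{s.precursor_charge}+",
        }
        params.update({k: v for k, v in sorted(s.metadata.items())})
        entries.append({
            "m/z array": np.round(s.mz, 6),
            "intensity array": np.round(s.intensity, 6),
            "params": params,
        })
    _mgf.write(entries, str(path), file_mode="w")


def peptides_to_tsv(
    peptides: Sequence[Peptide], table: MassTable, path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in peptides],
            "start": [p.protein_start for p in peptides],
            "end": [p.protein_end for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "mods": [
                ";".join(f"{m.name}@{p.protein_coord(m.position)}"
                         for m in sorted(p.modifications, key=lambda m: m.position))
                for p in peptides
            ],
            "neutral_mass": [round(peptide_neutral_mass(p, table), 5) for p in peptides],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def ladder_to_tsv(ions: Sequence[FragmentIon], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "series": [f.series for f in ions],
            "index": [f.index for f in ions],
            "charge": [f.charge for f in ions],
            "mz": [round(f.mz, 5) for f in ions],
            "suppressed": [f.suppressed for f in ions],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def _assignment_record(a: SiteAssignment, peptide: Peptide | None = None) -> dict:
    gap = a.supporting_gap
    return {
        "spectrum_id": a.spectrum_id,
        "peptide": peptide.sequence if peptide else "",
        "status": a.status,
        "sites": ";".join(a.site_labels),
        "n_phospho": a.n_phospho,
        "residual": None if np.isnan(a.residual) else round(a.residual, 4),
        "supporting_gap": (
            f"{gap.series}{gap.lower_index}-{gap.series}{gap.upper_index}" if gap else ""
        ),
        "observed_gap": round(gap.observed_gap, 4) if gap else None,
        "span_mass": round(gap.span_mass, 4) if gap else None,
        "diagnostic": a.diagnostic,
    }


def assignments_to_tsv(
    records: Sequence[tuple[SiteAssignment, Peptide | None]], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame([_assignment_record(a, p) for a, p in records])
    df.to_csv(path, sep="\t", index=False)
    return df


def assignments_to_json(
    records: Sequence[tuple[SiteAssignment, Peptide | None]], path: str | Path
) -> None:
    payload = [_assignment_record(a, p) for a, p in records]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_annotated_spectrum(
    spectrum: Spectrum, match: MatchResult, path: str | Path
) -> None:
    """Stick plot of the spectrum with matched fragment ions labelled."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.vlines(spectrum.mz, 0, spectrum.intensity, color="0.7", linewidth=1)
    top = float(spectrum.intensity.max()) if len(spectrum) else 1.0
    for a in match.assignments:
        ax.vlines(a.peak_mz, 0, a.peak_intensity, color="C3", linewidth=1.4)
        ax.annotate(a.ion.label, (a.peak_mz, a.peak_intensity + 0.02 * top),
                    rotation=90, fontsize=7, ha="center")
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    ax.set_title(spectrum.id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
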