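"""Peak matching, bracket-gap analysis and phosphosite localization.

The localization procedure mirrors how site assignments are read off an
ETD spectrum by hand. Matched ladder ions bracket every unobserved
cleavage position; the observed mass gap between two consecutive matched
ions, minus the unmodified residue mass of the spanned stretch, is the
gap's *residual*. A residual near zero means the span carries no
modification; a residual near (a multiple of) the phosphate mass places
that many phosphates somewhere on the span's S/T/Y residues. When the
span holds exactly one acceptor residue the site is localized; with
several the call is ambiguous among them.

Gaps are computed from the observed peak m/z values, not from theory, so
a constant calibration offset cancels out of every residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragmentation import FragmentIon
from .masses import MassTable, Peptide

__all__ = [
    "Spectrum",
    "Assignment",
    "MatchResult",
    "BracketGap",
    "SiteAssignment",
    "match_spectrum",
    "find_bracket_gaps",
    "localize_phospho",
    "verify_identity",
    "resolve_spectrum",
    "aggregate_sites",
]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum: precursor plus a sorted peak list."""

    id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if mz.size and np.any(np.diff(mz) < 0):
            raise ValueError(f"spectrum {self.id!r}: peaks not sorted by m/z")
        if np.any(mz <= 0):
            raise ValueError(f"spectrum {self.id!r}: non-positive m/z peak")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")

    @classmethod
    def from_peaks(
        cls,
        id: str,
        precursor_mz: float,
        precursor_charge: int,
        peaks: Iterable[tuple[float, float]],
        metadata: Mapping[str, str] | None = None,
    ) -> "Spectrum":
        pk = sorted(peaks)
        mz = np.array([p[0] for p in pk], dtype=float)
        inten = np.array([p[1] for p in pk], dtype=float)
        return cls(id, precursor_mz, precursor_charge, mz, inten, metadata or {})

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Assignment:
    ion: FragmentIon
    peak_mz: float
    peak_intensity: float
    error: float  # observed − theoretical, Da (m/z units)


@dataclass(frozen=True)
class MatchResult:
    peptide: Peptide | None
    spectrum_id: str
    assignments: tuple[Assignment, ...]
    unmatched: tuple[FragmentIon, ...]
    product_tol: float

    def matched_indices(self, series: str, charge: int | None = None) -> set[int]:
        return {
            a.ion.index
            for a in self.assignments
            if a.ion.series == series and (charge is None or a.ion.charge == charge)
        }

    @property
    def n_matched(self) -> int:
        return len(self.assignments)

    @property
    def total_abs_error(self) -> float:
        return float(sum(abs(a.error) for a in self.assignments))


def match_spectrum(
    spectrum: Spectrum,
    ladders: Sequence[FragmentIon],
    product_tol: float,
    peptide: Peptide | None = None,
) -> MatchResult:
    """Pair each non-suppressed ladder ion with its nearest peak within tolerance.

    Deterministic greedy assignment: within one series, ions are processed
    by ascending (index, charge) and each takes the nearest still-unused
    peak (exact distance ties break to the lower m/z peak). A peak may be
    reused across different series but not within one. Suppressed ions are
    never matched; they are reported among the unmatched ions.
    """
    if product_tol <= 0:
        raise ValueError("product tolerance must be positive")
    if not ladders:
        raise ValueError("empty fragment ladder")
    mz = spectrum.mz
    assignments: list[Assignment] = []
    unmatched: list[FragmentIon] = []
    by_series: dict[str, list[FragmentIon]] = {}
    for ion in ladders:
        by_series.setdefault(ion.series, []).append(ion)
    for series in sorted(by_series):
        used: set[int] = set()
        for ion in sorted(by_series[series], key=lambda f: (f.index, f.charge)):
            if ion.suppressed:
                unmatched.append(ion)
                continue
            j = _nearest_unused(mz, ion.mz, product_tol, used)
            if j is None:
                unmatched.append(ion)
            else:
                used.add(j)
                assignments.append(
                    Assignment(ion, float(mz[j]), float(spectrum.intensity[j]),
                               float(mz[j] - ion.mz))
                )
    return MatchResult(peptide, spectrum.id, tuple(assignments), tuple(unmatched), product_tol)


def _nearest_unused(mz: np.ndarray, target: float, tol: float, used: set[int]) -> int | None:
    if mz.size == 0:
        return None
    lo = int(np.searchsorted(mz, target - tol, side="left"))
    hi = int(np.searchsorted(mz, target + tol, side="right"))
    best: int | None = None
    best_d = np.inf
    for j in range(lo, hi):
        if j in used:
            continue
        d = abs(mz[j] - target)
        # strict < keeps the lower-m/z peak on an exact tie
        if d < best_d:
            best, best_d = j, d
    return best


@dataclass(frozen=True)
class BracketGap:
    """The neutral-mass interval between two consecutive matched ladder ions."""

    series: str
    charge: int
    lower_index: int
    upper_index: int
    observed_gap: float       # charge-corrected neutral-mass difference, Da
    span_start: int           # peptide positions lower_index+1 .. upper_index
    span_end: int
    span_sequence: str
    span_mass: float          # unmodified residue mass of the span
    residual: float           # observed_gap − span_mass

    def __post_init__(self) -> None:
        if self.upper_index <= self.lower_index:
            raise ValueError("bracket gap requires upper_index > lower_index")


_SERIES_OFFSET = {"c": "ammonia", "z_dot": "z_dot_constant", "b": None, "y": "water"}


def _series_constant(table: MassTable, series: str) -> float:
    attr = _SERIES_OFFSET[series]
    return getattr(table, attr) if attr else 0.0


def find_bracket_gaps(
    match: MatchResult,
    peptide: Peptide,
    table: MassTable,
    series: str = "c",
    precursor_neutral: float | None = None,
    anchor_termini: bool = True,
) -> list[BracketGap]:
    """One gap per consecutive pair of matched indices in ``series``.

    ``observed_gap`` comes from the matched *peak* m/z values (converted to
    neutral-mass differences for the fragment charge); ``span_mass`` is the
    unmodified residue mass of the bracketed stretch under ``table``.
    Suppressed ions are never matched, so they cannot be gap endpoints but
    may sit inside a span.

    With ``anchor_termini`` the ladder is bracketed against its termini as
    well: a virtual index-0 fragment of known constant mass anchors the
    span up to the first matched ion, and, when ``precursor_neutral`` is
    given, a virtual full-length fragment derived from the precursor mass
    anchors the span beyond the last one. Without these anchors a
    modification outside the matched range shifts every observed ion
    equally and cancels out of all pairwise differences.
    """
    by_charge: dict[int, list[Assignment]] = {}
    for a in match.assignments:
        if a.ion.series == series:
            by_charge.setdefault(a.ion.charge, []).append(a)
    gaps: list[BracketGap] = []
    n = len(peptide)
    const = _series_constant(table, series)
    for z, assigned in sorted(by_charge.items()):
        assigned.sort(key=lambda a: a.ion.index)
        # (index, observed neutral fragment mass) pairs, termini included
        points = [(a.ion.index, a.peak_mz * z - z * table.proton) for a in assigned]
        if anchor_termini:
            points.insert(0, (0, const))
            if precursor_neutral is not None:
                points.append((n, precursor_neutral - table.water + const))
        for (i1, m1), (i2, m2) in zip(points, points[1:]):
            if series in ("c", "b"):
                start, end = i1 + 1, i2
            else:  # C-terminal series: index j covers the last j residues
                start, end = n - i2 + 1, n - i1
            span = peptide.sequence[start - 1 : end]
            span_mass = table.sum_residues(span)
            gaps.append(
                BracketGap(series, z, i1, i2, m2 - m1, start, end, span, span_mass,
                           (m2 - m1) - span_mass)
            )
    return gaps


@dataclass(frozen=True)
class SiteAssignment:
    """A phosphosite call supported by one bracket gap (or a combination)."""

    spectrum_id: str
    status: str                       # localized | ambiguous | none
    candidate_positions: frozenset[int]  # protein coordinates, S/T/Y only
    site_labels: tuple[str, ...]      # e.g. ("S320",), protein coordinates
    supporting_gap: BracketGap | None
    residual: float
    n_phospho: int = 1
    diagnostic: str = ""


def localize_phospho(
    gaps: Sequence[BracketGap],
    peptide: Peptide,
    phospho_delta: float,
    residual_tol: float = 1.2,
    n_phospho: int = 1,
    spectrum_id: str = "",
) -> list[SiteAssignment]:
    """Turn phosphate-sized bracket residuals into site assignments.

    A gap whose residual is within ``residual_tol`` of k·``phospho_delta``
    (k = 1..``n_phospho``) assigns k phosphates to the S/T/Y residues of
    its span, reported in protein coordinates. Gaps with residual near
    zero are unmodified spans and emit nothing. A phosphate-sized residual
    over a span with no acceptor residue yields a diagnostic ``none`` call.
    """
    if residual_tol <= 0:
        raise ValueError("residual tolerance must be positive")
    out: list[SiteAssignment] = []
    for gap in gaps:
        if abs(gap.residual) <= residual_tol:
            continue  # unmodified span
        for k in range(1, n_phospho + 1):
            if abs(gap.residual - k * phospho_delta) > residual_tol:
                continue
            sites = [
                pos
                for pos in range(gap.span_start, gap.span_end + 1)
                if peptide.sequence[pos - 1] in "STY"
            ]
            labels = tuple(peptide.site_label(p) for p in sites)
            coords = frozenset(peptide.protein_coord(p) for p in sites)
            if not sites:
                status, diag = "none", (
                    f"gap {gap.series}{gap.lower_index}-{gap.series}{gap.upper_index}: "
                    f"phosphate-sized residual {gap.residual:.2f} over span "
                    f"{gap.span_sequence!r} with no S/T/Y acceptor"
                )
            elif len(sites) == 1:
                status, diag = "localized", ""
            else:
                status, diag = "ambiguous", ""
            out.append(
                SiteAssignment(spectrum_id, status, coords, labels, gap,
                               gap.residual, k, diag)
            )
            break
    return out


def verify_identity(
    match: MatchResult,
    peptide: Peptide,
    table: MassTable,
    min_series_count: int = 7,
    series: str = "c",
    residual_tol: float = 1.2,
    n_phospho: int = 1,
) -> tuple[bool, dict]:
    """Check that the matched ladder supports the peptide's identity.

    True when at least ``min_series_count`` non-suppressed ions of
    ``series`` are matched and every unmatched index strictly between the
    first and last matched ion is accounted for: either suppressed
    (pre-proline bond) or inside a bracket whose residual is
    mass-consistent (within ``residual_tol`` of 0 or of k phosphates).
    The report lists matched indices and the explanation per hole.
    """
    matched = sorted(match.matched_indices(series))
    report: dict = {"series": series, "matched_indices": matched, "holes": {}}
    if len(matched) < min_series_count:
        report["reason"] = (
            f"only {len(matched)} matched {series} ions; need {min_series_count}"
        )
        return False, report
    suppressed = {
        ion.index for ion in match.unmatched
        if ion.series == series and ion.suppressed
    }
    gaps = find_bracket_gaps(match, peptide, table, series=series)
    consistent: list[BracketGap] = []
    for g in gaps:
        ok = abs(g.residual) <= residual_tol or any(
            abs(g.residual - k * table.phospho_delta) <= residual_tol
            for k in range(1, n_phospho + 1)
        )
        if ok:
            consistent.append(g)
    ok_overall = True
    for idx in range(matched[0] + 1, matched[-1]):
        if idx in matched:
            continue
        if idx in suppressed:
            report["holes"][idx] = "suppressed (pre-proline bond)"
        elif any(g.lower_index < idx < g.upper_index for g in consistent):
            report["holes"][idx] = "inside mass-consistent bracket"
        else:
            report["holes"][idx] = "unexplained"
            ok_overall = False
    report["verified"] = ok_overall
    return ok_overall, report


def resolve_spectrum(
    assignments: Sequence[SiteAssignment],
    spectrum_id: str = "",
) -> SiteAssignment:
    """Combine the phospho gap calls of one spectrum into a single call.

    Independent brackets (e.g. from the c and z• series) each constrain the
    site; intersecting their candidate sets can turn an ambiguous call into
    a localized one. Conflicting evidence (empty intersection) yields
    ``none`` with a diagnostic.
    """
    calls = [a for a in assignments if a.status in ("localized", "ambiguous")]
    if not calls:
        diag = "; ".join(a.diagnostic for a in assignments if a.diagnostic)
        return SiteAssignment(spectrum_id, "none", frozenset(), (), None,
                              float("nan"), diagnostic=diag or "no phosphate-sized gap")
    coords = frozenset.intersection(*(a.candidate_positions for a in calls))
    if not coords:
        return SiteAssignment(
            spectrum_id, "none", frozenset(), (), None, float("nan"),
            diagnostic="conflicting bracket evidence (empty candidate intersection)",
        )
    label_by_coord = {
        c: lab for a in calls for c, lab in zip(sorted(a.candidate_positions),
                                                sorted(a.site_labels, key=_label_coord))
    }
    labels = tuple(label_by_coord[c] for c in sorted(coords))
    best = min(calls, key=lambda a: (len(a.candidate_positions), abs(a.residual)))
    status = "localized" if len(coords) == 1 else "ambiguous"
    return SiteAssignment(spectrum_id, status, coords, labels,
                          best.supporting_gap, best.residual, best.n_phospho)


def _label_coord(label: str) -> int:
    return int(label[1:])


def aggregate_sites(assignments: Sequence[SiteAssignment]) -> pd.DataFrame:
    """Per-residue evidence summary across spectra.

    Counts, for every candidate protein residue, the spectra in which it
    was the unique localized site and those in which it appeared in an
    ambiguous set. No probabilistic claim is made.
    """
    rows: dict[int, dict] = {}
    for a in assignments:
        for coord, label in zip(sorted(a.candidate_positions),
                                sorted(a.site_labels, key=_label_coord)):
            row = rows.setdefault(coord, {"site": label, "position": coord,
                                          "n_localized": 0, "n_ambiguous": 0})
            if a.status == "localized":
                row["n_localized"] += 1
            elif a.status == "ambiguous":
                row["n_ambiguous"] += 1
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["position"]),
        columns=["site", "position", "n_localized", "n_ambiguous"],
    )
    return df
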