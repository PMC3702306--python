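"""End-to-end localization pipeline and its configuration.

Composes the stages: digest the protein database, select candidate
phosphoforms by precursor m/z, build theoretical c/z• ladders, match
them to the observed peak list, bracket the unmatched stretches, convert
phosphate-sized bracket residuals into site assignments, and aggregate
evidence across spectra.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .digestion import DigestParams, Protein, enumerate_phosphoforms, find_peptide
from .fragmentation import ladder_set
from .localization import (
    BracketGap,
    MatchResult,
    SiteAssignment,
    Spectrum,
    aggregate_sites,
    find_bracket_gaps,
    localize_phospho,
    match_spectrum,
    resolve_spectrum,
    verify_identity,
)
from .masses import MassTable, Peptide, TableKind, build_mass_table

__all__ = [
    "PipelineConfig",
    "SpectrumResult",
    "best_match",
    "localize_spectrum",
    "run_localize",
    "load_config",
]

log = logging.getLogger("etdloc")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one localization run.

    Defaults follow conventional ion-trap search settings: two missed
    tryptic cleavages, ±2.5 Da precursor and ±0.7 Da product tolerance,
    one variable phosphate on S/T/Y.
    """

    fasta: str = ""
    mgf: str = ""
    out_dir: str = "etdloc_out"
    table: str = "monoisotopic"
    localization_table: str | None = None  # span masses/phospho delta; default: table
    max_missed_cleavages: int = 2
    min_length: int = 5
    max_length: int = 60
    precursor_tol: float = 2.5
    product_tol: float = 0.7
    residual_tol: float = 1.2
    n_phospho: int = 1
    series: tuple[str, ...] = ("c", "z_dot")
    charges: tuple[int, ...] = (1,)
    min_series_count: int = 7
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "product_tol", "residual_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest_params(self) -> DigestParams:
        return DigestParams(
            max_missed_cleavages=self.max_missed_cleavages,
            min_length=self.min_length,
            max_length=self.max_length,
        )

    def mass_table(self) -> MassTable:
        return build_mass_table(self.table)

    def loc_table(self) -> MassTable:
        return build_mass_table(self.localization_table or self.table)


_TUPLE_FIELDS = {"series": str, "charges": int}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a plain-text ``key = value`` config file; kwargs override it."""
    values: dict = {}
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(key, value)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def _coerce(key: str, value: str):
    if key in _TUPLE_FIELDS:
        conv = _TUPLE_FIELDS[key]
        return tuple(conv(v.strip()) for v in value.split(",") if v.strip())
    typ = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}[key]
    if "int" in str(typ):
        return int(value)
    if "float" in str(typ):
        return float(value)
    return value


@dataclass(frozen=True)
class SpectrumResult:
    """Everything the pipeline derived from one spectrum."""

    spectrum: Spectrum
    peptide: Peptide | None                 # best-matching phosphoform
    match: MatchResult | None
    gaps: tuple[BracketGap, ...]
    gap_assignments: tuple[SiteAssignment, ...]
    assignment: SiteAssignment              # combined per-spectrum call
    identity_verified: bool | None = None
    identity_report: dict = field(default_factory=dict)


def best_match(
    spectrum: Spectrum,
    forms: Sequence[Peptide],
    table: MassTable,
    product_tol: float,
    series: Sequence[str] = ("c", "z_dot"),
    charges: Sequence[int] = (1,),
) -> tuple[Peptide, MatchResult]:
    """Match every candidate phosphoform and keep the best.

    Ranking: most matched ions, then smallest total |error|, then the
    lexicographically first modification position tuple (deterministic).
    """
    if not forms:
        raise ValueError("no candidate peptides to match")
    scored = []
    for form in forms:
        ladder = ladder_set(form, table, charges, series)
        m = match_spectrum(spectrum, ladder, product_tol, peptide=form)
        key = (-m.n_matched, m.total_abs_error, form.protein_id, form.protein_start,
               tuple(mod.position for mod in form.modifications))
        scored.append((key, form, m))
    scored.sort(key=lambda t: t[0])
    _, form, m = scored[0]
    return form, m


def call_site(
    spectrum: Spectrum,
    form: Peptide,
    match: MatchResult,
    loc_table: MassTable,
    series: Sequence[str] = ("c", "z_dot"),
    residual_tol: float = 1.2,
    n_phospho: int = 1,
) -> tuple[tuple[BracketGap, ...], tuple[SiteAssignment, ...], SiteAssignment]:
    """Bracket-gap analysis of a matched spectrum → one combined site call."""
    gaps: list[BracketGap] = []
    per_gap: list[SiteAssignment] = []
    z = spectrum.precursor_charge
    precursor_neutral = spectrum.precursor_mz * z - z * loc_table.proton
    for s in series:
        s_gaps = find_bracket_gaps(match, form, loc_table, series=s,
                                   precursor_neutral=precursor_neutral)
        gaps.extend(s_gaps)
        per_gap.extend(
            localize_phospho(s_gaps, form, loc_table.phospho_delta,
                             residual_tol=residual_tol, n_phospho=n_phospho,
                             spectrum_id=spectrum.id)
        )
    resolved = resolve_spectrum(per_gap, spectrum_id=spectrum.id)
    return tuple(gaps), tuple(per_gap), resolved


def localize_spectrum(
    spectrum: Spectrum,
    base_peptide: Peptide,
    table: MassTable,
    product_tol: float = 0.7,
    residual_tol: float = 1.2,
    series: Sequence[str] = ("c", "z_dot"),
    charges: Sequence[int] = (1,),
    n_phospho: int = 1,
    loc_table: MassTable | None = None,
) -> SpectrumResult:
    """Localize phosphate(s) on a known base peptide from one spectrum.

    Candidate phosphoforms (0..n_phospho phosphates on the base sequence)
    compete for the best ladder match; the winner's bracket gaps are then
    converted into a site call.
    """
    forms = [
        f
        for k in range(n_phospho + 1)
        for f in enumerate_phosphoforms(base_peptide, k, delta=table.phospho_delta)
    ]
    form, m = best_match(spectrum, forms, table, product_tol, series, charges)
    gaps, per_gap, resolved = call_site(
        spectrum, form, m, loc_table or table, series, residual_tol, n_phospho
    )
    return SpectrumResult(spectrum, form, m, gaps, per_gap, resolved)


def run_localize(
    config: PipelineConfig,
    proteins: Sequence[Protein] | None = None,
    spectra: Sequence[Spectrum] | None = None,
) -> tuple[list[SpectrumResult], pd.DataFrame]:
    """Run the full pipeline and write reports under ``config.out_dir``.

    ``proteins``/``spectra`` may be passed directly (e.g. from the
    simulator); otherwise they are read from ``config.fasta`` and
    ``config.mgf``. Writes sites.tsv, sites.json, aggregate.tsv and
    run.log; re-running with identical inputs reproduces the reports
    byte-for-byte.
    """
    from . import io as eio  # local import: io pulls optional heavy deps

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log", config.log_level)
    log.info("resolved config: %s", json.dumps(dataclasses.asdict(config), default=str))

    if proteins is None:
        proteins = eio.read_fasta(config.fasta)
    if spectra is None:
        spectra = eio.read_mgf(config.mgf)
    table = config.mass_table()
    loc_table = config.loc_table()
    log.info("%d protein(s), %d spectrum/spectra", len(proteins), len(spectra))

    results: list[SpectrumResult] = []
    for spec in spectra:
        candidates: list[Peptide] = []
        for prot in proteins:
            candidates.extend(
                find_peptide(prot, spec.precursor_mz, spec.precursor_charge,
                             config.precursor_tol, table,
                             params=config.digest_params(),
                             n_phospho=config.n_phospho)
            )
        if not candidates:
            log.info("%s: no candidate peptide within ±%.2f Da of precursor %.3f",
                     spec.id, config.precursor_tol, spec.precursor_mz)
            results.append(
                SpectrumResult(
                    spec, None, None, (), (),
                    SiteAssignment(spec.id, "none", frozenset(), (), None,
                                   float("nan"),
                                   diagnostic="no candidate peptide within precursor tolerance"),
                )
            )
            continue
        form, m = best_match(spec, candidates, table, config.product_tol,
                             config.series, config.charges)
        gaps, per_gap, resolved = call_site(spec, form, m, loc_table,
                                            config.series, config.residual_tol,
                                            config.n_phospho)
        id_series = "c" if "c" in config.series else config.series[0]
        ok, report = verify_identity(m, form, loc_table,
                                     min_series_count=config.min_series_count,
                                     series=id_series,
                                     residual_tol=config.residual_tol,
                                     n_phospho=config.n_phospho)
        log.info("%s: peptide %s [%d-%d], %d matched ions, identity=%s, call=%s %s",
                 spec.id, form.sequence, form.protein_start, form.protein_end,
                 m.n_matched, ok, resolved.status, ";".join(resolved.site_labels))
        results.append(SpectrumResult(spec, form, m, gaps, per_gap, resolved, ok, report))

    records = [(r.assignment, r.peptide) for r in results]
    eio.assignments_to_tsv(records, out / "sites.tsv")
    eio.assignments_to_json(records, out / "sites.json")
    agg = aggregate_sites([r.assignment for r in results])
    agg.to_csv(out / "aggregate.tsv", sep="\t", index=False)
    log.info("aggregate site report:\n%s", agg.to_string(index=False) if len(agg) else "(empty)")
    return results, agg


def _setup_logging(logfile: Path, level: str) -> None:
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)
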