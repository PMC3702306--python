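"""Peak matching, bracket gaps and the phosphate localization logic."""

import numpy as np
import pytest

from etdloc import (
    Peptide,
    Spectrum,
    aggregate_sites,
    c_ladder,
    find_bracket_gaps,
    ladder_set,
    localize_phospho,
    match_spectrum,
    peptide_neutral_mass,
    phospho,
    resolve_spectrum,
    verify_identity,
    z_ladder,
)
from etdloc.localization import SiteAssignment
from conftest import random_peptide


def theoretical_spectrum(peptide, table, series=("c", "z_dot"), drop_indices=()):
    ions = [
        f for f in ladder_set(peptide, table, (1,), series)
        if not f.suppressed and (f.series, f.index) not in drop_indices
    ]
    return Spectrum.from_peaks("theory", 0.0 + (peptide_neutral_mass(peptide, table)
                                                + 2 * table.proton) / 2,
                               2, [(f.mz, 100.0) for f in ions])


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum("s", 500.0, 2, np.array([2.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        Spectrum("s", 500.0, 2, np.array([-1.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        Spectrum("s", 500.0, 0, np.array([1.0]), np.array([1.0]))
    s = Spectrum.from_peaks("s", 500.0, 2, [(300.0, 1.0), (100.0, 2.0)])
    assert list(s.mz) == [100.0, 300.0]


def test_self_match_is_exact(mono):
    p = Peptide("SAMPLESEQK", modifications=(phospho(7),))
    spec = theoretical_spectrum(p, mono)
    ladder = ladder_set(p, mono, (1,), ("c", "z_dot"))
    m = match_spectrum(spec, ladder, 0.7, peptide=p)
    n_expected = sum(1 for f in ladder if not f.suppressed)
    assert m.n_matched == n_expected
    assert all(a.error == 0.0 for a in m.assignments)
    assert all(f.suppressed for f in m.unmatched)


def test_empty_peak_list_gives_zero_matches(mono):
    p = Peptide("SAMPLEK")
    spec = Spectrum("empty", 500.0, 2, np.array([]), np.array([]))
    m = match_spectrum(spec, c_ladder(p, mono), 0.7)
    assert m.n_matched == 0 and len(m.unmatched) == len(p) - 1


def test_matching_equals_brute_force_oracle(mono, rng):
    """Greedy-by-index nearest-within-tolerance, re-implemented naively."""
    for _ in range(50):
        p = Peptide(random_peptide(rng, 6, 20))
        peaks = np.sort(rng.uniform(100, 2000, size=rng.integers(3, 40)))
        spec = Spectrum("r", 600.0, 2, peaks, np.ones_like(peaks))
        ladder = c_ladder(p, mono)
        tol = float(rng.uniform(0.2, 5.0))
        m = match_spectrum(spec, ladder, tol, peptide=p)
        got = {(a.ion.index, a.peak_mz) for a in m.assignments}
        expected = set()
        used = set()
        for ion in ladder:  # already in ascending index order
            if ion.suppressed:
                continue
            cands = [
                (abs(x - ion.mz), x, j)
                for j, x in enumerate(peaks)
                if abs(x - ion.mz) <= tol and j not in used
            ]
            if cands:
                _, x, j = min(cands)  # ties resolve to lower m/z via tuple order
                used.add(j)
                expected.add((ion.index, x))
        assert got == expected


def test_tie_breaks_to_lower_mz_peak(mono):
    p = Peptide("GG")
    c1 = c_ladder(p, mono)[0].mz
    spec = Spectrum.from_peaks("tie", 200.0, 1, [(c1 - 0.2, 5.0), (c1 + 0.2, 9.0)])
    m = match_spectrum(spec, c_ladder(p, mono), 0.7)
    assert m.assignments[0].peak_mz == pytest.approx(c1 - 0.2)


def test_bracket_gap_from_observed_peaks(mono, legend, fra2_ph14):
    """Two matched ions with one suppressed bond between them reproduce the
    hand-checked 265.1 Da gap and its +80.9 phosphate residual."""
    ladder = c_ladder(fra2_ph14, mono)
    spec = Spectrum.from_peaks("panel", 1023.5, 2, [(1269.7, 1.0), (1534.8, 1.0)])
    m = match_spectrum(spec, ladder, 1.3, peptide=fra2_ph14)
    gaps = find_bracket_gaps(m, fra2_ph14, legend, series="c", anchor_termini=False)
    assert len(gaps) == 1
    g = gaps[0]
    assert (g.lower_index, g.upper_index) == (13, 15)
    assert g.observed_gap == pytest.approx(265.1, abs=1e-9)
    assert g.span_sequence == "SP"
    assert g.span_mass == pytest.approx(184.20, abs=1e-9)
    assert g.residual == pytest.approx(80.90, abs=1e-9)
    assert g.observed_gap - g.span_mass - g.residual == 0.0


def test_theoretical_full_ladder_residuals_are_zero(mono):
    p = Peptide("SAMPLESEQK")
    spec = theoretical_spectrum(p, mono)
    ladder = ladder_set(p, mono, (1,), ("c", "z_dot"))
    m = match_spectrum(spec, ladder, 0.7, peptide=p)
    neutral = peptide_neutral_mass(p, mono)
    for series in ("c", "z_dot"):
        for g in find_bracket_gaps(m, p, mono, series=series, precursor_neutral=neutral):
            assert g.residual == pytest.approx(0.0, abs=1e-9)


def test_residuals_invariant_under_constant_calibration_shift(mono):
    p = Peptide("SAMPLESEQK", modifications=(phospho(7),))
    ladder = ladder_set(p, mono, (1,), ("c",))
    base = theoretical_spectrum(p, mono, series=("c",))
    shifted = Spectrum.from_peaks("s", base.precursor_mz, 2,
                                  [(x + 0.3, 100.0) for x in base.mz])
    def interior(spec):
        m = match_spectrum(spec, ladder, 0.7, peptide=p)
        return [
            round(g.residual, 9)
            for g in find_bracket_gaps(m, p, mono, series="c", anchor_termini=False)
        ]
    assert interior(shifted) == interior(base)


def test_localize_legend_scenarios(legend, fra2_ph14):
    spec = Spectrum.from_peaks("upper", 1023.5, 2, [(1269.7, 1.0), (1534.8, 1.0)])
    m = match_spectrum(spec, c_ladder(fra2_ph14, legend), 1.3, peptide=fra2_ph14)
    gaps = find_bracket_gaps(m, fra2_ph14, legend, series="c", anchor_termini=False)
    calls = localize_phospho(gaps, fra2_ph14, legend.phospho_delta,
                             residual_tol=1.2, spectrum_id="upper")
    assert len(calls) == 1
    assert calls[0].status == "localized"
    assert calls[0].site_labels == ("S320",)

    spec2 = Spectrum.from_peaks("lower", 1023.5, 2, [(1269.6, 1.0), (1634.7, 1.0)])
    m2 = match_spectrum(spec2, c_ladder(fra2_ph14, legend), 1.3, peptide=fra2_ph14)
    gaps2 = find_bracket_gaps(m2, fra2_ph14, legend, series="c", anchor_termini=False)
    calls2 = localize_phospho(gaps2, fra2_ph14, legend.phospho_delta,
                              residual_tol=1.2, spectrum_id="lower")
    assert calls2[0].status == "ambiguous"
    assert calls2[0].candidate_positions == {320, 322}
    assert calls2[0].residual == pytest.approx(79.79, abs=1e-9)


def test_phospho_sized_residual_without_acceptor_is_diagnosed(mono):
    from etdloc import BracketGap

    p = Peptide("GGAGGAGGK")  # no S/T/Y anywhere
    span = "GGA"  # peptide positions 4..6
    span_mass = mono.sum_residues(span)
    gap = BracketGap("c", 1, 3, 6, span_mass + mono.phospho_delta,
                     4, 6, span, span_mass, mono.phospho_delta)
    calls = localize_phospho([gap], p, mono.phospho_delta)
    assert len(calls) == 1 and calls[0].status == "none"
    assert "no S/T/Y" in calls[0].diagnostic


def test_unmodified_gaps_emit_nothing(mono):
    p = Peptide("SAMPLESEQK")
    spec = theoretical_spectrum(p, mono, series=("c",))
    m = match_spectrum(spec, c_ladder(p, mono), 0.7, peptide=p)
    gaps = find_bracket_gaps(m, p, mono, series="c",
                             precursor_neutral=peptide_neutral_mass(p, mono))
    assert localize_phospho(gaps, p, mono.phospho_delta) == []


def test_verify_identity_on_listed_series(mono, legend, fra2_ph14, fra2_spectra):
    """Seven matched C ions with every hole suppressed or mass-consistent."""
    upper = fra2_spectra[0]
    m = match_spectrum(upper, c_ladder(fra2_ph14, mono), 1.3, peptide=fra2_ph14)
    assert sorted(m.matched_indices("c")) == [10, 12, 13, 15, 17, 18, 19]
    ok, report = verify_identity(m, fra2_ph14, legend, min_series_count=7)
    assert ok
    assert report["holes"][14] == "suppressed (pre-proline bond)"
    assert "consistent" in report["holes"][11]
    ok6, _ = verify_identity(m, fra2_ph14, legend, min_series_count=8)
    assert not ok6


def test_verify_identity_zero_matches_is_false(mono):
    p = Peptide("SAMPLEK")
    spec = Spectrum("none", 500.0, 2, np.array([]), np.array([]))
    m = match_spectrum(spec, c_ladder(p, mono), 0.7, peptide=p)
    ok, report = verify_identity(m, p, mono, min_series_count=1)
    assert not ok and "matched" in report["reason"]


def test_verify_identity_tolerates_suppressed_hole(mono):
    p = Peptide("SAMPLEPK")  # c6 suppressed (bond before P7)
    spec = theoretical_spectrum(p, mono, series=("c",))
    m = match_spectrum(spec, c_ladder(p, mono), 0.7, peptide=p)
    ok, report = verify_identity(m, p, mono, min_series_count=5)
    assert ok and report["holes"][6] == "suppressed (pre-proline bond)"


def test_resolve_spectrum_intersects_series_evidence(mono):
    """c-series evidence {S,T} ∩ z-series evidence {S} localizes the site."""
    p = Peptide("AAASPTAAK", modifications=(phospho(4),))
    spec = theoretical_spectrum(p, mono, drop_indices=[("c", 5)])
    ladder = ladder_set(p, mono, (1,), ("c", "z_dot"))
    m = match_spectrum(spec, ladder, 0.7, peptide=p)
    neutral = peptide_neutral_mass(p, mono)
    calls = []
    for series in ("c", "z_dot"):
        gaps = find_bracket_gaps(m, p, mono, series=series, precursor_neutral=neutral)
        calls += localize_phospho(gaps, p, mono.phospho_delta, spectrum_id="x")
    by_series = {c.supporting_gap.series: c for c in calls}
    assert by_series["c"].status == "ambiguous"  # span S4-P5-T6 from c side
    combined = resolve_spectrum(calls, "x")
    assert combined.status == "localized" and combined.site_labels == ("S4",)


def test_resolve_spectrum_edge_cases():
    none = resolve_spectrum([], "s")
    assert none.status == "none"
    a = SiteAssignment("s", "ambiguous", frozenset({1}), ("S1",), None, 80.0)
    b = SiteAssignment("s", "ambiguous", frozenset({3}), ("S3",), None, 80.0)
    conflict = resolve_spectrum([a, b], "s")
    assert conflict.status == "none" and "conflict" in conflict.diagnostic


def test_aggregate_sites_counts():
    loc = SiteAssignment("s1", "localized", frozenset({320}), ("S320",), None, 80.9)
    amb = SiteAssignment("s2", "ambiguous", frozenset({320, 322}),
                         ("S320", "T322"), None, 79.79)
    df = aggregate_sites([loc, amb])
    row320 = df[df.position == 320].iloc[0]
    row322 = df[df.position == 322].iloc[0]
    assert (row320.n_localized, row320.n_ambiguous) == (1, 1)
    assert (row322.n_localized, row322.n_ambiguous) == (0, 1)
    assert aggregate_sites([]).empty
    df3 = aggregate_sites([loc] * 3)
    assert df3[df3.position == 320].iloc[0].n_localized == 3
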