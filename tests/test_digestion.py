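"""Digestion against a brute-force enumerator, plus phosphoform counting."""

import numpy as np
import pytest

from etdloc import (
    DigestParams,
    Peptide,
    Protein,
    build_mass_table,
    digest,
    enumerate_phosphoforms,
    find_peptide,
    mz,
    peptide_neutral_mass,
)
from conftest import random_peptide

PEP20 = "SSSSGDQSSDSLNSPTLLAL"


def brute_force_digest(seq, max_missed, min_len=1, max_len=10**9):
    """Independent oracle: test every substring against the tryptic rule."""
    def cuts_before(i):  # a tryptic boundary exists between i-1 and i
        return i == 0 or (seq[i - 1] in "KR" and seq[i] != "P")

    out = []
    for a in range(len(seq)):
        for b in range(a + 1, len(seq) + 1):
            if not (cuts_before(a) and (b == len(seq) or cuts_before(b))):
                continue
            internal = sum(
                1 for i in range(a, b - 1) if seq[i] in "KR" and seq[i + 1] != "P"
            )
            if internal <= max_missed and min_len <= b - a <= max_len:
                out.append((a + 1, seq[a:b]))
    return sorted(out, key=lambda t: (t[0], len(t[1])))


def test_no_cleavage_before_proline():
    peps = digest(Protein("p", "AKRP"), DigestParams(max_missed_cleavages=0))
    assert [(p.protein_start, p.sequence) for p in peps] == [(1, "AK"), (3, "RP")]


def test_missed_cleavage_enumeration():
    peps = digest(Protein("p", "AKGR"), DigestParams(max_missed_cleavages=1))
    seqs = {p.sequence for p in peps}
    assert {"AKGR", "AK", "GR"} <= seqs


@pytest.mark.parametrize("missed", [0, 1, 2])
def test_digest_equals_brute_force_on_random_proteins(rng, missed):
    for _ in range(40):
        seq = random_peptide(rng, 30, 200)
        got = digest(Protein("p", seq), DigestParams(max_missed_cleavages=missed))
        assert [(p.protein_start, p.sequence) for p in got] == brute_force_digest(seq, missed)


def test_zero_missed_peptides_tile_the_protein(rng):
    for _ in range(25):
        seq = random_peptide(rng, 10, 120)
        peps = digest(Protein("p", seq), DigestParams(max_missed_cleavages=0))
        assert "".join(p.sequence for p in peps) == seq


def test_peptide_count_nondecreasing_in_missed_cleavages(rng):
    for _ in range(10):
        seq = random_peptide(rng, 50, 150)
        counts = [
            len(digest(Protein("p", seq), DigestParams(max_missed_cleavages=m)))
            for m in range(4)
        ]
        assert counts == sorted(counts)


def test_empty_protein_rejected():
    with pytest.raises(ValueError):
        Protein("p", "")


def test_phosphoform_enumeration_counts():
    assert len(enumerate_phosphoforms(Peptide("ASA"), 1)) == 1
    assert enumerate_phosphoforms(Peptide("ASA"), 1)[0].modifications[0].position == 2
    # the example 20-mer holds 8 serines and 1 threonine = 9 acceptors
    forms = enumerate_phosphoforms(Peptide(PEP20), 1)
    assert len(forms) == sum(1 for r in PEP20 if r in "STY") == 9
    positions = [f.modifications[0].position for f in forms]
    assert positions == sorted(positions)  # deterministic ascending order
    p = Peptide("ASA")
    assert enumerate_phosphoforms(p, 0) == [p]
    assert enumerate_phosphoforms(Peptide("AAA"), 1) == []
    assert enumerate_phosphoforms(Peptide("ASA"), 2) == []


def test_phosphoform_mass_is_base_plus_delta(mono, rng):
    for _ in range(20):
        seq = random_peptide(rng, 6, 25)
        base = Peptide(seq)
        for n in (1, 2):
            for form in enumerate_phosphoforms(base, n, delta=mono.phospho_delta):
                assert peptide_neutral_mass(form, mono) == pytest.approx(
                    peptide_neutral_mass(base, mono) + n * mono.phospho_delta, abs=1e-9
                )


def test_find_peptide_recovers_phosphopeptide_precursor(mono, fra2_protein):
    hits = find_peptide(fra2_protein, 1023.5, 2, 2.5, mono, n_phospho=1)
    assert hits and all(h.sequence == PEP20 for h in hits)
    assert all(len(h.modifications) == 1 for h in hits)
    assert {h.modifications[0].position for h in hits} == {1, 2, 3, 4, 8, 9, 11, 14, 16}
    assert find_peptide(fra2_protein, 500.0, 2, 2.5, mono, n_phospho=1) == []


def test_find_peptide_equals_brute_force(mono, rng):
    for _ in range(5):
        seq = random_peptide(rng, 40, 90)
        prot = Protein("p", seq)
        params = DigestParams(max_missed_cleavages=2, min_length=4, max_length=40)
        target = float(rng.uniform(400, 1200))
        got = find_peptide(prot, target, 2, 2.5, mono, params=params, n_phospho=1)
        expected = set()
        for start, sub in brute_force_digest(seq, 2, 4, 40):
            sites = [None] + [i + 1 for i, r in enumerate(sub) if r in "STY"]
            for site in sites:
                mass = sum(mono.residue_mass[r] for r in sub) + mono.water
                if site:
                    mass += mono.phospho_delta
                if abs(mz(mass, 2, mono) - target) <= 2.5:
                    expected.add((start, sub, site))
        assert {
            (p.protein_start, p.sequence,
             p.modifications[0].position if p.modifications else None)
            for p in got
        } == expected
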