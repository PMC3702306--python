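"""Theoretical fragment-ion ladders for ETD (c / z•) and CID (b / y).

ETD cleaves the backbone N–Cα bond: N-terminal fragments are c ions
(prefix residues + NH3), C-terminal fragments are z• radicals (suffix
residues + the z• constant, H2O − NH3 + H). The bond N-terminal to a
proline does not break under ETD, so the c/z• pair at that bond is
flagged ``suppressed`` rather than omitted — matchers and identity
reports can then explain the expected hole in the ladder.

The site-determining property: a phosphate at position k shifts every
c_i with i >= k (and every z•_j covering position k) by the phospho
delta while leaving the rest of the ladder untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .masses import MassTable, Peptide

__all__ = ["FragmentIon", "c_ladder", "z_ladder", "b_ladder", "y_ladder", "ladder_set"]

_ETD_SERIES = ("c", "z_dot")
_ALL_SERIES = ("c", "z_dot", "b", "y")


@dataclass(frozen=True)
class FragmentIon:
    series: str          # c, z_dot, b or y
    index: int           # number of residues in the fragment, >= 1
    charge: int
    mz: float
    suppressed: bool = False  # ETD pre-proline bond: ion not expected

    @property
    def label(self) -> str:
        z = "" if self.charge == 1 else f"^{self.charge}+"
        name = {"c": "c", "z_dot": "z•", "b": "b", "y": "y"}[self.series]
        return f"{name}{self.index}{z}"


def _prefix_masses(p: Peptide, t: MassTable) -> list[float]:
    """Cumulative residue+modification mass of prefixes 1..n."""
    deltas = {m.position: m.delta for m in p.modifications}
    out, acc = [], 0.0
    for i, r in enumerate(p.sequence, start=1):
        acc += t.mass_of(r) + deltas.get(i, 0.0)
        out.append(acc)
    return out


def _check(p: Peptide, z: int) -> None:
    if len(p) < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")
    if z < 1:
        raise ValueError(f"fragment charge must be >= 1, got {z}")


def c_ladder(p: Peptide, t: MassTable, z: int = 1) -> list[FragmentIon]:
    """c1..c(n-1); c_i is suppressed when residue i+1 is proline."""
    _check(p, z)
    prefix = _prefix_masses(p, t)
    return [
        FragmentIon(
            "c", i, z,
            (prefix[i - 1] + t.ammonia + z * t.proton) / z,
            suppressed=p.sequence[i] == "P",
        )
        for i in range(1, len(p))
    ]


def z_ladder(p: Peptide, t: MassTable, z: int = 1) -> list[FragmentIon]:
    """z•1..z•(n-1); z•_j is suppressed when residue n-j+1 is proline
    (the same pre-proline bond as the complementary c ion)."""
    _check(p, z)
    prefix = _prefix_masses(p, t)
    total = prefix[-1]
    n = len(p)
    return [
        FragmentIon(
            "z_dot", j, z,
            (total - prefix[n - j - 1] + t.z_dot_constant + z * t.proton) / z,
            suppressed=p.sequence[n - j] == "P",
        )
        for j in range(1, n)
    ]


def b_ladder(p: Peptide, t: MassTable, z: int = 1) -> list[FragmentIon]:
    """CID b ions (prefix residues only); no ETD suppression applies."""
    _check(p, z)
    prefix = _prefix_masses(p, t)
    return [
        FragmentIon("b", i, z, (prefix[i - 1] + z * t.proton) / z)
        for i in range(1, len(p))
    ]


def y_ladder(p: Peptide, t: MassTable, z: int = 1) -> list[FragmentIon]:
    """CID y ions (suffix residues + water)."""
    _check(p, z)
    prefix = _prefix_masses(p, t)
    total = prefix[-1]
    n = len(p)
    return [
        FragmentIon("y", j, z, (total - prefix[n - j - 1] + t.water + z * t.proton) / z)
        for j in range(1, n)
    ]


_BUILDERS = {"c": c_ladder, "z_dot": z_ladder, "b": b_ladder, "y": y_ladder}


def ladder_set(
    p: Peptide,
    t: MassTable,
    charges: Sequence[int] = (1,),
    series: Iterable[str] = _ETD_SERIES,
) -> list[FragmentIon]:
    """Union of the requested ladders, sorted by (series, index, charge)."""
    series = sorted(set(series))
    if not series:
        raise ValueError("at least one fragment series is required")
    unknown = [s for s in series if s not in _ALL_SERIES]
    if unknown:
        raise ValueError(f"unknown fragment series {unknown}; expected {_ALL_SERIES}")
    if not charges:
        raise ValueError("at least one fragment charge is required")
    ions = [
        ion
        for s in series
        for z in sorted(set(charges))
        for ion in _BUILDERS[s](p, t, z)
    ]
    ions.sort(key=lambda f: (f.series, f.index, f.charge))
    return ions
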