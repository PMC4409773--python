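"""Masses and ion series for head-to-tail cyclic peptides (orbitides).

An orbitide is cyclized N-to-C, so its neutral monoisotopic mass is the plain
sum of residue masses — no terminal water is added.  Two conventions for the
singly charged adduct ions are provided:

``atom``
    m/z = M + mass of the neutral atom (H, Na or K).  This is the convention
    under which the literature value for cyclic GVPWAIAA (MH+ 766.4252)
    reproduces exactly: 765.4173 + 1.007825.
``ion``
    m/z = M + (cation mass − electron mass), i.e. the physically strict
    charged-adduct mass (766.4246 for the same peptide — 0.0006 Da lower).

Fragments are modelled as b-type acylium ions of the ring-opened peptide: one
ion per contiguous cyclic substring of length 1..n−1, at +1 charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import monoisotopic_protein_weights

from .io_formats import PeakList

__all__ = [
    "MassTable",
    "TheoreticalIon",
    "MatchResult",
    "cyclic_mass",
    "adduct_mz",
    "theoretical_ions",
    "ring_opened_fragments",
    "match_peaks",
    "matched_fraction",
]

WATER = 18.0105646863
PROTON = 1.007276466879
ELECTRON = 0.000548579909
H_ATOM = 1.0078250319
NA_ATOM = 22.98976928
K_ATOM = 38.96370649


def _residue_masses() -> dict[str, float]:
    # IUPACData tabulates free amino-acid monoisotopic masses; the residue
    # (in-chain) mass is that minus one water.
    return {
        aa: monoisotopic_protein_weights[aa] - WATER
        for aa in "ACDEFGHIKLMNPQRSTVWY"
    }


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue and particle masses used throughout the module."""

    residues: dict[str, float] = field(default_factory=_residue_masses)
    proton: float = PROTON
    electron: float = ELECTRON
    h_atom: float = H_ATOM
    na_atom: float = NA_ATOM
    k_atom: float = K_ATOM

    def residue(self, aa: str) -> float:
        try:
            return self.residues[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {aa!r}") from None


DEFAULT_MASSES = MassTable()

_ADDUCT_ATOMS = {"M+H": H_ATOM, "M+Na": NA_ATOM, "M+K": K_ATOM}


@dataclass(frozen=True)
class TheoreticalIon:
    """A predicted singly charged ion of a cyclic peptide or its fragment."""

    peptide_id: str
    species: str  # M+H | M+Na | M+K | fragment
    mz: float
    charge: int = 1
    fragment_seq: str | None = None
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass
class MatchResult:
    """Assignment of a theoretical ion to (at most) one observed peak."""

    ion: TheoreticalIon
    peak_index: int | None
    delta_mz: float | None
    matched: bool


def cyclic_mass(seq: str, masses: MassTable = DEFAULT_MASSES) -> float:
    """Neutral monoisotopic mass (Da) of the head-to-tail cyclic peptide ``seq``.

    The cyclization amide consumes the terminal water, so the mass is exactly
    the residue-mass sum; it is therefore invariant to rotation of ``seq``.
    """
    if len(seq) < 2:
        raise ValueError("a cyclic peptide needs at least 2 residues")
    return float(sum(masses.residue(aa) for aa in seq))


def adduct_mz(neutral_mass: float, species: str, convention: str = "atom",
              masses: MassTable = DEFAULT_MASSES) -> float:
    """m/z of the singly charged adduct ``species`` (``M+H``/``M+Na``/``M+K``)."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    atom = {"M+H": masses.h_atom, "M+Na": masses.na_atom, "M+K": masses.k_atom}
    if species not in atom:
        raise ValueError(f"unknown adduct species {species!r}")
    if convention == "atom":
        return neutral_mass + atom[species]
    if convention == "ion":
        return neutral_mass + atom[species] - masses.electron
    raise ValueError(f"unknown convention {convention!r} (use 'atom' or 'ion')")


def theoretical_ions(seq: str, peptide_id: str | None = None,
                     species=("M+H", "M+Na", "M+K"), convention: str = "atom",
                     masses: MassTable = DEFAULT_MASSES) -> list[TheoreticalIon]:
    """Molecular-ion series for one cyclic peptide."""
    pid = peptide_id if peptide_id is not None else seq
    m = cyclic_mass(seq, masses)
    return [
        TheoreticalIon(peptide_id=pid, species=sp,
                       mz=adduct_mz(m, sp, convention, masses))
        for sp in species
    ]


def ring_opened_fragments(seq: str, masses: MassTable = DEFAULT_MASSES
                          ) -> list[TheoreticalIon]:
    """b-type +1 fragment ions for every contiguous cyclic substring.

    An n-residue ring yields n(n−1) substrings of length 1..n−1 (each of the n
    ring-opening positions starts n−1 prefixes); substrings identical in mass
    are collapsed with their multiplicity recorded.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("ring must have at least 2 residues")
    doubled = seq + seq
    by_mass: dict[float, list[str]] = {}
    for start in range(n):
        acc = 0.0
        for length in range(1, n):
            acc += masses.residue(doubled[start + length - 1])
            key = round(acc, 6)
            by_mass.setdefault(key, []).append(doubled[start:start + length])
    ions = []
    for key in sorted(by_mass):
        subs = by_mass[key]
        ions.append(
            TheoreticalIon(
                peptide_id=seq,
                species="fragment",
                mz=key + masses.proton,
                fragment_seq=min(subs),
                multiplicity=len(subs),
            )
        )
    return ions


def match_peaks(peaks: PeakList, ions, tol: float = 0.10,
                mode: str = "absolute") -> list[MatchResult]:
    """Match each theoretical ion to its nearest observed peak within tolerance.

    ``tol`` is in Th for ``mode='absolute'`` or in parts-per-million for
    ``mode='ppm'``.  An empty peak list simply yields all-unmatched results.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in {"absolute", "ppm"}:
        raise ValueError(f"unknown tolerance mode {mode!r}")
    results = []
    mz = peaks.mz
    for ion in ions:
        if len(mz) == 0:
            results.append(MatchResult(ion=ion, peak_index=None, delta_mz=None,
                                       matched=False))
            continue
        idx = int(np.argmin(np.abs(mz - ion.mz)))
        delta = float(mz[idx] - ion.mz)
        limit = tol if mode == "absolute" else tol * ion.mz * 1e-6
        ok = abs(delta) <= limit
        results.append(
            MatchResult(ion=ion, peak_index=idx if ok else None,
                        delta_mz=delta if ok else None, matched=ok)
        )
    return results


def matched_fraction(results) -> float:
    """Fraction of theoretical ions that found a peak within tolerance."""
    results = list(results)
    if not results:
        return float("nan")
    return sum(r.matched for r in results) / len(results)
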