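"""Cyclic-peptide mass arithmetic, ion series and peak matching.

The element-composition oracle below is an independent route to the residue
masses: residue → CHNOS atom counts → mass from atomic masses, never touching
the package's own residue table.
"""

import itertools

import numpy as np
import pytest

from scampps.io_formats import PeakList
from scampps.orbitide_ms import (MassTable, adduct_mz, cyclic_mass,
                                 match_peaks, matched_fraction,
                                 ring_opened_fragments, theoretical_ions)

# independent oracle: residue elemental compositions (C, H, N, O, S) and
# CODATA-style atomic monoisotopic masses
_ATOM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
         "O": 15.9949146221, "S": 31.97207069}
_RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}


def oracle_cyclic_mass(seq: str) -> float:
    total = 0.0
    for aa in seq:
        c, h, n, o, s = _RESIDUE_FORMULA[aa]
        total += (c * _ATOM["C"] + h * _ATOM["H"] + n * _ATOM["N"]
                  + o * _ATOM["O"] + s * _ATOM["S"])
    return total


class TestCyclicMass:
    def test_gg_is_two_glycine_residues(self):
        assert cyclic_mass("GG") == pytest.approx(2 * 57.02146, abs=1e-4)

    def test_gvpwaiaa_neutral_mass(self):
        # hand summation of standard residue masses
        assert cyclic_mass("GVPWAIAA") == pytest.approx(765.4173, abs=5e-4)

    @pytest.mark.parametrize("seq", ["GVPWAIAA", "GYVAA", "GGAPPWF",
                                     "GLIATTF", "GVPIWPYWN"])
    def test_rotation_invariance(self, seq):
        ref = cyclic_mass(seq)
        for k in range(1, len(seq)):
            assert cyclic_mass(seq[k:] + seq[:k]) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("seq", ["GVPWAIAA", "ACDEFGHIKLMNPQRSTVWY",
                                     "GYVAA", "WW"])
    def test_element_composition_oracle(self, seq):
        assert cyclic_mass(seq) == pytest.approx(oracle_cyclic_mass(seq),
                                                 abs=1e-4)

    def test_concatenation_additivity(self):
        a, b = "GYVAA", "GVPWAIAA"
        assert cyclic_mass(a) + cyclic_mass(b) == pytest.approx(
            cyclic_mass(a + b), abs=1e-9)

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'B'"):
            cyclic_mass("GB")

    def test_too_short(self):
        with pytest.raises(ValueError):
            cyclic_mass("G")


class TestAdducts:
    def test_proton_vs_atom_conventions_differ_by_electron(self):
        m = cyclic_mass("GVPWAIAA")
        atom = adduct_mz(m, "M+H", "atom")
        ion = adduct_mz(m, "M+H", "ion")
        assert atom - ion == pytest.approx(0.000549, abs=1e-6)

    def test_k_minus_h_difference_both_conventions(self):
        m = cyclic_mass("GYVAA")
        mt = MassTable()
        for conv in ("atom", "ion"):
            diff = adduct_mz(m, "M+K", conv) - adduct_mz(m, "M+H", conv)
            assert diff == pytest.approx(mt.k_atom - mt.h_atom, abs=1e-9)

    def test_unknown_species(self):
        with pytest.raises(ValueError):
            adduct_mz(100.0, "M+Cs")


class TestFragments:
    def test_gg_single_unique_fragment_with_multiplicity(self):
        frags = ring_opened_fragments("GG")
        assert len(frags) == 1
        assert frags[0].mz == pytest.approx(57.02146 + 1.00728, abs=1e-4)
        assert frags[0].multiplicity == 2

    @pytest.mark.parametrize("seq", ["GYVAA", "GVPWAIAA", "GLIATTF"])
    def test_substring_count_matches_brute_force(self, seq):
        # oracle: explicit enumeration of all cyclic substrings length 1..n-1
        n = len(seq)
        doubled = seq + seq
        brute = [doubled[s:s + ln]
                 for s, ln in itertools.product(range(n), range(1, n))]
        assert len(brute) == n * (n - 1)
        frags = ring_opened_fragments(seq)
        assert sum(f.multiplicity for f in frags) == n * (n - 1)
        # each unique fragment mass must equal its residue-sum + proton
        for f in frags:
            assert f.mz == pytest.approx(
                sum(oracle_cyclic_mass(c) for c in f.fragment_seq) + 1.00728,
                abs=1e-3)

    def test_all_fragments_below_molecular_ion(self):
        seq = "GVPWAIAA"
        mh = cyclic_mass(seq) + 1.00728
        assert all(f.mz < mh for f in ring_opened_fragments(seq))


class TestMatching:
    def test_planted_ions_recovered_with_jitter(self, rng):
        ions = theoretical_ions("GVPWAIAA", species=("M+H", "M+K"))
        jitter = rng.normal(0, 0.01, size=2)
        peaks = PeakList(mz=np.array([i.mz for i in ions]) + jitter,
                         intensity=np.ones(2))
        res = match_peaks(peaks, ions, tol=0.10)
        assert all(r.matched for r in res)
        deltas = sorted(r.delta_mz for r in res)
        assert deltas == pytest.approx(sorted(jitter), abs=1e-9)

    def test_tiny_tolerance_rejects_jittered_peaks(self):
        ions = theoretical_ions("GYVAA", species=("M+H",))
        peaks = PeakList(mz=np.array([ions[0].mz + 0.01]),
                         intensity=np.ones(1))
        res = match_peaks(peaks, ions, tol=1e-9)
        assert not any(r.matched for r in res)

    def test_tolerance_monotonicity(self, rng):
        ions = theoretical_ions("GGAPPWF")
        peaks = PeakList(mz=rng.uniform(300, 1000, 50), intensity=np.ones(50))
        counts = [sum(r.matched for r in match_peaks(peaks, ions, tol=t))
                  for t in (0.05, 0.1, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts)

    def test_empty_peaklist_all_unmatched(self):
        ions = theoretical_ions("GYVAA")
        res = match_peaks(PeakList(mz=np.array([]), intensity=np.array([])),
                          ions, tol=0.1)
        assert len(res) == len(ions) and not any(r.matched for r in res)
        assert matched_fraction(res) == 0.0
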