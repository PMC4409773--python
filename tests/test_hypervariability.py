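"""Pairwise alignment, domain labelling and the mismatch-concentration test."""

import math

import numpy as np
import pytest

from scampps.hypervariability import (align_pair, hypervariability_test,
                                      label_domain, shared_residues)
from scampps.synthetic_data import (SimConfig, make_gene, make_precursor,
                                    make_transcript_pair)

# ---------------------------------------------------------------------------
# independent quadratic-space Gotoh oracle (same scoring convention as
# align_pair's DNA defaults: +2/-3, first gap char -5, extension -2)
# ---------------------------------------------------------------------------

def oracle_global_score(a, b, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0):
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignPair:
    def test_identical_sequences(self):
        aln = align_pair("ACGTACGT", "ACGTACGT")
        assert aln.id_overall == 100.0
        assert aln.region_counts()["gap_columns"] == 0

    def test_single_mismatch(self):
        aln = align_pair("ACGT", "ACGA")
        c = aln.region_counts()
        assert (c["matches"], c["mismatches"]) == (3, 1)
        assert aln.id_overall == pytest.approx(75.0)

    def test_score_matches_independent_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(8):
            n1, n2 = rng.integers(150, 250, size=2)
            a = "".join(bases[rng.integers(0, 4, n1)])
            b = "".join(bases[rng.integers(0, 4, n2)])
            aln = align_pair(a, b)
            assert aln.score == pytest.approx(oracle_global_score(a, b))

    def test_swap_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 120)])
        b = "".join(np.where(rng.random(120) < 0.1,
                             bases[rng.integers(0, 4, 120)], list(a)))
        f, r = align_pair(a, b), align_pair(b, a)
        assert f.id_overall == pytest.approx(r.id_overall)
        assert f.score == pytest.approx(r.score)

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            align_pair("ACGTACGT", "MKWSEPLF")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestLabelDomain:
    def test_whole_sequence_domain_flank_nan_safe(self):
        aln = align_pair("ACGTAC", "ACGTAC")
        label_domain(aln, (0, 6))
        assert math.isnan(aln.id_flank)
        assert aln.id_domain == 100.0

    def test_empty_interval_all_flank(self):
        aln = align_pair("ACGTAC", "ACTTAC")
        label_domain(aln, (0, 0))
        assert aln.id_overall == pytest.approx(aln.id_flank)

    def test_out_of_range_interval(self):
        aln = align_pair("ACGT", "ACGT")
        with pytest.raises(ValueError):
            label_domain(aln, (0, 10))

    def test_synthetic_pair_domain_columns_match_truth(self, rng):
        cfg = SimConfig(seed=2)
        prec, iv = make_precursor(cfg, rng)
        gene = make_gene(prec, iv, cfg, rng)
        a, b = make_transcript_pair(gene.transcript,
                                    gene.domain_nt_transcript, cfg, rng)
        aln = align_pair(a, b)
        label_domain(aln, gene.domain_nt_transcript)
        d0, d1 = gene.domain_nt_transcript
        dom_cols = int((aln.labels == "domain").sum())
        # substitutions-only mutation: no gaps, so columns == truth nt count
        assert dom_cols == d1 - d0 == 3 * len(gene.domain)


class TestHypervariabilityTest:
    def test_single_term_tail_formula(self):
        # n=100 columns, m=20 domain, K=10 mismatches all in the domain:
        # p = C(20,10)/C(100,10) exactly (single hypergeometric term)
        a = list("A" * 100)
        b = list("A" * 100)
        for i in range(10):
            b[i] = "C"  # mismatches at columns 0..9
        aln = align_pair("".join(a), "".join(b))
        label_domain(aln, (0, 20))
        res = hypervariability_test(aln, n_perm=0)
        assert (res.n, res.m, res.K, res.k) == (100, 20, 10, 10)
        expected = math.comb(20, 10) / math.comb(100, 10)
        assert res.p_exact == pytest.approx(expected, rel=1e-9)

    def test_identical_sequences_p_one(self):
        aln = align_pair("ACGT" * 30, "ACGT" * 30)
        label_domain(aln, (10, 30))
        assert hypervariability_test(aln, n_perm=0).p_exact == 1.0

    def test_expected_count_not_significant(self, rng):
        # mismatches spread uniformly: k ≈ mK/n, so p should be large
        n, m = 200, 40
        a = list("A" * n)
        b = list(a)
        for i in rng.choice(n, size=20, replace=False):
            b[i] = "G"
        aln = align_pair("".join(a), "".join(b))
        label_domain(aln, (0, m))
        res = hypervariability_test(aln, n_perm=0)
        assert res.p_exact > 0.2

    def test_permutation_agrees_with_exact_within_3_mc_se(self, rng):
        cfg = SimConfig(seed=4)
        prec, iv = make_precursor(cfg, rng)
        gene = make_gene(prec, iv, cfg, rng)
        a, b = make_transcript_pair(gene.transcript,
                                    gene.domain_nt_transcript, cfg, rng)
        aln = align_pair(a, b)
        label_domain(aln, gene.domain_nt_transcript)
        res = hypervariability_test(aln, n_perm=10_000, seed=123)
        se = max(res.p_perm_se, math.sqrt(res.p_exact * (1 - res.p_exact)
                                          / res.n_perm), 1 / res.n_perm)
        assert abs(res.p_perm - res.p_exact) <= 3 * se + 1e-12

    def test_requires_labels(self):
        aln = align_pair("ACGT", "ACGT")
        with pytest.raises(ValueError):
            hypervariability_test(aln)


class TestSharedResidues:
    def test_equal_length_positional(self):
        assert shared_residues("GGAPPWF", "GLIATTF") == 2

    def test_unequal_length_uses_alignment(self):
        # GYVAA vs GVPWAIAA: counted on the gapped protein alignment
        assert shared_residues("GYVAA", "GVPWAIAA") >= 2

    def test_identity(self):
        assert shared_residues("GVPWAIAA", "GVPWAIAA") == 8
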