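"""Generator invariants: precursors, genes, genomes, pairs, peak lists."""

import numpy as np
import pytest
from scipy import stats

from scampps.io_formats import read_gff3
from scampps.orbitide_ms import adduct_mz, cyclic_mass, match_peaks
from scampps.synthetic_data import (SimConfig, TruthRecord, make_gene,
                                    make_genome, make_peaklist,
                                    make_precursor, make_transcript_pair,
                                    write_bundle, _splice)


class TestMakePrecursor:
    def test_forced_domain_sits_after_wse(self, rng):
        prec, iv = make_precursor(SimConfig(), rng, domain="GVPWAIAA")
        assert "WSEGVPWAIAA" in prec
        assert prec[iv[0]:iv[1]] == "GVPWAIAA"
        assert prec.startswith("M")

    def test_fixed_length_range(self, rng):
        cfg = SimConfig(domain_len_range=(5, 5))
        for _ in range(20):
            _, iv = make_precursor(cfg, rng)
            assert iv[1] - iv[0] == 5

    def test_domain_length_uniform(self, rng):
        # exact multinomial check: 1000 draws over 6 lengths; each bin count
        # must sit inside the two-sided 99.9% binomial interval for p=1/6
        cfg = SimConfig(domain_len_range=(5, 10))
        counts = np.zeros(6, dtype=int)
        for _ in range(1000):
            _, iv = make_precursor(cfg, rng)
            counts[iv[1] - iv[0] - 5] += 1
        lo = stats.binom.ppf(0.0005, 1000, 1 / 6)
        hi = stats.binom.ppf(0.9995, 1000, 1 / 6)
        assert counts.sum() == 1000
        assert np.all((counts >= lo) & (counts <= hi))

    def test_length_in_stated_band(self, rng):
        for _ in range(50):
            prec, _ = make_precursor(SimConfig(), rng)
            assert 45 <= len(prec) <= 55


class TestMakeGene:
    def test_intron_exact_at_zero_variance(self, rng):
        cfg = SimConfig(intron_len_mean=100, intron_len_sd=0)
        prec, iv = make_precursor(cfg, rng)
        gene = make_gene(prec, iv, cfg, rng)
        i0, i1 = gene.intron
        assert i1 - i0 == 100
        assert gene.seq[i0:i0 + 2] == "GT"
        assert gene.seq[i1 - 2:i1] == "AG"

    def test_splice_reconstructs_transcript(self, rng):
        cfg = SimConfig()
        for _ in range(10):
            prec, iv = make_precursor(cfg, rng)
            gene = make_gene(prec, iv, cfg, rng)
            assert _splice(gene) == gene.transcript

    def test_cds_length_includes_stop(self, rng):
        cfg = SimConfig()
        prec, iv = make_precursor(cfg, rng)
        gene = make_gene(prec, iv, cfg, rng)
        c0, c1 = gene.cds
        i0, i1 = gene.intron
        assert (c1 - c0) - (i1 - i0) == 3 * (len(prec) + 1)

    def test_transcript_near_450(self, rng):
        cfg = SimConfig()
        lengths = [len(make_gene(*make_precursor(cfg, rng), cfg, rng).transcript)
                   for _ in range(10)]
        assert all(430 <= n <= 470 for n in lengths)


class TestMakeGenome:
    def test_single_cluster_within_window(self):
        cfg = SimConfig(seed=1, n_genes=5, cluster_count=1)
        sim = make_genome(cfg)
        starts = sorted(t.feature.start for t in sim.truth)
        assert max(np.diff(starts)) <= 100_000

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=42, n_genes=6, cluster_count=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(make_genome(cfg), d1)
        write_bundle(make_genome(cfg), d2)
        for name in ("genome.fa", "truth_genes.gff3", "nblrr.gff3",
                     "truth.tsv", "precursors.fa"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_invariants_hold_for_all_genes(self, sim20):
        # TruthRecord.__post_init__ asserts WSE-G structure; re-check here
        for t in sim20.truth:
            d0, d1 = t.domain_interval
            assert t.precursor[d0:d1] == t.domain
            assert t.domain.startswith("G")
            assert t.precursor[d0 - 3:d0] == "WSE"
            g0, g1 = t.intron
            iseq = sim20.genome.fetch(g0, g1, strand=t.feature.strand)
            assert iseq.startswith("GT") and iseq.endswith("AG")

    def test_cluster_truth_recoverable(self):
        from scampps.genome_architecture import cluster_loci
        cfg = SimConfig(seed=9, n_genes=20, cluster_count=4)
        sim = make_genome(cfg)
        clusters = cluster_loci([t.feature for t in sim.truth])
        assert len(clusters) == 4
        assert sorted(c.count for c in clusters) == [5, 5, 5, 5]

    def test_sizing_error(self):
        cfg = SimConfig(seed=0, n_genes=5, cluster_count=1, genome_length=1000)
        with pytest.raises(ValueError, match="too short"):
            make_genome(cfg)

    def test_truth_gff3_round_trips(self, tmp_path):
        sim = make_genome(SimConfig(seed=2, n_genes=4, cluster_count=2))
        paths = write_bundle(sim, tmp_path)
        feats = read_gff3(paths["truth_gff3"])
        assert len(feats) == 4
        for f, t in zip(feats, sim.truth):
            assert (f.start, f.end) == (t.feature.start, t.feature.end)
            assert f.attributes["precursor"] == t.precursor


class TestMakeTranscriptPair:
    def test_zero_rates_identical(self, rng):
        cfg = SimConfig(flank_sub_rate=0.0, domain_sub_rate=0.0)
        a, b = make_transcript_pair("ACGT" * 100, (100, 130), cfg, rng)
        assert a == b == "ACGT" * 100

    def test_flank_identity_near_97_percent(self, rng):
        # two copies mutated at the default flank rate: expected pairwise
        # identity (1-r)^2 + r^2/3 ≈ 0.97; mean of 200 replicates within 3 SE
        cfg = SimConfig()
        tpl = "ACGT" * 120
        n_flank = len(tpl) - 30
        ids = []
        for _ in range(200):
            a, b = make_transcript_pair(tpl, (200, 230), cfg, rng)
            same = sum(x == y for x, y in zip(a, b))
            same_dom = sum(a[i] == b[i] for i in range(200, 230))
            ids.append((same - same_dom) / n_flank)
        r = cfg.flank_sub_rate
        expected = (1 - r) ** 2 + r ** 2 / 3
        se = np.sqrt(expected * (1 - expected) / (n_flank * 200))
        assert abs(np.mean(ids) - expected) <= 3 * se
        assert np.mean(ids) == pytest.approx(0.97, abs=0.01)

    def test_two_rate_signal_detected(self, rng):
        # power of the exact test at the stated default rates
        from scampps.hypervariability import (align_pair, label_domain,
                                              hypervariability_test)
        cfg = SimConfig()
        rejected = 0
        n = 50
        for _ in range(n):
            prec, iv = make_precursor(cfg, rng)
            gene = make_gene(prec, iv, cfg, rng)
            a, b = make_transcript_pair(gene.transcript,
                                        gene.domain_nt_transcript, cfg, rng)
            aln = align_pair(a, b)
            label_domain(aln, gene.domain_nt_transcript)
            rejected += hypervariability_test(aln, n_perm=0).p_exact <= 0.05
        assert rejected / n >= 0.8


class TestMakePeaklist:
    def test_planted_ions_at_exact_mz_without_jitter(self, rng):
        cfg = SimConfig(mz_noise_sd=0.0, noise_peaks=0)
        pl = make_peaklist(["GVPWAIAA"], cfg, rng, adducts=("M+H", "M+K"))
        assert len(pl) == 2
        m = cyclic_mass("GVPWAIAA")
        assert set(np.round(pl.mz, 6)) == {
            round(adduct_mz(m, "M+H"), 6), round(adduct_mz(m, "M+K"), 6)}

    def test_no_adducts_no_noise_one_peak_per_peptide(self, rng):
        cfg = SimConfig(noise_peaks=0)
        pl = make_peaklist(["GYVAA", "GGAPPWF"], cfg, rng, adducts=("M+H",))
        assert len(pl) == 2

    def test_match_peaks_recovers_all_planted_ions(self, rng):
        from scampps.orbitide_ms import theoretical_ions
        cfg = SimConfig(noise_peaks=20, mz_noise_sd=0.005)
        peps = ["GVPWAIAA", "GYVAA"]
        pl = make_peaklist(peps, cfg, rng)
        ions = [i for p in peps for i in theoretical_ions(p)]
        res = match_peaks(pl, ions, tol=0.1)
        assert all(r.matched for r in res)
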