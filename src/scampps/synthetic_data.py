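"""Synthetic genomes, transcripts and peak lists with known ground truth.

The generator emulates the structure of a plant orbitide-precursor gene
family:

* ~50-residue precursors: a conserved N-terminal leader, the WSE processing
  site, a hypervariable cyclic domain (G-initial, 5–10 residues, enriched in
  non-polar residues) and a conserved polar C-terminal flank;
* two-exon genes with an ~100 bp GT–AG intron inside the ~150 bp CDS and long
  UTRs giving ~450 nt transcripts;
* loci laid out in tandem clusters separated by long gaps, with NB-LRR-like
  dummy loci adjacent to a configurable fraction of clusters;
* paralogous transcript pairs diverging under a two-rate model (fast inside
  the cyclic-domain codons, slow elsewhere);
* LC-MS peak lists carrying the [M+H]+/[M+Na]+/[M+K]+ ions of cyclic products
  plus uniform decoy peaks.

Every generator is a pure function of (config, rng state): a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import orbitide_ms
from .io_formats import (FeatureRecord, GenomeSequence, PeakList,
                         TranscriptRecord, write_fasta, write_gff3)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "GeneSim",
    "SimulatedGenome",
    "make_precursor",
    "make_gene",
    "make_genome",
    "make_transcript_pair",
    "make_peaklist",
    "write_bundle",
]

# Conserved precursor scaffold (invented sequence, realistic shape): an
# M-initial leader ending just before the WSE processing site, and a polar
# C-terminal flank.  Precursor = LEADER + "WSE" + domain + C_FLANK.
LEADER = "MAKLTCLFVFALLLSLSAEIAEAR"   # 24 residues, signal-peptide-like
C_FLANK = "SDNKASELTSQTED"            # 14 residues, polar/charged

# Residue weights for drawing cyclic-domain positions after the initial G:
# non-polar-heavy, mirroring the composition bias of known products.
_DOMAIN_WEIGHTS = {
    "A": 14, "V": 10, "L": 10, "I": 10, "P": 12, "F": 10, "W": 10, "G": 6,
    "M": 2, "Y": 4, "S": 5, "T": 4, "N": 2, "Q": 1, "K": 3, "R": 2, "H": 1,
    "D": 1, "E": 1, "C": 1,
}
_DOMAIN_AA = np.array(list(_DOMAIN_WEIGHTS))
_DOMAIN_P = np.array(list(_DOMAIN_WEIGHTS.values()), dtype=float)
_DOMAIN_P /= _DOMAIN_P.sum()

# standard nuclear code, inverted: amino acid -> codons (stops kept apart)
_STANDARD_CODONS: dict[str, list[str]] = {}
for _codon in ("".join(b) for b in itertools.product("TCAG", repeat=3)):
    _STANDARD_CODONS.setdefault(str(Seq(_codon).translate()), []).append(_codon)
STOP_CODONS = _STANDARD_CODONS.pop("*")

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the simulated world (defaults follow the stated biology).

    ``flank_sub_rate``/``domain_sub_rate`` are per-site, per-copy substitution
    probabilities for :func:`make_transcript_pair`; the defaults (0.0152 and
    0.383) put the expected pairwise identity of two independently mutated
    copies at ~97% (flank) and ~43% (domain), the contrast reported for real
    paralog pairs.
    """

    seed: int = 0
    n_genes: int = 20
    cluster_count: int = 4
    intron_len_mean: int = 100
    intron_len_sd: int = 10
    utr5_len: int = 150
    utr3_len: int = 150
    domain_len_range: tuple[int, int] = (5, 10)
    flank_sub_rate: float = 0.0152
    domain_sub_rate: float = 0.383
    nblrr_per_cluster: int = 3
    nblrr_assoc_fraction: float = 1.0
    noise_peaks: int = 10
    mz_noise_sd: float = 0.005
    precursor_sub_rate: float = 0.0
    expressed_fraction: float = 0.35
    intra_gap_range: tuple[int, int] = (2_000, 8_000)
    inter_cluster_gap: int = 300_000
    margin: int = 10_000
    genome_length: int | None = None  # None -> auto-sized
    random_strand: bool = True

    def validate(self) -> None:
        for r in (self.flank_sub_rate, self.domain_sub_rate,
                  self.precursor_sub_rate, self.nblrr_assoc_fraction,
                  self.expressed_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        lo, hi = self.domain_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid domain_len_range")
        for v in (self.n_genes, self.cluster_count, self.intron_len_mean,
                  self.utr5_len, self.utr3_len, self.margin):
            if v < 0:
                raise ValueError("lengths/counts must be non-negative")
        if self.intron_len_mean < 20:
            raise ValueError("intron_len_mean must be >= 20 (GT..AG core)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GeneSim:
    """One simulated gene in gene-local forward coordinates."""

    seq: str                      # utr5 + exon1 + intron + exon2 + utr3
    cds: tuple[int, int]          # local, includes stop codon
    intron: tuple[int, int]       # local
    transcript: str               # spliced: utr5 + CDS + utr3
    domain_nt_transcript: tuple[int, int]  # cyclic-domain codons on transcript
    precursor: str
    domain: str
    domain_interval: tuple[int, int]       # on the precursor


@dataclass
class TruthRecord:
    """Ground truth for one planted locus, in absolute genome coordinates."""

    feature: FeatureRecord        # type "gene", full gene span
    cds: tuple[int, int]
    intron: tuple[int, int]
    precursor: str
    domain: str
    domain_interval: tuple[int, int]
    expressed: bool
    cluster: int
    gene: GeneSim

    def __post_init__(self) -> None:
        d0, d1 = self.domain_interval
        assert self.precursor[d0:d1] == self.domain
        assert self.domain.startswith("G")
        assert self.precursor[d0 - 3:d0] == "WSE"


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    truth: list[TruthRecord]
    nblrr: list[FeatureRecord]
    transcripts: list[TranscriptRecord]
    config: SimConfig


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_precursor(config: SimConfig, rng: np.random.Generator,
                   domain: str | None = None) -> tuple[str, tuple[int, int]]:
    """Draw one precursor protein; returns (protein, domain interval).

    The domain is G followed by residues drawn from a non-polar-weighted
    distribution, its length uniform over ``domain_len_range``; pass
    ``domain`` to force a specific product (e.g. a published one).

    ``precursor_sub_rate`` applies per-residue substitutions everywhere except
    the start Met, the WSE processing site and the domain-initial G, so family
    members drift from the consensus while the anchors that define the family
    stay intact.
    """
    config.validate()
    if domain is None:
        lo, hi = config.domain_len_range
        length = int(rng.integers(lo, hi + 1))
        domain = "G" + "".join(rng.choice(_DOMAIN_AA, size=length - 1,
                                          p=_DOMAIN_P))
    precursor = LEADER + "WSE" + domain + C_FLANK
    start = len(LEADER) + 3
    if config.precursor_sub_rate > 0:
        aa20 = "ACDEFGHIKLMNPQRSTVWY"
        # family-defining anchors are under purifying selection: the start
        # Met, the WSE processing site and the domain-initial G stay fixed
        protected = {0, *range(len(LEADER), start + 1)}
        chars = list(precursor)
        hit = rng.random(len(chars)) < config.precursor_sub_rate
        for i in np.flatnonzero(hit):
            if int(i) in protected:
                continue
            options = [a for a in aa20 if a != chars[i]]
            chars[i] = options[rng.integers(0, len(options))]
        precursor = "".join(chars)
    return precursor, (start, start + len(domain))


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_STANDARD_CODONS[aa][rng.integers(0, len(_STANDARD_CODONS[aa]))]
              for aa in protein]
    codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    return "".join(codons)


def make_gene(precursor: str, domain_interval: tuple[int, int],
              config: SimConfig, rng: np.random.Generator) -> GeneSim:
    """Build a two-exon gene around a precursor protein.

    The CDS (uniform synonymous codons plus a stop) is split at a uniform
    internal position by a GT..AG intron of length Normal(mean, sd) (exact at
    sd=0, floor 20), then flanked by UTRs so the spliced transcript comes out
    near 450 nt at the default UTR lengths.
    """
    cds = _back_translate(precursor, rng)
    cds_len = len(cds)  # 3 * (len(precursor) + 1), stop included
    split = int(rng.integers(3, cds_len - 2))  # any phase, strictly internal
    ilen = config.intron_len_mean if config.intron_len_sd == 0 else max(
        20, int(round(rng.normal(config.intron_len_mean, config.intron_len_sd))))
    intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
    utr5 = _random_dna(rng, config.utr5_len)
    utr3 = _random_dna(rng, config.utr3_len)
    seq = utr5 + cds[:split] + intron + cds[split:] + utr3
    d0, d1 = domain_interval
    return GeneSim(
        seq=seq,
        cds=(len(utr5), len(utr5) + cds_len + ilen),
        intron=(len(utr5) + split, len(utr5) + split + ilen),
        transcript=utr5 + cds + utr3,
        domain_nt_transcript=(len(utr5) + 3 * d0, len(utr5) + 3 * d1),
        precursor=precursor,
        domain=precursor[d0:d1],
        domain_interval=domain_interval,
    )


def _splice(gene: GeneSim) -> str:
    i0, i1 = gene.intron
    return gene.seq[:i0] + gene.seq[i1:]


def make_genome(config: SimConfig, name: str = "chrS") -> SimulatedGenome:
    """Plant ``n_genes`` genes in ``cluster_count`` tandem clusters on one
    chromosome-like sequence, with NB-LRR dummy loci adjacent to a fraction of
    clusters, and emit exact truth records.
    """
    config.validate()
    if config.cluster_count < 1 or config.n_genes < 1:
        raise ValueError("need at least one cluster and one gene")
    rng = config.rng()
    # round-robin gene counts per cluster
    sizes = [config.n_genes // config.cluster_count] * config.cluster_count
    for i in range(config.n_genes % config.cluster_count):
        sizes[i] += 1
    placements = []   # (pos, strand, GeneSim, expressed, cluster)
    nblrr_pos = []    # (start, end, cluster)
    cursor = config.margin
    for ci, size in enumerate(sizes):
        # NB-LRR dummies are interleaved with the genes of associated
        # clusters, mirroring the mixed tandem arrays seen on real
        # chromosomes (resistance-gene and peptide-gene duplications share
        # the same array)
        associated = rng.random() < config.nblrr_assoc_fraction
        slots = {(k + 1) * size // (config.nblrr_per_cluster + 1)
                 for k in range(config.nblrr_per_cluster)} if associated else set()
        for gi in range(size):
            if gi in slots:
                cursor += int(rng.integers(2_000, 6_000))
                nblrr_pos.append((cursor, cursor + 4_000, ci))
                cursor += 4_000
            precursor, dom_iv = make_precursor(config, rng)
            gene = make_gene(precursor, dom_iv, config, rng)
            strand = "-" if (config.random_strand and rng.random() < 0.5) else "+"
            expressed = bool(rng.random() < config.expressed_fraction)
            placements.append((cursor, strand, gene, expressed, ci))
            lo, hi = config.intra_gap_range
            cursor += len(gene.seq) + int(rng.integers(lo, hi + 1))
        # jittered spacing: a near-periodic layout would be unrealistic and
        # would let circular rotations re-align clusters with NB-LRR blocks
        gap = int(config.inter_cluster_gap * rng.uniform(0.5, 1.5))
        cursor += gap
    total = cursor - gap + config.margin
    if config.genome_length is not None:
        if config.genome_length < total:
            raise ValueError(
                f"genome_length {config.genome_length} too short; "
                f"layout needs {total} bp")
        total = config.genome_length
    arr = _BASES[rng.integers(0, 4, size=total)]
    truth: list[TruthRecord] = []
    transcripts: list[TranscriptRecord] = []
    for gi, (pos, strand, gene, expressed, ci) in enumerate(placements):
        gseq = gene.seq if strand == "+" else str(Seq(gene.seq).reverse_complement())
        arr[pos:pos + len(gene.seq)] = list(gseq)
        glen = len(gene.seq)

        def abs_iv(local):
            s, e = local
            if strand == "+":
                return (pos + s, pos + e)
            return (pos + glen - e, pos + glen - s)

        gene_id = f"scampps_sim_{gi:03d}"
        feature = FeatureRecord(
            seqid=name, start=pos, end=pos + glen, strand=strand, type="gene",
            attributes={"ID": gene_id, "cluster": str(ci),
                        "expressed": str(expressed).lower(),
                        "precursor": gene.precursor, "domain": gene.domain},
        )
        truth.append(TruthRecord(
            feature=feature, cds=abs_iv(gene.cds), intron=abs_iv(gene.intron),
            precursor=gene.precursor, domain=gene.domain,
            domain_interval=gene.domain_interval, expressed=expressed,
            cluster=ci, gene=gene,
        ))
        if expressed:
            transcripts.append(TranscriptRecord(
                id=f"EST_{gene_id}", seq=gene.transcript,
                description=f"simulated transcript of {gene_id}"))
    nblrr = [
        FeatureRecord(seqid=name, start=s, end=e, strand="+", type="nblrr",
                      attributes={"ID": f"nblrr_{i:03d}", "cluster": str(ci)})
        for i, (s, e, ci) in enumerate(nblrr_pos)
    ]
    genome = GenomeSequence(name=name, seq="".join(arr))
    return SimulatedGenome(genome=genome, truth=truth, nblrr=nblrr,
                           transcripts=transcripts, config=config)


def make_transcript_pair(transcript: str, domain_interval: tuple[int, int],
                         config: SimConfig, rng: np.random.Generator
                         ) -> tuple[str, str]:
    """Two independently mutated copies of a transcript under the two-rate
    model: ``domain_sub_rate`` per site inside the cyclic-domain codons,
    ``flank_sub_rate`` elsewhere; substitutions only (truth intervals stay
    exact)."""
    config.validate()
    d0, d1 = domain_interval
    if not (0 <= d0 <= d1 <= len(transcript)):
        raise ValueError("domain interval outside transcript")
    rates = np.full(len(transcript), config.flank_sub_rate)
    rates[d0:d1] = config.domain_sub_rate

    def mutate() -> str:
        seq = np.array(list(transcript))
        hit = rng.random(len(seq)) < rates
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, 3)]
        return "".join(seq)

    return mutate(), mutate()


def make_peaklist(peptides, config: SimConfig, rng: np.random.Generator,
                  adducts=("M+H", "M+Na", "M+K"), convention: str = "atom"
                  ) -> PeakList:
    """Peak list containing the molecular-ion series of each cyclic peptide
    (m/z jitter ~ Normal(0, mz_noise_sd)) plus ``noise_peaks`` uniform decoys.

    Truth is attached as ``PeakList.annotations``: a dict with the peptide and
    species for planted ions, ``None`` for decoys.
    """
    config.validate()
    mz, inten, notes = [], [], []
    for pep in peptides:
        seq = pep.residues if hasattr(pep, "residues") else str(pep)
        mass = orbitide_ms.cyclic_mass(seq)
        for sp in adducts:
            true_mz = orbitide_ms.adduct_mz(mass, sp, convention)
            jitter = rng.normal(0.0, config.mz_noise_sd) if config.mz_noise_sd else 0.0
            mz.append(true_mz + jitter)
            inten.append(float(rng.lognormal(mean=9.0, sigma=0.5)))
            notes.append({"peptide": seq, "species": sp, "true_mz": true_mz})
    for _ in range(config.noise_peaks):
        mz.append(float(rng.uniform(300.0, 1200.0)))
        inten.append(float(rng.lognormal(mean=5.0, sigma=1.0)))
        notes.append(None)
    return PeakList(mz=np.array(mz), intensity=np.array(inten), annotations=notes)


def write_bundle(sim: SimulatedGenome, outdir) -> dict[str, Path]:
    """Write genome, transcripts, precursors and truth tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "precursors": outdir / "precursors.fa",
        "truth_gff3": outdir / "truth_genes.gff3",
        "nblrr_gff3": outdir / "nblrr.gff3",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_fasta([sim.genome], paths["genome"])
    if sim.transcripts:
        write_fasta(sim.transcripts, paths["transcripts"])
    with open(paths["precursors"], "w") as fh:
        for t in sim.truth:
            fh.write(f">{t.feature.attributes['ID']}\n{t.precursor}\n")
    feats = []
    for t in sim.truth:
        f = t.feature
        attrs = dict(f.attributes)
        attrs.update({"cds_start": str(t.cds[0]), "cds_end": str(t.cds[1]),
                      "intron_start": str(t.intron[0]),
                      "intron_end": str(t.intron[1])})
        feats.append(FeatureRecord(seqid=f.seqid, start=f.start, end=f.end,
                                   strand=f.strand, type=f.type, attributes=attrs))
    write_gff3(feats, paths["truth_gff3"])
    write_gff3(sim.nblrr, paths["nblrr_gff3"])
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("id\tcluster\texpressed\tprecursor\tdomain\n")
        for t in sim.truth:
            fh.write(f"{t.feature.attributes['ID']}\t{t.cluster}\t"
                     f"{str(t.expressed).lower()}\t{t.precursor}\t{t.domain}\n")
    return paths
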