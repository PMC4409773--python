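"""From candidate loci to gene models with expression evidence.

A candidate locus from the scanner covers only the consensus-aligned core.
Here the CDS is extended outward to the nearest in-frame start and stop
codons, the precursor protein is re-deduced from the spliced CDS, and each
model is classified as expressed when at least one transcript (EST) aligns to
the spliced gene region at high identity — the criterion used to call a locus
an expressed gene rather than an unexpressed or pseudogene copy.

Identity here is computed over aligned columns excluding terminal overhangs
(the transcript's UTRs may extend past the extracted gene region); the
threshold pair (min_identity, min_aligned_fraction) is carried in the report
so counts are always interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .io_formats import FeatureRecord, GenomeSequence
from .precursor_scan import CandidateLocus

__all__ = [
    "PrecursorModel",
    "build_gene_model",
    "associate_transcripts",
    "family_report",
    "models_to_features",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class PrecursorModel:
    """A finished gene model: locus structure plus deduced precursor protein."""

    locus: CandidateLocus
    exon1: tuple[int, int]        # CDS part, genomic coords, coding-first
    exon2: tuple[int, int]
    protein: str
    partial_start: bool
    partial_end: bool
    pseudo: bool
    supporters: list[tuple[str, float, int]] = field(default_factory=list)
    expressed: bool = False
    family: str = ""

    @property
    def seqid(self) -> str:
        return self.locus.seqid

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def intron(self) -> tuple[int, int]:
        return self.locus.intron

    @property
    def cds_span(self) -> tuple[int, int]:
        coords = [*self.exon1, *self.exon2]
        return (min(coords), max(coords))

    @property
    def partial(self) -> bool:
        return self.partial_start or self.partial_end


def _spliced_cds(genome: GenomeSequence, strand: str, exon1, exon2) -> str:
    return genome.fetch(*exon1, strand) + genome.fetch(*exon2, strand)


def build_gene_model(candidate: CandidateLocus, genome: GenomeSequence,
                     search_window: int = 60) -> PrecursorModel:
    """Extend a candidate to start/stop codons and deduce the precursor.

    The upstream search walks in-frame codons (within ``search_window`` nt on
    the spliced sequence) for an ATG, stopping at an intervening stop codon;
    the downstream search looks for the nearest in-frame stop.  A missing end
    flags the model partial; an internal stop demotes it to the pseudo tier.
    """
    strand = candidate.strand
    exon1, exon2 = list(candidate.exon1), list(candidate.exon2)

    # work on the coding strand with a helper that grows exon boundaries
    def grow_upstream(n):  # prepend n nt of genomic context to exon1
        if strand == "+":
            take = min(n, exon1[0])
            exon1[0] -= take
        else:
            take = min(n, len(genome) - exon1[1])
            exon1[1] += take
        return take

    def grow_downstream(n):
        if strand == "+":
            take = min(n, len(genome) - exon2[1])
            exon2[1] += take
        else:
            take = min(n, exon2[0])
            exon2[0] -= take
        return take

    up_taken = grow_upstream(search_window)
    down_taken = grow_downstream(search_window)
    cds = _spliced_cds(genome, strand, tuple(exon1), tuple(exon2))

    # upstream: in-frame ATG nearest the aligned core, stopping at a stop
    partial_start = True
    start_off = up_taken
    for off in range(up_taken, -1, -3):
        codon = cds[off:off + 3]
        if codon == "ATG":
            start_off = off
            partial_start = False
            break
        if codon in _STOPS:
            break

    # downstream: nearest in-frame stop after the original end
    core_end = len(cds) - down_taken
    partial_end = True
    end_off = core_end
    scan = core_end - (core_end - start_off) % 3
    for off in range(scan, len(cds) - 2, 3):
        if cds[off:off + 3] in _STOPS:
            end_off = off + 3
            partial_end = False
            break

    final_cds = cds[start_off:end_off]
    usable = len(final_cds) - len(final_cds) % 3
    protein = str(Seq(final_cds[:usable]).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    pseudo = "*" in protein or candidate.pseudo

    # shrink exon coordinates back to [start_off, end_off) on the spliced axis
    e1_len = exon1[1] - exon1[0]

    def cut(start_cut, end_cut):
        # start_cut nt removed from the coding 5' end, end_cut from the 3' end
        a1, a2 = list(exon1), list(exon2)
        take1 = min(start_cut, e1_len)
        rest = start_cut - take1
        if strand == "+":
            a1[0] += take1
            a2[0] += rest
        else:
            a1[1] -= take1
            a2[1] -= rest
        take2 = min(end_cut, a2[1] - a2[0])
        rest2 = end_cut - take2
        if strand == "+":
            a2[1] -= take2
            a1[1] -= rest2
        else:
            a2[0] += take2
            a1[0] += rest2
        return tuple(a1), tuple(a2)

    new_exon1, new_exon2 = cut(start_off, len(cds) - end_off)
    return PrecursorModel(
        locus=candidate, exon1=new_exon1, exon2=new_exon2, protein=protein,
        partial_start=partial_start, partial_end=partial_end, pseudo=pseudo,
    )


def _identity_local(aligner: Align.PairwiseAligner, a: str, b: str
                    ) -> tuple[float, int]:
    """(identity, aligned length) of the best local hit.

    The denominator is every column of the local alignment — matches,
    mismatches and *internal* gap columns (terminal overhangs are trimmed by
    the local mode).  Counting internal gaps matters: an intron-retaining
    transcript must not reach the identity of a correctly spliced one.
    """
    aln = aligner.align(a, b)
    if len(aln) == 0:
        return 0.0, 0
    top = aln[0]
    sa, sb = str(top[0]), str(top[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    aligned = len(sa)
    return (matches / aligned if aligned else 0.0), aligned


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1)}


def associate_transcripts(models, transcripts, genome: GenomeSequence | None = None,
                          min_identity: float = 0.99,
                          min_aligned_fraction: float = 0.8,
                          utr_pad: int = 250, kmer: int = 15):
    """Attach transcript support to each model and set the expression flag.

    Each transcript is aligned (local, both orientations) against the model's
    spliced gene region — the CDS exons plus ``utr_pad`` nt of flanking
    genomic sequence on each side with the intron removed (precomputed via
    :func:`attach_regions` when ``genome`` is given).  A transcript supports a
    model when identity ≥ ``min_identity`` over ≥ ``min_aligned_fraction`` of
    the transcript.  A shared-k-mer prefilter skips alignments that cannot
    reach the identity floor.  Returns the same model list, mutated.
    """
    models = list(models)
    transcripts = list(transcripts)
    if genome is not None:
        attach_regions(models, genome, utr_pad=utr_pad)
    for m in models:
        if not hasattr(m, "spliced_region"):
            raise ValueError("models lack spliced regions; pass genome= or "
                             "run attach_regions first")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    if not transcripts:
        for m in models:
            m.supporters = []
            m.expressed = False
        return models
    t_kmers = {t.id: _kmer_set(t.seq, kmer) for t in transcripts}
    for m in models:
        region = m.spliced_region
        m.supporters = []
        r_kmers = _kmer_set(region, kmer) | _kmer_set(
            str(Seq(region).reverse_complement()), kmer)
        for t in transcripts:
            if not (t_kmers[t.id] & r_kmers):
                continue
            best_id, best_len = 0.0, 0
            for seq in (t.seq, str(Seq(t.seq).reverse_complement())):
                ident, alen = _identity_local(aligner, region, seq)
                if (ident, alen) > (best_id, best_len):
                    best_id, best_len = ident, alen
            if (best_id >= min_identity
                    and best_len >= min_aligned_fraction * len(t.seq)):
                m.supporters.append((t.id, round(100 * best_id, 3), best_len))
        m.supporters.sort(key=lambda s: (-s[1], -s[2], s[0]))
        m.expressed = bool(m.supporters)
    return models


def attach_regions(models, genome: GenomeSequence, utr_pad: int = 250):
    """Precompute each model's spliced gene region (CDS ± UTR pad, intron
    removed, coding orientation) for transcript association."""
    for m in models:
        e1, e2 = list(m.exon1), list(m.exon2)
        if m.strand == "+":
            e1[0] = max(0, e1[0] - utr_pad)
            e2[1] = min(len(genome), e2[1] + utr_pad)
        else:
            e1[1] = min(len(genome), e1[1] + utr_pad)
            e2[0] = max(0, e2[0] - utr_pad)
        m.spliced_region = (genome.fetch(*e1, m.strand)
                            + genome.fetch(*e2, m.strand))
    return models


def family_report(models, thresholds: dict | None = None) -> pd.DataFrame:
    """Per-sequence tallies of total / expressed / pseudo / partial loci.

    Deterministic (sorted by seqid, with a TOTAL row last) and invariant to
    the input order of models.
    """
    rows = {}
    for m in models:
        r = rows.setdefault(m.seqid, {"seqid": m.seqid, "loci": 0,
                                      "expressed": 0, "pseudo": 0, "partial": 0})
        r["loci"] += 1
        r["expressed"] += int(m.expressed)
        r["pseudo"] += int(m.pseudo)
        r["partial"] += int(m.partial)
    out = [rows[k] for k in sorted(rows)]
    total = {"seqid": "TOTAL",
             "loci": sum(r["loci"] for r in out),
             "expressed": sum(r["expressed"] for r in out),
             "pseudo": sum(r["pseudo"] for r in out),
             "partial": sum(r["partial"] for r in out)}
    out.append(total)
    df = pd.DataFrame(out, columns=["seqid", "loci", "expressed", "pseudo",
                                    "partial"])
    if thresholds:
        df.attrs["thresholds"] = dict(thresholds)
    return df


def models_to_features(models) -> list[FeatureRecord]:
    """Flatten models to gene/CDS/intron features for GFF3 output."""
    feats = []
    for i, m in enumerate(models):
        span = m.cds_span
        gene_id = f"scampps_model_{i:03d}"
        feats.append(FeatureRecord(
            seqid=m.seqid, start=span[0], end=span[1], strand=m.strand,
            type="pseudogene" if m.pseudo else "gene",
            attributes={"ID": gene_id, "protein": m.protein,
                        "expressed": str(m.expressed).lower(),
                        "partial": str(m.partial).lower(),
                        "score": f"{m.locus.score:.1f}",
                        "supporters": ",".join(s[0] for s in m.supporters)}))
        for part, iv in (("CDS", m.exon1), ("intron", m.intron), ("CDS", m.exon2)):
            feats.append(FeatureRecord(
                seqid=m.seqid, start=iv[0], end=iv[1], strand=m.strand,
                type=part, attributes={"Parent": gene_id}))
    return feats
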