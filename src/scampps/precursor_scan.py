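"""Spliced six-frame consensus scan for orbitide-precursor loci.

The historical identification of these loci used visual dot-matrix comparison
of a precursor consensus against downloaded chromosomes.  This module replaces
that with a reproducible two-phase scan:

1. *Seeding* — Smith–Waterman local alignment (BLOSUM62) of the consensus
   against overlapping windows of all six translated frames.  A real two-exon
   gene shows up as at least one strong partial hit, because the intron can
   interrupt the coding region at any phase but always leaves one exon with
   most of the precursor.
2. *Splice refinement* — around each seed, every GT..AG intron candidate whose
   length falls in the configured window is excised, the spliced DNA is
   re-translated in the seed's frame, and the consensus is re-aligned against
   the spliced translation.  The best-scoring splice that actually spans the
   junction defines the candidate locus, with exact exon/intron coordinates.

Candidates whose spliced translation contains an internal stop are kept in a
separate "pseudo" tier rather than dropped, mirroring the pseudogene copies
that real assemblies carry.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GenomeSequence

__all__ = [
    "ConsensusProfile",
    "CandidateLocus",
    "ScanParams",
    "Frame",
    "build_consensus",
    "six_frame_translate",
    "scan_spliced",
    "candidate_to_feature",
    "feature_to_candidate",
]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Majority-rule consensus of precursor proteins with motif anchors.

    ``motif_start`` indexes the W of the WSE processing site; ``domain_g`` the
    conserved G that opens the cyclic domain (both on the consensus string).
    """

    consensus: str
    motif_start: int
    domain_g: int
    column_support: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not 30 <= len(self.consensus) <= 80:
            raise ValueError(
                f"consensus length {len(self.consensus)} outside [30, 80]")
        if self.consensus[self.domain_g] != "G":
            raise ValueError("domain_g does not point at a G")

    def __len__(self) -> int:
        return len(self.consensus)


def _align_with_mafft(seqs: list[str]) -> list[str]:
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError(
            "precursors are not equal-length and mafft is not on PATH; "
            "supply a pre-aligned precursor set")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        fin.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        out = subprocess.run([exe, "--auto", "--quiet", str(fin)],
                             capture_output=True, text=True, check=True)
        fout = Path(tmp) / "out.fa"
        fout.write_text(out.stdout)
        recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fout), "fasta")}
    return [recs[f"s{i}"] for i in range(len(seqs))]


def build_consensus(precursors, majority_threshold: float = 0.5,
                    require_motif: bool = True) -> ConsensusProfile:
    """Majority-rule consensus profile from ≥2 precursor proteins.

    Equal-length inputs are treated as already aligned; otherwise they are
    aligned with MAFFT.  Per column: the majority residue if its fraction of
    non-gap characters reaches ``majority_threshold`` (ties broken
    alphabetically), else ``X``; gap-majority columns are dropped.  Raises if
    the WSE-G anchor cannot be located in the consensus.
    """
    seqs = [str(s).upper() for s in precursors]
    if len(seqs) < 2:
        raise ValueError("need at least two precursors")
    if len({len(s) for s in seqs}) > 1:
        seqs = _align_with_mafft(seqs)
    ncol = len(seqs[0])
    letters: list[str] = []
    support: list[float] = []
    for col in range(ncol):
        column = [s[col] for s in seqs]
        residues = [c for c in column if c != "-"]
        if len(residues) * 2 <= len(column):
            continue  # gap-majority column
        best = max(sorted(set(residues)), key=residues.count)
        frac = residues.count(best) / len(column)
        letters.append(best if frac >= majority_threshold else "X")
        support.append(frac)
    consensus = "".join(letters)
    at = consensus.find("WSEG")
    if at < 0:
        if require_motif:
            raise ValueError(
                "WSE-G processing-site anchor not found in consensus; "
                "annotate the motif manually or lower the threshold")
        at = 0
    return ConsensusProfile(consensus=consensus, motif_start=at,
                            domain_g=at + 3, column_support=support)


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

def _translate(dna: str) -> str:
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


@dataclass
class Frame:
    """One translated reading frame with an exact residue→codon coordinate map."""

    strand: str
    offset: int          # 0, 1 or 2 on the reading strand
    protein: str
    genome_length: int

    def codon_interval(self, i: int) -> tuple[int, int]:
        """Forward-strand genomic interval of the codon for residue ``i``."""
        if not 0 <= i < len(self.protein):
            raise IndexError(f"residue {i} outside frame")
        local = self.offset + 3 * i
        if self.strand == "+":
            return (local, local + 3)
        return (self.genome_length - local - 3, self.genome_length - local)


def six_frame_translate(genome: GenomeSequence) -> list[Frame]:
    """All six translated frames of a genome sequence (non-ACGT read as N→X)."""
    if len(genome) < 3:
        raise ValueError("genome too short to translate")
    fwd = genome.scan_seq
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for offset in range(3):
            frames.append(Frame(strand=strand, offset=offset,
                                protein=_translate(seq[offset:]),
                                genome_length=len(genome)))
    return frames


# ---------------------------------------------------------------------------
# Spliced scan
# ---------------------------------------------------------------------------

@dataclass
class ScanParams:
    gap_open: float = 11.0
    gap_extend: float = 1.0
    seed_min_score: float = 60.0
    min_combined_score: float = 100.0
    intron_window: tuple[int, int] = (50, 500)
    window_size: int = 400
    window_step: int = 300
    pad: int = 12          # nt slack around the seed-implied CDS bounds
    stop_bonus: float = 3.0  # rank bonus for an in-frame stop right after the match
    include_pseudo: bool = True


@dataclass
class CandidateLocus:
    """A scored candidate locus with exact spliced gene structure.

    ``exon1`` is coding-first: on the minus strand its forward-strand
    coordinates lie to the right of ``exon2``.  All intervals are genomic,
    0-based half-open.
    """

    seqid: str
    strand: str
    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    score: float
    translation: str
    pseudo: bool = False
    consensus_span: tuple[int, int] = (0, 0)

    @property
    def span(self) -> tuple[int, int]:
        coords = [*self.exon1, *self.intron, *self.exon2]
        return (min(coords), max(coords))

    @property
    def spliced_length(self) -> int:
        return (self.exon1[1] - self.exon1[0]) + (self.exon2[1] - self.exon2[0])

    def validate(self, genome: GenomeSequence,
                 intron_window: tuple[int, int] = (50, 500)) -> None:
        """Assert every structural invariant of the type."""
        if self.strand == "+":
            assert self.exon1[1] == self.intron[0], "intron must abut exon1"
            assert self.intron[1] == self.exon2[0], "intron must abut exon2"
        else:
            assert self.exon2[1] == self.intron[0], "intron must abut exon2"
            assert self.intron[1] == self.exon1[0], "intron must abut exon1"
        iseq = genome.fetch(*self.intron, strand=self.strand)
        assert iseq.startswith("GT") and iseq.endswith("AG"), \
            "intron must be GT..AG on the coding strand"
        lo, hi = intron_window
        assert lo <= self.intron[1] - self.intron[0] <= hi
        if not self.pseudo:
            assert "*" not in self.translation, "internal stop in non-pseudo locus"


def _make_local_aligner(params: ScanParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _seed_hits(frames, aligner, profile, params):
    """Windowed local alignments of the consensus against each frame."""
    seeds = []
    seen = set()
    cons = profile.consensus
    for fi, frame in enumerate(frames):
        prot = frame.protein
        step = params.window_step
        for w0 in range(0, max(1, len(prot)), step):
            window = prot[w0:w0 + params.window_size]
            if len(window) < 10:
                continue
            try:
                aln = aligner.align(window, cons)
            except (ValueError, OverflowError):
                continue
            if len(aln) == 0 or aln.score < params.seed_min_score:
                continue
            best = aln[0]
            t_blocks, q_blocks = best.aligned
            ps = int(t_blocks[0][0]) + w0
            pe = int(t_blocks[-1][1]) + w0
            qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
            key = (fi, ps)
            if key in seen:
                continue
            seen.add(key)
            seeds.append({"frame": frame, "score": float(best.score),
                          "ps": ps, "pe": pe, "qs": qs, "qe": qe})
    return seeds


def _refine_seed(strand_seq, seed, aligner, profile, params):
    """Enumerate GT..AG splices around a seed; return the best spliced match.

    Works in strand-local nt coordinates (the reading strand's own sequence);
    the caller converts back to forward-strand genomic coordinates.
    """
    frame = seed["frame"]
    imin, imax = params.intron_window
    g_start = frame.offset + 3 * seed["ps"]
    g_end = frame.offset + 3 * seed["pe"]
    pre, post = seed["qs"], len(profile.consensus) - seed["qe"]
    # if consensus columns are missing before the seed, the intron (and the
    # first exon) may lie up to an intron-length further upstream
    up = 3 * pre + (imax + params.pad if pre > 0 else params.pad)
    cds_lo = max(0, g_start - up)
    cds_hi = min(len(strand_seq), g_end + 3 * post + params.pad)
    best = None
    for d in range(cds_lo + 3, cds_hi):
        if strand_seq[d:d + 2] != "GT":
            continue
        for e in range(d + imin, min(d + imax, len(strand_seq) - 1) + 1):
            if strand_seq[e - 2:e] != "AG":
                continue
            tail_hi = min(len(strand_seq), cds_hi + (e - d))
            if e >= tail_hi:
                continue
            spliced = strand_seq[cds_lo:d] + strand_seq[e:tail_hi]
            # translation frame anchored on the seed
            if g_start < d:
                o = (g_start - cds_lo) % 3
            else:
                o = (g_start - cds_lo - (e - d)) % 3
            prot = _translate(spliced[o:])
            if not prot:
                continue
            try:
                aln = aligner.align(prot, profile.consensus)
            except (ValueError, OverflowError):
                continue
            if len(aln) == 0:
                continue
            top = aln[0]
            t_blocks, _q_blocks = top.aligned
            ts, te = int(t_blocks[0][0]), int(t_blocks[-1][1])
            sn_start, sn_end = o + 3 * ts, o + 3 * te  # spliced nt, rel cds_lo
            junction = d - cds_lo
            if not (sn_start < junction < sn_end):
                continue  # match must actually span the splice
            # a stop codon immediately after the matched region marks a
            # complete gene structure; use it to break near-ties between
            # splice variants that encode the same protein
            rank_score = float(top.score)
            if te < len(prot) and prot[te] == "*":
                rank_score += params.stop_bonus
            cand = {
                "score": float(top.score),
                "exon1": (cds_lo + sn_start, d),
                "intron": (d, e),
                "exon2": (e, cds_lo + sn_end + (e - d)),
                "translation": prot[ts:te],
                "q_span": (int(_q_blocks[0][0]), int(_q_blocks[-1][1])),
            }
            key = (rank_score, cand["exon1"][1] - cand["exon1"][0]
                   + cand["exon2"][1] - cand["exon2"][0], -d)
            if best is None or key > best[0]:
                best = (key, cand)
    return None if best is None else best[1]


def scan_spliced(genome: GenomeSequence, profile: ConsensusProfile,
                 params: ScanParams | None = None) -> list[CandidateLocus]:
    """Scan a genome sequence for spliced matches to the precursor consensus.

    Returns candidates sorted by descending combined score; overlapping
    candidates are resolved to the best-scoring one (ties: longer spliced
    match, then leftmost).  Pseudogene-like hits (internal stop in the spliced
    translation) carry ``pseudo=True``.
    """
    if params is None:
        params = ScanParams()
    aligner = _make_local_aligner(params)
    frames = six_frame_translate(genome)
    fwd = genome.scan_seq
    rev = str(Seq(fwd).reverse_complement())
    strand_seqs = {"+": fwd, "-": rev}
    L = len(genome)
    raw: list[CandidateLocus] = []
    for seed in _seed_hits(frames, aligner, profile, params):
        strand = seed["frame"].strand
        refined = _refine_seed(strand_seqs[strand], seed, aligner, profile, params)
        if refined is None or refined["score"] < params.min_combined_score:
            continue

        def to_genomic(iv):
            if strand == "+":
                return iv
            return (L - iv[1], L - iv[0])

        translation = refined["translation"]
        pseudo = "*" in translation
        if pseudo and not params.include_pseudo:
            continue
        raw.append(CandidateLocus(
            seqid=genome.name, strand=strand,
            exon1=to_genomic(refined["exon1"]),
            intron=to_genomic(refined["intron"]),
            exon2=to_genomic(refined["exon2"]),
            score=refined["score"], translation=translation, pseudo=pseudo,
            consensus_span=refined["q_span"],
        ))
    # de-duplicate identical structures found from multiple seeds
    unique = {}
    for c in raw:
        key = (c.strand, c.exon1, c.intron, c.exon2)
        if key not in unique or c.score > unique[key].score:
            unique[key] = c
    ranked = sorted(unique.values(),
                    key=lambda c: (-c.score, -c.spliced_length, c.span[0]))
    kept: list[CandidateLocus] = []
    for c in ranked:
        s, e = c.span
        if any(not (e <= k.span[0] or s >= k.span[1]) for k in kept):
            continue
        kept.append(c)
    return kept


def candidate_to_feature(candidate: CandidateLocus):
    """Serialize a candidate as a single GFF3 feature (structure in attributes)."""
    from .io_formats import FeatureRecord
    s, e = candidate.span

    def fmt(iv):
        return f"{iv[0]}-{iv[1]}"

    return FeatureRecord(
        seqid=candidate.seqid, start=s, end=e, strand=candidate.strand,
        type="pseudogene_candidate" if candidate.pseudo else "gene_candidate",
        attributes={
            "exon1": fmt(candidate.exon1), "intron": fmt(candidate.intron),
            "exon2": fmt(candidate.exon2), "score": f"{candidate.score:.3f}",
            "translation": candidate.translation,
            "consensus_span": fmt(candidate.consensus_span),
        })


def feature_to_candidate(feature) -> CandidateLocus:
    """Rebuild a :class:`CandidateLocus` from its GFF3 serialization."""

    def iv(key):
        a, _, b = feature.attributes[key].partition("-")
        return (int(a), int(b))

    return CandidateLocus(
        seqid=feature.seqid, strand=feature.strand,
        exon1=iv("exon1"), intron=iv("intron"), exon2=iv("exon2"),
        score=float(feature.attributes.get("score", 0.0)),
        translation=feature.attributes.get("translation", ""),
        pseudo=feature.type == "pseudogene_candidate",
        consensus_span=iv("consensus_span") if "consensus_span"
        in feature.attributes else (0, 0),
    )
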