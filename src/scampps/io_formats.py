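"""Readers/writers and the coordinate conventions shared across the package.

All coordinates handled by this package are 0-based half-open on the forward
strand.  Formats that use different conventions (GFF3: 1-based inclusive) are
converted at the read/write boundary, and every converting writer is covered by
a round-trip test.

Sequences are stored exactly as read (uppercased); bases outside the ACGT
alphabet are preserved but masked to ``N`` in the scanner-facing view so that
ambiguity codes never silently translate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptRecord",
    "FeatureRecord",
    "PeakList",
    "read_fasta",
    "read_genome",
    "read_transcripts",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_peaklist",
    "write_peaklist",
]

_DNA_STRICT = set("ACGT")
_SCAN_TABLE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVNU-."}  # IUPAC ambiguity codes and gaps -> N
)


@dataclass
class GenomeSequence:
    """A named DNA sequence (chromosome/scaffold) with strand-aware access."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def scan_seq(self) -> str:
        """Sequence with every non-ACGT character masked to ``N``."""
        return self.seq.translate(_SCAN_TABLE)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Subsequence on ``strand`` for the forward-strand interval [start, end)."""
        if not (0 <= start < end <= len(self.seq)):
            raise ValueError(f"interval [{start}, {end}) outside {self.name!r}")
        sub = self.seq[start:end]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return sub


@dataclass
class TranscriptRecord:
    """An EST/mRNA record (accession-style id, DNA sequence, free description)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"transcript {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FeatureRecord:
    """A located genomic feature: carrier for gene models, NB-LRR loci, clusters.

    ``start``/``end`` are 0-based half-open forward-strand coordinates.
    """

    seqid: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature interval [{self.start}, {self.end}) is not a valid "
                "0-based half-open interval"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, as_: str = "genome"):
    """Read a multi-record FASTA into :class:`GenomeSequence` or
    :class:`TranscriptRecord` objects (``as_`` = ``"genome"`` | ``"transcript"``).

    Order is preserved, sequences are uppercased.  Raises ``FileNotFoundError``
    for a missing file, ``ValueError`` for an empty file or a header without an
    id (naming the offending line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    # pre-scan headers so an empty id can be reported with its line number
    with open(path) as fh:
        n_headers = 0
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                n_headers += 1
                if not line[1:].strip():
                    raise ValueError(
                        f"{path}: header with empty id at line {lineno}: {line.rstrip()!r}"
                    )
    if n_headers == 0:
        raise ValueError(f"{path}: no FASTA records found")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if as_ == "genome":
            records.append(GenomeSequence(name=rec.id, seq=str(rec.seq)))
        elif as_ == "transcript":
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq), description=desc))
        else:
            raise ValueError(f"unknown record kind {as_!r}")
    return records


def read_genome(path) -> list[GenomeSequence]:
    return read_fasta(path, as_="genome")


def read_transcripts(path) -> list[TranscriptRecord]:
    return read_fasta(path, as_="transcript")


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.name if isinstance(rec, GenomeSequence) else rec.id
            fh.write(f">{rid}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_GFF_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"),
                (",", "%2C"), ("\t", "%09"), ("\n", "%0A")]


def _gff_escape(value: str) -> str:
    for raw, enc in _GFF_ESCAPES:
        value = value.replace(raw, enc)
    return value


def _gff_unescape(value: str) -> str:
    for raw, enc in reversed(_GFF_ESCAPES):
        value = value.replace(enc, raw)
    return value


def write_gff3(features, path, source: str = "scampps") -> None:
    """Write features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(
                f"{_gff_escape(k)}={_gff_escape(str(v))}" for k, v in f.attributes.items()
            ) or "."
            fh.write(
                f"{f.seqid}\t{source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[FeatureRecord]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: {line!r}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attr_col = cols
            attributes: dict[str, str] = {}
            if attr_col != ".":
                for item in attr_col.split(";"):
                    if not item:
                        continue
                    key, _, val = item.partition("=")
                    attributes[_gff_unescape(key)] = _gff_unescape(val)
            features.append(
                FeatureRecord(
                    seqid=seqid,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    type=ftype,
                    attributes=attributes,
                )
            )
    return features


def write_bed(features, path) -> None:
    """BED6; BED shares this package's 0-based half-open convention."""
    with open(path, "w") as fh:
        for f in features:
            name = f.attributes.get("ID", f.type)
            fh.write(f"{f.seqid}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_bed(path, type: str = "region") -> list[FeatureRecord]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            name = cols[3] if len(cols) > 3 else type
            strand = cols[5] if len(cols) > 5 else "+"
            features.append(
                FeatureRecord(
                    seqid=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=strand,
                    type=type,
                    attributes={"ID": name},
                )
            )
    return features


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """(m/z, intensity) pairs, kept sorted ascending by m/z.

    ``annotations`` optionally carries ground-truth or match metadata aligned
    with the peak order (re-ordered together with the peaks on construction).
    """

    mz: np.ndarray
    intensity: np.ndarray
    annotations: list | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.annotations is not None:
            if len(self.annotations) != len(self.mz):
                raise ValueError("annotations must align with peaks")
            self.annotations = [self.annotations[i] for i in order]

    def __len__(self) -> int:
        return len(self.mz)


def read_peaklist(path) -> PeakList:
    """Read a peak list from two-column TSV or a minimal MGF ``BEGIN IONS`` block.

    MGF ``KEY=VALUE`` header lines inside the block are ignored; peaks may be
    separated by whitespace or tabs in either dialect.  A non-numeric peak row
    raises ``ValueError`` with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    is_mgf = path.suffix.lower() == ".mgf" or any(
        line.strip() == "BEGIN IONS" for line in lines[:5]
    )
    mz, inten = [], []
    in_block = not is_mgf
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if is_mgf:
            if s == "BEGIN IONS":
                in_block = True
                continue
            if s == "END IONS":
                in_block = False
                continue
            if not in_block or "=" in s:
                continue
        parts = s.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: expected two columns at line {lineno}: {s!r}")
        try:
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric peak at line {lineno}: {s!r}") from exc
    return PeakList(mz=np.array(mz), intensity=np.array(inten))


def write_peaklist(peaks: PeakList, path) -> None:
    with open(path, "w") as fh:
        for m, i in zip(peaks.mz, peaks.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")
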