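"""Prediction of the cyclic product domain from a precursor protein.

The cyclic (orbitide) domain of a precursor begins with a conserved glycine
immediately following the -WSE- amino-terminal processing site.  The processing
machinery gives no hard rule for the C-terminal boundary, so candidate domains
are enumerated over a length range and ranked by a composite score:

* motif fidelity — whether the processing-site match is the canonical WSE or a
  permitted degenerate form;
* a length prior centred on 8 residues (the length of the one product verified
  by LC-MS, and near the middle of the 5–12 residue range known for plant
  orbitides);
* composition — cyclic products are strongly enriched in non-polar residues,
  so the fraction of {A,V,L,I,P,F,W,M,G} in the candidate discriminates the
  true boundary from over-extension into the polar C-terminal flank.

Known products (including rule exceptions such as the chr4 GVPIWPYWN peptide,
which does not start at the canonical site) can be supplied as an override
table that short-circuits ranking for their precursors.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CyclicPeptide",
    "CompositionReport",
    "predict_cyclic_domain",
    "composition_stats",
    "NONPOLAR",
    "DEFAULT_BACKGROUND",
]

NONPOLAR = frozenset("AVLIPFWMG")
BASIC = frozenset("KRH")
ACIDIC = frozenset("DE")

# Generic proteome-average amino-acid frequencies (UniProtKB/Swiss-Prot release
# statistics, rounded); a neutral default background for enrichment reporting,
# overridable per call.  Normalized to sum exactly 1 at import.
_SWISSPROT_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.64, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}
_total = sum(_SWISSPROT_FREQ.values())
DEFAULT_BACKGROUND = {aa: v / _total for aa, v in _SWISSPROT_FREQ.items()}


@dataclass(frozen=True)
class CyclicPeptide:
    """A predicted or known cyclic product tied to its precursor."""

    residues: str
    precursor_id: str = ""
    interval: tuple[int, int] = (0, 0)  # on the precursor, 0-based half-open
    rule: str = "wse-g"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", self.residues):
            raise ValueError(f"ambiguous residues in product {self.residues!r}")
        if self.rule == "wse-g" and not self.residues.startswith("G"):
            raise ValueError("canonical-rule product must start with G")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CompositionReport:
    observed: dict[str, float]
    background: dict[str, float]
    enrichment: dict[str, float]       # log2(observed/background), smoothed
    nonpolar_fraction: float
    basic_count: int
    acidic_count: int
    net_charge: int
    n_residues: int

    @property
    def basic_acidic_ratio(self) -> float:
        """∞-safe ratio; inf when acidic count is zero but basic is not."""
        if self.acidic_count == 0:
            return math.inf if self.basic_count else math.nan
        return self.basic_count / self.acidic_count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue": aa, "observed": self.observed[aa],
             "background": self.background[aa], "log2_enrichment": self.enrichment[aa]}
            for aa in sorted(self.observed)
        ]
        return pd.DataFrame(rows)


def _motif_pattern(motif: str) -> re.Pattern:
    # the motif is a restricted regex over residue letters and [..] classes
    if not re.fullmatch(r"(\[[A-Z]+\]|[A-Z])+", motif):
        raise ValueError(f"invalid processing-site motif {motif!r}")
    return re.compile(motif)


def predict_cyclic_domain(
    precursor: str,
    motif: str = "WSE",
    length_range: tuple[int, int] = (5, 10),
    length_center: float = 8.0,
    length_sd: float = 2.0,
    known_products: dict[str, str] | None = None,
    precursor_id: str = "",
) -> list[CyclicPeptide]:
    """Enumerate and rank candidate cyclic domains of one precursor.

    Candidates start at every G immediately following a processing-site motif
    match; for each start, all lengths in ``length_range`` (truncated at the
    precursor end) are scored.  Returns candidates ranked best-first; an empty
    list when no motif+G anchor exists.  A ``known_products`` entry for
    ``precursor_id`` overrides ranking by exact substring lookup (rule tag
    ``known``), accommodating documented rule exceptions.
    """
    precursor = precursor.upper()
    if len(precursor) < 20:
        raise ValueError("precursor too short (<20 residues)")
    if known_products and precursor_id in known_products:
        product = known_products[precursor_id].upper()
        at = precursor.find(product)
        if at < 0:
            raise ValueError(
                f"known product {product!r} not found in precursor {precursor_id!r}")
        return [CyclicPeptide(residues=product, precursor_id=precursor_id,
                              interval=(at, at + len(product)),
                              rule="known", score=math.inf)]
    pat = _motif_pattern(motif)
    lo, hi = length_range
    candidates: list[CyclicPeptide] = []
    for m in pat.finditer(precursor):
        start = m.end()
        if start >= len(precursor) or precursor[start] != "G":
            continue
        fidelity = 1.0 if m.group(0) == "WSE" else 0.8
        for length in range(lo, hi + 1):
            end = start + length
            if end > len(precursor):
                break
            dom = precursor[start:end]
            if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", dom):
                continue
            length_prior = math.exp(-((length - length_center) ** 2)
                                    / (2 * length_sd ** 2))
            nonpolar = sum(aa in NONPOLAR for aa in dom) / length
            score = fidelity + 0.5 * length_prior + nonpolar
            candidates.append(
                CyclicPeptide(residues=dom, precursor_id=precursor_id,
                              interval=(start, end), rule="wse-g",
                              score=round(score, 12))
            )
    # total order: score desc, then longer, then leftmost — deterministic
    candidates.sort(key=lambda c: (-c.score, -len(c.residues), c.interval[0]))
    return candidates


def composition_stats(peptides, background: dict[str, float] | None = None
                      ) -> CompositionReport:
    """Pooled residue composition of predicted products vs a background.

    Enrichment is log2(observed/background) with additive (0.5-count)
    smoothing so residues absent from the pool stay finite.  The raw observed
    frequencies (unsmoothed) sum to 1.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("need at least one peptide")
    if background is None:
        background = DEFAULT_BACKGROUND
    alphabet = sorted(DEFAULT_BACKGROUND)
    missing = [aa for aa in alphabet if aa not in background]
    if missing:
        raise ValueError(f"background missing residues: {missing}")
    total_bg = sum(background[aa] for aa in alphabet)
    if abs(total_bg - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    counts = {aa: 0 for aa in alphabet}
    for pep in peptides:
        seq = pep.residues if isinstance(pep, CyclicPeptide) else str(pep).upper()
        for aa in seq:
            if aa not in counts:
                raise ValueError(f"non-standard residue {aa!r} in {seq!r}")
            counts[aa] += 1
    n = sum(counts.values())
    observed = {aa: counts[aa] / n for aa in alphabet}
    smoothed = {aa: (counts[aa] + 0.5) / (n + 0.5 * len(alphabet)) for aa in alphabet}
    # smoothing only where the count is zero keeps the
    # "matches background -> all enrichments zero" identity exact
    enrichment = {
        aa: math.log2((observed[aa] if counts[aa] else smoothed[aa]) / background[aa])
        for aa in alphabet
    }
    basic = sum(counts[aa] for aa in BASIC)
    acidic = sum(counts[aa] for aa in ACIDIC)
    return CompositionReport(
        observed=observed,
        background={aa: background[aa] for aa in alphabet},
        enrichment=enrichment,
        nonpolar_fraction=sum(counts[aa] for aa in NONPOLAR) / n,
        basic_count=basic,
        acidic_count=acidic,
        net_charge=basic - acidic,
        n_residues=n,
    )
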