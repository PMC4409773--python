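"""Tandem locus clusters and their spatial association with NB-LRR arrays.

Orbitide-precursor loci sit in localized tandem clusters along the chromosome,
interleaved with nucleotide-binding leucine-rich-repeat (NB-LRR) disease
resistance gene arrays.  This module detects clusters by single-linkage 1-D
grouping and makes the "proximal to NB-LRR arrays" observation testable with a
circular-rotation permutation test that preserves the clustering of both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureRecord

__all__ = ["LocusCluster", "AssociationResult", "cluster_loci", "association_test"]


@dataclass
class LocusCluster:
    seqid: str
    member_ids: list[str]
    start: int
    end: int

    @property
    def count(self) -> int:
        return len(self.member_ids)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def to_feature(self) -> FeatureRecord:
        return FeatureRecord(
            seqid=self.seqid, start=self.start, end=self.end, strand="+",
            type="locus_cluster",
            attributes={"ID": f"cluster_{self.seqid}_{self.start}",
                        "members": ",".join(self.member_ids),
                        "count": str(self.count)},
        )


@dataclass
class AssociationResult:
    """Observed mean cluster→nearest-NB-LRR distance against a rotation null."""

    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: int | None = None
    null_values: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def cluster_loci(loci, max_gap: int = 100_000, min_size: int = 2
                 ) -> list[LocusCluster]:
    """Single-linkage 1-D clustering of loci by start-coordinate gaps.

    Loci (any iterable of :class:`FeatureRecord`) are grouped per seqid and
    sorted internally, so the result is invariant to input order.  Consecutive
    loci whose start coordinates differ by ≤ ``max_gap`` join one cluster;
    clusters smaller than ``min_size`` are dropped.
    """
    by_seq: dict[str, list[FeatureRecord]] = {}
    for f in loci:
        by_seq.setdefault(f.seqid, []).append(f)
    clusters: list[LocusCluster] = []
    for seqid in sorted(by_seq):
        members = sorted(by_seq[seqid], key=lambda f: (f.start, f.end))
        run: list[FeatureRecord] = []
        for f in members:
            if run and f.start - run[-1].start > max_gap:
                clusters.extend(_finish(seqid, run, min_size))
                run = []
            run.append(f)
        clusters.extend(_finish(seqid, run, min_size))
    return clusters


def _finish(seqid, run, min_size):
    if len(run) < min_size:
        return []
    ids = [f.attributes.get("ID", f"{f.seqid}:{f.start}-{f.end}") for f in run]
    return [LocusCluster(seqid=seqid, member_ids=ids,
                         start=min(f.start for f in run),
                         end=max(f.end for f in run))]


def _circular_distance(a: float, b: float, length: float) -> float:
    d = abs(a - b) % length
    return min(d, length - d)


def association_test(clusters, nblrr_loci, seq_length: int, n_perm: int = 999,
                     seed: int | None = None) -> AssociationResult:
    """Permutation test of spatial association between clusters and NB-LRR loci.

    Statistic: mean distance from each cluster midpoint to the nearest NB-LRR
    midpoint.  Distances are circular, so rotating the cluster set by a
    uniform offset (which preserves inter-cluster spacing) gives an exact
    null; the statistic is kept continuous — no interval-overlap clamp — so
    that near-coincident arrangements remain distinguishable from merely
    nearby ones.  ``p = (1 + #{null ≤ observed}) / (1 + n_perm)`` — never
    exactly zero.
    """
    clusters = list(clusters)
    nblrr_loci = list(nblrr_loci)
    if not clusters or not nblrr_loci:
        raise ValueError("need at least one cluster and one NB-LRR locus")
    if seq_length <= 0 or any(c.end > seq_length for c in clusters):
        raise ValueError("seq_length smaller than the spans it must contain")
    c_mids = np.array([c.midpoint for c in clusters])
    n_mids = np.array([f.midpoint for f in nblrr_loci])

    def stat(offset: float) -> float:
        total = 0.0
        for cm in (c_mids + offset) % seq_length:
            total += min(_circular_distance(cm, nm, seq_length)
                         for nm in n_mids)
        return total / len(c_mids)

    observed = stat(0.0)
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(0, seq_length, size=n_perm)
    null = np.array([stat(off) for off in offsets])
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return AssociationResult(
        observed=float(observed), null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else float("nan"),
        p_value=float(p), n_perm=n_perm, seed=seed, null_values=null,
    )
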