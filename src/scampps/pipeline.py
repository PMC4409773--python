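"""End-to-end orchestration: scan → annotate → predict → hypervar → clusters → ms.

A run is a pure function of (inputs, config, seed): the effective parameter
set is written next to the outputs, a single global seed fans out to per-stage
child seeds by stable derivation, and reruns with the same config produce
byte-identical run directories (no timestamps in any output).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gene_annotation, genome_architecture, hypervariability
from . import orbitide_ms, orbitide_predict, precursor_scan
from .io_formats import (read_bed, read_genome, read_gff3, read_peaklist,
                         read_transcripts, write_bed, write_gff3)

__all__ = ["RunConfig", "run_pipeline"]

_STAGE_KEYS = {
    "scan": {"gap_open", "gap_extend", "seed_min_score", "min_combined_score",
             "intron_window", "window_size", "window_step", "pad",
             "include_pseudo"},
    "annotate": {"min_identity", "min_aligned_fraction", "utr_pad",
                 "search_window"},
    "predict": {"motif", "length_range", "length_center", "length_sd"},
    "clusters": {"max_gap", "min_size", "n_perm"},
    "hypervar": {"n_perm"},
    "ms": {"tol", "mode", "convention", "adducts"},
    "consensus": {"majority_threshold"},
}


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    genome: str
    precursors: str
    outdir: str
    seed: int = 0
    transcripts: str | None = None
    nblrr: str | None = None
    peaks: str | None = None
    pairs: str | None = None
    scan: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    hypervar: dict = field(default_factory=dict)
    ms: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)

    def validate(self) -> None:
        for stage, keys in _STAGE_KEYS.items():
            given = getattr(self, stage)
            unknown = set(given) - keys
            if unknown:
                raise ValueError(
                    f"unknown {stage} config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _stage_seeds(seed: int, names) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all applicable stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    seeds = _stage_seeds(config.seed, ["clusters", "hypervar"])

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- inputs -------------------------------------------------------------
    genomes = read_genome(config.genome)
    precursors = [r.seq for r in read_transcripts(config.precursors)]
    log.append(f"inputs: {len(genomes)} sequence(s), {len(precursors)} precursors")

    # -- consensus + scan ---------------------------------------------------
    try:
        profile = precursor_scan.build_consensus(
            precursors, **config.consensus)
        params = precursor_scan.ScanParams(**{
            k: tuple(v) if k == "intron_window" else v
            for k, v in config.scan.items()})
        candidates = []
        for g in genomes:
            hits = precursor_scan.scan_spliced(g, profile, params)
            log.append(f"scan: {g.name}: {len(hits)} candidate(s)")
            candidates.extend((g, h) for h in hits)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("scan", exc)
    write_gff3([precursor_scan.candidate_to_feature(c) for _g, c in candidates],
               outdir / "candidates.gff3")

    # -- annotate -----------------------------------------------------------
    try:
        ann = dict(config.annotate)
        search_window = ann.pop("search_window", 60)
        models = [gene_annotation.build_gene_model(c, g, search_window)
                  for g, c in candidates]
        by_genome: dict[str, list] = {}
        for (g, _c), m in zip(candidates, models):
            by_genome.setdefault(g.name, []).append((g, m))
        transcripts = (read_transcripts(config.transcripts)
                       if config.transcripts else [])
        for name, pairs_ in by_genome.items():
            gene_annotation.associate_transcripts(
                [m for _g, m in pairs_], transcripts, genome=pairs_[0][0], **ann)
        report = gene_annotation.family_report(
            models, thresholds={"min_identity": ann.get("min_identity", 0.99),
                                "min_aligned_fraction":
                                    ann.get("min_aligned_fraction", 0.8)})
        log.append(f"annotate: {len(models)} models, "
                   f"{sum(m.expressed for m in models)} expressed, "
                   f"{sum(m.pseudo for m in models)} pseudo "
                   f"(thresholds {report.attrs.get('thresholds')})")
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)
    write_gff3(gene_annotation.models_to_features(models),
               outdir / "models.gff3")
    report.to_csv(outdir / "family_report.tsv", sep="\t", index=False)

    # -- predict + composition ---------------------------------------------
    try:
        rows = []
        peptides = []
        for i, m in enumerate(models):
            if m.pseudo:
                continue
            ranked = orbitide_predict.predict_cyclic_domain(
                m.protein, precursor_id=f"scampps_model_{i:03d}",
                **config.predict)
            for rank, pep in enumerate(ranked[:3], start=1):
                rows.append({"precursor": pep.precursor_id, "rank": rank,
                             "domain": pep.residues,
                             "start": pep.interval[0], "end": pep.interval[1],
                             "score": pep.score, "rule": pep.rule})
            if ranked:
                peptides.append(ranked[0])
        pd.DataFrame(rows, columns=["precursor", "rank", "domain", "start",
                                    "end", "score", "rule"]).to_csv(
            outdir / "predictions.tsv", sep="\t", index=False)
        if peptides:
            comp = orbitide_predict.composition_stats(peptides)
            comp.to_frame().to_csv(outdir / "composition.tsv", sep="\t",
                                   index=False)
            log.append(f"predict: {len(peptides)} products; non-polar "
                       f"fraction {comp.nonpolar_fraction:.3f}, "
                       f"basic:acidic {comp.basic_count}:{comp.acidic_count}")
    except Exception as exc:  # noqa: BLE001
        fail("predict", exc)

    # -- hypervariability (optional pairs) ----------------------------------
    if config.pairs:
        try:
            tdict = {t.id: t.seq for t in transcripts}
            out_rows = []
            pair_df = pd.read_csv(config.pairs, sep="\t")
            for _, row in pair_df.iterrows():
                a, b = tdict[row["id_a"]], tdict[row["id_b"]]
                aln = hypervariability.align_pair(a, b)
                iv = (int(row["domain_start"]), int(row["domain_end"]))
                hypervariability.label_domain(aln, iv)
                res = hypervariability.hypervariability_test(
                    aln, seed=seeds["hypervar"], **config.hypervar)
                out_rows.append({
                    "id_a": row["id_a"], "id_b": row["id_b"],
                    "id_overall": round(aln.id_overall, 2),
                    "id_flank": round(aln.id_flank, 2),
                    "id_domain": round(aln.id_domain, 2),
                    "k": res.k, "m": res.m, "K": res.K, "n": res.n,
                    "p_exact": res.p_exact, "p_perm": res.p_perm})
            pd.DataFrame(out_rows).to_csv(outdir / "hypervar.tsv", sep="\t",
                                          index=False)
            log.append(f"hypervar: {len(out_rows)} pair(s)")
        except Exception as exc:  # noqa: BLE001
            fail("hypervar", exc)

    # -- clusters + association --------------------------------------------
    try:
        cl_cfg = dict(config.clusters)
        n_perm = cl_cfg.pop("n_perm", 999)
        loci = [precursor_scan.candidate_to_feature(c) for _g, c in candidates]
        clusters = genome_architecture.cluster_loci(loci, **cl_cfg)
        write_bed([c.to_feature() for c in clusters], outdir / "clusters.bed")
        log.append(f"clusters: {len(clusters)} (max_gap="
                   f"{cl_cfg.get('max_gap', 100000)}, "
                   f"min_size={cl_cfg.get('min_size', 2)})")
        if config.nblrr and clusters:
            path = Path(config.nblrr)
            nblrr = (read_gff3(path) if path.suffix in {".gff", ".gff3"}
                     else read_bed(path, type="nblrr"))
            lengths = {g.name: len(g) for g in genomes}
            rows = []
            by_seq: dict[str, list] = {}
            for c in clusters:
                by_seq.setdefault(c.seqid, []).append(c)
            for seqid, cl in sorted(by_seq.items()):
                nb = [f for f in nblrr if f.seqid == seqid]
                if not nb:
                    continue
                res = genome_architecture.association_test(
                    cl, nb, lengths[seqid], n_perm=n_perm,
                    seed=seeds["clusters"])
                rows.append({"seqid": seqid, "observed_bp": res.observed,
                             "null_mean_bp": res.null_mean,
                             "null_sd_bp": res.null_sd, "p": res.p_value,
                             "n_perm": res.n_perm, "seed": res.seed})
            pd.DataFrame(rows).to_csv(outdir / "association.tsv", sep="\t",
                                      index=False)
            log.append(f"association: {len(rows)} sequence(s), "
                       f"n_perm={n_perm}, seed={seeds['clusters']}")
    except Exception as exc:  # noqa: BLE001
        fail("clusters", exc)

    # -- mass matching (optional peaks) -------------------------------------
    if config.peaks:
        try:
            ms_cfg = dict(config.ms)
            tol = ms_cfg.pop("tol", 0.10)
            mode = ms_cfg.pop("mode", "absolute")
            convention = ms_cfg.pop("convention", "atom")
            adducts = tuple(ms_cfg.pop("adducts", ("M+H", "M+Na", "M+K")))
            peaklist = read_peaklist(config.peaks)
            ions = []
            for pep in peptides:
                ions.extend(orbitide_ms.theoretical_ions(
                    pep.residues, peptide_id=pep.precursor_id,
                    species=adducts, convention=convention))
            matches = orbitide_ms.match_peaks(peaklist, ions, tol=tol, mode=mode)
            pd.DataFrame([
                {"peptide": r.ion.peptide_id, "species": r.ion.species,
                 "theoretical_mz": round(r.ion.mz, 5),
                 "peak_index": r.peak_index,
                 "delta_mz": None if r.delta_mz is None else round(r.delta_mz, 5),
                 "matched": r.matched}
                for r in matches]).to_csv(outdir / "ms_matches.tsv", sep="\t",
                                          index=False)
            log.append(f"ms: {sum(r.matched for r in matches)}/{len(matches)} "
                       f"ions matched at tol {tol} ({mode})")
        except Exception as exc:  # noqa: BLE001
            fail("ms", exc)

    config.to_yaml(outdir / "config_effective.yaml")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return outdir
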