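# scampps

Analysis toolkit for **small cyclic amphipathic peptide (SCAmpPs / orbitide)
gene families** in plant genomes — for genome annotators and peptide
biochemists who need to find these loci, predict their cyclic products and
verify them against LC-MS data.

Orbitide precursors are short (~50-residue) ribosomal proteins processed at a
`-WSE-` site into head-to-tail cyclic peptides of 5–10 residues that begin
with a conserved glycine. The genes are easy to miss with standard
annotators: a tiny CDS split by a single ~100 bp GT–AG intron, long UTRs, and
a hypervariable product-coding window inside otherwise highly conserved
paralogs. `scampps` provides:

* **spliced six-frame consensus scanning** — Smith–Waterman seeding of a
  precursor consensus against all translated frames, followed by exhaustive
  GT..AG splice refinement, recovering exact exon/intron coordinates;
* **gene-model building and expression calls** — CDS extension to start/stop
  codons and EST association at a stated identity/coverage threshold pair;
* **cyclic-product prediction** — WSE-G anchored domain enumeration ranked by
  motif fidelity, a length prior and non-polar composition, with composition
  and enrichment reports against a configurable background;
* **hypervariability statistics** — per-region identity of transcript pairs
  and an exact hypergeometric test for mismatch concentration in the
  cyclic-domain window: with K total mismatches over n comparable columns, the
  count k in the m domain columns has upper-tail p
  `P[X ≥ k], X ~ Hypergeom(n, K, m)`, cross-checked by permutation;
* **cluster detection and NB-LRR association** — single-linkage 1-D
  clustering and a circular-rotation permutation test of proximity to
  resistance-gene arrays;
* **cyclic-peptide mass spectrometry** — monoisotopic masses (no terminal
  water), [M+H]⁺/[M+Na]⁺/[M+K]⁺ adducts under both the H-atom and
  proton-electron conventions, ring-opened b-ion fragments, and tolerance
  matching against TSV/MGF peak lists;
* **a synthetic-data generator** producing genomes, transcript pairs and peak
  lists with exact ground truth for every stage.

## Worked example

Cyclic-peptide masses from the command line:

```text
$ scampps ms --peptide GVPWAIAA
cyclic GVPWAIAA: neutral monoisotopic mass 765.4174 Da
  [M+H]+ = 766.4252 m/z
  [M+Na]+ = 788.4071 m/z
  [M+K]+ = 804.3811 m/z
```

The neutral mass is the residue-mass sum (cyclization removes the terminal
water); the protonated ion at 766.4252 m/z is the value to look for in an
extracted-ion window, and the Na⁺/K⁺ adducts explain the satellite peaks seen
in plant extracts (potassium-rich phloem shifts intensity to 804.38).

A full synthetic round trip — simulate a genome with planted genes, then run
the pipeline on it:

```text
$ scampps simulate --seed 7 --n-genes 8 --clusters 2 --out simdemo
$ scampps run --config run.yaml     # points at the simdemo files
$ cat rundemo/log.txt
inputs: 1 sequence(s), 8 precursors
scan: chrS: 8 candidate(s)
annotate: 8 models, 1 expressed, 0 pseudo (thresholds {'min_identity': 0.99, 'min_aligned_fraction': 0.8})
predict: 8 products; non-polar fraction 0.825, basic:acidic 2:0
clusters: 2 (max_gap=100000, min_size=2)
association: 1 sequence(s), n_perm=999, seed=1201125462
```

All 8 planted loci are recovered, both clusters are detected, and the one
gene simulated as expressed is the one associated with a transcript. Pooled
product composition:

```text
$ scampps composition --peptides GGAPPWF,GLIATTF,GYVAA,GVPWAIAA
...
non-polar fraction: 0.889  basic:acidic 0:0  net charge +0
```

i.e. these products are overwhelmingly non-polar and carry no charged
residues — the amphipathic, membrane-seeking composition typical of the
family.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from residue masses at run time, the protonated molecular ion and
the sodium and potassium adduct m/z of cyclic GVPWAIAA and writes them as
JSON keyed by target id.

## Layout

```
src/scampps/
  io_formats.py          FASTA/GFF3/BED/peak-list I/O, coordinate conventions
  synthetic_data.py      ground-truth genome/transcript/peak-list generator
  precursor_scan.py      consensus building, six-frame spliced scan
  gene_annotation.py     gene models, EST association, family report
  orbitide_predict.py    cyclic-domain prediction, composition statistics
  hypervariability.py    pair alignment, exact/permutation domain test
  genome_architecture.py clustering, NB-LRR association test
  orbitide_ms.py         masses, adducts, fragments, peak matching
  pipeline.py, cli.py    end-to-end runs; `scampps` console entry point
docs/methods.md          model assumptions, parameter rationale, limitations
```
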