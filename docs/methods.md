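# Methods

This note records the models, conventions and numerical choices behind
`scampps`, and what the synthetic-data tests do and do not establish.

## The biological model

Small cyclic amphipathic peptides (SCAmpPs, a class of orbitides) are
head-to-tail cyclized 5–10 residue peptides excised from ~50-residue ribosomal
precursors. The precursor architecture the package assumes is:

```
M — conserved leader — W S E — G x x x x x (x x x x) — conserved C-flank
                        ^processing site   ^cyclic domain (G-initial)
```

Genes carry two exons separated by a single ~100 bp GT–AG intron inside the
~150 bp CDS, with long UTRs giving ~450 nt transcripts. Loci occur in tandem
clusters interleaved with NB-LRR resistance-gene arrays, and paralogous
transcripts diverge much faster inside the cyclic-domain codons than in the
flanks.

## Spliced consensus scan (`precursor_scan`)

The scan replaces visual dot-matrix identification with a reproducible
two-phase algorithm:

1. **Seeding.** Smith–Waterman (BLOSUM62, gap open 11 / extend 1) of the
   precursor consensus against 400-residue windows (step 300) of all six
   translated frames; windows scoring ≥ `seed_min_score` (default 60) become
   seeds. Because the intron leaves at least one exon with most of the
   precursor, a real gene always produces a strong seed in some frame.
2. **Splice refinement.** Around each seed, every GT..AG excision whose length
   falls in `intron_window` (default 50–500 nt, generalizing the ~100 bp
   observation) is applied, the spliced DNA re-translated in the seed's frame
   and re-aligned to the consensus. The best alignment that spans the
   junction defines the candidate. Ties between splice variants that encode
   the same protein are broken by a small bonus (+3) for an in-frame stop
   codon immediately after the matched region — the variant consistent with a
   complete gene structure — then by longer spliced match, then leftmost
   donor.

Thresholds (`seed_min_score` 60, `min_combined_score` 100) are calibrated on
simulation, not taken from any publication: at those defaults random 100 kb
sequences yield no candidates in ≥95% of draws while planted genes at 10%
precursor divergence are recovered with recall and precision ≥0.9.

Candidates whose spliced translation contains an internal stop are kept in a
separate pseudo tier, mirroring the pseudogene copies real assemblies carry.

**Known limitation.** When the consensus is built from precursors with
*variable* domain lengths, the hypervariable domain collapses to a run of `X`
wildcards of one particular length. For genes whose true domain is shorter,
a splice variant that pads the domain to the consensus length can outscore
the true splice (a gap costs more than an `X` mismatch), shifting the intron
by a few nucleotides while leaving the CDS span intact. Exact exon/intron
recovery is therefore guaranteed only when the consensus domain-slot count
matches (the fixed-domain test world); in the variable world, CDS boundaries
are still exact for ≥90% of loci.

## Gene models and expression (`gene_annotation`)

The CDS is extended from the aligned core to the nearest in-frame ATG
(upstream) and stop (downstream) within 60 nt windows — a pragmatic bound for
~50-residue ORFs; missing ends flag the model partial, internal stops demote
it to the pseudo tier.

Expression is called by transcript association: a transcript supports a model
when a local alignment against the model's spliced gene region (CDS ± 250 nt
of genomic flank, intron removed) reaches ≥99% identity over ≥80% of the
transcript. Identity counts *all* columns of the local alignment — matches,
mismatches and internal gap columns — so an intron-retaining transcript
(~20% gap against a spliced region) cannot support a spliced model. The
`min_aligned_fraction` guard (0.8) blocks short spurious matches. Both
thresholds are echoed in every report; counts are meaningless without them.

## Cyclic-product prediction (`orbitide_predict`)

Candidate domains start at each G immediately following a WSE-like motif
(degeneracy configurable, e.g. `[WF]SE`). The C-terminal boundary has no
known rule, so lengths 5–10 are enumerated and ranked by

```
score = motif fidelity + 0.5·exp(−(L−8)²/8) + non-polar fraction
```

The length prior is centred on 8 (the LC-MS-verified product length, near the
middle of the 5–12 residue range known for plant orbitides). The composition
term exploits the strong non-polar enrichment of real products: extending a
candidate into the polar flank lowers its score, which is what carries the
boundary signal. On synthetic precursors the top-1 start position is always
correct; top-1 full-domain accuracy (~0.3) is limited by boundary information
and is reported, not assumed. Known products — including rule exceptions such
as a product that does not start at the canonical site — can be supplied as a
per-precursor override table that bypasses ranking.

Composition reports use pooled residue frequencies against a configurable
background (default: a generic proteome-average table bundled with the
package; every enrichment statement is relative to the named background).
Enrichment is log2(observed/background); residues absent from the pool get
0.5-count additive smoothing, which necessarily depends on pool size. Net
charge is an integer count model at neutral pH (K, R, H positive; D, E
negative) — no pKa model.

## Hypervariability test (`hypervariability`)

Pairs are aligned globally (DNA +2/−3, gap open 5 extend 2; protein BLOSUM62
11/1 — stated in output metadata since published identity figures rarely name
an alignment method). Identities exclude gap columns from denominators.

The test conditions on the total mismatch count K among the n comparable
(gap-free) columns: under uniform placement, the count k falling in the m
domain columns is hypergeometric, giving an exact upper-tail p-value with no
substitution-rate model. A permutation version (uniform reassignment of
mismatch columns) is provided and agrees with the exact tail within 3
Monte-Carlo standard errors at 10,000 permutations.

"Common residues" between equal-length products are ungapped positional
matches; unequal-length products are compared on the gapped protein
alignment.

## Clusters and NB-LRR association (`genome_architecture`)

Clusters are single-linkage 1-D groups by start-coordinate gaps
(`max_gap` 100 kb, `min_size` 2 — no published thresholds exist; the defaults
are calibrated on the synthetic world and echoed in output). The association
statistic is the mean circular distance from each cluster midpoint to the
nearest NB-LRR midpoint; the null rotates the whole cluster set by a uniform
offset, preserving inter-cluster spacing (a uniform-scatter null would ignore
the clustering of both sets and overstate significance).
`p = (1 + #{null ≤ observed})/(1 + n_perm)` never returns 0. The statistic is
deliberately continuous — no "overlap counts as zero" clamp — because with
interleaved arrays a clamped statistic ties with every rotation landing
within the summed half-widths and caps attainable significance near 0.05.

## Mass spectrometry (`orbitide_ms`)

Neutral monoisotopic mass of a head-to-tail cycle is the plain residue-mass
sum (cyclization consumes the terminal water), hence rotation-invariant.
Residue masses come from Biopython's monoisotopic tables; an independent
element-composition oracle (residue → CHNOS counts → atomic masses) agrees to
1e-4 Da in the test suite.

Two adduct conventions are offered because the literature value for cyclic
GVPWAIAA (MH⁺ 766.4252) corresponds to M + *neutral H atom* (765.4173 +
1.00783), not M + proton (766.4246, 0.0006 Da lower). The `atom` convention
is the reproduction default; `ion` (cation minus electron mass) is available.
Fragments are modelled as b-type acylium ions of the ring-opened peptide at
+1 only — one ion per contiguous cyclic substring (n(n−1) before mass
collapse) — and matching reports a matched fraction, not a spectrum score.
The default matching tolerance is 0.10 Th absolute, the half-width of a
typical extracted-ion window.

## Synthetic world (`synthetic_data`)

Defaults are the stated biology: domain length uniform on 5–10 (G-initial,
non-polar-weighted residues), ~100 bp introns (σ = 10, exact at σ = 0),
150 nt UTRs giving ~450 nt transcripts, CDS = 3·(precursor+stop). Flank and
domain substitution rates (0.0152 / 0.383 per site per copy) are set so two
independently mutated copies show ~97% flank and ~43% domain identity — the
contrast reported for real paralog pairs. Back-translation uses uniform
synonymous codons (codon bias is irrelevant to everything tested);
substitutions only, so truth intervals stay exact.

Layout: genes in `cluster_count` clusters with 2–8 kb intra-cluster gaps and
inter-cluster gaps jittered U(0.5, 1.5)×300 kb — a strictly periodic layout
would let circular rotations re-align clusters with NB-LRR blocks, which real
chromosomes do not do. NB-LRR dummies (position-only features, no sequence
realism) are interleaved between genes of associated clusters, mirroring the
mixed resistance-gene/peptide-gene tandem arrays observed in real assemblies.
The start Met, WSE and domain G are protected from precursor substitutions:
these anchors define the family and a broken start codon would make truth
CDS boundaries unrecoverable by any honest annotator.

What the generator does **not** emulate: repeat content and repeat-interrupted
pseudogenes, codon bias, indel divergence (optional in principle, off so
truth stays exact), realistic NB-LRR sequence, isotope envelopes or retention
times in peak lists. A green test therefore establishes correctness of the
algorithms under the stated two-rate substitution world, not robustness to
assembly artefacts or alignment-confounding indels.

Every generator is a pure function of (config, seed); fixed seeds give
byte-identical bundles.

## Pipeline

One global seed fans out to per-stage child seeds via `SeedSequence.spawn`,
so stages are individually reproducible; reruns with the same config are
byte-identical apart from the recorded output directory. Stage thresholds are
logged next to every count they produced.

## Scaling of the test suite

Simulation-based checks run at desk scale: 20-gene/1 Mb genomes for recovery,
30 generator replicates for association power, 50 for hypervariability power,
200 for null calibration, 10,000 permutations for the exact-vs-permutation
agreement. These sizes keep the whole suite under ~2 minutes while leaving
the binomial error of each power estimate well inside the asserted margins.
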