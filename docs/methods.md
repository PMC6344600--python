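# Methods

This note documents the models and procedures implemented in
`eetscan`, the defaults and why they were chosen, what the synthetic
data emulate (and what they do not), and the numerical conventions
that make runs reproducible.

## Heme-motif scanning

Heme *c* binds covalently at the C-X{k}-C-H signature.  The scanner
reports every start index at which the pattern matches, for each
spacer length *k* in the configured motif set (`motif.spacers`,
default `{2}`, i.e. the canonical CXXCH).  Rules:

* the two cysteines and the histidine are exact matches; spacer
  positions match any residue;
* `X` (to which the ambiguity codes B, Z, U, J, O are normalized on
  input) matches only spacer positions, never C or H — conservative
  motif calling on uncertain residues;
* overlapping matches at distinct start indices all count, so the heme
  count is a deterministic function of the sequence, independent of
  scan order.

CX3CH/CX4CH variants exist in some cytochromes; they are available by
adding 3, 4 to `motif.spacers` but are off by default because the
canonical motif is the conservative community standard.  Adding spacer
lengths can only add motif positions (count monotonicity), which the
test suite checks as a property.

Thresholds: `mhc_min = 5` heme motifs defines an MHC; `bin_split = 10`
separates the reported 5–10 and >10 bins; `emph_min = 8` is a second,
more stringent reporting threshold.  All three are plain config values.

## Homology search

Known EET families are found by optimal local alignment
(Smith–Waterman, BLOSUM62, affine gaps with a gap of length L costing
`gap_open + (L-1)·gap_extend`, defaults 11/1) against a bundled
reference set, computed with Biopython's `PairwiseAligner`.  A hit is
kept when identity ≥ 0.30 and query coverage ≥ 0.50; identity is
identical residues over alignment columns (gaps included), coverage is
the aligned span over sequence length.  Alignments scoring below
`min_score = 50` are discarded without a traceback; at realistic
protein lengths such alignments cannot satisfy the identity and
coverage thresholds, so this is purely a speed floor.  The thresholds
are package defaults, stated in every report's embedded config; no
E-value model is attempted at this database scale.

The family → role map is fixed: MtrB/MtoB/PioB/OmbB and a generic
porin are `porin`; MtrA/MtoA/PioA/OmaB are `periplasmic_MHC`;
MtrC/OmcB are `extracellular_MHC`; OmcE/OmcS/OmcZ are
`outer_surface_MHC`; Cyc2 is `cyc2`.  The search keeps the best
above-threshold hit per role.

**The bundled references are synthetic.**  They are random-background
sequences carrying each family's hallmark architecture — heme-motif
count (e.g. decaheme MtrA, octaheme OmaB, dodecaheme OmcB, monoheme
N-terminal Cyc2), a signal peptide, and a family-typical length — and
are certified mutually non-homologous under the default thresholds.
They make the package self-contained and give the synthetic benchmark
exact ground truth, but they carry no real phylogenetic signal: for
real assemblies, supply a curated reference FASTA (same sidecar format)
or a precomputed hit table (`query_id, family, identity,
query_coverage, score[, q_start, q_end]`), which replaces the internal
search verbatim.

## Localization

Rather than rebuilding a SignalP/PSORTb-class predictor, localization
is resolved by strict precedence:

1. a user-supplied annotation table (any external predictor's output);
2. homology-implied compartments (porin or outer-surface/extracellular
   family hits place a protein in the outer membrane or extracellular
   space);
3. a transparent signal-peptide heuristic: within the first
   `n_region_len = 45` residues, a run of ≥ `h_min = 7` consecutive
   strongly hydrophobic residues ({A,F,I,L,M,V,W}) preceded by at
   least one K/R — the classic tripartite n/h-region shape.  Signal
   peptide present ⇒ periplasmic, else cytoplasmic.  Proteins shorter
   than 30 residues never qualify.

For MAGs flagged `monoderm` in the MAG table (default diderm), secreted
MHCs map to `cell_wall`, since Gram-positive envelopes have no outer
membrane; this keeps cell-wall electron-transfer proteins visible to
the outer-surface caller.  The heuristic trades sensitivity for full
determinism; on real data an external predictor via the annotation
table is strictly better and takes precedence by design.

## EET gene calling

**PCC clusters.**  Contigs are scanned in gene-rank order.  A porin
gene (porin-role hit) within `max_gene_gap = 1` intervening genes of a
secreted MHC (heme count ≥ `pcc_mhc_min`, default inherited from
`mhc_min`; signal peptide required) forms a cluster; an
extracellular-family MHC inside the same window joins as third member.
Assembly is greedy leftmost with ties broken by smaller start
coordinate, and each gene joins at most one cluster, so tandem arrays
resolve deterministically.  Strand agreement is not required by
default (`strand_required` exists): real conduit operons are
co-oriented, but annotation strand errors are common enough in
assemblies that the permissive default loses less than it admits.
Clusters are `known_family` when any member hits
MtrAB(C)/MtoAB/PioAB/OmbB-OmaB-OmcB, else `novel_organization` — the
organization-only rule is what lets unknown conduit systems surface.
Widening `max_gene_gap` can only add clusters (window monotonicity).

**Outer-surface MHCs** are MHCs localized to the outer membrane,
extracellular space, or cell wall that belong to no PCC cluster.

**Cyc2-like genes** require exactly one heme motif, starting within the
first `n_term_window = 60` residues; a Cyc2-family hit covering ≥
`cterm_cov = 0.40` of the C-terminal half (an explicit, swappable proxy
for the C-terminal porin β-barrel — de novo barrel prediction is out of
scope); and length within [150, 800] residues.

The three classes partition the gene set; PCC membership wins any
overlap.

## Abundance and summaries

The normalization denominator is the arithmetic mean of the
housekeeping genes' contig-inherited coverages ("average" taken
literally; a median option exists for outlier-heavy assemblies).
Genes inherit their contig's mean coverage because reads are mapped to
contigs, not genes; a per-gene coverage column, if supplied, overrides.
Normalized values are invariant under global rescaling of coverage.

Metagenome summaries are *sums* of member-gene normalized abundances
per series (all-MHC by bin, EET-MHC by bin, Cyc2): a sum measures the
aggregate abundance of the gene class and is the only statistic that
makes metagenome totals exactly additive over the per-MAG breakdown
(checked as an invariant).  MAG summaries are the *mean* over that
MAG's EET genes — genes of one genome share its coverage, so the mean
estimates the organism's relative abundance.  The housekeeping
denominator is metagenome-wide, not per-MAG, so MAG means remain
comparable within a metagenome.  EET genes on unbinned contigs are
accounted in a reserved `unbinned` row.

## Synthetic metagenomes

The generator plants every detectable class alongside decoys designed
to fail exactly one requirement each: 4-heme near-MHCs (below the MHC
threshold), lone porins (no MHC partner), secreted-looking MHCs without
signal peptides, porin/MHC pairs separated by more than the gene-gap
window, and cysteine-rich non-motif proteins.  Background residues are
drawn from a C/H-depleted distribution and every emitted protein is
re-scanned with an independent brute-force window check; items whose
heme count, signal-peptide status, or homology profile deviates from
the plan are resampled (rejection sampling), so the truth table is
exact by construction rather than adjusted after the fact.  Planted
homologs are point-mutated copies of the bundled references (target
identity 0.70, motif positions and signal region protected, and C/H
never written so no new motifs can arise).  Random MHC sequences
occasionally align to MHC references at borderline identity through
heme-motif chaining (~10% of draws); certification rejects these so
cluster typing stays unambiguous.

Each planted unit occupies its own contig (with 0–2 certified filler
genes), so planted neighborhoods cannot collide; background and
housekeeping genes fill multi-gene contigs (4–8 genes).  Contigs are
assigned to MAGs with every MAG guaranteed non-empty, a configurable
unbinned fraction (default 12%), one monoderm MAG hosting the
cell-wall MHC cluster, and the largest planted MHC (51 hemes by
default) on an unbinned contig — echoing how the most heme-rich
conduit cytochromes can turn up outside any genome bin.

Coverage is lognormal per contig (μ = 2.5, σ = 0.25, i.e. ~12× median
depth with ~25% within-genome spread) times a per-MAG abundance factor
(lognormal, σ = 0.20).  The three-lake preset applies EET-density
multipliers 1:2:4 to the planted classes while holding background
constant.  The noise defaults come from an a-priori power analysis:
with these spreads and the preset's planted counts, the designed 4:2:1
gradient orders all three summary panels correctly in ≈98% of seeds,
so the gradient — not abundance noise — dominates the between-lake
contrast.  Real communities vary far more between organisms; the
generator is a controlled experiment for the *pipeline*, not a
community simulator.

What passing the synthetic benchmark does **not** show: robustness to
fragmented gene calls, chimeric contigs, real homology gradients
(paralogs, distant family members near the identity threshold),
composition-biased backgrounds, or localization-predictor errors.
Perfect precision/recall on planted truth demonstrates that the rules
are implemented exactly as stated, on data where their assumptions
hold.

## Numerical and reproducibility choices

* Internal coordinates are 0-based half-open; GFF3 I/O converts at the
  boundary (1-based inclusive).  Gene rank is the per-contig order by
  ascending start, ties broken by gene id.
* All randomness flows from a single `random.Random(seed)`; identical
  config + seed reproduce every emitted file byte for byte.  Report
  tables are sorted on their key columns; run metadata (resolved
  config, seed, input checksums) is serialized with sorted keys and no
  timestamps.
* Ties in cluster assembly break by rank distance, then start
  coordinate; best-hit ties break by score, then family name.
* Degenerate inputs: empty FASTA/GFF3 yield empty results; an empty
  housekeeping set or zero denominator is a validation error (not a
  silent NaN); proteins shorter than the motif window scan to zero
  hemes.
* Problem sizes used by the shipped checks: the default planted
  metagenome holds ~320 proteins on ~105 contigs (50 standalone MHCs,
  12 conduit operons, 6 Cyc2, 9 outer-surface MHCs, 36+ decoys); the
  gradient preset runs three metagenomes of ~60–170 proteins for ten
  seeds.  These sizes exercise every rule while keeping a full run in
  minutes on one CPU.

## Known limitations

* The signal-peptide heuristic is intentionally simple; lipoprotein
  signals and twin-arginine (Tat) motifs are not modelled.
* Heme counting assumes CXXCH-family motifs only; CXXCK active-site
  variants are out of scope.
* The Cyc2 porin-structure proxy is homology to Cyc2 references; a
  genuinely novel Cyc2-like family without sequence similarity would
  be missed (as it would by any homology-based screen).
* Operon calling uses gene-count windows, not base-pair distances, and
  ignores strand by default; both are configurable but the defaults
  are deliberately permissive.
* e-pilins, archaeal EET systems, and Gram-positive conduit complexes
  beyond cell-wall MHC flagging are not detected.
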