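# Methods

`krabkit` re-implements, as a tested library, the computational workflow used
to characterize the KRAB zinc-finger protein (KRAB-ZFP) gene family in mouse
and human and its expression across early-embryonic cell states: a
protein-domain census, genomic cluster detection, cross-species ortholog
calling from zinc-finger-array homology, NanoString nCounter normalization
and stage-specific differential calling, ChIP-interval meta-gene and
ERV-distance analysis, and ΔΔCT quantification. This note records the models,
parameter choices and numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Domain census

KRAB-domain presence is an *input*: an annotation table (gene, protein, KRAB
coordinates) stands in for the Pfam/InterPro/SMART/PROSITE + BioMart lookup
that produced the original gene lists. Re-running profile-HMM domain
detection is out of scope; the pipeline's own computation starts downstream
of domain identification.

C2H2 zinc fingers are matched with the pattern `C-X(2-4)-C-X(12)-H-X(3-5)-H`
on the longest protein isoform per gene. The variable-gap pattern is
ambiguous on real sequence; we fix the semantics as **leftmost,
shortest-match, non-overlapping** scanning (the scan resumes after the end
of each accepted match). This is the minimal-finger reading and makes finger
counts reproducible. `X` is accepted anywhere in a sequence but can never
occupy one of the four coordinating C/H positions. Equal-length isoform ties
break on the lexicographically smallest transcript id.

A gene with ≥1 finger is a KRAB-ZFP; with none, KRAB-O. The D5/V6 dipeptide
(aspartate/valine at KRAB positions 5 and 6, 1-based within the annotated
domain), required for KAP1 recruitment by canonical KRAB modules, is
evaluated directly on the annotated substring.

## Genomic clusters

A cluster is ≥2 family genes "within 200 kb of each other". We interpret the
distance as the **edge-to-edge gap between neighbouring genes** (overlap → 0)
with single-linkage chaining per chromosome, not an all-pairs constraint —
the only reading under which clusters spanning megabases (e.g. 41 genes) can
exist. Whether the published distances were TSS-to-TSS or edge-to-edge is
not stated; the choice is recorded here and configurable via `max_gap`.
Strand is ignored. Cluster ids ascend by natural chromosome order
(1, 2, …, 10, …, X, Y) then leftmost coordinate; singletons carry id 0.
A running-maximum of gene ends makes chaining robust to nested/overlapping
genes; tests assert equality with a brute-force transitive-closure oracle.

## Orthology by zinc-finger-array homology

Each KRAB-ZFP is reduced to the concatenation of its finger sequences
(spacers excluded). Cross-species pairs are scored by global alignment of
these arrays; pairs with >70% homology are retained, including one-to-many
matches (sequence alone cannot pick the "true" ortholog). KRAB-O proteins
(empty arrays) are excluded.

The original analysis used Clustal Omega, whose percent-homology output is
not bit-reproducible from the publication. We therefore define the score
precisely: affine-gap Needleman–Wunsch (Gotoh) with match +1, mismatch −1,
gap open −5, gap extend −1, deterministic traceback (diagonal > gap-in-B >
gap-in-A on ties), and **percent homology = 100 × identical columns / total
alignment columns including gaps**. The gap-inclusive denominator penalizes
length-mismatched arrays, which is what makes a pair like the mouse/human
ZFP57 orthologs (2 shared fingers out of 3 vs 6) fall below threshold — the
known limitation of the array-homology criterion. Scoring is configurable
(`AlignmentScoring`) and symmetric by construction (arrays are aligned in
canonical order). Under a different but reasonable scoring the set of pairs
near the threshold can shift by a few entries; published pair counts should
be compared with that in mind.

## nCounter pipeline

1. **Background**: per assay, subtract the geometric mean of the
   negative-control probe counts; zeros among the negatives are replaced by 1
   before the geometric mean (counts are integers; keeps the scale);
   corrected values ≤0 are floored at 0.1 so ratios and logs stay defined.
2. **geNorm**: for housekeeping gene *j*, M_j = mean over partners *k*≠*j* of
   the standard deviation (n−1) across assays of log2(x_j/x_k). The
   **one-pass** rule — select all genes with M < 0.5 — is the default, since
   that is how the published reference set was chosen; the classical
   iterative-exclusion ranking is exposed (`genorm_iterative_ranking`) for
   QC. Fewer than two passing genes triggers a warning and fallback to the
   two lowest-M genes. M is invariant to scaling any single assay (log-ratio
   cancellation), asserted numerically in tests.
3. **Normalization factors**: per assay, geometric mean of the selected
   genes' corrected counts, rescaled to geometric mean 1 across assays; all
   probes are divided by their assay's NF. Housekeeping probes are kept for
   QC.
4. **Summarization**: arithmetic mean over replicate assays per cell type;
   expressed ⇔ mean > θ (default 99 counts) in ≥1 cell type (strict
   inequality); relative log2 r_gc = log2(mean_gc) − mean_c' log2(mean_gc'),
   so Σ_c r_gc = 0 per gene. Averaging precedes the relative-log transform
   (the published order of operations is ambiguous; this order is fixed
   here).
5. **Correlation/clustering**: Pearson on relative log2 of target probes;
   agglomerative average-linkage on Euclidean distances for the dendrogram
   order.
6. **Differential calling**: the study only says "non-parametric analysis".
   We use a two-sided Mann–Whitney U of the pluripotent groups (G1∪G2)
   versus the rest on replicate-level normalized counts,
   Benjamini–Hochberg adjusted across target genes, plus a ≥2-fold filter on
   group means (floored at 0.1). Direction assigns
   pluripotency-associated vs non-pluripotent-associated. Housekeeping-like
   requires all six pairwise group comparisons non-significant (BH per
   comparison) *and* max between-group fold < 2. α defaults to 0.05; the
   stricter 0.01 used in one part of the original description is available
   as a config preset. With these choices the published stage-specific gene
   counts are soft targets only — the exact test the authors used is
   unknown. The study's own design (duplicates for MEFs) means groups can
   have as few as 2 replicate assays; the caller accepts ≥2 per side.

## ChIP interval analysis

Windows are strand-aware: promoter = TSS −3.5 kb/+0.5 kb, extended = gene
body ±3.5 kb, clamped at the chromosome origin. Enrichment is any-overlap
(≥1 bp) of 0-based half-open intervals — no minimum overlap fraction. The
meta-gene profile divides the **extended window** (not the body alone; the
alternative is available via `body_only`) into 8 near-equal bins, remainder
spread left-to-right, bin 1 being 5′-most in gene orientation. The per-bin
statistic is the fraction of genes whose bin is hit.

Nearest-ERV distance: ERVs shorter than 500 bp are dropped; distance is the
edge-to-edge gap from the **gene body** to the closest retained ERV on the
same chromosome (0 on overlap; genes on ERV-free chromosomes are excluded).
Group comparison uses the two-sided Wilcoxon rank-sum test — exact null
enumeration when the pooled sample is ≤12 without ties, otherwise the normal
approximation with tie and continuity corrections (scipy backend; an
enumeration oracle guards it in tests). When several marks are tested, BH
adjustment applies across marks.

Peak calling and read alignment are upstream and out of scope: the module
consumes interval files (BED). Signal-level (read-depth) profiles are not
computed — bin hits are binary.

## ΔΔCT quantification

ΔCT = CT(target) − mean CT(normalizers); ΔΔCT = ΔCT(sample) −
ΔCT(reference); RQ = 2^(−ΔΔCT). Multi-normalizer aggregation is the
arithmetic mean of CTs, equivalent to the geometric mean of quantities.
Replicate CTs per (sample, gene) are averaged before differencing. Two exact
identities are asserted: adding a constant to all CTs of a sample leaves RQ
unchanged, and shifting the target CT by −1 doubles RQ. No
amplification-efficiency correction is applied (efficiency 2 assumed).

## Synthetic data

Generators produce seeded inputs with planted ground truth for every stage;
one RNG stream per generator is derived from (master seed, stable label), so
adding a generator never perturbs the others and identical (seed, config)
yields byte-identical output.

* **Proteomes**: each protein is a linker + a fixed 62-residue KRAB-like
  consensus (D5/V6 present; optionally V6-mutated to emulate Ssx-type
  domains) + k pattern-true fingers separated by linkers. Linkers and
  spacers avoid C and H entirely, so the planted fingers are provably the
  only matches and recovery can be scored exactly. Real proteins have C/H in
  spacers and near-miss motifs; the generator does not emulate that, so
  recovery tests validate the scanning semantics, not robustness to
  ambiguous biology.
* **Loci**: planted cluster blocks with consecutive gaps ≤200 kb, separated
  by gaps >200 kb. Real cluster boundaries are not this clean; the generator
  makes the planted partition identifiable by construction.
* **Counts**: signal = round(lognormal(μ_gene + group effect, σ)) + Poisson
  background (λ=4); negatives carry background only; housekeeping genes get
  ascending σ (planted stability order). σ is set from the target CV
  (default 10%, σ = √log(1+CV²)). The default design mirrors the study's
  structure scaled down: 10 cell types over the four groups (ground-state
  pluripotent; serum/BMP4 pluripotent; EpiSC/EB; committed), 3 replicates
  each and 2 for MEFs, 8 housekeeping and 6 negative probes. Lognormal ×
  Poisson is a simple positive overdispersed model, not a calibrated
  NanoString error model — passing tests demonstrate the statistics, not
  platform realism.
* **ChIP/ERVs**: per-gene bin hits are Bernoulli with configurable per-bin
  probabilities; one ERV per gene at a normal-distributed distance downstream
  (mean 1 kb for the designated "near" group vs 6 kb otherwise, sd 300 bp),
  plus sub-500 bp decoy ERVs parked at gene edges that the length filter
  must remove. Planted distances are exactly recoverable only when genes
  are spaced so windows don't interleave (the acceptance setup uses
  separated singletons).
* **qPCR**: CT tables built so 2^(−ΔΔCT) returns the planted fold exactly at
  zero noise; replicate noise is configurable.

## Problem sizes and numerical notes

Self-contained acceptance checks use: 100–357 synthetic genes for the
census, ≤50-gene instances for the cluster-oracle comparison, ≤12-residue
arrays for the alignment-oracle comparison, 100 target genes (10 planted
4-fold effects, CV 10%, triplicates) for the sensitivity check, 1000 null
genes for the false-positive-rate check, and 200 genes (100 per group,
planted 5 kb shift) for the ERV-distance test. Tolerances: exact arithmetic
identities are asserted to ~1e-9 absolute (NF geometric mean, relative-log2
row sums) or 1e-9 relative (ΔΔCT); oracle comparisons are exact in floating
point. Degenerate inputs are defined rather than left to chance: all-zero
negative probes give background 1 per the zero-replacement rule, constant
genes give p=1 in the differential caller, and bins raise when the window is
shorter than the bin count.

## Known limitations

* The published census/cluster/expression counts derive from frozen 2012
  genome-annotation exports; reproducing them requires the journal's
  supplementary tables, which ship as XLSX and are not redistributed here.
  The converter (`krabkit.io.convert_xlsx_to_tsv`) and the exact
  computations are provided; the corresponding checks run only when the
  converted TSVs are supplied under `data/supplementary/`.
* Percent homology depends on alignment scoring; only the identity case
  (100%) is scoring-independent.
* The differential caller's category counts depend on the unstated original
  test; only planted-effect recovery and error-rate control are asserted.
* Bin profiles are presence/absence, not signal intensity; adjacent genes
  with overlapping extended windows share marks by construction.
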