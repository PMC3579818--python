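# krabkit

Analysis toolkit for the **KRAB zinc-finger protein (KRAB-ZFP) gene family**
— the largest transcription-factor family in mammalian genomes, central to
the silencing of endogenous retroelements in early embryos via the
corepressor KAP1/TRIM28. `krabkit` is aimed at computational biologists who
need a reproducible, scriptable version of the family's standard desk
analyses:

* **Domain census** — scan protein sequences for C2H2 zinc fingers matching
  `C-X(2-4)-C-X(12)-H-X(3-5)-H`, check the KRAB D5/V6 dipeptide, and classify
  genes as KRAB-ZFP (≥1 finger) or KRAB-O (none), using the longest isoform
  per gene.
* **Genomic clusters** — single-linkage chaining of family genes whose
  edge-to-edge gap is ≤ 200 kb on one chromosome.
* **Orthology** — mouse–human putative ortholog pairs from the percent
  homology of concatenated zinc-finger arrays (spacers excluded):
  global affine-gap alignment (match +1, mismatch −1, gap open −5, extend
  −1), identity over all alignment columns including gaps, threshold 70%.
* **nCounter pipeline** — negative-probe geometric-mean background
  subtraction (floor 0.1), geNorm reference-gene selection (stability
  M < 0.5), normalization-factor scaling, replicate averaging, expressed
  calls at >99 counts, relative-log2 heat-map values, Pearson/average-linkage
  sample clustering, and Mann–Whitney + Benjamini–Hochberg stage-specific
  calls (adj. p ≤ 0.05, fold ≥ 2) across four cell-state groups.
* **ChIP interval analysis** — strand-aware promoter (−3.5 kb/+0.5 kb) and
  extended (body ±3.5 kb) windows, per-gene mark tables, 8-bin meta-gene
  profiles, nearest-ERV distances (ERVs < 500 bp excluded) with a Wilcoxon
  rank-sum comparison.
* **ΔΔCT quantification** — RQ = 2^(−ΔΔCT) with multi-gene normalizers.
* **Synthetic data** — seeded generators with planted ground truth for every
  stage (proteomes, gene layouts, count matrices, interval sets, CT tables).

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Simulate a small proteome, build the census, then detect clusters on a
simulated gene layout:

```bash
krabkit simulate proteome --seed 3 --out sim/
krabkit census --fasta sim/proteome.fasta \
    --annotations sim/krab_annotations.tsv --out census.tsv
krabkit simulate loci --seed 3 --out simloci/
krabkit clusters --bed simloci/loci.bed --out clusters.tsv
```

The census step logs

```
INFO krabkit: census: 50 genes (45 KRAB-ZFP, 5 KRAB-O)
```

meaning 50 KRAB-annotated genes were classified, 45 of them with at least
one C2H2 finger on their longest isoform and 5 KRAB-only. The cluster step
logs

```
INFO krabkit: clusters: 3 clusters, 10 singletons
```

i.e. the 58 simulated genes fall into 3 genomic clusters (≥2 genes within
200 kb of each other) plus 10 isolated genes; `clusters.tsv` maps each
gene to its cluster id (0 = singleton). The full nCounter pipeline runs as

```bash
krabkit simulate counts --seed 3 --out simcounts/
krabkit ncounter --counts simcounts/counts.tsv \
    --design simcounts/design.tsv --outdir run/
```

which logs

```
INFO krabkit: geNorm selected references: probe_h01, probe_h00, probe_h02, probe_h03
INFO krabkit: ncounter: 108 probes expressed, 97 differential calls
```

and writes normalized counts, the per-cell-type expression table, the sample
correlation matrix and the stage-specific differential calls under `run/`.
Other entry points: `krabkit orthologs`, `krabkit chip profile|marks|
erv-distance`, `krabkit qpcr rq`, `krabkit validate`.

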