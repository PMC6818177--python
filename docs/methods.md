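# Methods

## Coordinate and counting conventions

All internal coordinates are 0-based half-open; GTF records are converted
at the parsing boundary (start − 1, end unchanged) and restored on export.
The TSS is `interval.start` on the plus strand and `interval.end − 1` on
the minus strand. Multi-transcript genes collapse to the transcript with
the largest exonic length, whose span and exonic length define the gene
model; a single TSS per gene is required by all TSS-anchored analyses.

Reads are counted by **midpoint** (`floor((start+end)/2)`) for fine-binned
MNase profiles — the midpoint of a nucleosomal fragment approximates the
dyad, and midpoint assignment makes adjacent bins a partition, so counts
are conserved exactly — and by **≥ 1 bp overlap** for broad regions
(promoters, enhancers, 200 bp state bins, sliding windows). Both modes are
implemented as sorted-array rank queries: the number of reads overlapping
`[s, e)` equals `#{start < e} − #{end ≤ s}`, exact because every read has
start < end. Signal is normalised as RPM (`count · 10⁶ / total_mapped`)
and expression as RPKM.

Minus-strand TSS windows are mirrored so that "upstream" is biological
upstream: the oriented NDR `[−150, +50)` maps to genomic
`[tss − 49, tss + 151)` on the minus strand, and profile bin *k* covers
oriented offsets `[−1000 + 10k, −1000 + 10(k+1))` on both strands. Genes
whose windows cross a chromosome end keep zero-filled bins and are flagged
rather than dropped, so the gene universe is identical across cell types.

## Differential expression

With one library per cell type there is no replicate-based dispersion to
estimate, so differential expression between two libraries is an exact
conditional binomial rate test: conditional on a gene's pooled count
n = cA + cB, cA ~ Binomial(n, N_A/(N_A+N_B)) under the null of equal
sampling rates (N are library totals). Two-sided p-values are twice the
smaller tail, capped at 1 — this reproduces the exact tail in the
one-sided extreme and p = 1 at perfect balance — and are BH-adjusted per
pair; a gene is a DEG at q < 0.05. Genes with zero counts in both
libraries receive p = 1 and stay in the BH family (deterministic and
conservative). The pseudocount (default 1 read, scaled by the smaller
library) affects only the reported log2 fold change, never the test. On
equal-rate simulations the empirical q < 0.05 discovery fraction is far
below nominal, as expected for a discrete exact test.

## Chromatin states

H3K9ac and H3K27me3 are binarised independently on a genome-tiling 200 bp
grid: with λ the genome-wide mean reads per bin (overlap counting), a bin
is marked when P(Poisson(λ) ≥ k) ≤ 10⁻⁴. The four states are the mark
combinations (H3K9ac⁺, H3K27me3⁺, both, unmarked). A trained multi-state
HMM would add smoothing along the genome on top of this per-bin
classification; with exactly two binary marks the state space is the mark
combinations, so the package uses direct combinatorial labelling and
offers an optional 3-bin strict-majority filter (off by default) in place
of HMM smoothing. No input-control track is modelled; the Poisson
background plays that role. State flows between two cell types are plain
4 × 4 per-bin contingency tables; they conserve the bin count by
construction.

## Enhancer calling

1 kb windows at 100 bp steps are overlap-counted and tested against the
genome-wide mean window count with an upper-tail Poisson p, BH-adjusted
across all windows; windows with q < 0.001 are merged when overlapping or
adjacent. Because a 1 kb window reaches up to 900 bp beyond a point source,
merged spans systematically overhang the enriched interval, so peak
boundaries are refined to the outermost 100 bp step whose count is at
least 3× the empirical genome-wide step-level mean (measured directly,
which absorbs the read-length inflation of overlap counts); if no step
passes, the unrefined span is kept. Refined peaks overlapping any promoter
(TSS ± 1 kb) by ≥ 1 bp are discarded. The reported peak q-value is the
minimum over member windows.

Targets are the nearest TSS measured from the nearer peak boundary (0 if
the TSS lies inside), ties broken by smaller gene id; enhancers whose
nearest TSS is > 10 kb away stay unassigned. An enhancer is H3K9ac⁺ in a
cell type when ≥ 1 of its 200 bp state bins is H3K9ac-marked there;
neuron-specific enhancers are Neuron's H3K9ac⁺ enhancers with no ≥ 1 bp
overlap with any H3K9ac⁺ enhancer of Glia (and vice versa). Gene-set
enrichment is a hypergeometric upper tail against user-supplied GMT sets
intersected with the universe, BH-adjusted, with the best five flagged.

## ROC evaluation

Activity labels follow a top-k/bottom-k convention (k = 1500 by default,
matching genome-scale annotations; boundary ties break by gene id so
exactly k genes are positive). On the 1000-gene synthetic annotation the
pipeline caps k at a quarter of the universe (250), preserving the
"extreme quartile versus rest" character of the labels. Every distinct
signal value serves as a ≥ threshold; AUC is the trapezoid area, which
equals the pairwise-comparison statistic exactly (asserted against full
enumeration in the tests). H3K9ac is evaluated with top-k positives,
H3K27me3 with bottom-k. Enhancer signal reaches genes through target
assignment with max-aggregation over a gene's enhancers; genes without
enhancers are excluded from that evaluation rather than imputed at zero,
which avoids artifactual separation. Promoter-based AUCs are the
calibration surface: enhancer-based evaluations run on a ~4× smaller gene
universe and are correspondingly noisier.

## Clustering and topology comparison

Rows are Z-scored with the population (divisor n) standard deviation;
zero-variance rows are dropped with a logged count. Cell types are
clustered on Euclidean distance with complete linkage by default (average
and Ward are available; the linkage is a logged config value). Columns are
processed in lexicographic label order so distance ties break
deterministically. A dendrogram whose merge heights are all equal within
10⁻⁹ is flagged "unresolved" and never claims a topology.

Topology is compared to the reference lineage two ways: through
bipartitions (for four leaves every binary tree induces exactly one
non-trivial bipartition, so this detects the progenitor/differentiated
split) and through the full set of merge clusters, which distinguishes the
nested order ({NSC, GNP}, then + Glia, then + Neuron) from other trees
sharing the same bipartition.

## The synthetic-data generator

The generator emulates the study design — four cell types, one library per
cell type and assay — on a 6 Mb toy chromosome with 1000 genes on a 6 kb
grid and 300 planted enhancers, ~2 × 10⁶ declared mapped reads per track
of which a few hundred thousand fall in modelled regions (the declared
total is the RPM denominator).

Latent structure, per gene g and cell type c:

- expression: log λ = z_g + B_{g,c} + ε, with gene baseline z_g ~ N(0, 1.6²),
  block effects B of ± 0.6 (progenitor-high 25% of genes, differentiated-high
  25%, neuron-specific 10%, glia-specific 10%, rest flat) and ε ~ N(0, 0.25²);
  counts are Poisson with per-cell libraries of 10⁶ reads.
- promoter H3K9ac: log-level 0.9 · z-scored expression + N(0, 0.3²) — the
  active mark tracks activity, hence carries the same two-block geometry.
- promoter/enhancer H3K27me3: −3.0 · standardized baseline + tree drift + N(0, 0.15²),
  capped at e^3.5. The drift performs independent Gaussian steps along the
  lineage edges (NSC→GNP 0.3, GNP→Glia 0.6, NSC→Neuron 1.0 on the log
  scale), so expected squared distances between cell types are proportional
  to tree path lengths. The activity anti-coupling is deliberately
  **cell-invariant**: it cancels under per-row Z-scoring, so the
  between-cell-type geometry of H3K27me3 is pure lineage drift while raw
  signal still anti-predicts expression within every cell type.
- MNase: per-gene phased arrays (Gaussian nucleosome peaks at −180, +120,
  +295, +470 bp from the oriented TSS, sd 40 bp, 50 expected reads each)
  over a flanking floor of 0.03 reads/bp; the NDR floor is multiplied by
  exp(−coupling × standardised expression), coupling 1.0 by default.
- H3K4me1: 10-fold enrichment over the 0.01 reads/bp genome-wide
  background inside planted enhancers, in the cell types where the
  enhancer is active (shared enhancers in all four; neuron-/glia-specific
  enhancers only in their cell, where they also carry strong H3K9ac).
- enhancers are 0.7–1.2 kb wide, planted 1.3–2.7 kb upstream of their
  target TSS on the fixed gene grid, which keeps them clear of every
  promoter and pairwise disjoint; total coverage stays below 5% of the
  genome.

All counts are Poisson draws from these expectations; reads are emitted as
49 bp intervals whose midpoint carries the sampled position. A single
`numpy` generator seeded from the config drives everything, so a fixed
seed yields byte-identical output files.

What the generator does **not** emulate: sequence content and mappability,
paired-end fragment structure, replicate variability, input/control
tracks, copy-number or accessibility artifacts, distance-dependent
enhancer–promoter interactions, and continuous (rather than block)
expression programs. Passing the calibration suite therefore shows that
the pipeline recovers planted structure under idealised sampling noise —
not that it is robust to the full artifact spectrum of real chromatin
data.

## Calibration studies and problem sizes

The calibration suite (also re-run by `scripts/acceptance.py`) uses 100
default simulations for topology-recovery rates, 5 of them for planted
ROC AUCs and 10 for enhancer recovery, 20 label shuffles for the ROC
negative control, 20 pure-background 6 Mb genomes for the false-peak rate,
5 planted state-map pairs (2 Mb, 30% H3K9ac⁺→unmarked switch) for the
transition estimate, and 20 equal-rate null datasets for DEG type-I error.
These sizes keep the whole suite around a minute on one CPU while leaving
the binomial Monte-Carlo error of each rate well inside the margins being
asserted.

## Known limitations

- The enhancer boundary refinement assumes point-like or block-like
  enrichment; broad, gradually decaying domains would be trimmed
  conservatively.
- The binarizer uses a single global Poisson background; on real data with
  copy-number variation or accessibility bias a local (e.g. windowed λ)
  background would be needed.
- The DEG test models sampling noise only; without biological replicates
  its calls on real data would be anti-conservative with respect to
  biological variability (as is true of any single-library rate test).
- Topology comparison is specialised to small leaf sets; no bootstrap
  support values are computed.
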