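# Methods

## The pipeline

`occumap` quantifies protein occupancy on transcribed genes from aligned
single-end ChIP-seq reads, for experiments that include an exogenous
chromatin spike-in. The processing chain is:

1. **Read partition.** Aligned reads are split by chromosome-name prefix
   into experiment-genome and spike-in-genome reads; unmapped records are
   dropped. No MAPQ filtering or deduplication is applied beyond "mapped"
   (none is assumed by the model).
2. **Pileup.** Each read adds +1 to every base of its mapped span. Reads
   are counted as mapped (no fragment extension by default, since 51-bp
   single-end reads carry no fragment-size information; an `extend_to`
   option is available). Tracks are float32.
3. **Spike-in normalization.** Every sample is scaled by
   `1e6 / spikein_reads`, i.e. each sample's spike-in depth is adjusted to
   one million reads. This makes per-base signal (RPM) comparable across
   samples with different IP yields: an IP that pulls down little specific
   chromatin sequences proportionally more spike-in, and scaling by the
   spike-in count shrinks its track accordingly. The guarantee is exact
   scale invariance: duplicating every read of a library (experiment and
   spike-in alike) leaves the RPM track unchanged.
4. **Background subtraction.** The no-tag control (a strain without the
   epitope tag, processed and normalized identically, sequenced once) is
   subtracted per base from each replicate. Negative values are clamped to
   zero for visualization tracks; subtraction and averaging are linear, so
   with clamping off the order of these two steps is provably immaterial —
   with clamping on it is not, and the order is fixed as
   subtract-each-replicate-then-average.
5. **Replicate averaging.** Arithmetic per-base mean of the corrected
   replicates.
6. **Profiles.** Anchored matrices hold one row per gene over a window
   `[-flank_up, +flank_down)` around the TSS or TTS, strand-flipped so
   offset 0 is the first transcribed base and positive offsets always point
   downstream. Cells are bin means of per-base RPM. Window bases beyond a
   chromosome end are masked (NaN) and excluded from bin means and
   metagenes — zero-filling would fabricate depletion at short
   chromosomes. Metagenes are per-bin means over gene groups (length
   classes or expression tiers).
7. **Windowed quantification.** Per-gene occupancy near an anchor
   (default −100..+300 bp of the TSS) is RPKM: reads overlapping the
   strand-aware window by ≥1 bp, per kb of window, per million
   experiment-genome reads. RPKM is depth-relative by definition, so
   spike-in scaling is deliberately not applied here. Background is
   removed by subtracting, unclamped, the same quantity measured in a null
   strain lacking the ChIP target.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`; BED is
native, GFF3 is converted on input. The TSS of a minus-strand gene is its
exclusive `end` bound; relative offset `x` maps to genomic base
`anchor + x` (plus strand) or `anchor − 1 − x` (minus strand), which makes
strand mirroring an exact symmetry of the matrix builder.

Gene-length classes are half-open: XS `[1, 750)`, S `[750, 1500)`,
M `[1500, 2250)`, L `[2250, 3000)`, XL `[3000, 3750)`. A 750-bp gene is S,
a 1500-bp gene is M. Genes ≥ 3750 bp are labelled `OVER`: they stay in
whole-gene-set heatmaps but are excluded from five-class metagenes (the
minimal reading; truncating them into XL would mix populations).
Expression tiers split the RPKM-ranked gene list as
floor(n/3) / floor(n/3) / remainder — for 6020 genes, 2006 high, 2006
medium, 2008 low — with ties broken by gene id so the split is
deterministic.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| heatmap bin | 10 | bp | fine-grained rows over ±1500 bp windows |
| metagene bin | 25 | bp | smooths Poisson noise without blurring peaks |
| flanks | 1500/1500 | bp | the standard ±1.5 kb promoter/terminator view |
| quantify window | −100..+300 | bp | TSS-proximal occupancy window |
| read extension | none | bp | mapped span only; no fragment model assumed |
| clamp | on (tracks) / off (RPKM tables) | — | visualization vs scatter semantics |
| heatmap color cap | 95th percentile | — | plotting-only; matrices are emitted unscaled |

Neighboring or overlapping genes are *not* excluded from profiles; this is
a documented caveat — a gene's window can contain a neighbor's signal.

## The simulator

The synthetic module generates a small multi-chromosome genome (default
2 × 200 kb plus one 100 kb spike-in chromosome), ~120 non-overlapping,
strand-mixed genes covering all five length classes, log-normal per-gene
expression values, and 51-bp single-end reads drawn from parametric
occupancy landscapes:

- **uniform_gene_body** — read starts uniform over the gene body, per-gene
  weight proportional to gene length (constant per-bp intensity);
- **tss_peak / tts_peak** — read starts from a Gaussian kernel at
  anchor+offset (defaults +100 bp, σ = 150 bp) in strand-flipped
  coordinates;
- **mixture** — weighted combination (e.g. 60% TSS / 40% TTS);
- **background_only** — nonspecific signal only.

A uniform background (default 25 reads/kb genome-wide) underlies every
landscape. Reads are allocated multinomially in proportion to landscape
weights, extended 51 bp downstream on a uniformly random strand (ChIP
signal is strand-symmetric), and truncated at chromosome ends. Everything
is deterministic given (config, seed).

The multi-condition suite emulates a study of the H2Bub → H3K4me3 axis:
uniform occupancy for the ubiquitinase (Rad6-like), TSS peaks for the
methyltransferase machinery and its mark (Set1/H3K4me3-like), a TSS+TTS
mixture for the shared COMPASS/CPF subunit (Swd2-like), loss of the 5'
peak with a *stronger* 3' peak when the methyltransferase is deleted, and
background-only landscapes for the ubiquitinase deletion and the no-tag
control. Tier-scaled amplitudes (4 / 1.5 / 0.5 for high / medium / low
expression) encode the transcription–occupancy correlation.

**IP-yield spike-in model.** Sequencing depth is fixed per sample, so the
spike-in read *fraction* must reflect IP yield for spike-in normalization
to be meaningful. The suite computes each condition's spike-in fraction as
`K / (K + S + B)`, where `S` is specific signal mass, `B` nonspecific
background mass, and `K` the spike-in chromatin mass calibrated so that a
background-only IP yields the nominal 10% chromatin fraction as its read
fraction. High-yield IPs therefore carry ~0.6% spike-in reads and
background-only IPs ~10%, and after normalization the background-only
track collapses to the control level — the property the deletion-strain
contrast tests.

## Numerical and statistical choices

- Tracks are float32; averaging and mass sums accumulate in float64.
- Peak-position recovery is read off metagenes built with 150-bp bins —
  bin width comparable to the σ = 150 bp placement kernel. At 25-bp
  resolution the kernel is nearly flat across adjacent bins and the argmax
  bin is decided by Poisson noise; at kernel-scale resolution the bin
  containing the planted offset dominates decisively.
- Gene-body flatness is evaluated on genes ≥ 1500 bp over bins +100..+1400
  (inside every such gene, clear of the ~51-bp coverage ramp at the TSS).
- The windowed-RPKM scatter can only display a *global* occupancy loss
  when nonspecific background absorbs the freed sequencing depth (RPKM
  normalizes by total depth); the planted-reduction test simulates that
  background-dominated regime. With a signal-dominated library the same
  planted loss is visible in spike-in-normalized RPM but not in RPKM —
  which is exactly why track-level comparisons use spike-in scaling.
- Ties (equal gene lengths in row sorting, equal RPKM at tier boundaries)
  break by gene id, making every ordering bit-reproducible.

## What the simulations do and do not show

The simulator reproduces the *statistical geometry* of occupancy data —
read-count noise, strand mixing, chromosome-end truncation, spike-in
dilution, background contamination — so passing tests demonstrate that the
pipeline recovers planted structure through every processing stage. It
does not model sequence content, mappability, nucleosome positioning,
copy-number variation, antibody cross-reactivity, or correlated replicate
artifacts; agreement on simulated data therefore validates the
computation, not any biological conclusion drawn from real libraries.

## Problem sizes

Default suite: 2 × 200 kb genome, 120 genes, 13 samples × 200,000 reads,
2 replicates per tagged condition — a deliberate desk-scale rendering of a
genome-wide design (the real study: 12 Mb genome, 6020 genes, millions of
reads). All suite-derived statistics are ratios, positions, or
coefficients of variation, which are scale-free under this reduction.
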