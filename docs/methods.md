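# Methods

This note documents the statistical procedures, the conventions and defaults
they depend on, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and gene geometry

All internal coordinates are 0-based half-open (BED convention); GTF input
and output (1-based fully closed) are converted at the boundary, and the two
converters are exact inverses. Gene geometry is always derived from exons,
never read from a gene line: the span is the min/max over the exons of all
transcripts, the exonic union is the per-base union of exons, and exonic
content is exonic length over span length (in (0, 1]). The TSS is the
strand-aware 5' end — `span.start` on the plus strand, `span.end − 1` on the
minus strand; "gene start" in annotation files is deliberately interpreted
strand-aware, since the biological promoter sits at the 5' end. The promoter
is the 200 nt window centred on the TSS, clipped at chromosome edges. Score
tracks (bedGraph) treat uncovered bases as score 0, the usual convention for
conservation tracks; the missing value is configurable. Nearest-feature
queries are strand-ignored absolute TSS-to-TSS distances within a
chromosome, with ties broken to the lexicographically smaller subject id so
outputs are bit-stable.

## Benchmarking ranked predictions

Predictions are (gene, cohort, q-value) rows, q already FDR-adjusted by the
producer; no re-correction is applied here. For a cohort, genes are sorted
by ascending q (ties by gene id); precision at rank k is the fraction of
gold-standard genes among the top k, plotted against the baseline fraction
of gold among all tested genes. Cutoff metrics use the strict rule
q &lt; cutoff (default 0.1; ≤ available by flag). Enrichment is a two-sided
Fisher exact test on (gold vs non-gold) × (candidate vs non-candidate);
one-sided "greater" is available by flag. Pooling across cohorts counts a
gene as a candidate if it passes the cutoff in any cohort, with tested sets
unioned.

## Feature panel

Quantitative features use a two-sided Wilcoxon rank-sum test, while the
reported effect is the log2 ratio of group means. This asymmetry (rank-based
test, mean-based effect) is intentional and mirrors how such panels are
usually displayed; it means a significant p with a near-zero effect is
possible under skew. When either mean is non-positive the effect is reported
as NaN with a flag, and the p-value is still computed. When the two samples
contain identical values the p is reported as 1 directly (the rank statistic
has zero variance there). Qualitative features form a 2×2 table of
(focal/background) × (flag); the odds ratio is the plain cross-product,
with a Haldane +0.5 added to every cell only when some cell is zero (the
row is flagged). SNP catalogues are point sets deduplicated by position;
"SNP within 100 kb" is an inclusive distance from the TSS. Repeat-class
enrichment intersects each class with gene TSSs as width-1 points. GC
content and similar sequence-derived quantities enter the panel as plain
per-gene numeric columns (`extra_numeric`); the package does not read FASTA.

## Distribution-matched sampling

`match_distribution` draws a subset of a pool whose distribution over a
covariate matches a target sample. Bins are quantile bins of the target
(default 20). Two numerical choices matter:

* **Bin edges are anchored at observed target values** (`np.quantile`
  with `method="lower"`). With interpolated edges and a target smaller than
  the bin count, bins can contain no target value yet contain pool members —
  those members would be permanently unsampleable, silently biasing every
  matched control.
* **Per-bin demands use largest-remainder allocation** so the sample size
  equals N exactly. N is the largest total such that every bin's ceil-demand
  is available in the pool, optionally capped by a `size` argument. The
  resampling nulls cap at the focal set size: a null statistic computed on
  systematically larger samples has less sampling variance than the observed
  statistic and the empirical p is no longer calibrated.

A target bin with no pool candidates is dropped with a warning and the
proportions renormalised. Sampling is without replacement and fully
determined by the seed.

The "potentially functional" background (`select_pf_subset`) is the
two-stage version: match the focal conservation distribution first, then
match the focal expression distribution within the result.

## Orientation classification

Each transcript is classified against the protein-coding annotation:
overlap of spans gives `overlapping_sense`/`overlapping_antisense` (partner
is the gene with the largest overlap); otherwise, if the nearest
protein-coding TSS is more than 10 kb away **and** no protein-coding span
lies within 10 kb of the transcript span, the transcript is `intergenic`;
otherwise the orientation of the nearest (TSS-to-TSS) protein-coding gene
decides: opposite strand with the partner's TSS on the 5' side of the
lncRNA TSS (promoters back to back, transcription pointing apart) is
`divergent`, opposite strand with 3' ends facing is `convergent`, same
strand is `samestrand_pc_up`/`samestrand_pc_down` by the partner's position
relative to the lncRNA 5' end. The seven classes close the partition so
classification is total. A gene takes the modal class of its transcripts;
ties resolve by a fixed precedence (overlap &gt; divergent &gt; convergent &gt;
same-strand &gt; intergenic). The 10 kb genic and 200 kb pairing thresholds
are configuration constants.

## Coexpression and its nulls

Pairs are each focal lncRNA with its nearest protein-coding partner at
TSS–TSS &lt; 200 kb. Within each expression sample, Pearson r is computed
across pairs after a log2(x+1) transform (raw mode by flag); zero-variance
samples yield NaN with a flag. Two controls: (i) distance-matched control
pairs — candidate lncRNAs outside the observed set paired with the same
partners, subsampled by `match_distribution` on TSS–TSS distance; (ii) a
shuffled-pairing null — partner assignments permuted n_iter times (sample
identity preserved, derangement not enforced), all per-sample r values
pooled, and a two-sample KS test of observed vs pooled null. The headline
KS p uses the pooled null; per-sample values are retained in the result.

## Insertion-site enrichment

Insertion records longer than 1000 bp are discarded, as are (optionally)
records overlapping any protein-coding gene span by ≥1 bp. A gene "carries"
an insertion when the insertion overlaps its span (not exons only) by ≥1 bp,
half-open; with `mask_pc` the protein-coding overlap is subtracted from the
gene span first. Class rates partition the genome by precedence gold
protein-coding &gt; other protein-coding &gt; focal lncRNA &gt; other lncRNA &gt;
intergenic; class base pairs sum to the genome size and each insertion is
assigned to the highest-precedence class it overlaps.

Two empirical nulls, both with the counting p-value
`p = #{null ≥ observed}/n_iter` (no pseudocount; p can be 0; a conservative
(r+1)/(N+1) mode is available by flag):

* **Length-matched null** — background genes resampled (per iteration) to
  match the focal gene-length distribution, statistic = insertions per Mb of
  the aggregate (masked) sampled span.
* **Relocation null** — each gene relocated (length preserved) uniformly at
  random into the complement of the excluded regions, across chromosomes by
  default (same-chromosome mode by flag); relocated genes may overlap each
  other but never the exclusions; statistic = number of genes carrying ≥1
  insertion.

**Calibration and its limits.** On effect-free synthetic genomes with
enough insertion events (equal focal/background rates around 25/Mb, ~30
focal genes) both nulls and both coexpression controls reject at α=0.05 at
close to the nominal rate (measured 0–15% over 20 replicates). Two caveats
are inherent to the prescribed procedure: the r/N formula without
pseudocount is mildly anti-conservative (the observed value is not counted
as one realisation of the null), and at very low event counts the per-Mb
rate statistic is so discrete that a single insertion hit can exceed every
null value. Users applying the nulls to sparse insertion sets should prefer
the conservative p mode and read p = 0 as p &lt; 1/n_iter.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline detects, not
sequence-level biology. A genome of 4 × 10 Mb chromosomes carries 400
non-overlapping protein-coding genes (10% "gold") and 400 lncRNAs (10%
"census"), single-transcript by default (a multi-transcript mode exercises
the majority-vote classification). Planted effects, all configurable and
all switchable off together via `SimulationConfig.effect_free()`:

| effect | default | emulated feature |
|---|---|---|
| census length multiplier | 3.0 | longer census genes |
| proximity placement prob | 0.5 (within 50 kb of a gold gene) | clustering near cancer genes |
| divergent placement prob | 0.30 vs 0.05 | divergent-orientation excess |
| cancer-SNP proximity prob | 0.5 (within 100 kb) | germline-variant proximity |
| exon/promoter conservation mean | 0.5 vs 0.15 | conservation excess |
| TSS simple-repeat prob | 0.5 vs 0.05 | repeat-class preference |
| expression multiplier | 4.0 | higher census expression |
| pair latent correlation r | 0.7 | proximal-pair coexpression |
| insertion rate | 20/Mb vs 0.5/Mb | insertion-site enrichment |
| prediction π, low-q law | 0.8, Beta(1, 500) | census excess at top ranks |

Gene lengths are log-normal (σ=0.5, floor 300 bp); expression is log-normal
(natural-log mean 4, σ=1.5) with paired genes sharing a per-sample latent
factor weighted √r so the within-sample cross-pair correlation hits the
target on the log scale (the correlation is planted for *all* proximal
pairs, emulating the generic nearby-gene coexpression that the
distance-matched control is designed to absorb); insertions are Poisson in
census spans at the focal rate and in the remaining non-protein-coding
space at the background rate, with lengths uniform in [1, 1000]; prediction
q-values are Beta(1, 500) with probability π for census genes and uniform
otherwise, per cohort. The Beta(1, 500) law reflects that true drivers'
FDR-adjusted q-values sit far below the 0.1 cutoff. Each artefact type
draws from its own RNG stream derived from the master seed with a fixed
stream index, so adding a generator never changes existing outputs, and
regeneration under a fixed config is byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: overlapping gene models (planted genes never
overlap, so the overlapping orientation classes arise only in hand-built
test cases), realistic mutation spectra or cohort sizes, inter-gene
correlation structure beyond the planted pair latents, chromosome-scale
covariates (GC/replication timing) that confound real driver predictions,
and orthology mapping noise in the insertion sites (inputs are consumed
pre-mapped).

## Fixtures

`data/insertion_sites_table1.tsv` transcribes the ten published intergenic
human/mouse insertion-site records with both genomes' coordinates and
provenance columns. `data/census_v1_synthetic.tsv` is a synthetic stand-in
for the version-1 census supplement (which is not redistributable here): its
per-gene rows are generated, but its marginal counts — 122 genes, 8
pseudogene biotypes, 77/35/10 role split, 333 gene-cancer relationships
over 29 cancer types, 19 genes with ≥3 evidence classes, and the four most
prolific genes — match the published release, and the gene names/ids that
are printed in the source tables are used verbatim.

## Problem sizes

Default analysis sizes were chosen so the complete pipeline (simulation,
all analyses, both nulls at n_iter = 200/500) runs in seconds: a 40 Mb
genome with 800 genes gives every planted effect a comfortably detectable
signal while keeping brute-force oracle comparisons (per-base painting,
exact enumeration) instant. The null-calibration suite uses 20 replicate
6 Mb genomes with reduced n_iter = 100, and the relocation null's default
10,000 iterations is exercised at 500 in tests — the empirical-p machinery
is iteration-count-agnostic.

## Known limitations

* The census loader validates structure, not curation: transcription errors
  in a census table are data issues it cannot detect.
* The length-matched null matches marginal gene length only; covariates
  correlated with insertion density (e.g. chromatin state in real screens)
  are not matched.
* The Wilcoxon test falls back to the normal approximation under ties
  (scipy behaviour); exact enumeration holds for small tie-free samples.
* Orientation classification consults gene spans, not transcript-level
  overlap fractions; a lncRNA barely touching a protein-coding gene is
  "overlapping".
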