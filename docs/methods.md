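# Methods

## The signal and its container

Bisulfite sequencing cannot distinguish 5-methylcytosine from
5-hydroxymethylcytosine, so every level in this package is total DNA
modification. A track stores one record per CpG dyad — the +/− strand
records of a dyad are summed at input, because no downstream quantity is
strand-resolved — as sorted per-chromosome arrays of (position,
methylated reads *m*, unmethylated reads *u*). Coordinates are 0-based
half-open everywhere except cytosine-report I/O, which is 1-based.

Two summary conventions are used deliberately:

- **Site level** `m/(m+u)`, reported only at coverage ≥ `min_coverage`
  (default 5 reads for site-level calls, 1 read inside region summaries
  where pooling already stabilizes the estimate).
- **Weighted region level** `Σm/Σ(m+u)` over the CpGs of an interval,
  never the mean of per-site levels: with uneven coverage the weighted
  form is the maximum-likelihood estimate of a shared underlying level
  and is invariant to how reads are split across replicate records.

Replicates of a genotype are **pooled by summing counts** for region
detection (replicates model sampling from one methylome) but **averaged
at the profile level** for metagene displays, which mirrors how
per-replicate lines are inspected. On equal-coverage data the two orders
agree exactly, and the test suite asserts this.

## Metagene profiles

Each gene's TSS→TTS span is divided into 100 equal-width bins, ordered
5′→3′ (reversed for − strand genes). Bin means are weighted levels; a
bin without covered CpGs is missing (NaN), never imputed as 0 — imputing
would drag gene-body averages toward hypomethylation precisely in
CpG-poor genes. The promoter summary is the weighted level over
TSS ± 2 kb; a single promoter definition is used everywhere. The
gene-body delta between genotypes is the mean over bins 26–100 of the
per-bin (DKO − WT) difference, restricted to bins defined in both; the
first quarter of the gene is excluded because it is dominated by the
promoter-proximal unmethylated zone. Genes shorter than 100 bp yield
all-missing profiles (zero-width bins are meaningless) and are logged.

## Undermethylated regions and canyons

Membership is seeded on a rolling mean over 3 consecutive CpG levels
below `umr_max_level` = 0.10. Smoothing suppresses single-CpG dropouts,
but at a region border it borrows from the high neighbour and would trim
one genuine boundary CpG per side; each run is therefore extended
outward over adjacent CpGs whose **raw** level clears the threshold
(bounded by the gap limit so extension cannot jump a CpG desert). Runs
are merged across gaps ≤ 500 bp, then filtered: ≥ 5 member CpGs and
weighted level < 0.10 over the members. Intervals span first to last
member CpG. Canyons are UMRs of length ≥ 3.5 kb (inclusive).

**Edge dynamics.** Canyons are called in WT and re-measured in the
knockout — not matched against independently called DKO canyons, which
would make shrinkage a call-matching artifact. Edge windows are
`min(1 kb, 25 % of length)` per side: proportional for small canyons,
bounded for huge ones. Δedge is the mean over both sides of the DKO−WT
weighted level; shrinking at ≥ +0.10, expanding at ≤ −0.10, else stable.
A canyon with an uncovered edge in either genotype is labelled missing
and excluded from denominators. Note a structural asymmetry: a canyon
called at < 0.10 cannot mathematically lose another 0.10 at its edges,
so *expanding* labels require canyons whose edge windows carry
intermediate methylation — with the default thresholds the label exists
for completeness and for externally supplied canyon sets, and the
generator does not plant expanding canyons.

## Differentially modified regions

Sliding windows of 25 CpGs (covered in both pooled tracks), stepped by
5, are tested with Fisher's exact test on the pooled 2×2 count table;
q-values are Benjamini–Hochberg across all windows genome-wide. A window
is significant at q ≤ 0.05 **and** |Δ weighted level| ≥ 0.10 — the
effect-size gate matters because pooled coverage makes biologically
trivial differences (the ~0.03 global gain) statistically certain.
Touching significant windows of one direction merge into a DMR; level,
Δ and p are recomputed on the merged span, the reported q is the minimum
member-window q (BH q is defined at window level), and a merged span
diluted below the effect-size gate is dropped so every emitted DMR
satisfies its own invariants when recomputed from raw counts. Fixed
CpG-count windows keep the per-window information content comparable
between CpG-dense islands and sparse background. No per-replicate
dispersion model is fitted; with replicates pooled, the Fisher test is
exact under the generator's binomial read sampling, which the 20-seed
null suite confirms (no significant windows on effect-free data).

DMR annotation precedence is promoter/TSS > gene body > intergenic, so
each region receives exactly one deterministic label.

## CGI shores

Each island contributes an upstream and a downstream shore: the 2 kb
flank truncated at the nearest neighbouring island and clipped at
chromosome ends, so shores never intersect any island (the generator
plants non-overlapping islands; overlapping input islands should be
merged first). Shores intersecting any TSS ± 2 kb window are flagged as
promoter shores.

## Expression classification

Counts are CPM-normalized (library size = column sum). Fold change is
`(mean CPM_DKO + 0.5)/(mean CPM_WT + 0.5)`; the pseudocount keeps silent
genes finite. The p-value is a two-sided exact binomial test of the
gene's pooled knockout count against the knockout share of the total
library; gates are p ≤ 0.05 (inclusive) with FC strictly > 1.5 (up) or
strictly < 0.67 (down). A BH-adjusted gating mode is a switch
(`adjust=True`) since raw-p thresholding is anticonservative by design.

Two caveats are documented rather than hidden, and both are visible in
the package's own outputs. First, the pooled binomial test is calibrated
only under its sampling assumptions: the null-calibration suite uses
Poisson counts (where conditioning on the total makes the binomial test
exact; measured p ≤ 0.05 fraction ≈ 0.046 over 10,000 null genes), while
under negative-binomial overdispersion the raw test is strongly
anticonservative — only the fold-change gate keeps false calls rare.
Second, total-count normalization carries **composition bias**: planting
2:1 up:down DE inflates the knockout library, biasing null genes toward
apparent downregulation; low-count genes occasionally cross both gates,
which pulls the recovered up:down ratio below the planted 2:1 (e.g.
~1.4–1.6 at the default conditions). A median-of-ratios normalization
would remove this but is out of scope for this analysis's fixed recipe.

## Integration statistics

Canyon→promoter links use a strict < 2 kb rule between the interval and
the TSS point (0 if the TSS lies inside; otherwise the gap to the
nearest covered base); links are many-to-many. The direction contingency
is an uncorrected Pearson χ² (expected counts from margins,
Σ(O−E)²/E, df = 1) of the (down, up) split in a gene group against the
remaining DE genes; the background choice and a continuity-correction
switch are exposed because the comparison set is a genuine free choice.
Zero-margin tables raise instead of returning NaN. Printed percentages
round half-away-from-zero, matching how the study's ratios are quoted
(3,864/5,555 → 70 %).

Enhancer density maps scale every enhancer to [0, 1), cut it into 20
position bins, and count covered CpGs per (position bin, level decile);
level 1.0 closes into the top decile. Totals conserve the covered CpGs
inside the enhancer set. The central-region summary pools CpG levels
over the central third of every enhancer and reports the DKO−WT median
shift.

## The synthetic-data generator

The generator plants, per seed, the structure the analysis assumes:

- **Genome**: 2 chromosomes × 1.5 Mb. Genes occupy disjoint slots;
  promoter CGIs (TSS ± 500 bp) on 160 genes; 50 canyons (planted length
  3.8–8 kb) centred on CGI-promoters of alternating slots so planted
  canyons never touch; 140 enhancers (1.5 kb) rejection-placed ≥ 600 bp
  clear of islands and canyons — beyond the caller's 500 bp merge range,
  so distinct planted features cannot fuse into one call.
- **CpGs**: Poisson process at 0.008/bp background, enriched to 0.04/bp
  in islands and canyons and 2× background in enhancers (~39,000 dyads).
  Canyon truth intervals are additionally recorded **snapped to their
  first/last CpG**, because a planted region is only observable over
  that span — the same convention the caller uses — and the 300 bp
  planting margin above 3.5 kb keeps the observable extent above the
  canyon threshold.
- **Levels**: true per-CpG WT levels drawn once (shared by all
  replicates) from Beta distributions around 0.85 (background), 0.02
  (islands/canyons), 0.55/0.15 (enhancer flanks/centres), concentration
  60 — giving the bimodal genome-wide histogram. DKO levels add 0.03
  everywhere (the slight global gain), +0.20 on the edge windows of the
  41 % of canyons planted as shrinking, and +0.15 on enhancer flanks,
  clamped to [0, 1].
- **Reads**: per replicate, coverage ~ Poisson(30) per CpG
  (zero-coverage sites are emitted, exercising coverage filters);
  methylated reads ~ Binomial(coverage, level). Three replicates per
  genotype.
- **RNA**: negative-binomial counts (dispersion 0.01, i.e. a biological
  CV of 0.1 as typical for genetically identical model organisms) around
  log-uniform baseline means (5–5,000), with 10 % of genes DE at
  |log2FC| = 1.5 and a 2:1 up:down split.

All randomness flows from one seed through named substreams, so the same
(config, seed) reproduces byte-identical files, and annotation, CpG
placement and true levels are identical across genotypes — the only
WT/DKO differences are the planted effects.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: read-level artifacts (bisulfite
conversion failure, mapping bias, PCR duplicates), non-CpG methylation,
copy-number and SNP effects, spatially correlated coverage, partially
methylated domains, biological replicate heterogeneity in the methylome
(replicates share one true methylome), real CGI/canyon sequence
structure, and any genuine methylation–expression coupling. The
independence result on synthetic data shows the pipeline does not
*fabricate* coupling; it cannot show that real data lack it.

## Problem sizes and determinism

Default analyses run on the 3 Mb genome above (~10 s per full pipeline).
The null-calibration suites use 20 seeds on a 400 kb single-chromosome
genome (DMR windows) and 20 × 500 Poisson genes (DE test), sizes chosen
so the Monte-Carlo error on the estimated rates is a small fraction of
the nominal 0.05 while the whole suite stays interactive. Every test and
script fixes its seeds; `scripts/acceptance.py` derives all its
substream seeds from the single `--seed` argument.
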