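# Methods

## Screen model and scope

The pipeline analyses paired pooled CRISPRi fitness screens: one guide
library assayed in two isogenic backgrounds (`reference`, `mutant`), each
with sequencing at an initial (`start`) and final (`end`) timepoint and
one or more replicates. Inputs are three TSVs — guide annotation (guide →
gene, or non-targeting control), sample metadata, raw counts — and the
output is a per-gene table of genetic-interaction (GI) scores, exact mHG
p-values, BH q-values, directions and hit tiers. Upstream read processing
(demultiplexing, guide assignment) and single-background essentiality
calling are out of scope.

## Fitness computation

1. **Normalization** — each sample column is scaled to a common total.
   Default target is the *mean raw column sum* (`mean_depth`), which keeps
   values on a read-count scale so the coverage threshold of 100 reads
   stays interpretable; `per_million` (CPM) is available. A sample with
   zero total reads is a data error, not a silent drop.
2. **Replicate pooling** — normalized replicate columns of the same
   (background, timepoint) are summed, then the pooled columns are
   normalized again. Pooling trades replicate-level dispersion estimates
   for depth; the scoring below uses rank enrichment rather than
   per-guide variance, so depth is what matters.
3. **Coverage filter** — a guide passes in a background iff its pooled
   normalized count at `start` is ≥ 100 (strictly fewer fails). The filter
   runs after pooling and renormalization, the only point where a screen
   has a single normalized start value per guide. Only guides passing in
   *both* backgrounds enter interaction scoring: the per-guide difference
   is undefined when one side is unmeasured, and one-sided retention would
   bias the ranked list.
4. **log2FC** — `log2((norm_end + 1)/(norm_start + 1))`. The +1
   pseudocount keeps dropouts finite; at the default depth (hundreds of
   reads per guide) its bias is ≤ ~0.01 log2 units except for strongly
   depleted guides, where the sign is unambiguous anyway.
5. **Control centering** — per background, the median log2FC of
   non-targeting controls *that pass the filter* is subtracted (
   low-coverage controls carry the largest pseudocount bias, so they are
   excluded from the reference point). Median of an even-sized set is the
   mean of the middle pair. A background with no surviving controls is an
   error.

## Interaction scoring

Per guide, Δ = centered log2FC(mutant) − centered log2FC(reference).
Guides are sorted by Δ ascending (most synthetic-sick first), with exact
ties broken by guide id for determinism.

**Statistic.** For a gene with B guides among N ranked guides, the mHG
statistic is the minimum over prefix lengths n = 1..N−1 of the
hypergeometric tail P(X ≥ b_n | N, B, n), where b_n counts the gene's
guides in the top n. The full-list prefix is excluded (its tail is 1) and
the statistic is capped at 1. Prefix cuts that would split a block of
exactly tied Δ values are disallowed: ties carry no ranking information,
and without this rule the deterministic tie-break would manufacture
enrichment (an all-tied list must give statistic 1). Ties are
measure-zero on real data; the rule matters only for degenerate inputs.

**Exact p-value.** The statistic is not a p-value (it is minimized over
~N prefixes). The exact p is the null probability, over the C(N,B)
equally likely placements of the gene's guides among the ranks, that the
minimum tail is ≤ the observed statistic. A placement is a monotone
lattice path (0,0) → (N,B); the rejection region {(n,b): tail ≤ s} is
upward-closed in b and contiguous in n, so paths can enter it only
through its staircase boundary by a label step. The implementation counts
paths avoiding the region with exact integer arithmetic (Python
arbitrary-precision), accumulating first-entry mass times free
completions C(N−n, B−b); p = hit / C(N,B) evaluated as an exact rational
before conversion to float. There is no underflow, cancellation, or
tolerance anywhere in the count; the only float comparison is the region
membership test `tail ≤ stat·(1+1e−12)`, whose slack exists so that the
region always contains the cell that produced the observed statistic.
The DP costs O(N·B) cells; a configurable cell budget (default 5×10^7)
guards against pathological sizes, with the permutation estimator as the
documented fallback. Hypergeometric tails come from `scipy.stats.
hypergeom.sf`, precomputed per (N, B) as a B × (N−1) table shared by all
genes of a screen.

**Two directions.** The test is run on the ranked list (negative
interactions, synthetic sickness) and on the reversed list (positive
interactions, suppression); the reported p is min(1, 2·min(p_neg,
p_pos)) — a Bonferroni doubling, conservative but simple — and the
direction is the smaller side (negative on ties). The GI score is the
gene's median Δ, signed; direction and sign agree whenever there is real
signal.

**Multiplicity and tiers.** Benjamini–Hochberg step-up over all tested
genes (untested genes — no guide surviving the filters — are reported
with NaN statistics and excluded from the FDR input). Hits: q < 0.05 and
|GI| > 1 (tier1) or |GI| > 2 (tier2); thresholds are configurable. The
magnitude |GI| is compared because both synthetic-sick (GI < 0) and
suppressor (GI > 0) interactions are biologically meaningful hits.

**Permutation estimator.** `permutation_pvalue` draws uniform label
placements directly (positions of the B labels in a random permutation),
evaluates the statistic only at label steps — the tail can fall only
when a label is appended, so the prefix minimum is attained there — and
applies the add-one correction (1 + hits)/(n_perm + 1). It serves as an
independent cross-check of the exact DP, not as the primary method.

## Synthetic screens

The generator emulates the screen design: `n_genes × guides_per_gene`
targeting guides (default 5 per gene) plus `n_controls` non-targeting
controls (default 100), two backgrounds × two timepoints ×
`replicates` (default 2) samples, `generations` = 17 of competitive
growth.

* **Effects.** A fraction `frac_neutral` (default 0.8) of genes is
  exactly neutral; the rest draw a per-generation fitness defect
  −|N(0, `fitness_sd`)| (default sd 0.05), the same in both backgrounds.
  CRISPRi knockdowns are overwhelmingly neutral-to-deleterious, which
  this half-normal mixture captures with two parameters. A
  `frac_interacting` subset (⌊frac·n_genes⌋ genes, chosen uniformly)
  additionally receives `delta_effect` per generation (default −0.15) in
  the mutant only.
* **Guides.** Efficacy is uniform on `efficacy_range` (default
  [0.6, 1]) and multiplies the gene effect linearly — the first-order
  model of partial knockdown, giving the within-gene variability the mHG
  test must tolerate. Controls have zero effect.
* **Growth.** Deterministic exponential competition from uniform initial
  abundance: abundance_i ∝ 2^(G·s·e). No growth noise, no cloning or
  dilution bottleneck — multinomial sequencing sampling at each timepoint
  is the only stochastic element, with `depth_per_guide` (default 500)
  expected reads per guide per sample. All randomness derives from one
  seed through counter-based sub-streams, so runs are bitwise
  reproducible and sample-order independent.

Consequently the simulation reproduces the statistical structure the
scoring assumes (rank enrichment driven by a shared gene effect across
guides, noise shrinking with depth) but **not** several features of real
screens: overdispersion from PCR jackpots and dilution bottlenecks, polar
dCas9 effects and operon structure, guide off-targets, batch effects
between replicates. Passing the simulation-based tests therefore
demonstrates the pipeline's correctness and calibration under its own
model, not robustness to those artefacts. One such gap is visible even in
simulation: strongly depleted genes have noisier end counts, hence
slightly heavier-tailed null Δ ranks; the measured null positive rate
(~5%) stays near nominal at realistic effect scales.

## Numerical and design notes

* Filter boundary: "fewer than 100" is strict — exactly 100 passes.
* Ranking tie-break: stable sort by (Δ, guide_id); together with the
  fixed column order this makes the whole pipeline byte-deterministic
  for a given config and seed.
* Results serialization: 12 significant digits; read/write round-trips
  at that precision. Sorting: q ascending, then |GI| descending.
* q-values of genes with p so small it underflows are still finite: p is
  floored at 1e−300 before BH (the exact p of a 5-guide gene cannot
  actually reach that scale at any realistic N).
* The mHG statistic's `pivot` (smallest minimizing prefix) is reported
  by `mhg_statistic` for inspection but does not enter the p-value.
* Validation problem sizes (`crispri_gi.validation`): calibration and
  recovery screens use 2000 genes × 5 guides + 100 controls at 10^4
  reads per guide — large enough for stable rate estimates at
  genome-like N while keeping a full scored screen around half a minute;
  the growth-law limit check uses 50 genes at 10^5 reads per guide,
  where multinomial noise (≲0.02 log2 units) sits well inside the ±0.05
  agreement band.

## Known limitations

* The Bonferroni doubling across directions is slightly conservative
  compared with an exact two-sided mHG null.
* Replicates are pooled, not modelled; concordance between replicates is
  not scored (a correlation report is trivial to add upstream).
* Guides present in counts but missing from the annotation are retained
  and ranked (they shape N) but belong to no gene and no control set.
* A gene's guides are assumed exchangeable; no efficacy reweighting or
  outlier rejection is applied.
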