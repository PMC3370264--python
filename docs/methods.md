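# Methods

## Model and assumptions

The scan treats a genome as a set of scaffolds, each an ordered list of
genes; a gene's position is its 0-based ordinal in that list. Base-pair
coordinates are carried through for reporting (BED output) but never enter
the statistic: gene density varies much less in gene-count space than in bp
space, and scaffold assemblies without chromosome coordinates support it
naturally. Strand is ignored — co-location, not co-orientation, is the
question.

Under the null hypothesis the `n` hit genes are an unordered uniform draw
from the `N` loci. The expected ordinal spacing between consecutive hits is
then `N/n`, and the scan declares a cluster where consecutive gaps are
"threefold tighter than random": all gaps ≤ `(N/n)/spacing_divisor`. Two
further rules make calls meaningful:

* `min_hits` (default 3): a pair of adjacent hits always clears any density
  threshold and is uninformative.
* `min_enrichment` (default 3): local density `n_hits/span_genes` must be
  at least threefold the genome-wide density, mirroring the "threefold
  increase over the random distribution" framing of the threshold itself.

With the default divisor 3, a run of `k` hits with gaps ≤ ⌊τ⌋ has density
at least `k/(⌊τ⌋(k−1)+1)` — above threefold the genome density whenever
τ ≈ 3.9 — so the enrichment rule rarely bites at the defaults; it is kept
as an independent rule so either criterion can be tightened alone.

**Gap metric.** "Distance in genes" between hits is ambiguous: the ordinal
difference (adjacent genes → 1) or the intervening-gene count (adjacent →
0). The ordinal difference is the default (`gap_metric="ordinal"`);
`"intervening"` is a one-flag switch. The comparison is `gap ≤ τ` with τ
real-valued (τ ≈ 3.963 admits integer gaps up to 3); `strict_threshold`
switches to `<`. Note one consequence: in the saturated case where every
gene is a hit, the ordinal metric yields no runs at all (every gap is 1 >
τ = ⅓) while the intervening metric yields one run per scaffold at
enrichment exactly 1.

**Permutation null.** The observed statistic is the genome-wide cluster
count. Permutations redraw `n` hit loci uniformly without replacement over
the fixed scaffold structure (optionally stratified: per-scaffold hit
counts preserved) and rescan with identical parameters;
`p = (1 + #{count ≥ observed}) / (n_perm + 1)` (add-one smoothing, never
exactly 0). The cluster count is discrete, and ties between the observed
value and the permutation distribution make the test mildly conservative;
calibration on 200 null genomes gives P(p ≤ 0.05) ≈ 0.04. A caveat worth
stating: when a substantial fraction of hits is clustered, the *dispersed
remainder* is thinner than a uniform redraw of all `n` hits, so null
permutations can assemble more chance runs than the observed background —
the cluster-count statistic is conservative in exactly the regime where
clustering is strong. Scanning with `min_hits` matched to the cluster size
of interest removes most of that background (see benchmarks below).

## Differential-expression stage

The selection chain targets replicated two-condition intensity matrices on
the linear scale:

1. **Quantile normalization**: each sample's values are replaced by the
   reference (row mean of all samples' sorted vectors) at their rank; tied
   values within a sample receive the mean of the reference values at the
   tied ranks. For ties of 3+ this differs from limma's
   `normalizeQuantiles(ties=TRUE)` (which interpolates the reference at the
   mean tied rank); on tie-free data the two agree to machine precision and
   the operation is exactly idempotent.
2. **Replicate-CV filter** (default 0.20): "SD > 20% within replicates" is
   read as the coefficient of variation per condition — an absolute SD is
   meaningless on arbitrary intensity units. Sample SD (n−1); a gene must
   pass in every condition; zero-mean genes fail with a recorded reason.
3. **Fold change and test**: fold = max(ratio, 1/ratio) of condition means
   on the linear scale; direction from the sign of the difference; p from a
   Welch two-sample t on log2 intensities. The test is a pluggable
   function — array-era pipelines delegated testing to vendor software, so
   no single per-gene test is canonical; Welch-on-log2 is the conservative
   default. With < 2 replicates per condition p is reported missing and the
   gene is unselectable.
4. **BH FDR** (statsmodels step-up) and **selection** at fold ≥ 2, q ≤ 0.05
   in the requested direction; a raw-p mode (`use_q=False`) exists for
   emulating pipelines that thresholded unadjusted P = 0.05.

Thresholds are applied to normalized condition means, and normalization
precedes filtering and testing.

## Synthetic data

`SimulationConfig` defaults encode the target study design: 9143 genes on
30 scaffolds (equal weights; configurable), 769 regulated genes
(downregulated, log2fc −2), 20 planted clusters of 6–10 hits at
within-cluster gaps ≤ 2, two biological replicates per condition. How the
regulated genes split between clustered and dispersed is a free parameter —
planted cluster sizes are drawn from `cluster_size_range` and the remainder
is placed uniformly on the unused loci, which is exactly the permutation
null. Planted spans are separated by a 30-locus guard gap so ground truth
is unambiguous.

Expression is the standard additive microarray model on log2 scale:
per-gene baseline ~ N(10, 2), replicate noise ~ N(0, `noise_sd`), the
regulated effect added in the treatment condition only, emitted as `2^x`.
The baseline spread matters: real arrays span many log2 units of
constitutive expression, and that spread is what keeps quantile
normalization nearly fold-preserving. With a degenerate baseline the 8.4%
shifted genes dominate the lower tail of the distribution and normalization
itself erases the effect (fold 4 → ~1.7). Even with spread, normalization
compresses a 4-fold effect to ~3.5-fold median — visible in the worked
example as 766/769 genes recovered. Default replicate noise is
`noise_sd = 0.1` (typical replicate-array log2 SD ≈ 0.1–0.3).

Not emulated: probe-level structure, background, dye/batch effects,
intensity-dependent (loess-type) bias, correlated noise between neighbouring
genes. Passing tests therefore demonstrate the statistics' behaviour under
the stated noise model, not robustness to array artefacts.

One RNG stream per function with fixed draw order (cluster sizes →
placement → within-cluster gaps → dispersed hits → bp coordinates → strands
→ categories; baselines → noise), so a seed pins every output bit-for-bit.
Category labels ("CAZyme", genome-average probability 320/9143) are drawn
with a boosted probability inside planted spans and a compensating lower
probability outside, preserving the genome-wide average while making the
in-cluster density ≈ `category_cluster_boost`× (default 5×) the random
expectation.

## Benchmark designs and parameter choices

* **Planted-cluster recovery** runs the scan with `min_hits = 6`, the
  smallest planted cluster size. At the default `min_hits = 3` the ~600
  dispersed hits alone assemble ~18 qualifying runs per genome (they pass
  the threefold-enrichment rule automatically, since gaps ≤ 3 force local
  density ≥ 3/7), so a benchmark counting "unplanted calls" must match
  `min_hits` to the signal it planted. Span agreement is measured as
  coverage of the true span by the call: dispersed hits that legitimately
  satisfy the gap rule can abut a planted cluster and extend the call, and
  that is correct scan behaviour, not a boundary error; overcalling is
  scored separately via unplanted calls.
* **DE recovery** uses 4 replicates per condition and disables the CV
  filter. With duplicates, a Welch test has ~2 degrees of freedom and its
  attainable p-values sit above the BH cutoff for any realistic genome —
  recall at q ≤ 0.05 is near zero regardless of effect size. (The pipeline
  default still simulates duplicates, faithful to the emulated design; the
  end-to-end demo and benchmarks use the power-adequate 4.) At
  `noise_sd = 0.25` the true linear CV is ≈ 0.175, right at the 0.20
  filter boundary, so the CV filter would measure noise rather than the
  selection rule under test.
* **Permutation calibration** uses 200 null genomes × 499 permutations at
  full scale (9143 genes, 769 hits) — ~15 s; the acceptance pipeline uses
  999 permutations.
* **Scan-oracle equivalence** checks 500 random instances (≤ 200 loci)
  against an O(n²) exhaustive maximal-interval enumeration, over both gap
  metrics and both threshold strictness modes.

## Numerical and degenerate-input conventions

* Ordinals 0-based contiguous per scaffold; bp 1-based inclusive
  internally; BED emitted/read 0-based half-open. GFF3/BED ordinals derive
  from sorting by (start, end, gene_id) — a deterministic tie-break for
  overlapping genes.
* `expected_spacing` errors on zero hits; display rounding (one decimal) is
  the caller's concern — `11.889/3 = 3.963` truncates to the conventional
  "3.9".
* BH: NaN p-values propagate and are excluded from `n`; q ∈ [p, 1].
* Hypergeometric overlap p is upper-tail `P(X ≥ k)`; a zero overlap gives
  p = 1 by the ≥ 0 convention. The universe must contain |A ∪ B|.
* Permutation p uses add-one smoothing; seeds below 2³¹; the CLI fans one
  global seed out by fixed offsets (genome +0, expression +1, permutations
  +2).

## Known limitations

* The cluster-count permutation statistic loses power when clustering is
  strong (see above); a hits-in-clusters or max-run statistic would be
  natural extensions.
* Cluster boundaries stop at the first/last hit; no extension into flanking
  non-hit genes.
* Gene-order space ignores physical gap sizes; two hits separated by one
  enormous intergenic region still count as adjacent-but-one.
* The DE stage assumes a gene-level matrix; probe summarization and
  background correction are out of scope.
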