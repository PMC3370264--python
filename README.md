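# posclust

Positional clustering of co-regulated genes on genome scaffolds.

In many fungi, functionally related genes — carbohydrate-active enzyme
(CAZyme) genes, secondary-metabolite genes — sit in discrete genomic
clusters. When a regulator is deleted and hundreds of genes lose
expression, a natural question is whether the affected genes are randomly
scattered along the scaffolds or concentrated in such clusters. `posclust`
answers that question for gene sets derived from replicated two-condition
intensity data (classical microarray designs), working entirely in
**gene-order space**: the unit of distance is the ordinal position of a gene
on its scaffold, not base pairs.

## The statistic

With `N` genes on the scaffolds and `n` of them *hits* (e.g. genes at least
twofold downregulated), uniform random placement puts one hit at every
`N/n`-th locus on average — the **expected spacing**. For `N = 9143`,
`n = 769` that is `9143/769 ≈ 11.9`, i.e. one hit at roughly every twelfth
locus. A **cluster** is a maximal run of at least `min_hits` hits whose
consecutive ordinal gaps are all at most

```
τ = (N/n) / spacing_divisor        # default divisor 3:  τ ≈ 11.9/3 ≈ 3.9
```

and whose local hit density (hits per spanned gene) exceeds the genome-wide
density `n/N` by at least `min_enrichment`-fold (default 3). Significance
of the genome-wide cluster count is assessed by permutation: hit labels are
redrawn uniformly over all loci, the scan is repeated with identical
parameters, and `p = (1 + #{permutations with ≥ observed clusters}) /
(n_permutations + 1)`.

Upstream, the package reproduces the classical selection chain — quantile
normalization, a replicate-CV filter (drop genes with CV > 20% within a
condition), fold change of condition means with a Welch t-test on log2
intensities, Benjamini–Hochberg FDR, selection at fold ≥ 2 and q ≤ 0.05.
Downstream it compares gene lists by directional overlap with a
hypergeometric test, and quantifies category (e.g. CAZyme) density
enrichment inside called regions. A synthetic-data generator plants
clusters of regulated genes in simulated genomes so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
from posclust import (SimulationConfig, simulate_genome, simulate_expression,
                      quantile_normalize, build_de_table, select_regulated,
                      ScanParams, scan_genome, permutation_test)

cfg = SimulationConfig(n_replicates=4, seed=1)   # 9143 genes, 769 downregulated
sim = simulate_genome(cfg)
em  = simulate_expression(sim, cfg, seed=2)

det      = build_de_table(quantile_normalize(em))
selected = select_regulated(det)                  # fold >= 2, q <= 0.05, down
print(len(selected))                              # 766

params = ScanParams(seed=3)                       # divisor 3, min_hits 3
res = scan_genome(sim.genome, selected, params)
res.permutation_p = permutation_test(sim.genome, len(selected), res, params,
                                     n_permutations=999, hits=selected)
print(round(res.expected_spacing, 1))             # 11.9
print(round(res.threshold, 1))                    # 4.0  (11.889/3 = 3.963)
print(res.n_clusters, res.n_scaffolds_with_clusters)   # 39 25
print(round(res.mean_hits_per_cluster, 1))        # 6.1
print(round(res.mean_enrichment, 1))              # 8.5
print(res.permutation_p)                          # 0.054
```

The selection recovers 766 of the 769 planted downregulated genes with no
false selections. The scan finds 39 dense regions on 25 scaffolds: the 20
planted clusters plus runs assembled by chance from the ~600 dispersed
hits — at this hit density a purely random placement already produces
~30 qualifying runs of ≥ 3 hits, which is why the permutation p-value on
the raw cluster count is modest and why benchmarks targeting the planted
clusters scan with `min_hits` matched to the planted size (see
`docs/methods.md`).

The same stages are available from a shell:

```
posclust run-all --seed 1 --out demo_out
posclust scan --config cfg.yaml --min-hits 6 --permutations 999
```

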