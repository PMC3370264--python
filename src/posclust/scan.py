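"""Density-threshold scanning for positional clusters of hit genes.

The statistic works entirely in gene-order (ordinal) space.  With N genes on
the scaffolds and n of them "hits" (e.g. significantly downregulated), the
expected spacing between hits under uniform random placement is N/n; for the
target study's numbers, 9143/769 ~= 11.9, i.e. one hit at roughly every
twelfth locus.  A cluster is a maximal run of at least ``min_hits`` hits in
which every consecutive gap is at most the expected spacing divided by
``spacing_divisor`` (default 3, giving the study's threshold of 11.9/3 ~=
3.9), provided the run's local hit density exceeds the genome-wide density
by at least ``min_enrichment``-fold (default 3).

Significance of the genome-wide cluster count is assessed by a permutation
null: hit labels are redrawn uniformly without replacement over all loci
(optionally stratified per scaffold), the scan is repeated with identical
parameters, and the add-one-smoothed upper-tail p-value is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .io import GeneList, GenomeTable, ValidationError

__all__ = [
    "ScanParams",
    "ClusterCall",
    "ScanResult",
    "expected_spacing",
    "spacing_threshold",
    "scan_scaffold",
    "scan_genome",
    "permutation_test",
    "category_density_enrichment",
]


@dataclass
class ScanParams:
    """Tunables of the cluster scan.

    gap_metric: ``ordinal`` measures the gap between consecutive hits as the
    difference of their ordinal positions (adjacent genes -> gap 1);
    ``intervening`` counts the genes strictly between them (adjacent -> 0).
    ``strict_threshold`` switches the comparison from gap <= tau to gap < tau.
    """

    spacing_divisor: float = 3.0
    min_hits: int = 3
    min_enrichment: float = 3.0
    n_permutations: int = 1000
    seed: int = 0
    gap_metric: str = "ordinal"  # or "intervening"
    strict_threshold: bool = False
    stratified_permutation: bool = False

    def __post_init__(self) -> None:
        if self.spacing_divisor <= 0:
            raise ValidationError("spacing_divisor must be > 0")
        if self.min_hits < 2:
            raise ValidationError("min_hits must be >= 2")
        if self.gap_metric not in ("ordinal", "intervening"):
            raise ValidationError(f"unknown gap_metric {self.gap_metric!r}")


@dataclass
class ClusterCall:
    """One called positional cluster on a scaffold (ordinals inclusive)."""

    scaffold: str
    start_ordinal: int
    end_ordinal: int
    hit_genes: GeneList
    n_hits: int
    span_genes: int
    local_density: float
    enrichment: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hit_genes"] = list(self.hit_genes.ids)
        return d


@dataclass
class ScanResult:
    """Genome-wide scan summary plus the individual cluster calls."""

    n_total: int
    n_hits: int
    expected_spacing: float
    threshold: float
    clusters: list[ClusterCall]
    permutation_p: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_scaffolds_with_clusters(self) -> int:
        return len({c.scaffold for c in self.clusters})

    @property
    def mean_hits_per_cluster(self) -> float:
        return float(np.mean([c.n_hits for c in self.clusters])) if self.clusters else float("nan")

    @property
    def mean_span_genes(self) -> float:
        return float(np.mean([c.span_genes for c in self.clusters])) if self.clusters else float("nan")

    @property
    def mean_enrichment(self) -> float:
        return float(np.mean([c.enrichment for c in self.clusters])) if self.clusters else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hits": self.n_hits,
            "expected_spacing": self.expected_spacing,
            "threshold": self.threshold,
            "n_clusters": self.n_clusters,
            "n_scaffolds_with_clusters": self.n_scaffolds_with_clusters,
            "mean_hits_per_cluster": self.mean_hits_per_cluster,
            "mean_span_genes": self.mean_span_genes,
            "mean_enrichment": self.mean_enrichment,
            "permutation_p": self.permutation_p,
            "clusters": [c.to_dict() for c in self.clusters],
        }


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def expected_spacing(n_total: int, n_hits: int) -> float:
    """Mean gap between hits under uniform placement: n_total / n_hits.

    Returned unrounded; display conventionally rounds to one decimal
    (9143/769 -> 11.889..., shown as 11.9).
    """
    if n_hits <= 0:
        raise ValidationError("expected_spacing undefined for n_hits = 0")
    if n_hits > n_total:
        raise ValidationError("n_hits cannot exceed n_total")
    return n_total / n_hits


def spacing_threshold(spacing: float, divisor: float = 3.0) -> float:
    """Cluster gap threshold: expected spacing / divisor (11.9/3 -> ~3.9)."""
    if divisor <= 0:
        raise ValidationError("divisor must be > 0")
    return spacing / divisor


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _run_boundaries(ordinals: np.ndarray, threshold: float, params: ScanParams) -> list[np.ndarray]:
    """Split sorted hit ordinals into maximal runs with small internal gaps."""
    if len(ordinals) == 0:
        return []
    gaps = np.diff(ordinals)
    if params.gap_metric == "intervening":
        gaps = gaps - 1
    big = gaps >= threshold if params.strict_threshold else gaps > threshold
    return np.split(ordinals, np.where(big)[0] + 1)


def scan_scaffold(
    hit_ordinals: Sequence[int] | np.ndarray,
    threshold: float,
    params: ScanParams,
    global_density: float,
    scaffold: str = "",
    gene_id_of: dict[tuple[str, int], str] | None = None,
) -> list[ClusterCall]:
    """Call clusters on one scaffold from sorted hit ordinals.

    Maximal runs of hits whose consecutive gaps are all within the threshold
    become candidates; a candidate is kept iff it has at least
    ``params.min_hits`` hits and local density (hits per spanned gene) at
    least ``params.min_enrichment`` times ``global_density``.  Calls are
    disjoint and ordered along the scaffold.
    """
    ords = np.asarray(hit_ordinals, dtype=int)
    if len(ords) and (np.diff(ords) <= 0).any():
        raise ValidationError("hit ordinals must be strictly increasing")
    if (ords < 0).any():
        raise ValidationError("hit ordinals must be non-negative")
    calls: list[ClusterCall] = []
    for run in _run_boundaries(ords, threshold, params):
        n = len(run)
        if n < params.min_hits:
            continue
        span = int(run[-1] - run[0] + 1)
        density = n / span
        enrichment = density / global_density
        if enrichment < params.min_enrichment:
            continue
        if gene_id_of is not None:
            ids = tuple(gene_id_of[(scaffold, int(o))] for o in run)
        else:
            ids = tuple(f"{scaffold}:{int(o)}" for o in run)
        calls.append(
            ClusterCall(
                scaffold=scaffold,
                start_ordinal=int(run[0]),
                end_ordinal=int(run[-1]),
                hit_genes=GeneList(ids, label=f"{scaffold}:{int(run[0])}-{int(run[-1])}"),
                n_hits=n,
                span_genes=span,
                local_density=density,
                enrichment=enrichment,
            )
        )
    return calls


def scan_genome(genome: GenomeTable, hits: GeneList, params: ScanParams) -> ScanResult:
    """Scan every scaffold for clusters of the given hit genes.

    Raises when a hit id is absent from the genome.  The permutation p-value
    is not computed here; see :func:`permutation_test`.
    """
    n_total = genome.n_genes
    n_hits = len(hits)
    spacing = expected_spacing(n_total, n_hits)
    threshold = spacing_threshold(spacing, params.spacing_divisor)
    global_density = n_hits / n_total
    per_scaffold = genome.hit_ordinals(hits.ids)
    lookup = {
        (row.scaffold, int(row.ordinal)): row.gene_id
        for row in genome.df.itertuples(index=False)
    }
    clusters: list[ClusterCall] = []
    for scaffold in genome.scaffolds:
        if scaffold not in per_scaffold:
            continue
        clusters.extend(
            scan_scaffold(per_scaffold[scaffold], threshold, params, global_density,
                          scaffold=scaffold, gene_id_of=lookup)
        )
    return ScanResult(n_total=n_total, n_hits=n_hits, expected_spacing=spacing,
                      threshold=threshold, clusters=clusters)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _count_clusters_padded(
    positions: np.ndarray, threshold: float, params: ScanParams, global_density: float
) -> int:
    """Cluster count from sorted padded-global positions (fast path).

    Padding between scaffolds exceeds the threshold, so runs never cross a
    scaffold boundary; within-scaffold ordinal differences are preserved, so
    spans and densities are exact.
    """
    if len(positions) == 0:
        return 0
    gaps = np.diff(positions)
    if params.gap_metric == "intervening":
        gaps = gaps - 1
    big = gaps >= threshold if params.strict_threshold else gaps > threshold
    idx = np.concatenate([[0], np.where(big)[0] + 1, [len(positions)]])
    starts, ends = idx[:-1], idx[1:] - 1
    n = ends - starts + 1
    keep = n >= params.min_hits
    if not keep.any():
        return 0
    span = positions[ends[keep]] - positions[starts[keep]] + 1
    enr = (n[keep] / span) / global_density
    return int((enr >= params.min_enrichment).sum())


def _padded_layout(genome: GenomeTable, threshold: float) -> tuple[np.ndarray, int]:
    """Map every locus to a global coordinate with > threshold padding between scaffolds."""
    sizes = np.array(list(genome.scaffold_sizes().values()))
    pad = int(math.floor(threshold)) + 2
    offsets = np.concatenate([[0], np.cumsum(sizes + pad)])[:-1]
    coords = np.concatenate([off + np.arange(sz) for off, sz in zip(offsets, sizes)])
    return coords, int(sizes.sum())


def permutation_test(
    genome: GenomeTable,
    n_hits: int,
    observed: ScanResult,
    params: ScanParams,
    n_permutations: int | None = None,
    seed: int | None = None,
    hits: GeneList | None = None,
) -> float:
    """Upper-tail permutation p-value for the observed cluster count.

    Each permutation draws ``n_hits`` loci uniformly without replacement
    (over the whole genome, or per scaffold preserving the observed per-
    scaffold hit counts when ``params.stratified_permutation``), rescans
    with identical parameters and counts clusters.  p = (1 + #{permutation
    count >= observed count}) / (n_permutations + 1); the add-one smoothing
    means p is never exactly 0.
    """
    n_perm = params.n_permutations if n_permutations is None else n_permutations
    if n_perm < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    coords, n_total = _padded_layout(genome, observed.threshold)
    global_density = n_hits / n_total

    at_least = 0
    if params.stratified_permutation:
        # preserve per-scaffold hit counts of the observed configuration
        if hits is None:
            raise ValidationError("stratified permutation needs the observed hit list")
        per_scaffold = genome.hit_ordinals(hits.ids)
        counts = [len(per_scaffold.get(s, ())) for s in genome.scaffolds]
        sizes = list(genome.scaffold_sizes().values())
        offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        for _ in range(n_perm):
            draws = [
                off + rng.choice(sz, k, replace=False)
                for off, sz, k in zip(offsets, sizes, counts)
                if k
            ]
            pos = np.sort(coords[np.concatenate(draws)]) if draws else np.array([], int)
            if _count_clusters_padded(pos, observed.threshold, params, global_density) >= observed.n_clusters:
                at_least += 1
    else:
        for _ in range(n_perm):
            pos = np.sort(coords[rng.choice(n_total, n_hits, replace=False)])
            if _count_clusters_padded(pos, observed.threshold, params, global_density) >= observed.n_clusters:
                at_least += 1
    return (1 + at_least) / (n_perm + 1)


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------

def category_density_enrichment(
    genome: GenomeTable,
    regions: Iterable[tuple[str, tuple[int, int]]],
    category: str,
) -> float:
    """Fold change of a category's gene density inside regions vs genome-wide.

    regions are (scaffold, (start_ordinal, end_ordinal)) with inclusive
    bounds.  Returns (category genes in regions / genes in regions) divided
    by (category genes genome-wide / all genes).
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("category_density_enrichment needs at least one region")
    mask = genome.category_mask(category)
    total_cat = int(mask.sum())
    if total_cat == 0:
        raise ValidationError(f"category {category!r} absent from genome")
    in_genes = 0
    in_cat = 0
    cat_ids = set(genome.df.loc[mask.to_numpy(), "gene_id"])
    for scaffold, (lo, hi) in regions:
        span = genome.genes_in_span(scaffold, lo, hi)
        in_genes += len(span)
        in_cat += span["gene_id"].isin(cat_ids).sum()
    if in_genes == 0:
        raise ValidationError("regions contain no genes")
    return (in_cat / in_genes) / (total_cat / genome.n_genes)
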