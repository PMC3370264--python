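"""Synthetic genomes and replicated two-condition expression matrices.

The generator emulates the study design the pipeline targets: a fungal
genome of ~9143 genes laid out on scaffolds, of which a subset (~769 by
default) is downregulated in a deletion mutant.  Part of the regulated set is
planted in tight positional clusters (the signal the cluster scan must
recover); the remainder is dispersed uniformly, which is exactly the null
model of the permutation test.  Expression is simulated as Gaussian noise on
log2 intensities around condition means — the standard additive microarray
noise model — and emitted on the linear scale.

All randomness flows through one ``numpy`` Generator seeded from
``SimulationConfig.seed``; the draw order is fixed (cluster sizes, cluster
placement, within-cluster gaps, dispersed hits, bp coordinates, strands,
category labels, then expression noise), so a seed pins every output
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneList, GenomeTable, ValidationError

__all__ = ["SimulationConfig", "SimulatedGenome", "simulate_genome", "simulate_expression"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the target study's scale: 9143 genes, 769 regulated
    (downregulated at least twofold), two biological replicates per
    condition.  Twenty planted clusters of 6-10 hits at within-cluster gaps
    <= 2 emulate the CAZyme-cluster signal; the split between clustered and
    dispersed regulated genes is deliberately a free parameter.
    """

    n_genes: int = 9143
    n_scaffolds: int = 30
    scaffold_weights: tuple[float, ...] | None = None  # None -> equal
    n_regulated: int = 769
    n_planted_clusters: int = 20
    cluster_size_range: tuple[int, int] = (6, 10)  # hit genes per planted cluster
    within_cluster_spacing: int = 2  # max ordinal gap between planted hits
    cluster_separation: int = 30  # guard gap (ordinals) between planted spans
    n_replicates: int = 2  # per condition
    base_log2_intensity: float = 10.0
    base_log2_sd: float = 2.0  # spread of per-gene baselines (log2 scale)
    noise_sd: float = 0.1  # replicate noise (log2 scale)
    regulated_log2fc: float = -2.0  # negative = downregulated in treatment
    categories: dict[str, float] = field(default_factory=lambda: {"CAZyme": 320 / 9143})
    category_cluster_boost: float = 5.0  # in-cluster density multiple of genome average
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_scaffolds < 1:
            raise ValidationError("n_genes and n_scaffolds must be positive")
        if not 0 <= self.n_regulated <= self.n_genes:
            raise ValidationError("n_regulated must lie in [0, n_genes]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.base_log2_sd < 0:
            raise ValidationError("base_log2_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        lo, hi = self.cluster_size_range
        if not (0 < lo <= hi):
            raise ValidationError("cluster_size_range must be a positive interval")
        if self.within_cluster_spacing < 1:
            raise ValidationError("within_cluster_spacing must be >= 1")
        if self.n_planted_clusters * lo > self.n_regulated:
            raise ValidationError(
                f"{self.n_planted_clusters} clusters of >= {lo} hits exceed "
                f"n_regulated = {self.n_regulated}"
            )
        if self.scaffold_weights is not None:
            w = np.asarray(self.scaffold_weights, float)
            if len(w) != self.n_scaffolds:
                raise ValidationError("scaffold_weights length must equal n_scaffolds")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("scaffold_weights must be non-negative and sum to 1")
        for label, p in self.categories.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"category {label!r} probability {p} outside [0,1]")
            if not 0 <= p * self.category_cluster_boost <= 1:
                raise ValidationError(
                    f"category {label!r}: boosted in-cluster probability exceeds 1"
                )


@dataclass
class SimulatedGenome:
    """A genome table plus the planted ground truth."""

    genome: GenomeTable
    truth_regulated: GeneList
    truth_clusters: pd.DataFrame  # cluster_id, scaffold, start/end_ordinal, n_hits, gene_ids

    def write_truth(self, path: str | Path) -> None:
        """Per-gene truth TSV, kept separate from the analysis inputs."""
        df = self.genome.df[["gene_id"]].copy()
        reg = set(self.truth_regulated.ids)
        df["truth_regulated"] = df["gene_id"].isin(reg)
        member_of: dict[str, str] = {}
        for row in self.truth_clusters.itertuples(index=False):
            for g in row.gene_ids.split(";"):
                member_of[g] = row.cluster_id
        df["truth_cluster_id"] = df["gene_id"].map(member_of).fillna("")
        df.to_csv(path, sep="\t", index=False)

    def write_truth_clusters(self, path: str | Path) -> None:
        self.truth_clusters.to_csv(path, sep="\t", index=False)


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items by weights (deterministic)."""
    raw = weights * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out a genome and plant regulated genes, some in tight clusters.

    Every gene is assigned to exactly one scaffold with contiguous ordinals
    from 0; planted clusters are placed with a guard gap of
    ``cluster_separation`` ordinals so that ground-truth spans never touch;
    the remaining regulated genes are dropped uniformly at random on the
    loci not already used.  Raises when the requested clusters cannot fit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    weights = (
        np.full(config.n_scaffolds, 1.0 / config.n_scaffolds)
        if config.scaffold_weights is None
        else np.asarray(config.scaffold_weights, float)
    )
    sizes = _apportion(config.n_genes, weights)
    scaffold_names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]

    lo, hi = config.cluster_size_range
    cluster_sizes = rng.integers(lo, hi + 1, size=config.n_planted_clusters)
    if cluster_sizes.sum() > config.n_regulated:
        # redraw at the minimum size; if even that fails, validate() caught it
        cluster_sizes = np.full(config.n_planted_clusters, lo)

    # --- place planted clusters ------------------------------------------
    guard = config.cluster_separation
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.n_scaffolds)}
    planted: list[tuple[int, np.ndarray]] = []  # (scaffold index, hit ordinals)
    for k, csize in enumerate(cluster_sizes):
        gaps = rng.integers(1, config.within_cluster_spacing + 1, size=int(csize) - 1)
        span = int(gaps.sum()) + 1
        placed = False
        for _ in range(200):
            s = int(rng.integers(0, config.n_scaffolds))
            if sizes[s] < span:
                continue
            start = int(rng.integers(0, sizes[s] - span + 1))
            lo_g, hi_g = start - guard, start + span - 1 + guard
            if any(not (hi_g < a or lo_g > b) for a, b in occupied[s]):
                continue
            ords = start + np.concatenate([[0], np.cumsum(gaps)])
            occupied[s].append((start, start + span - 1))
            planted.append((s, ords))
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"cannot place planted cluster {k + 1} (span {span} + guard {guard}): "
                "scaffold capacity exhausted; reduce clusters or enlarge the genome"
            )

    # --- global indexing ---------------------------------------------------
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    scaffold_of = np.repeat(np.arange(config.n_scaffolds), sizes)
    ordinal_of = np.concatenate([np.arange(n) for n in sizes])

    planted_global: list[np.ndarray] = [offsets[s] + ords for s, ords in planted]
    planted_flat = (
        np.concatenate(planted_global) if planted_global else np.array([], dtype=int)
    )

    n_dispersed = config.n_regulated - len(planted_flat)
    free = np.setdiff1d(np.arange(config.n_genes), planted_flat, assume_unique=False)
    dispersed = (
        rng.choice(free, size=n_dispersed, replace=False) if n_dispersed else np.array([], int)
    )
    regulated = np.sort(np.concatenate([planted_flat, dispersed])).astype(int)

    # --- bp coordinates, strands, categories -------------------------------
    gene_len = rng.integers(500, 3001, size=config.n_genes)
    intergenic = rng.integers(100, 1001, size=config.n_genes)
    start_bp = np.empty(config.n_genes, dtype=int)
    end_bp = np.empty(config.n_genes, dtype=int)
    for s in range(config.n_scaffolds):
        mask = scaffold_of == s
        lens, gaps_bp = gene_len[mask], intergenic[mask]
        starts = 1 + np.concatenate([[0], np.cumsum(lens[:-1] + gaps_bp[:-1])])
        start_bp[mask] = starts
        end_bp[mask] = starts + lens - 1
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    in_cluster_span = np.zeros(config.n_genes, bool)
    for s, ords in planted:
        in_cluster_span[offsets[s] + np.arange(ords[0], ords[-1] + 1)] = True
    span_frac = in_cluster_span.mean()

    cats = [""] * config.n_genes
    for label, p_avg in config.categories.items():
        # in-cluster probability = boost * genome average; outside lowered so
        # the genome-wide average stays at p_avg (the paper-style contrast:
        # in-cluster density ~ boost x the expected random density)
        p_in = min(1.0, p_avg * config.category_cluster_boost)
        p_out = (p_avg - p_in * span_frac) / (1 - span_frac) if span_frac < 1 else p_avg
        if p_out < 0:
            raise ValidationError(
                f"category {label!r}: boost {config.category_cluster_boost} not achievable "
                "with the planted span fraction; lower the boost or the probability"
            )
        draw = rng.random(config.n_genes) < np.where(in_cluster_span, p_in, p_out)
        for i in np.where(draw)[0]:
            cats[i] = f"{cats[i]};{label}" if cats[i] else label

    gene_ids = np.array([f"g{i:05d}" for i in range(config.n_genes)])
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "scaffold": [scaffold_names[s] for s in scaffold_of],
            "ordinal": ordinal_of,
            "start_bp": start_bp,
            "end_bp": end_bp,
            "strand": strand,
            "categories": cats,
        }
    )
    genome = GenomeTable(df)

    truth_rows = []
    for k, (s, ords) in enumerate(planted):
        members = gene_ids[offsets[s] + ords]
        truth_rows.append(
            {
                "cluster_id": f"planted_{k + 1}",
                "scaffold": scaffold_names[s],
                "start_ordinal": int(ords[0]),
                "end_ordinal": int(ords[-1]),
                "n_hits": len(ords),
                "gene_ids": ";".join(members),
            }
        )
    truth_clusters = pd.DataFrame(
        truth_rows,
        columns=["cluster_id", "scaffold", "start_ordinal", "end_ordinal", "n_hits", "gene_ids"],
    )
    truth_regulated = GeneList(tuple(gene_ids[regulated]), label="truth_regulated",
                               direction="down" if config.regulated_log2fc < 0 else "up")
    return SimulatedGenome(genome, truth_regulated, truth_clusters)


def simulate_expression(sim: SimulatedGenome, config: SimulationConfig,
                        seed: int | None = None) -> ExpressionMatrix:
    """Replicated two-condition intensities for a simulated genome.

    log2 intensity = gene baseline + regulated_log2fc * 1[regulated gene,
    treatment sample] + N(0, noise_sd); the matrix is emitted on the linear
    scale (2^x, strictly positive).  Per-gene baselines are drawn once as
    N(base_log2_intensity, base_log2_sd): real arrays span many log2 units
    of constitutive expression, and that spread is what makes quantile
    normalization nearly fold-preserving — with a degenerate baseline the
    regulated genes would dominate the lower distribution tail and be
    normalized away.  Draw order is fixed (baselines, then the noise
    matrix); ``seed`` defaults to ``config.seed + 1`` so genome layout and
    expression come from distinct streams.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = sim.genome.df["gene_id"].to_numpy()
    regulated = np.isin(genes, list(sim.truth_regulated.ids))

    n_rep = config.n_replicates
    samples = [f"control_{r + 1}" for r in range(n_rep)] + [
        f"treatment_{r + 1}" for r in range(n_rep)
    ]
    baseline = config.base_log2_intensity + (
        rng.normal(0.0, config.base_log2_sd, size=len(genes)) if config.base_log2_sd else 0.0
    )
    mean_log2 = np.tile(baseline[:, None], (1, 2 * n_rep)).astype(float)
    mean_log2[regulated, n_rep:] += config.regulated_log2fc
    noise = rng.normal(0.0, config.noise_sd, size=mean_log2.shape) if config.noise_sd else 0.0
    values = pd.DataFrame(2.0 ** (mean_log2 + noise), index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    design = pd.DataFrame(
        {
            "condition": ["control"] * n_rep + ["treatment"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values, design)
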