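"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive each statistic from its definition
(quadratic-time enumeration, explicit combinatorics) and never call the
implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from posclust import ExpressionMatrix, GenomeTable, SimulationConfig, simulate_genome


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_runs(
    ordinals, threshold, min_hits, min_enrichment, global_density,
    strict=False, metric="ordinal",
):
    """Enumerate every maximal qualifying run by checking all intervals.

    For each pair (i, j) of hit indices, the interval qualifies when every
    internal gap is within the threshold; it is maximal when it cannot be
    extended on either side.  O(n^2), independent of the scan implementation.
    """
    ords = list(ordinals)
    n = len(ords)

    def gap_ok(a, b):
        g = b - a - (1 if metric == "intervening" else 0)
        return g < threshold if strict else g <= threshold

    out = []
    for i in range(n):
        for j in range(i, n):
            if any(not gap_ok(ords[k], ords[k + 1]) for k in range(i, j)):
                continue
            if i > 0 and gap_ok(ords[i - 1], ords[i]):
                continue
            if j < n - 1 and gap_ok(ords[j], ords[j + 1]):
                continue
            k = j - i + 1
            if k < min_hits:
                continue
            span = ords[j] - ords[i] + 1
            if (k / span) / global_density < min_enrichment:
                continue
            out.append((ords[i], ords[j], k))
    return out


def brute_force_bh(p):
    """Step-up BH from the definition: q(i) = min over p(j) >= p(i) of p(j)*n/rank(j)."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    q = [None] * n
    for i in range(n):
        candidates = [min(1.0, p[j] * n / rank[j]) for j in range(n) if p[j] >= p[i]]
        q[i] = min(candidates)
    return q


def brute_force_hypergeom_sf(k, universe, n_marked, n_drawn):
    """P(X >= k) for a hypergeometric draw, by explicit enumeration."""
    total = math.comb(universe, n_drawn)
    acc = 0
    for x in range(k, min(n_marked, n_drawn) + 1):
        if n_drawn - x > universe - n_marked:
            continue
        acc += math.comb(n_marked, x) * math.comb(universe - n_marked, n_drawn - x)
    return acc / total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_genome() -> GenomeTable:
    """Two scaffolds, 6 + 4 genes, with bp coordinates and one category."""
    rows = []
    for s, n in (("sA", 6), ("sB", 4)):
        pos = 1
        for i in range(n):
            rows.append(
                {
                    "gene_id": f"{s}_g{i}",
                    "scaffold": s,
                    "ordinal": i,
                    "start_bp": pos,
                    "end_bp": pos + 999,
                    "strand": "+" if i % 2 == 0 else "-",
                    "categories": "CAZyme" if i == 0 else "",
                }
            )
            pos += 1500
    return GenomeTable(pd.DataFrame(rows))


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x (2 control + 2 treatment), strictly positive."""
    values = pd.DataFrame(
        {
            "control_1": [100.0, 50.0, 80.0, 10.0],
            "control_2": [110.0, 52.0, 78.0, 12.0],
            "treatment_1": [25.0, 49.0, 320.0, 11.0],
            "treatment_2": [26.0, 51.0, 330.0, 10.0],
        },
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
    )
    design = pd.DataFrame(
        {"condition": ["control", "control", "treatment", "treatment"], "replicate": [1, 2, 1, 2]},
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionMatrix(values, design)


@pytest.fixture
def small_sim():
    """A 400-gene simulated genome with 4 planted clusters (fast)."""
    cfg = SimulationConfig(
        n_genes=400, n_scaffolds=4, n_regulated=60, n_planted_clusters=4,
        cluster_size_range=(4, 6), within_cluster_spacing=2, cluster_separation=15,
        n_replicates=4, seed=42,
    )
    return cfg, simulate_genome(cfg)
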