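"""The cluster scan: arithmetic, run chaining, invariances, permutation null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_runs
from posclust import (
    GeneList,
    ScanParams,
    SimulationConfig,
    ValidationError,
    category_density_enrichment,
    expected_spacing,
    permutation_test,
    scan_genome,
    scan_scaffold,
    simulate_genome,
    spacing_threshold,
)


# ---------------------------------------------------------------------------
# spacing arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_total,n_hits,expected",
    [(9143, 769, 11.889466840052016), (100, 100, 1.0), (1000, 40, 25.0)],
)
def test_expected_spacing(n_total, n_hits, expected):
    assert expected_spacing(n_total, n_hits) == pytest.approx(expected)


def test_expected_spacing_errors():
    with pytest.raises(ValidationError):
        expected_spacing(100, 0)
    with pytest.raises(ValidationError):
        expected_spacing(10, 11)


def test_spacing_threshold():
    assert spacing_threshold(12, 3) == 4.0
    assert spacing_threshold(11.889466840052016, 3) == pytest.approx(3.963155, abs=1e-5)
    s = 11.889466840052016
    assert spacing_threshold(s, 1) == s
    with pytest.raises(ValidationError):
        spacing_threshold(10, 0)


# ---------------------------------------------------------------------------
# single-scaffold scanning
# ---------------------------------------------------------------------------

DENSITY = 769 / 9143


def test_scan_scaffold_no_hits():
    assert scan_scaffold([], 3.9, ScanParams(), DENSITY) == []


def test_scan_scaffold_dense_run():
    calls = scan_scaffold(list(range(7)), 3.963, ScanParams(), DENSITY, scaffold="s")
    assert len(calls) == 1
    c = calls[0]
    assert c.n_hits == 7 and c.span_genes == 7
    assert c.enrichment == pytest.approx(1 / DENSITY, rel=1e-9)
    assert c.enrichment == pytest.approx(11.889, abs=1e-3)


def test_scan_scaffold_min_hits_discards_pairs():
    calls = scan_scaffold([0, 2, 50, 52, 54], 3.963, ScanParams(min_hits=3), DENSITY)
    assert len(calls) == 1
    assert (calls[0].start_ordinal, calls[0].end_ordinal, calls[0].n_hits) == (50, 54, 3)


def test_scan_scaffold_rejects_bad_input():
    with pytest.raises(ValidationError):
        scan_scaffold([5, 3], 3.9, ScanParams(), DENSITY)
    with pytest.raises(ValidationError):
        scan_scaffold([1, 1, 4], 3.9, ScanParams(), DENSITY)


def test_equally_spaced_hits_above_threshold_yield_nothing():
    ords = list(range(0, 200, 5))  # gaps of 5 > threshold 3.963
    assert scan_scaffold(ords, 3.963, ScanParams(), DENSITY) == []


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 199), min_size=1, max_size=60),
    st.floats(0.5, 8, allow_nan=False),
    st.integers(2, 5),
    st.sampled_from(["ordinal", "intervening"]),
    st.booleans(),
)
def test_scan_matches_brute_force_enumeration(ordset, threshold, min_hits, metric, strict):
    ords = sorted(ordset)
    params = ScanParams(min_hits=min_hits, min_enrichment=2.0,
                        gap_metric=metric, strict_threshold=strict)
    density = len(ords) / 200
    got = [(c.start_ordinal, c.end_ordinal, c.n_hits)
           for c in scan_scaffold(ords, threshold, params, density)]
    want = brute_force_runs(ords, threshold, min_hits, 2.0, density,
                            strict=strict, metric=metric)
    assert got == want


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.sets(st.integers(0, 150), min_size=3, max_size=40), st.integers(0, 10**6))
def test_reversal_invariance(ordset, seed):
    """Mirroring gene order within the scaffold mirrors the calls exactly."""
    ords = sorted(ordset)
    L = 151
    params = ScanParams(min_hits=2, min_enrichment=1.0)
    fwd = scan_scaffold(ords, 3.963, params, len(ords) / L)
    rev = scan_scaffold(sorted(L - 1 - o for o in ords), 3.963, params, len(ords) / L)
    mirrored = sorted((L - 1 - c.end_ordinal, L - 1 - c.start_ordinal, c.n_hits) for c in rev)
    assert sorted((c.start_ordinal, c.end_ordinal, c.n_hits) for c in fwd) == mirrored


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.sets(st.integers(0, 150), min_size=3, max_size=40),
       st.floats(0.5, 4, allow_nan=False), st.floats(1, 4, allow_nan=False))
def test_threshold_monotonicity(ordset, t_small, extra):
    """At a lower threshold every call lies inside some maximal run of the
    higher threshold, and no span grows."""
    ords = sorted(ordset)
    t_big = t_small + extra
    params = ScanParams(min_hits=2, min_enrichment=0.0)
    small = scan_scaffold(ords, t_small, params, len(ords) / 151)
    big = scan_scaffold(ords, t_big, params, len(ords) / 151)
    for c in small:
        assert any(b.start_ordinal <= c.start_ordinal and c.end_ordinal <= b.end_ordinal
                   for b in big)


# ---------------------------------------------------------------------------
# genome-wide scanning
# ---------------------------------------------------------------------------

def test_scan_genome_recovers_planted_clusters(small_sim):
    cfg, sim = small_sim
    res = scan_genome(sim.genome, sim.truth_regulated, ScanParams(min_hits=4))
    truth = [(t.scaffold, t.start_ordinal, t.end_ordinal)
             for t in sim.truth_clusters.itertuples(index=False)]
    for scaf, lo, hi in truth:
        assert any(c.scaffold == scaf and c.start_ordinal <= lo and hi <= c.end_ordinal
                   for c in res.clusters)
    # summary statistics recomputable from the cluster list
    assert res.mean_hits_per_cluster == pytest.approx(
        np.mean([c.n_hits for c in res.clusters]))
    assert res.mean_enrichment == pytest.approx(
        np.mean([c.enrichment for c in res.clusters]))
    assert res.n_scaffolds_with_clusters == len({c.scaffold for c in res.clusters})


def test_scan_genome_missing_hits_error(tiny_genome):
    with pytest.raises(ValidationError, match="ghost"):
        scan_genome(tiny_genome, GeneList(("sA_g0", "ghost")), ScanParams())


def test_all_genes_hit_saturation(tiny_genome):
    """Every gene a hit: adjacent hits chain into one run per scaffold under
    the intervening-gene metric (gap 0), at enrichment exactly 1 — so any
    min_enrichment > 1 discards everything."""
    hits = GeneList(tuple(tiny_genome.df["gene_id"]))
    res = scan_genome(tiny_genome, hits,
                      ScanParams(min_enrichment=3.0, gap_metric="intervening"))
    assert res.n_clusters == 0  # enrichment is exactly 1 everywhere
    res2 = scan_genome(tiny_genome, hits,
                       ScanParams(min_enrichment=1.0, gap_metric="intervening"))
    assert res2.n_clusters == len(tiny_genome.scaffolds)
    assert all(c.enrichment == pytest.approx(1.0) for c in res2.clusters)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_permutation_p_is_one_for_empty_scan():
    cfg = SimulationConfig(n_genes=500, n_scaffolds=2, n_regulated=10,
                           n_planted_clusters=0, seed=4)
    sim = simulate_genome(cfg)
    res = scan_genome(sim.genome, sim.truth_regulated, ScanParams(min_hits=5))
    if res.n_clusters == 0:
        p = permutation_test(sim.genome, 10, res, ScanParams(), n_permutations=49, seed=0)
        assert p == 1.0


def test_strongly_planted_signal_reaches_minimum_p():
    cfg = SimulationConfig(n_genes=9143, n_scaffolds=30, n_regulated=40,
                           n_planted_clusters=5, cluster_size_range=(8, 8),
                           within_cluster_spacing=1, seed=6)
    sim = simulate_genome(cfg)
    params = ScanParams(min_hits=8)  # matched to the planted cluster size
    res = scan_genome(sim.genome, sim.truth_regulated, params)
    assert res.n_clusters >= 5
    p = permutation_test(sim.genome, 40, res, params, n_permutations=999, seed=1)
    assert p == pytest.approx(1 / 1000)


def test_stratified_permutation_needs_hits_and_runs(small_sim):
    cfg, sim = small_sim
    params = ScanParams(min_hits=4, stratified_permutation=True)
    res = scan_genome(sim.genome, sim.truth_regulated, params)
    with pytest.raises(ValidationError, match="hit list"):
        permutation_test(sim.genome, len(sim.truth_regulated), res, params,
                         n_permutations=19)
    p = permutation_test(sim.genome, len(sim.truth_regulated), res, params,
                         n_permutations=19, hits=sim.truth_regulated)
    assert 0 < p <= 1
    with pytest.raises(ValidationError):
        permutation_test(sim.genome, 10, res, params, n_permutations=0,
                         hits=sim.truth_regulated)


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------

def test_category_enrichment_whole_genome_is_one(tiny_genome):
    regions = [("sA", (0, 5)), ("sB", (0, 3))]
    assert category_density_enrichment(tiny_genome, regions, "CAZyme") == pytest.approx(1.0)


def test_category_enrichment_arithmetic():
    # 2000-gene genome, 80 category genes; a 20-gene region holding 8 of them
    # -> (8/20) / (80/2000) = 10
    import pandas as pd

    cats = [""] * 2000
    for i in range(8):
        cats[i] = "X"
    for i in range(100, 172):
        cats[i] = "X"
    df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(2000)],
                       "scaffold": "s", "ordinal": range(2000), "categories": cats})
    from posclust import GenomeTable

    gt = GenomeTable(df)
    assert category_density_enrichment(gt, [("s", (0, 19))], "X") == pytest.approx(10.0)


def test_category_enrichment_empty_regions_error(tiny_genome):
    with pytest.raises(ValidationError):
        category_density_enrichment(tiny_genome, [], "CAZyme")
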