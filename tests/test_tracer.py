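from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from pangotrace.errors import DataError
from pangotrace.genodata import AlleleFrequencyTable, allele_frequencies
from pangotrace.tracer import (
    classify_trend,
    observed_private_alleles,
    presence_probability,
    private_richness_curves,
    select_tracing_loci,
    trace_individuals,
)
from pangotrace.synth import SimulationConfig, simulate_dataset
from conftest import make_dataset


def table_from_counts(counts_by_pop, locus="L1"):
    """AlleleFrequencyTable straight from gene-copy counts (one locus)."""
    n_genes = {p: {locus: sum(c.values())} for p, c in counts_by_pop.items()}
    return AlleleFrequencyTable(
        partition={p: [] for p in counts_by_pop},
        locus_names=[locus],
        counts={p: {locus: dict(c)} for p, c in counts_by_pop.items()},
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle
# ---------------------------------------------------------------------------

def oracle_presence(counts, allele, g):
    """P(allele in subsample of g copies) by enumerating every subsample."""
    genes = [a for a, c in counts.items() for _ in range(c)]
    combos = list(combinations(range(len(genes)), g))
    hit = sum(1 for cmb in combos if any(genes[i] == allele for i in cmb))
    return Fraction(hit, len(combos))


def oracle_private(counts_by_pop, focal, g):
    """Exact expected private richness and frequency-weighted measure."""
    alleles = sorted({a for c in counts_by_pop.values() for a in c})
    N = sum(counts_by_pop[focal].values())
    rich = Fraction(0)
    freq = Fraction(0)
    for a in alleles:
        q = oracle_presence(counts_by_pop[focal], a, g)
        for p, c in counts_by_pop.items():
            if p != focal:
                q *= 1 - oracle_presence(c, a, g)
        rich += q
        freq += Fraction(counts_by_pop[focal].get(a, 0), N) * q
    return rich, freq


def test_presence_probability_examples():
    assert presence_probability(10, 0, 3) == 0.0
    assert presence_probability(10, 4, 10) == 1.0
    assert presence_probability(4, 1, 2) == pytest.approx(0.5)


def test_presence_probability_matches_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n_alleles = rng.integers(1, 4)
        counts = {100 + 2 * k: int(rng.integers(1, 4)) for k in range(n_alleles)}
        N = sum(counts.values())
        g = int(rng.integers(1, N + 1))
        for a in counts:
            exact = oracle_presence(counts, a, g)
            assert presence_probability(N, counts[a], g) == pytest.approx(
                float(exact), abs=1e-12)


def test_private_curves_match_enumeration_small_instances():
    """Exact agreement with full subsample enumeration, <= 8 gene copies/pop."""
    rng = np.random.default_rng(3)
    for _ in range(8):
        J = int(rng.integers(2, 4))
        pops = [f"P{i}" for i in range(J)]
        counts_by_pop = {}
        for p in pops:
            k = int(rng.integers(1, 4))
            c = {100 + 2 * m: int(rng.integers(0, 4)) for m in range(k)}
            c = {a: v for a, v in c.items() if v} or {100: 2}
            while sum(c.values()) < 2:
                c[100] = c.get(100, 0) + 1
            counts_by_pop[p] = c
        g_max = min(sum(c.values()) for c in counts_by_pop.values())
        if g_max < 2:
            continue
        ft = table_from_counts(counts_by_pop)
        res = private_richness_curves(ft, g_max=g_max, K_range=[J], g_unit="genes")
        for focal in pops:
            rich = res.richness[("L1", focal, J)]
            freq = res.mean_freq[("L1", focal, J)]
            for gi, g in enumerate(res.g_values):
                er, ef = oracle_private(counts_by_pop, focal, g)
                assert rich[gi] == pytest.approx(float(er), abs=1e-9)
                assert freq[gi] == pytest.approx(float(ef), abs=1e-9)


def test_hand_worked_two_population_case():
    # pop1 {A:1, B:3}, pop2 {B:4}, g = 2 gene copies:
    # private richness of pop1 = Q_A(2) * 1 = 0.5
    ft = table_from_counts({"p1": {1: 1, 2: 3}, "p2": {2: 4}})
    res = private_richness_curves(ft, g_max=2, K_range=[2], g_unit="genes")
    assert res.richness[("L1", "p1", 2)][0] == pytest.approx(0.5)


def test_truly_private_fixed_allele_tends_to_one():
    # allele fixed in pop1, absent elsewhere: contribution Q -> 1 as g grows
    ft = table_from_counts({"p1": {1: 8}, "p2": {2: 8}})
    res = private_richness_curves(ft, g_max=8, K_range=[2], g_unit="genes")
    curve = res.richness[("L1", "p1", 2)]
    assert np.all(np.diff(curve) >= -1e-12)  # monotone for private alleles
    assert curve[-1] == pytest.approx(1.0)


def test_private_sum_bounded_by_allele_count(study_scale):
    ds, _ = study_scale
    forest = ds.by_site_class("forest")
    ft = allele_frequencies(forest)
    res = private_richness_curves(ft, g_max=5)
    K = max(res.levels)
    for locus in ft.locus_names:
        na = len({a for p in ft.groups for a in ft.counts[p][locus]})
        total = sum(res.richness[(locus, p, K)][-1]
                    for p in ft.groups if (locus, p, K) in res.richness)
        assert total <= na + 1e-9


def test_combination_averaging_counts_all_subsets(study_scale):
    ds, _ = study_scale
    ft = allele_frequencies(ds.by_site_class("forest"))
    res = private_richness_curves(ft, g_max=3, K_range=[2, 3])
    J = len(ft.groups)
    # every population appears at levels 2 and 3 for an unskipped locus
    locus = ft.locus_names[0]
    for p in ft.groups:
        assert (locus, p, 2) in res.richness
        assert (locus, p, 3) in res.richness


def test_k_above_population_count_rejected():
    ft = table_from_counts({"p1": {1: 4}, "p2": {2: 4}})
    with pytest.raises(DataError):
        private_richness_curves(ft, g_max=2, K_range=[3], g_unit="genes")


# ---------------------------------------------------------------------------
# Catalog, trend classification, selection, tracing
# ---------------------------------------------------------------------------

def test_observed_private_alleles_rules():
    ds = make_dataset(
        [[(1, 2)], [(1, 1)], [(1, 3)], [(1, 1)]],
        populations=["a", "a", "b", "b"],
    )
    cat = observed_private_alleles(allele_frequencies(ds))
    assert cat.by_population["a"] == {("L1", 2)}   # allele 1 shared, not private
    assert cat.by_population["b"] == {("L1", 3)}


def test_planted_allele_lands_in_catalog():
    cfg = SimulationConfig(n_pops=3, pop_sizes=(12, 12, 12), n_loci=4,
                           alleles_per_locus=3, fst_target=0.05, fis_target=0.0,
                           missing_rate=0.0, seed=21,
                           private_plan=[(0, "P2", 0.5)])
    ds, truth = simulate_dataset(cfg)
    locus, pop, label, _ = truth.planted[0]
    cat = observed_private_alleles(allele_frequencies(ds.by_site_class("forest")))
    assert (locus, label) in cat.by_population[pop]


@pytest.mark.parametrize("curve, expected", [
    ([0.58, 0.60, 0.60], "plateau"),
    ([0.10, 0.20, 0.46], "exponential"),
    ([0.30, 0.25, 0.20], "decreasing"),
    ([0.10, 0.15, 0.18], "rejected"),      # rising but below both thresholds
])
def test_classify_trend_rules(curve, expected):
    assert classify_trend(np.array(curve)) == expected


def test_selection_requires_both_lines_of_evidence():
    ft = table_from_counts({"p1": {1: 6, 3: 2}, "p2": {1: 2, 2: 6}})
    res = private_richness_curves(ft, g_max=6, K_range=[2], g_unit="genes")
    cat = observed_private_alleles(ft)
    selected = select_tracing_loci(res, cat, measure="frequency",
                                   plateau_thresh=0.0, expo_thresh=0.0)
    # observed private alleles exist for both pops; with zero thresholds any
    # non-decreasing curve passes
    for locus, by_pop in selected.items():
        for pop, alleles in by_pop.items():
            assert alleles <= {a for (l, a) in cat.by_population[pop]}
    # no observed private allele -> never selected, whatever the curve
    cat_empty = observed_private_alleles(
        table_from_counts({"p1": {1: 4, 2: 4}, "p2": {1: 4, 2: 4}}))
    assert select_tracing_loci(res, cat_empty, plateau_thresh=0.0,
                               expo_thresh=0.0) == {}


def test_trace_individual_verdicts():
    market = make_dataset(
        [[(9, 9), (1, 1)], [(9, 9), (7, 7)], [(1, 1), (1, 1)]],
        populations=["M", "M", "M"], site_class=["market"] * 3,
        loci=["L1", "L2"],
    )
    selected = {"L1": {"p2": {9}}, "L2": {"p5": {7}}}
    report = trace_individuals(market, selected)
    assert report.records["S1"]["verdict"] == "traced"
    assert report.records["S1"]["source"] == "p2"
    assert report.records["S2"]["verdict"] == "ambiguous"
    assert report.records["S2"]["source"] == ["p2", "p5"]
    assert report.records["S3"]["verdict"] == "untraceable"
    with pytest.raises(DataError):
        trace_individuals(market, {})
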