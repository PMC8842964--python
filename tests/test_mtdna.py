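import math

import numpy as np
import pytest

from pangotrace.errors import DataError
from pangotrace.genodata import HaplotypeAlignment
from pangotrace.mtdna import (
    _tajimas_d_from,
    assign_lineage,
    coalescent_pvalues,
    collapse_haplotypes,
    fus_fs,
    k2p_distance,
    mismatch_distribution,
    neutrality_stats,
    nucleotide_diversity,
    r2_statistic,
    tajimas_d,
)


def aln(*seqs, ids=None):
    return HaplotypeAlignment(
        sequence_ids=ids or [f"s{i + 1}" for i in range(len(seqs))],
        sequences=list(seqs),
    )


# ---------------------------------------------------------------------------
# Haplotype collapse and diversity
# ---------------------------------------------------------------------------

def test_identical_sequences_single_haplotype():
    hs = collapse_haplotypes(aln("ACGT", "ACGT", "ACGT", "ACGT"))
    assert hs.h == 1 and hs.Hd == pytest.approx(0.0)


def test_all_distinct_hd_one():
    hs = collapse_haplotypes(aln("AAAA", "AAAT", "AATT", "ATTT"))
    assert hs.h == 4
    assert hs.Hd == pytest.approx(1.0)


def test_hd_hand_value_frequencies_2_1_1():
    hs = collapse_haplotypes(aln("AAAA", "AAAA", "AAAT", "AATT"))
    assert sorted(hs.frequencies, reverse=True) == [2, 1, 1]
    assert hs.Hd == pytest.approx((4 / 3) * (1 - 0.375))


def test_sequences_with_n_excluded_then_gap_columns_dropped():
    hs = collapse_haplotypes(aln("ACGT", "ACNT", "AC-T", "ACGT"))
    # the N sequence goes first; then the gap column is excluded for the rest
    assert hs.n_sequences == 3
    assert hs.n_sites == 3
    assert hs.h == 1


def test_complete_deletion_invariant_to_order():
    seqs = ["ACGTA", "AC-TA", "ACGTT", "ACGAA"]
    a = collapse_haplotypes(aln(*seqs))
    b = collapse_haplotypes(aln(*reversed(seqs)))
    assert a.n_sites == b.n_sites and a.h == b.h
    assert a.Hd == pytest.approx(b.Hd)
    assert a.pi == pytest.approx(b.pi)


def test_nucleotide_diversity_values():
    assert nucleotide_diversity(aln("ACGT", "ACGT")) == 0.0
    assert nucleotide_diversity(aln("A" * 100, "A" * 99 + "T")) == pytest.approx(0.01)
    # n=4, one singleton over 432 sites: (3/6)/432
    base = "A" * 432
    one = "T" + "A" * 431
    assert nucleotide_diversity(aln(base, base, base, one)) == pytest.approx(
        0.5 / 432)


# ---------------------------------------------------------------------------
# Mismatch distribution / raggedness
# ---------------------------------------------------------------------------

def test_raggedness_identical_pairs():
    _, r = mismatch_distribution(aln("AAAA", "AAAA", "AAAA"))
    assert r == pytest.approx(1.0)


def test_raggedness_hand_values():
    from pangotrace.mtdna import _mismatch_from_counts
    _, r = _mismatch_from_counts(np.array([0, 1, 1, 2]))
    assert r == pytest.approx(0.1875)  # freqs (0.25, 0.5, 0.25)
    _, r2 = _mismatch_from_counts(np.array([0, 1]))
    assert r2 == pytest.approx(0.25)   # freqs (0.5, 0.5)


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------

def test_tajimas_d_hand_oracle():
    base = "AAAA"
    d = tajimas_d(aln(base, base, base, "TAAA"))
    assert d == pytest.approx(-0.6123724, abs=1e-6)


def test_tajimas_d_zero_when_estimators_agree():
    n, S = 6, 4
    a1 = sum(1 / i for i in range(1, n))
    assert _tajimas_d_from(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)


def test_fus_fs_two_sequences_one_difference():
    assert fus_fs(aln("AC", "AT")) == pytest.approx(0.0, abs=1e-12)


def test_fus_fs_identical_sequences_flagged_infinite():
    assert fus_fs(aln("ACGT", "ACGT", "ACGT")) == math.inf


def test_r2_hand_oracle():
    base = "AAAA"
    r2 = r2_statistic(aln(base, base, base, "TAAA"))
    assert r2 == pytest.approx(math.sqrt(0.75 / 4), abs=1e-6)


def test_r2_star_genealogy_smaller_than_structured():
    # all-singleton (star-like) data vs deeply split data at equal S
    star = aln("TAAAA", "ATAAA", "AATAA", "AAATA", "AAAAT",
               *["AAAAA"] * 5)
    split = aln(*["TTTTT"] * 5, *["AAAAA"] * 5)
    assert r2_statistic(star) < r2_statistic(split)


def test_neutrality_stats_bundle():
    stats = neutrality_stats(aln("AAAA", "AATA", "ATAA", "TTAA"))
    assert stats.n == 4 and stats.S == 3
    assert np.isfinite(stats.D) and np.isfinite(stats.R2)


# ---------------------------------------------------------------------------
# Coalescent p-values
# ---------------------------------------------------------------------------

def test_neutral_data_gets_unremarkable_pvalues():
    from pangotrace.synth import simulate_coalescent_sample

    obs_aln = simulate_coalescent_sample(20, 12, seed=5)
    stats = coalescent_pvalues(obs_aln, reps=400, seed=9)
    for key in ("D", "Fs", "R2", "raggedness"):
        assert 1 / 401 <= stats.pvalues[key] <= 1.0
    # neutral data should rarely look extreme
    assert stats.pvalues["D"] > 0.01


def test_reps_floor_enforced():
    with pytest.raises(DataError):
        coalescent_pvalues(aln("AC", "AT"), reps=10)


# ---------------------------------------------------------------------------
# K2P and lineage assignment
# ---------------------------------------------------------------------------

def test_k2p_values_and_symmetry():
    assert k2p_distance("ACGT", "ACGT") == 0.0
    d = k2p_distance("AAAAAAAAGC", "AAAAAAAAAA")  # 1 transition + 1 transversion
    assert d == pytest.approx(0.5 * math.log(1 / 0.7) + 0.25 * math.log(1 / 0.8))
    assert k2p_distance("ACGTAC", "AGGTAC") == k2p_distance("AGGTAC", "ACGTAC")


def test_k2p_saturation_flagged_infinite():
    assert k2p_distance("ACAC", "CACA") == math.inf


def test_k2p_pairwise_deletion():
    # gap/N columns excluded from both P and Q
    assert k2p_distance("AC-T", "ACNT") == 0.0


def test_assign_lineage_nearest_and_ties():
    panel = aln("AAAAAAAAAA", "AAAAAAAATT", ids=["ref1", "ref2"])
    lineages = {"ref1": "DGL", "ref2": "WCA"}
    q = aln("AAAAAAAAAA", ids=["q1"])
    out = assign_lineage(q, panel, lineages)
    assert out.loc[0, "lineage"] == "DGL"
    # equidistant query -> unassigned
    q2 = aln("AAAAAAAAAT", ids=["q2"])
    out2 = assign_lineage(q2, panel, lineages)
    assert out2.loc[0, "lineage"] == "unassigned"


def test_assign_lineage_separates_diverged_clusters():
    rng = np.random.default_rng(0)
    L = 400
    base = rng.choice(list("ACGT"), size=L)
    other = base.copy()
    flip = rng.choice(L, size=20, replace=False)   # ~5% divergence
    subs = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i in flip:
        other[i] = subs[other[i]]

    def mutate(seq, k):
        s = seq.copy()
        for i in rng.choice(L, size=k, replace=False):
            s[i] = subs[s[i]]
        return "".join(s)

    panel = aln(mutate(base, 2), mutate(base, 2), mutate(other, 2), mutate(other, 2),
                ids=["a1", "a2", "b1", "b2"])
    lineages = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    queries, truth = [], []
    for i in range(50):
        src = base if i % 2 == 0 else other
        queries.append(mutate(src, 2))
        truth.append("A" if i % 2 == 0 else "B")
    out = assign_lineage(aln(*queries), panel, lineages)
    assert list(out["lineage"]) == truth
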