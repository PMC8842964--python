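import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pangotrace.errors import DataError
from pangotrace.genodata import (
    MISSING,
    HaplotypeAlignment,
    allele_frequencies,
    consensus_from_replicates,
    filter_by_completeness,
    read_alignment,
    read_genotype_table,
    write_genotype_table,
)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

NATIVE = """sample_id,population,site_class,lat,lon,L1,L2
S1,P1,forest,7.1,2.3,210/214,100/100
S2,P1,forest,7.2,2.4,214/210,./.
S3,M1,market,,,210/210,102/100
"""


def test_native_read_parses_calls_and_metadata(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text(NATIVE)
    ds = read_genotype_table(p)
    assert ds.sample_ids == ["S1", "S2", "S3"]
    assert ds.locus_names == ["L1", "L2"]
    assert tuple(ds.calls[0, 0]) == (210, 214)
    # "214/210" and "210/214" parse to the same canonical (sorted) call
    assert tuple(ds.calls[1, 0]) == (210, 214)
    assert tuple(ds.calls[1, 1]) == (MISSING, MISSING)
    assert tuple(ds.calls[2, 1]) == (100, 102)
    assert ds.site_class[2] == "market"
    assert ds.coords[0, 0] == pytest.approx(7.1)


@pytest.mark.parametrize("cell, message", [
    ("210/214/216", "malformed"),
    ("210/x", "non-integer"),
    ("210/.", "non-integer"),
])
def test_native_malformed_cell_names_row_and_locus(tmp_path, cell, message):
    p = tmp_path / "g.csv"
    p.write_text(
        "sample_id,population,site_class,lat,lon,L1\n"
        f"S1,P1,forest,,,{cell}\n"
    )
    with pytest.raises(DataError, match="L1"):
        read_genotype_table(p)


def test_duplicate_sample_id_rejected(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text(
        "sample_id,population,site_class,lat,lon,L1\n"
        "S1,P1,forest,,,1/1\nS1,P1,forest,,,1/1\n"
    )
    with pytest.raises(DataError, match="S1"):
        read_genotype_table(p)


def test_genalex_dialect_zero_pairs_and_half_missing(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text(
        "sample_id,population,site_class,lat,lon,L1,L1b,L2,L2b\n"
        "S1,P1,forest,,,210,214,0,0\n"
    )
    ds = read_genotype_table(p, dialect="genalex")
    assert ds.locus_names == ["L1", "L2"]
    assert tuple(ds.calls[0, 0]) == (210, 214)
    assert tuple(ds.calls[0, 1]) == (MISSING, MISSING)
    p.write_text(
        "sample_id,population,site_class,lat,lon,L1,L1b\n"
        "S1,P1,forest,,,210,0\n"
    )
    with pytest.raises(DataError, match="half-missing"):
        read_genotype_table(p, dialect="genalex")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_round_trip_preserves_calls_and_metadata(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    n, L = rng.integers(1, 8), rng.integers(1, 5)
    genos = []
    for _ in range(n):
        row = []
        for _ in range(L):
            if rng.random() < 0.2:
                row.append(None)
            else:
                row.append(tuple(rng.integers(100, 130, size=2)))
        genos.append(row)
    pops = [f"P{rng.integers(1, 3)}" for _ in range(n)]
    classes = [("forest", "market")[rng.integers(0, 2)] for _ in range(n)]
    coords = rng.uniform(-10, 10, size=(n, 2))
    ds = make_dataset(genos, populations=pops, site_class=classes, coords=coords)
    path = tmp_path_factory.mktemp("rt") / "ds.csv"
    write_genotype_table(ds, path)
    back = read_genotype_table(path)
    assert back.sample_ids == ds.sample_ids
    assert back.locus_names == ds.locus_names
    assert np.array_equal(back.calls, ds.calls)
    assert back.population == ds.population
    assert back.site_class == ds.site_class
    np.testing.assert_allclose(back.coords, ds.coords)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def test_read_alignment_validates(tmp_path):
    ok = tmp_path / "ok.fa"
    ok.write_text(">a\n" + "ACGT" * 108 + "\n>b\n" + "ACGA" * 108 + "\n")
    aln = read_alignment(ok)
    assert aln.n_sequences == 2 and aln.length == 432

    ragged = tmp_path / "ragged.fa"
    ragged.write_text(">a\nACGT\n>b\nACG\n")
    with pytest.raises(DataError, match="b"):
        read_alignment(ragged)

    bad = tmp_path / "bad.fa"
    bad.write_text(">a\nACGU\n")
    with pytest.raises(DataError, match="disallowed"):
        read_alignment(bad)

    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(DataError):
        read_alignment(empty)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _reps(triples):
    """Three replicate datasets from a list of per-sample lists of calls."""
    out = []
    for r in range(3):
        out.append(make_dataset([[row[r]] for row in triples]))
    return out


@pytest.mark.parametrize("triple, expected", [
    # A appears 3x, B 2x -> both qualify
    ([(1, 2), (1, 2), (1, 1)], (1, 2)),
    # no allele reaches 2 replicates
    ([(1, 1), (2, 2), None], (MISSING, MISSING)),
    # only A qualifies -> homozygous call
    ([(1, 1), (1, 1), (1, 2)], (1, 1)),
])
def test_consensus_two_of_three_rule(triple, expected):
    ds = consensus_from_replicates(_reps([triple]))
    assert tuple(ds.calls[0, 0]) == expected


def test_consensus_tie_flagged_missing(caplog):
    # three alleles each in >= 2 replicates -> ambiguous, set missing
    ds = consensus_from_replicates(_reps([[(1, 2), (2, 3), (1, 3)]]))
    assert tuple(ds.calls[0, 0]) == (MISSING, MISSING)


# ---------------------------------------------------------------------------
# Completeness filter
# ---------------------------------------------------------------------------

def test_completeness_boundary_15_of_20():
    genos = []
    for typed in (15, 14, 20):
        row = [(1, 1)] * typed + [None] * (20 - typed)
        genos.append(row)
    ds = make_dataset(genos)
    kept = filter_by_completeness(ds, 0.75)
    assert kept.sample_ids == ["S1", "S3"]
    again = filter_by_completeness(kept, 0.75)
    assert again.sample_ids == kept.sample_ids  # idempotent


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def test_allele_frequency_counting():
    ds = make_dataset([[(1, 1)], [(1, 2)]])
    ft = allele_frequencies(ds)
    assert ft.freqs("P1", "L1") == {1: 0.75, 2: 0.25}
    assert ft.n_genes["P1"]["L1"] == 4


def test_all_missing_locus_flagged():
    ds = make_dataset([[None], [None]])
    ft = allele_frequencies(ds)
    assert ("P1", "L1") in ft.undefined
    assert ft.freqs("P1", "L1") == {}


def test_partition_additivity_and_frequency_sums():
    rng = np.random.default_rng(5)
    genos = [[tuple(rng.integers(1, 5, 2)) for _ in range(3)] for _ in range(10)]
    pops = ["A"] * 4 + ["B"] * 6
    ds = make_dataset(genos, populations=pops)
    ft = allele_frequencies(ds)
    pooled = ft.pooled()
    for locus in ds.locus_names:
        merged = {}
        for g in ft.groups:
            for a, c in ft.counts[g][locus].items():
                merged[a] = merged.get(a, 0) + c
        assert merged == pooled.counts["all"][locus]
        for g in ft.groups:
            freqs = ft.freqs(g, locus)
            if freqs:
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


def test_half_missing_construction_rejected():
    with pytest.raises(DataError, match="half-missing"):
        make_dataset([[(MISSING, 5)]])
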