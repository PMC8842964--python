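"""Forensic identity: genotype matching, genotype probability, PI statistics.

The probability-of-identity machinery quantifies whether the marker panel can
distinguish individuals: uPI is the sample-size-corrected probability that two
random individuals share a multilocus genotype, PIsibs the same probability
for full siblings (the conservative forensic bound).  Multi-locus values are
products over loci, so both are non-increasing as loci are added.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genodata import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "MatchReport",
    "PiCurve",
    "match_genotypes",
    "pgen",
    "psex",
    "unbiased_pi",
    "pi_sibs",
    "min_loci_curve",
]

log = logging.getLogger(__name__)


@dataclass
class MatchReport:
    """Groups of samples with identical multilocus genotypes.

    ``groups`` are transitive closures of pairwise matches (singletons not
    listed); ``psex`` holds, per group, the probability that >= 1 other sample
    shares the representative genotype by chance; ``n_distinct`` counts
    distinct genotypes (singletons + groups).
    """

    groups: list[list[str]]
    psex: list[float]
    n_samples: int

    @property
    def n_distinct(self) -> int:
        in_groups = sum(len(g) for g in self.groups)
        return self.n_samples - in_groups + len(self.groups)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": [";".join(g) for g in self.groups],
            "size": [len(g) for g in self.groups],
            "psex": self.psex,
        })


def match_genotypes(ds: GenotypeDataset, min_shared_loci: int = 15) -> MatchReport:
    """Find samples with identical genotypes.

    Two samples match iff their calls agree at every locus typed in both and
    at least ``min_shared_loci`` loci are mutually typed (so missing data
    cannot fabricate matches).  Match groups are transitive closures.
    """
    n = ds.n_samples
    typed = ds.typed
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            shared = typed[i] & typed[j]
            if shared.sum() < min_shared_loci:
                continue
            if np.array_equal(ds.calls[i][shared], ds.calls[j][shared]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    groups = [sorted(m) for m in clusters.values() if len(m) > 1]
    groups.sort()
    pooled = allele_frequencies(ds, {"all": list(ds.sample_ids)})
    psex_vals = []
    for members in groups:
        pg = pgen(ds, ds.sample_ids[members[0]], pooled)
        psex_vals.append(psex(pg, n))
    return MatchReport(
        groups=[[ds.sample_ids[i] for i in g] for g in groups],
        psex=psex_vals, n_samples=n,
    )


def pgen(ds: GenotypeDataset, sample_id: str,
         freq_table: AlleleFrequencyTable | None = None) -> float:
    """HWE probability of a sample's multilocus genotype from pooled frequencies.

    Product over typed loci of 2*p_a*p_b (heterozygote) or p_a^2 (homozygote).
    No inbreeding correction is applied (the simplest published definition).
    """
    if freq_table is None:
        freq_table = allele_frequencies(ds, {"all": list(ds.sample_ids)})
    if len(freq_table.groups) != 1:
        freq_table = freq_table.pooled()
    grp = freq_table.groups[0]
    i = ds.sample_index(sample_id)
    prob = 1.0
    typed_any = False
    for j, locus in enumerate(ds.locus_names):
        a, b = ds.calls[i, j]
        if a == MISSING:
            continue
        typed_any = True
        freqs = freq_table.freqs(grp, locus)
        if a not in freqs or b not in freqs:
            raise DataError(
                f"allele absent from frequency table at locus {locus} "
                f"for sample {sample_id}"
            )
        prob *= freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    if not typed_any:
        raise DataError(f"sample {sample_id} typed at no locus")
    return prob


def psex(pgen_value: float, n_samples: int) -> float:
    """P(>= 1 of the other n-1 samples shares the genotype by chance)."""
    if not 0 <= pgen_value <= 1:
        raise DataError("pgen must be in [0, 1]")
    if n_samples < 2:
        raise DataError("n_samples must be >= 2")
    return 1.0 - (1.0 - pgen_value) ** (n_samples - 1)


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------

def _moments(freqs: dict[int, float]) -> tuple[float, float, float]:
    p = np.array(list(freqs.values()))
    return float(np.sum(p ** 2)), float(np.sum(p ** 3)), float(np.sum(p ** 4))


def _upi_locus(freqs: dict[int, float], n: int) -> float:
    """Sample-size-corrected (unbiased) single-locus PI.

    The small-sample estimator reduces to 1 at a monomorphic locus and to the
    naive 2*(sum p^2)^2 - sum p^4 as n grows.  Requires n >= 4 individuals.
    """
    a2, a3, a4 = _moments(freqs)
    num = (n ** 3 * (2 * a2 ** 2 - a4) - 2 * n ** 2 * (a3 + 2 * a2)
           + n * (9 * a2 + 2) - 6)
    return num / ((n - 1) * (n - 2) * (n - 3))


def _pisibs_locus(freqs: dict[int, float]) -> float:
    a2, _, a4 = _moments(freqs)
    return 0.25 + 0.5 * a2 + 0.5 * a2 ** 2 - 0.25 * a4


def _single_partition(ft: AlleleFrequencyTable) -> tuple[str, AlleleFrequencyTable]:
    if len(ft.groups) != 1:
        ft = ft.pooled()
    return ft.groups[0], ft


def unbiased_pi(freq_table: AlleleFrequencyTable) -> tuple[pd.Series, float]:
    """Per-locus unbiased PI and the multi-locus product.

    Loci with fewer than 4 typed individuals are flagged and excluded from
    the product.
    """
    grp, ft = _single_partition(freq_table)
    vals = {}
    for locus in ft.locus_names:
        n = ft.n_genes[grp][locus] // 2
        if n < 4:
            log.warning("locus %s has n=%d < 4; excluded from uPI product", locus, n)
            vals[locus] = float("nan")
            continue
        vals[locus] = _upi_locus(ft.freqs(grp, locus), n)
    series = pd.Series(vals, name="uPI")
    return series, float(np.nanprod(series.values))


def pi_sibs(freq_table: AlleleFrequencyTable) -> tuple[pd.Series, float]:
    """Per-locus PI among full siblings and the multi-locus product."""
    grp, ft = _single_partition(freq_table)
    vals = {locus: _pisibs_locus(ft.freqs(grp, locus)) for locus in ft.locus_names}
    series = pd.Series(vals, name="PIsibs")
    return series, float(np.prod(series.values))


@dataclass
class PiCurve:
    """Cumulative uPI / PIsibs over an informativeness-ordered locus list."""

    loci: list[str]
    cum_upi: np.ndarray
    cum_pisibs: np.ndarray
    min_loci: int | None    # smallest k with cumulative PIsibs < threshold
    threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.loci,
            "k": np.arange(1, len(self.loci) + 1),
            "cum_uPI": self.cum_upi,
            "cum_PIsibs": self.cum_pisibs,
        })


def min_loci_curve(freq_table: AlleleFrequencyTable, threshold: float = 0.01) -> PiCurve:
    """Cumulative PI over loci ordered most-informative first.

    Loci are sorted by ascending single-locus PIsibs ("optimized"
    combinations); returns the smallest locus count whose cumulative PIsibs
    falls below ``threshold`` (None if never reached).
    """
    upi_locus, _ = unbiased_pi(freq_table)
    pis_locus, _ = pi_sibs(freq_table)
    order = pis_locus.sort_values(kind="stable").index.tolist()
    cum_upi = np.nancumprod(upi_locus[order].values)
    cum_pis = np.cumprod(pis_locus[order].values)
    below = np.nonzero(cum_pis < threshold)[0]
    k = int(below[0]) + 1 if len(below) else None
    return PiCurve(loci=order, cum_upi=cum_upi, cum_pisibs=cum_pis,
                   min_loci=k, threshold=threshold)
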