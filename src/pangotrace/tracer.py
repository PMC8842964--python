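"""Trade tracing via private alleles and generalized rarefaction.

The procedure: (1) compute, by generalized rarefaction, the expected
private-allele measure of each locus x population over all K-subsets of the
reference populations at standardized subsample size g; (2) classify the
shape of each curve (plateau / exponential / decreasing) against frequency
thresholds; (3) cross-validate candidate loci against the private alleles
actually observed in the reference populations; (4) screen market genotypes
for the retained private alleles and attribute carriers to source
populations.  Ambiguous multi-population hits are reported, never resolved
silently.

All rarefaction expectations are exact hypergeometric combinatorics — for an
allele with c of the N gene copies of a population, the probability it shows
up in a uniform subsample of g copies is Q = 1 - C(N-c, g)/C(N, g); a
population's expected private-allele richness in a K-subset sums, over its
alleles, Q there times the probability of absence from every other member.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError
from .genodata import MISSING, AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "PrivateAlleleCatalog",
    "RarefactionResult",
    "TraceReport",
    "observed_private_alleles",
    "presence_probability",
    "private_richness_curves",
    "classify_trend",
    "select_tracing_loci",
    "trace_individuals",
]

log = logging.getLogger(__name__)


@dataclass
class PrivateAlleleCatalog:
    """(locus, allele) pairs observed in exactly one reference population."""

    by_population: dict  # pop -> set[(locus, allele)]

    def alleles(self, pop: str, locus: str) -> set:
        return {a for (l, a) in self.by_population.get(pop, set()) if l == locus}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"population": p, "locus": l, "allele": a}
            for p, pairs in self.by_population.items()
            for (l, a) in sorted(pairs)
        ]
        return pd.DataFrame(rows, columns=["population", "locus", "allele"])


def observed_private_alleles(freq_table: AlleleFrequencyTable) -> PrivateAlleleCatalog:
    """Alleles present in one reference population and absent from all others."""
    pops = freq_table.groups
    if len(pops) < 2:
        raise DataError("need >= 2 populations to define private alleles")
    catalog: dict[str, set] = {p: set() for p in pops}
    for locus in freq_table.locus_names:
        presence: dict[int, list[str]] = {}
        for p in pops:
            for a, c in freq_table.counts[p][locus].items():
                if c > 0:
                    presence.setdefault(a, []).append(p)
        for a, carriers in presence.items():
            if len(carriers) == 1:
                catalog[carriers[0]].add((locus, a))
    return PrivateAlleleCatalog(by_population=catalog)


def presence_probability(n_total_genes: int, n_allele_copies: int, g: int) -> float:
    """P(allele appears in a uniform subsample of g gene copies).

    Q = 1 - C(N - c, g) / C(N, g) with N total and c allele copies.
    """
    if not 0 <= n_allele_copies <= n_total_genes:
        raise DataError("allele copies must be within [0, total]")
    if not 1 <= g <= n_total_genes:
        raise DataError("subsample size g must be within [1, total]")
    if n_allele_copies == 0:
        return 0.0
    if g > n_total_genes - n_allele_copies:
        return 1.0
    return 1.0 - math.comb(n_total_genes - n_allele_copies, g) / math.comb(n_total_genes, g)


@dataclass
class RarefactionResult:
    """Expected private-allele curves per (locus, population, combination level K).

    ``g_values`` are subsample sizes (individuals by default; each counts two
    gene copies).  ``richness[(locus, pop, K)]`` is the expected number of
    alleles private to ``pop`` within a K-subset of populations, averaged
    over all subsets containing ``pop``; ``mean_freq`` is the analogous
    allele-frequency-weighted measure (scale 0..1).
    """

    g_values: list[int]
    g_unit: str
    levels: list[int]
    richness: dict
    mean_freq: dict
    skipped: list = field(default_factory=list)  # (locus, combination) with too few copies

    def curve(self, locus: str, pop: str, K: int, measure: str = "frequency") -> np.ndarray:
        table = self.mean_freq if measure == "frequency" else self.richness
        return table[(locus, pop, K)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (locus, pop, K), rich in self.richness.items():
            freq = self.mean_freq[(locus, pop, K)]
            for g, r, f in zip(self.g_values, rich, freq):
                rows.append({"locus": locus, "population": pop, "K": K,
                             "g": g, "private_richness": r, "private_freq": f})
        return pd.DataFrame(rows)


def private_richness_curves(freq_table: AlleleFrequencyTable,
                            g_max: int = 7,
                            K_range: list[int] | None = None,
                            g_unit: str = "individuals") -> RarefactionResult:
    """Generalized rarefaction of private alleles over population combinations.

    For every K in ``K_range`` (default 2..J), every K-subset S of reference
    populations and every population j in S, the expected private-allele
    measures at subsample size g are computed exactly and averaged over the
    C(J-1, K-1) subsets containing j.  ``g`` runs from 2 to ``g_max`` in
    individuals (2g gene copies) unless ``g_unit="genes"``.  Combinations in
    which some population lacks enough gene copies at a locus are skipped for
    that locus (and logged).
    """
    pops = freq_table.groups
    J = len(pops)
    if K_range is None:
        K_range = list(range(2, J + 1))
    if any(K > J for K in K_range):
        raise DataError(f"combination level K exceeds number of populations J={J}")
    if g_unit not in ("individuals", "genes"):
        raise DataError("g_unit must be 'individuals' or 'genes'")
    g_values = list(range(2, g_max + 1))
    gene_sizes = [2 * g if g_unit == "individuals" else g for g in g_values]

    result = RarefactionResult(g_values=g_values, g_unit=g_unit,
                               levels=list(K_range), richness={}, mean_freq={})
    acc_rich: dict = {}
    acc_freq: dict = {}
    n_combos: dict = {}
    for locus in freq_table.locus_names:
        counts = {p: freq_table.counts[p][locus] for p in pops}
        n_genes = {p: freq_table.n_genes[p][locus] for p in pops}
        alleles = sorted({a for p in pops for a in counts[p]})
        for K in K_range:
            for S in combinations(pops, K):
                if any(n_genes[p] < max(gene_sizes) for p in S):
                    result.skipped.append((locus, S))
                    log.debug("locus %s skipped for combination %s (too few copies)",
                              locus, S)
                    continue
                # Q[p][allele] per g
                for j in S:
                    rich = np.zeros(len(g_values))
                    freq = np.zeros(len(g_values))
                    for a in alleles:
                        cj = counts[j].get(a, 0)
                        if cj == 0:
                            continue
                        pj = cj / n_genes[j]
                        for gi, gg in enumerate(gene_sizes):
                            q = presence_probability(n_genes[j], cj, gg)
                            for other in S:
                                if other == j:
                                    continue
                                q *= 1.0 - presence_probability(
                                    n_genes[other], counts[other].get(a, 0), gg)
                            rich[gi] += q
                            freq[gi] += pj * q
                    key = (locus, j, K)
                    acc_rich[key] = acc_rich.get(key, 0) + rich
                    acc_freq[key] = acc_freq.get(key, 0) + freq
                    n_combos[key] = n_combos.get(key, 0) + 1
    for key, total in acc_rich.items():
        result.richness[key] = total / n_combos[key]
        result.mean_freq[key] = acc_freq[key] / n_combos[key]
    return result


def classify_trend(curve: np.ndarray, plateau_thresh: float = 0.50,
                   expo_thresh: float = 0.45, flat_eps: float = 0.05) -> str:
    """Classify a rarefaction curve as plateau / exponential / decreasing / rejected.

    Formalizes visual curve reading: with v the final value and D_last,
    D_prev the last two increments — decreasing if D_last < 0; plateau if the
    curve has flattened (|D_last| <= flat_eps * v) at v >= plateau_thresh;
    exponential if still accelerating (D_last >= D_prev > is positive) with
    v >= expo_thresh; otherwise rejected.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 3:
        raise DataError("trend classification needs >= 3 curve points")
    v = curve[-1]
    d_last = curve[-1] - curve[-2]
    d_prev = curve[-2] - curve[-3]
    if d_last < 0:
        return "decreasing"
    if abs(d_last) <= flat_eps * max(v, 1e-12) and v >= plateau_thresh:
        return "plateau"
    if d_last > 0 and d_last >= d_prev and v >= expo_thresh:
        return "exponential"
    return "rejected"


def select_tracing_loci(rarefaction: RarefactionResult,
                        catalog: PrivateAlleleCatalog,
                        measure: str = "richness",
                        K: int | None = None,
                        plateau_thresh: float = 0.50,
                        expo_thresh: float = 0.45,
                        flat_eps: float = 0.05) -> dict:
    """Cross-validate rarefaction candidates against observed private alleles.

    A (locus, population) is retained iff its curve at combination level K
    (default: the highest level computed, i.e. all reference populations)
    classifies as plateau or exponential AND the catalog holds >= 1 observed
    private allele for that population at that locus.  Returns
    ``{locus: {population: set(alleles)}}``.
    """
    if K is None:
        K = max(rarefaction.levels)
    selected: dict[str, dict[str, set]] = {}
    for (locus, pop, level), _ in rarefaction.richness.items():
        if level != K:
            continue
        curve = rarefaction.curve(locus, pop, level, measure=measure)
        trend = classify_trend(curve, plateau_thresh, expo_thresh, flat_eps)
        if trend not in ("plateau", "exponential"):
            continue
        observed = catalog.alleles(pop, locus)
        if not observed:
            continue
        selected.setdefault(locus, {}).setdefault(pop, set()).update(observed)
    return selected


@dataclass
class TraceReport:
    """Per-market-individual assignment outcome.

    ``records`` maps sample id to a dict with keys ``hits`` (list of
    (locus, allele, population)), ``verdict`` in {"traced", "ambiguous",
    "untraceable"} and ``source`` (population for traced, sorted candidate
    list for ambiguous, None otherwise).
    """

    records: dict

    @property
    def traced(self) -> dict:
        return {s: r["source"] for s, r in self.records.items()
                if r["verdict"] == "traced"}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sid, r in self.records.items():
            rows.append({
                "sample_id": sid,
                "verdict": r["verdict"],
                "source": (r["source"] if r["verdict"] == "traced"
                           else ";".join(r["source"]) if r["verdict"] == "ambiguous"
                           else ""),
                "hits": ";".join(f"{l}:{a}->{p}" for l, a, p in r["hits"]),
            })
        return pd.DataFrame(rows, columns=["sample_id", "verdict", "source", "hits"])


def trace_individuals(market_ds: GenotypeDataset, selected: dict) -> TraceReport:
    """Screen market genotypes for selected private alleles.

    A market individual is traced to a population iff it carries >= 1 selected
    private allele and all its hits point to the same population; hits to
    several populations yield an ambiguous verdict.
    """
    if not selected:
        raise DataError("no selected tracing alleles")
    records = {}
    for i, sid in enumerate(market_ds.sample_ids):
        if market_ds.site_class[i] != "market":
            continue
        hits = []
        for j, locus in enumerate(market_ds.locus_names):
            if locus not in selected:
                continue
            a, b = market_ds.calls[i, j]
            if a == MISSING:
                continue
            for pop, alleles in selected[locus].items():
                for allele in sorted(alleles):
                    if allele in (a, b):
                        hits.append((locus, allele, pop))
        pops = sorted({p for _, _, p in hits})
        if not hits:
            verdict, source = "untraceable", None
        elif len(pops) == 1:
            verdict, source = "traced", pops[0]
        else:
            verdict, source = "ambiguous", pops
        records[sid] = {"hits": hits, "verdict": verdict, "source": source}
    return TraceReport(records=records)
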