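"""Per-locus diversity statistics, HWE tests, and Weir-Cockerham F-statistics.

Multi-locus F-statistics combine the Weir-Cockerham variance components
(a, b, c) by summation across loci and alleles — ratios of sums, never means
of per-locus ratios.  Allelic richness is the rarefaction expectation of the
number of distinct alleles in a gene-copy subsample of standardized size g.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .genodata import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "allelic_richness",
    "locus_summary",
    "hwe_test",
    "wc_f_statistics",
    "fst_permutation_test",
    "default_partitions",
    "FStatistics",
    "FstMatrix",
]

log = logging.getLogger(__name__)


def allelic_richness(counts: dict[int, int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    ``counts`` maps allele -> gene-copy count; N = total copies.  The
    rarefaction expectation is sum_i [1 - C(N - N_i, g) / C(N, g)].
    """
    N = sum(counts.values())
    if g < 1 or g > N:
        raise DataError(f"rarefaction size g={g} outside [1, N={N}]")
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - c, g) / denom for c in counts.values()))


# ---------------------------------------------------------------------------
# Encodings shared by the estimators
# ---------------------------------------------------------------------------

def _encode_loci(ds: GenotypeDataset, idx: list[int]):
    """Per locus: (allele labels, dosage D (n x A), het-carrier H (n x A), typed (n,))."""
    out = []
    for j in range(ds.n_loci):
        calls = ds.calls[idx, j, :]
        typed = calls[:, 0] != MISSING
        labels = np.unique(calls[typed])
        A = len(labels)
        D = np.zeros((len(idx), A))
        H = np.zeros((len(idx), A))
        if A:
            pos = {a: k for k, a in enumerate(labels)}
            for r, (a, b) in enumerate(calls):
                if a == MISSING:
                    continue
                D[r, pos[a]] += 1
                D[r, pos[b]] += 1
                if a != b:
                    H[r, pos[a]] = 1
                    H[r, pos[b]] = 1
        out.append((labels, D, H, typed.astype(float)))
    return out


# ---------------------------------------------------------------------------
# Locus summaries
# ---------------------------------------------------------------------------

def locus_summary(ds: GenotypeDataset, g: int | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Table-1-style per-locus summary over the whole dataset, plus column means.

    Columns: ``n`` typed individuals, ``Na`` distinct alleles, ``Ho`` observed
    heterozygosity, ``He`` unbiased expected heterozygosity
    (2n/(2n-1))(1 - sum p^2), ``Ar`` allelic richness at gene-sample size g
    (default: the smallest per-locus gene count in the dataset), ``Fis`` the
    Weir-Cockerham within-population f treating the dataset as one unit, and
    ``p_hwe`` the chi-square HWE p-value (NaN and flagged for monomorphic loci).
    """
    if ds.n_samples == 0:
        raise DataError("empty dataset")
    ft = allele_frequencies(ds, {"all": list(ds.sample_ids)})
    n_genes = [ft.n_genes["all"][l] for l in ds.locus_names]
    if min(n_genes) == 0:
        bad = ds.locus_names[int(np.argmin(n_genes))]
        raise DataError(f"locus {bad} has no typed individuals")
    if g is None:
        g = min(n_genes)
    rows = []
    enc = _encode_loci(ds, list(range(ds.n_samples)))
    for j, locus in enumerate(ds.locus_names):
        counts = ft.counts["all"][locus]
        N = ft.n_genes["all"][locus]
        if g > N:
            raise DataError(f"g={g} exceeds gene copies N={N} at locus {locus}")
        n = N // 2
        p = np.array([c / N for c in counts.values()])
        labels, D, H, typed = enc[j]
        ho = float(H.max(axis=1).sum() / typed.sum())
        he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p ** 2))) if n > 1 else float("nan")
        fis = _fis_single_unit(D, H, typed) if n > 1 else float("nan")
        stat, df, p_hwe = hwe_test(ds, locus)
        rows.append({
            "locus": locus, "n": n, "Na": len(counts), "Ho": ho, "He": he,
            "Ar": allelic_richness(counts, g), "Fis": fis, "p_hwe": p_hwe,
        })
    table = pd.DataFrame(rows).set_index("locus")
    table.attrs["g"] = g
    means = table[["n", "Na", "Ho", "He", "Ar", "Fis"]].mean()
    return table, means


def _fis_single_unit(D, H, typed) -> float:
    """Weir-Cockerham f for one population at one locus (r = 1 components)."""
    n = typed.sum()
    if n < 2:
        return float("nan")
    p = D.sum(axis=0) / (2 * n)
    h = H.sum(axis=0) / n
    b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2
    denom = float(np.sum(b + c))
    if denom == 0:
        return float("nan")
    return 1.0 - float(np.sum(c)) / denom


def hwe_test(ds: GenotypeDataset, locus: str,
             partition_samples: list[str] | None = None) -> tuple[float, int, float]:
    """Chi-square goodness of fit of genotype counts against HWE expectations.

    Returns ``(statistic, df, p)`` with df = k(k-1)/2 for k observed alleles.
    Monomorphic loci are flagged and return ``(nan, 0, nan)``.
    """
    j = ds.locus_index(locus)
    idx = (list(range(ds.n_samples)) if partition_samples is None
           else [ds.sample_index(s) for s in partition_samples])
    calls = ds.calls[idx, j, :]
    calls = calls[calls[:, 0] != MISSING]
    if len(calls) == 0:
        raise DataError(f"no typed individuals at locus {locus}")
    labels = np.unique(calls)
    k = len(labels)
    if k < 2:
        log.warning("locus %s is monomorphic; HWE undefined", locus)
        return float("nan"), 0, float("nan")
    n = len(calls)
    pos = {a: m for m, a in enumerate(labels)}
    geno_counts = np.zeros((k, k))
    for a, b in calls:
        geno_counts[pos[a], pos[b]] += 1  # a <= b by canonical order
    p = np.zeros(k)
    for a, b in calls:
        p[pos[a]] += 1
        p[pos[b]] += 1
    p /= 2 * n
    chi2 = 0.0
    for u in range(k):
        for v in range(u, k):
            exp = n * (p[u] ** 2 if u == v else 2 * p[u] * p[v])
            obs = geno_counts[u, v]
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    df = k * (k - 1) // 2
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

@dataclass
class FStatistics:
    """Multi-locus Weir-Cockerham estimates and their per-locus components."""

    theta: float                 # FST
    f: float                     # FIS over populations
    F: float                     # FIT
    fis_per_group: dict
    per_locus: pd.DataFrame      # columns a, b, c, theta, f


def _wc_components_locus(D, H, typed, group_idx: list[np.ndarray]):
    """Summed (a, b, c) over alleles for one locus and r >= 2 groups.

    Groups with no typed individual at the locus are dropped; returns zeros
    (no contribution) if fewer than two informative groups remain or the mean
    sample size is <= 1.
    """
    ns, ps, hs = [], [], []
    for gi in group_idx:
        t = typed[gi].sum()
        if t < 1:
            continue
        ns.append(t)
        ps.append(D[gi].sum(axis=0) / (2 * t))
        hs.append(H[gi].sum(axis=0) / t)
    r = len(ns)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array(ns)
    P = np.stack(ps)      # r x A
    Hh = np.stack(hs)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
    s2 = (ns[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ns[:, None] * Hh).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_f_statistics(ds: GenotypeDataset, partition: dict[str, list[str]]) -> FStatistics:
    """Weir-Cockerham F-statistics over the groups of ``partition``.

    FIS per group uses the single-population (b, c) components; overall
    theta/f/F are ratios of components summed over loci and alleles.
    """
    groups = list(partition)
    all_idx = [ds.sample_index(s) for grp in groups for s in partition[grp]]
    # map group members to positions within the encoded subset
    offset = 0
    group_idx = []
    for grp in groups:
        k = len(partition[grp])
        group_idx.append(np.arange(offset, offset + k))
        offset += k
    enc = _encode_loci(ds.subset(all_idx), list(range(len(all_idx))))
    rows = []
    for j, locus in enumerate(ds.locus_names):
        labels, D, H, typed = enc[j]
        a, b, c = _wc_components_locus(D, H, typed, group_idx)
        tot = a + b + c
        rows.append({
            "locus": locus, "a": a, "b": b, "c": c,
            "theta": a / tot if tot else float("nan"),
            "f": 1 - c / (b + c) if (b + c) else float("nan"),
        })
    per_locus = pd.DataFrame(rows).set_index("locus")
    A, B, C = per_locus["a"].sum(), per_locus["b"].sum(), per_locus["c"].sum()
    theta = A / (A + B + C) if (A + B + C) else float("nan")
    f = 1 - C / (B + C) if (B + C) else float("nan")
    F = 1 - C / (A + B + C) if (A + B + C) else float("nan")

    fis_per_group = {}
    for grp in groups:
        idx = [ds.sample_index(s) for s in partition[grp]]
        if sum(1 for i in idx) < 2:
            log.warning("group %s has < 2 individuals; FIS skipped", grp)
            fis_per_group[grp] = float("nan")
            continue
        enc_g = _encode_loci(ds.subset(idx), list(range(len(idx))))
        B_g = C_g = 0.0
        informative = False
        for labels, D, H, typed in enc_g:
            n = typed.sum()
            if n < 2:
                continue
            informative = True
            p = D.sum(axis=0) / (2 * n)
            h = H.sum(axis=0) / n
            B_g += float(np.sum((n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)))
            C_g += float(np.sum(h / 2))
        if not informative or (B_g + C_g) == 0:
            log.warning("group %s carries no within-population FIS information "
                        "(too few typed individuals or monomorphic); excluded", grp)
            fis_per_group[grp] = float("nan")
        else:
            fis_per_group[grp] = 1 - C_g / (B_g + C_g)
    return FStatistics(theta=float(theta), f=float(f), F=float(F),
                       fis_per_group=fis_per_group, per_locus=per_locus)


# ---------------------------------------------------------------------------
# Pairwise theta with permutation significance
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    labels: list[str]
    theta: pd.DataFrame
    pvalues: pd.DataFrame | None
    n_permutations: int


def _theta_batch(enc, G: np.ndarray) -> np.ndarray:
    """Multi-locus theta for B two-group label assignments at once.

    ``G`` is (B, n) boolean membership of group 1; group sizes may vary by
    row.  Loci/rows where either group has no typed individual, or the mean
    sample size is <= 1, contribute nothing.
    """
    B = G.shape[0]
    num = np.zeros(B)
    den = np.zeros(B)
    Gf = G.astype(float)
    for labels, D, H, typed in enc:
        if len(labels) < 2:
            continue
        t1 = Gf @ typed
        t2 = typed.sum() - t1
        ok = (t1 >= 1) & (t2 >= 1) & ((t1 + t2) > 2)
        if not ok.any():
            continue
        c1 = Gf @ D                       # B x A allele copy counts
        c2 = D.sum(axis=0) - c1
        hh1 = Gf @ H
        hh2 = H.sum(axis=0) - hh1
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = c1 / (2 * t1[:, None])
            p2 = c2 / (2 * t2[:, None])
            h1 = hh1 / t1[:, None]
            h2 = hh2 / t2[:, None]
            nbar = (t1 + t2) / 2
            nc = 2 * nbar - (t1 ** 2 + t2 ** 2) / (2 * nbar)
            pbar = (t1[:, None] * p1 + t2[:, None] * p2) / (t1 + t2)[:, None]
            s2 = (t1[:, None] * (p1 - pbar) ** 2
                  + t2[:, None] * (p2 - pbar) ** 2) / nbar[:, None]
            hbar = (t1[:, None] * h1 + t2[:, None] * h2) / (t1 + t2)[:, None]
            a = (nbar / nc)[:, None] * (
                s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)[:, None]
            )
            bb = (nbar / (nbar - 1))[:, None] * (
                pbar * (1 - pbar) - s2 / 2
                - ((2 * nbar - 1) / (4 * nbar))[:, None] * hbar
            )
            cc = hbar / 2
        a = np.where(ok[:, None], np.nan_to_num(a), 0.0)
        bb = np.where(ok[:, None], np.nan_to_num(bb), 0.0)
        cc = np.where(ok[:, None], np.nan_to_num(cc), 0.0)
        num += a.sum(axis=1)
        den += (a + bb + cc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def pairwise_theta(ds: GenotypeDataset, partition: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta matrix (no permutations)."""
    return fst_permutation_test(ds, partition, n_perm=0).theta


def fst_permutation_test(ds: GenotypeDataset, partition: dict[str, list[str]],
                         n_perm: int = 10000, seed: int | None = None) -> FstMatrix:
    """Pairwise theta with permutation p-values.

    For each pair, individuals are permuted among the two groups (sizes
    preserved) and theta recomputed; p = (#{perm theta >= observed} + 1)
    / (n_perm + 1).  ``n_perm=0`` skips the test.
    """
    groups = [g for g in partition if len(partition[g]) >= 2]
    if len(groups) < 2:
        raise DataError("need >= 2 groups with >= 2 members for pairwise FST")
    rng = np.random.default_rng(seed)
    theta = pd.DataFrame(0.0, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups) if n_perm else None
    for x in range(len(groups)):
        for y in range(x + 1, len(groups)):
            g1, g2 = groups[x], groups[y]
            idx = [ds.sample_index(s) for s in partition[g1] + partition[g2]]
            sub = ds.subset(idx)
            enc = _encode_loci(sub, list(range(len(idx))))
            n1 = len(partition[g1])
            n = len(idx)
            obs = _theta_batch(enc, np.arange(n)[None, :] < n1)[0]
            theta.loc[g1, g2] = theta.loc[g2, g1] = obs
            if n_perm:
                G = np.zeros((n_perm, n), dtype=bool)
                for b in range(n_perm):
                    G[b, rng.permutation(n)[:n1]] = True
                perm = _theta_batch(enc, G)
                p = (np.sum(perm >= obs) + 1) / (n_perm + 1)
                pvals.loc[g1, g2] = pvals.loc[g2, g1] = p
    return FstMatrix(labels=groups, theta=theta, pvalues=pvals, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Partition schemes
# ---------------------------------------------------------------------------

def default_partitions(ds: GenotypeDataset, min_n: int = 7) -> dict[str, list[str]]:
    """Forest populations with >= ``min_n`` samples become reference groups.

    Market samples never enter reference partitions; undersized populations
    are dropped from population-level analyses (their samples remain
    available for individual-level ones).
    """
    groups: dict[str, list[str]] = {}
    for sid, pop, sc in zip(ds.sample_ids, ds.population, ds.site_class):
        if sc != "forest":
            continue
        groups.setdefault(pop, []).append(sid)
    kept = {p: m for p, m in groups.items() if len(m) >= min_n}
    if len(kept) < 2:
        log.warning("fewer than 2 qualifying groups (min_n=%d)", min_n)
    return kept
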