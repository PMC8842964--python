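"""mtDNA haplotype statistics, neutrality tests with coalescent nulls, K2P assignment.

Statistics operate on the complete-deletion site set (columns holding a gap
or N in any retained sequence are excluded), the convention under which the
source tools report haplotype diversity, nucleotide diversity, Tajima's D,
Fu's Fs, the Harpending raggedness index and Ramos-Onsins & Rozas' R2.
P-values come from neutral constant-size coalescent replicates conditioned
on the observed number of segregating sites.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DataError
from .genodata import HaplotypeAlignment
from .synth import simulate_coalescent_sites

__all__ = [
    "HaplotypeSet",
    "NeutralityStats",
    "collapse_haplotypes",
    "nucleotide_diversity",
    "mismatch_distribution",
    "tajimas_d",
    "fus_fs",
    "r2_statistic",
    "neutrality_stats",
    "coalescent_pvalues",
    "k2p_distance",
    "assign_lineage",
]

log = logging.getLogger(__name__)

_GAPLIKE = {"-", "N"}


# ---------------------------------------------------------------------------
# Alignment -> matrix plumbing
# ---------------------------------------------------------------------------

def _matrix(aln: HaplotypeAlignment, exclude_missing: bool = True) -> tuple[np.ndarray, list[int]]:
    """Character matrix over the complete-deletion site set.

    When ``exclude_missing`` sequences containing N are dropped first; then
    every column holding a gap or N in any retained sequence is excluded.
    Returns (matrix, retained sequence indices).
    """
    keep = list(range(aln.n_sequences))
    if exclude_missing:
        keep = [i for i in keep if "N" not in aln.sequences[i]]
        if not keep:
            raise DataError("all sequences excluded (every sequence contains N)")
    mat = np.array([list(aln.sequences[i]) for i in keep])
    ok_cols = ~np.isin(mat, list(_GAPLIKE)).any(axis=0)
    return mat[:, ok_cols], keep


def _pairwise_diffs(mat: np.ndarray) -> np.ndarray:
    """(n x n) matrix of pairwise differing-site counts."""
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i, i + 1:] = (mat[i + 1:] != mat[i]).sum(axis=1)
    return d + d.T


def _site_stats(mat: np.ndarray):
    """(S, pi_total, singletons per sequence, distinct haplotype count)."""
    n, L = mat.shape
    S = 0
    pi_pairs = 0.0
    U = np.zeros(n)
    npairs = n * (n - 1) / 2
    for col in mat.T:
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) < 2:
            continue
        S += 1
        pi_pairs += (npairs - sum(c * (c - 1) / 2 for c in counts))
        for v, c in zip(vals, counts):
            if c == 1:
                U[col == v] += 1
    pi_total = pi_pairs / npairs if npairs else 0.0
    k_obs = len({row.tobytes() for row in np.ascontiguousarray(mat)})
    return S, pi_total, U, k_obs


# ---------------------------------------------------------------------------
# Haplotype diversity
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Collapsed haplotypes with frequencies and diversity indices."""

    haplotypes: list[str]
    frequencies: list[int]
    assignment: dict            # sequence id -> haplotype index
    h: int                      # haplotype count
    Hd: float                   # haplotype diversity
    pi: float                   # nucleotide diversity per analyzed site
    n_sequences: int
    n_sites: int


def collapse_haplotypes(aln: HaplotypeAlignment, exclude_missing: bool = True) -> HaplotypeSet:
    """Collapse identical sequences over the complete-deletion site set.

    Hd = n/(n-1) * (1 - sum f_i^2) with f_i haplotype relative frequencies;
    pi is the mean pairwise proportion of differing analyzed sites.
    """
    mat, keep = _matrix(aln, exclude_missing)
    n, L = mat.shape
    if L == 0:
        raise DataError("no analyzable sites after complete deletion")
    seen: dict[bytes, int] = {}
    haps: list[str] = []
    freqs: list[int] = []
    assignment: dict[str, int] = {}
    for row_i, i in enumerate(keep):
        key = mat[row_i].tobytes()
        if key not in seen:
            seen[key] = len(haps)
            haps.append("".join(mat[row_i]))
            freqs.append(0)
        hid = seen[key]
        freqs[hid] += 1
        assignment[aln.sequence_ids[i]] = hid
    rel = np.array(freqs) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(rel ** 2))) if n > 1 else 0.0
    _, pi_total, _, _ = _site_stats(mat)
    return HaplotypeSet(haplotypes=haps, frequencies=freqs, assignment=assignment,
                        h=len(haps), Hd=hd, pi=pi_total / L,
                        n_sequences=n, n_sites=L)


def nucleotide_diversity(aln: HaplotypeAlignment, exclude_missing: bool = True) -> float:
    """Mean pairwise proportion of differing sites over the analyzed sites."""
    mat, _ = _matrix(aln, exclude_missing)
    n, L = mat.shape
    if n < 2:
        raise DataError("nucleotide diversity needs >= 2 sequences")
    if L == 0:
        raise DataError("no analyzable sites")
    _, pi_total, _, _ = _site_stats(mat)
    return pi_total / L


def mismatch_distribution(aln: HaplotypeAlignment, exclude_missing: bool = True,
                          ) -> tuple[np.ndarray, float]:
    """Relative frequencies of pairwise difference counts plus raggedness r.

    With x_i the relative frequency of difference class i = 0..d (d the
    largest observed count) and x_{d+1} = 0, r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2.
    """
    mat, _ = _matrix(aln, exclude_missing)
    if mat.shape[0] < 2:
        raise DataError("mismatch distribution needs >= 2 sequences")
    diffs = _pairwise_diffs(mat)
    iu = np.triu_indices(mat.shape[0], 1)
    return _mismatch_from_counts(diffs[iu])


def _mismatch_from_counts(pair_diffs: np.ndarray) -> tuple[np.ndarray, float]:
    d = int(pair_diffs.max()) if len(pair_diffs) else 0
    x = np.bincount(pair_diffs, minlength=d + 1) / len(pair_diffs)
    padded = np.concatenate([x, [0.0]])
    r = float(np.sum(np.diff(padded) ** 2))
    return x, r


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------

def _tajimas_d_from(S: int, pi_total: float, n: int) -> float:
    if S < 1:
        raise DataError("Tajima's D undefined with S = 0")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / math.sqrt(var)


def tajimas_d(aln: HaplotypeAlignment, exclude_missing: bool = True) -> float:
    """Tajima's D from the standard normalized difference of theta estimators."""
    mat, _ = _matrix(aln, exclude_missing)
    S, pi_total, _, _ = _site_stats(mat)
    return _tajimas_d_from(S, pi_total, mat.shape[0])


def _log_int(x: int) -> float:
    if x == 0:
        return -math.inf
    try:
        return math.log(x)
    except OverflowError:
        shift = x.bit_length() - 64
        return math.log(x >> shift) + shift * math.log(2)


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |S(n, k)| for k = 0..n (unsigned first kind), exact big-int recurrence."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = row[k - 1] + (m - 1) * (row[k] if k < m else 0)
        row = new
    return tuple(_log_int(v) for v in row)


def _fus_fs_from(theta: float, k_obs: int, n: int) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta, n) from Ewens."""
    if theta <= 0:
        return math.inf if k_obs <= 1 else -math.inf
    log_sn = _log_stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_pk = [log_sn[k] + k * math.log(theta) - log_rising for k in range(1, n + 1)]
    s_prime = float(np.exp(logsumexp(log_pk[k_obs - 1:])))
    s_prime = min(s_prime, 1.0)
    if s_prime >= 1.0:
        log.warning("Fu's Fs: S' = 1 numerically; +inf flagged")
        return math.inf
    if s_prime <= 0.0:
        log.warning("Fu's Fs: S' = 0 numerically; -inf flagged")
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def fus_fs(aln: HaplotypeAlignment, exclude_missing: bool = True) -> float:
    """Fu's Fs with theta-hat = mean pairwise differences (original definition)."""
    mat, _ = _matrix(aln, exclude_missing)
    if mat.shape[0] < 2:
        raise DataError("Fu's Fs needs >= 2 sequences")
    S, pi_total, _, k_obs = _site_stats(mat)
    return _fus_fs_from(pi_total, k_obs, mat.shape[0])


def _r2_from(S: int, pi_total: float, U: np.ndarray) -> float:
    if S < 1:
        raise DataError("R2 undefined with S = 0")
    n = len(U)
    return math.sqrt(float(np.mean((U - pi_total / 2) ** 2))) / S


def r2_statistic(aln: HaplotypeAlignment, exclude_missing: bool = True) -> float:
    """Ramos-Onsins & Rozas' R2 (singleton counts vs half the mean pairwise diff)."""
    mat, _ = _matrix(aln, exclude_missing)
    S, pi_total, U, _ = _site_stats(mat)
    return _r2_from(S, pi_total, U)


@dataclass
class NeutralityStats:
    n: int
    S: int
    pi_total: float            # mean pairwise differences (not per site)
    D: float
    Fs: float
    raggedness: float
    R2: float
    pvalues: dict | None = None


def neutrality_stats(aln: HaplotypeAlignment, exclude_missing: bool = True) -> NeutralityStats:
    mat, _ = _matrix(aln, exclude_missing)
    n = mat.shape[0]
    S, pi_total, U, k_obs = _site_stats(mat)
    diffs = _pairwise_diffs(mat)
    _, rag = _mismatch_from_counts(diffs[np.triu_indices(n, 1)])
    return NeutralityStats(
        n=n, S=S, pi_total=pi_total,
        D=_tajimas_d_from(S, pi_total, n) if S else float("nan"),
        Fs=_fus_fs_from(pi_total, k_obs, n),
        raggedness=rag,
        R2=_r2_from(S, pi_total, U) if S else float("nan"),
    )


def _stats_from_binary(sites: np.ndarray):
    """(D, Fs, raggedness, R2) from a binary site matrix (simulation path)."""
    n, S = sites.shape
    counts = sites.sum(axis=0)
    npairs = n * (n - 1) / 2
    pi_total = float(np.sum(counts * (n - counts)) / npairs)
    U = sites[:, counts == 1].sum(axis=1) + (1 - sites)[:, counts == n - 1].sum(axis=1)
    k_obs = len({row.tobytes() for row in np.ascontiguousarray(sites)})
    r = sites.sum(axis=1)
    dmat = r[:, None] + r[None, :] - 2 * (sites @ sites.T)
    _, rag = _mismatch_from_counts(dmat[np.triu_indices(n, 1)].astype(np.int64))
    D = _tajimas_d_from(S, pi_total, n) if S else float("nan")
    Fs = _fus_fs_from(pi_total, k_obs, n)
    R2 = _r2_from(S, pi_total, U.astype(float)) if S else float("nan")
    return D, Fs, rag, R2


def simulated_null(n: int, S: int, reps: int, seed: int | None = None) -> pd.DataFrame:
    """Null distributions of D, Fs, raggedness and R2 from coalescent replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(reps):
        sites = simulate_coalescent_sites(n, S, rng)
        D, Fs, rag, R2 = _stats_from_binary(sites)
        rows.append((D, Fs, rag, R2))
    return pd.DataFrame(rows, columns=["D", "Fs", "raggedness", "R2"])


def coalescent_pvalues(aln: HaplotypeAlignment, reps: int = 1000,
                       seed: int | None = None,
                       exclude_missing: bool = True) -> NeutralityStats:
    """Neutrality statistics with coalescent-simulated p-values.

    Replicates condition on the observed n and S (neutral, infinite sites,
    large constant population size).  Lower-tail p for D, Fs and R2; upper
    tail for raggedness.  The +1 correction keeps p in (0, 1].
    """
    if reps < 100:
        raise DataError("reps must be >= 100")
    obs = neutrality_stats(aln, exclude_missing)
    null = simulated_null(obs.n, obs.S, reps, seed)
    obs.pvalues = {
        "D": (np.sum(null["D"].values <= obs.D) + 1) / (reps + 1),
        "Fs": (np.sum(null["Fs"].values <= obs.Fs) + 1) / (reps + 1),
        "R2": (np.sum(null["R2"].values <= obs.R2) + 1) / (reps + 1),
        "raggedness": (np.sum(null["raggedness"].values >= obs.raggedness) + 1) / (reps + 1),
    }
    return obs


# ---------------------------------------------------------------------------
# K2P distance and lineage assignment
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance; pairwise deletion of gap/N sites.

    d = -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with P, Q the transition and
    transversion proportions.  Saturated pairs are flagged infinite.
    """
    if len(seq1) != len(seq2):
        raise DataError("sequences must have equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    comparable = transitions = transversions = 0
    for x, y in zip(seq1, seq2):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        comparable += 1
        if x == y:
            continue
        same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if comparable == 0:
        raise DataError("no comparable sites")
    P = transitions / comparable
    Q = transversions / comparable
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        log.warning("K2P saturation; distance flagged infinite")
        return math.inf
    return 0.5 * math.log(1 / w1) + 0.25 * math.log(1 / w2)


def assign_lineage(queries: HaplotypeAlignment, panel: HaplotypeAlignment,
                   panel_lineages: dict, margin_threshold: float = 0.0) -> pd.DataFrame:
    """Nearest-reference K2P lineage assignment.

    Each query gets the lineage with the minimum mean K2P distance to its
    reference sequences; the margin is the gap to the runner-up lineage.
    Queries whose margin does not exceed ``margin_threshold`` (ties at 0 by
    default) are left unassigned.
    """
    lineages = sorted(set(panel_lineages.values()))
    if len(lineages) < 2:
        raise DataError("reference panel must cover >= 2 lineages")
    members: dict[str, list[int]] = {l: [] for l in lineages}
    for i, sid in enumerate(panel.sequence_ids):
        if sid not in panel_lineages:
            raise DataError(f"panel sequence {sid!r} has no lineage label")
        members[panel_lineages[sid]].append(i)
    rows = []
    for qi, qid in enumerate(queries.sequence_ids):
        qseq = queries.sequences[qi]
        means = {}
        for l in lineages:
            dists = [k2p_distance(qseq, panel.sequences[i]) for i in members[l]]
            means[l] = float(np.mean(dists))
        ranked = sorted(means, key=means.get)
        best, second = ranked[0], ranked[1]
        margin = means[second] - means[best]
        assigned = best if margin > margin_threshold else "unassigned"
        rows.append({"query": qid, "lineage": assigned, "margin": margin,
                     **{f"d_{l}": means[l] for l in lineages}})
    return pd.DataFrame(rows)
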