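"""Isolation by distance: Edwards chord distance, geographic distance, Mantel test."""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genodata import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "DistancePair",
    "edwards_distance",
    "geographic_distances",
    "mantel_test",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistancePair:
    labels: list[str]
    genetic: pd.DataFrame
    geographic: pd.DataFrame


def _edwards_from_freqs(freq_by_locus_x: dict, freq_by_locus_y: dict) -> float:
    """Chord distance sqrt(1 - (1/L) sum_l sum_a sqrt(p_x p_y)) over shared loci."""
    shared = [l for l in freq_by_locus_x
              if freq_by_locus_x[l] and freq_by_locus_y.get(l)]
    if not shared:
        return float("nan")
    total = 0.0
    for l in shared:
        fx, fy = freq_by_locus_x[l], freq_by_locus_y[l]
        total += sum(math.sqrt(fx[a] * fy[a]) for a in fx if a in fy)
    inner = 1.0 - total / len(shared)
    return math.sqrt(max(inner, 0.0))


def edwards_distance(ds: GenotypeDataset, level: str = "population",
                     partition: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Edwards chord genetic distance matrix.

    ``level="population"`` uses group allele frequencies (``partition``
    defaults to grouping by population label); ``level="individual"`` treats
    each individual as a two-gene sample (within-individual frequencies 0,
    0.5, 1), dropping loci missing in either member of a pair.  Pairs with no
    shared typed loci get a flagged NaN entry.
    """
    if level == "population":
        ft = allele_frequencies(ds, partition)
        labels = ft.groups
        profiles = [
            {l: ft.freqs(g, l) for l in ft.locus_names} for g in labels
        ]
    elif level == "individual":
        labels = list(ds.sample_ids)
        profiles = []
        for i in range(ds.n_samples):
            prof = {}
            for j, locus in enumerate(ds.locus_names):
                a, b = ds.calls[i, j]
                if a == MISSING:
                    prof[locus] = {}
                elif a == b:
                    prof[locus] = {a: 1.0}
                else:
                    prof[locus] = {a: 0.5, b: 0.5}
            profiles.append(prof)
    else:
        raise DataError("level must be 'population' or 'individual'")
    n = len(labels)
    D = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d = _edwards_from_freqs(profiles[x], profiles[y])
            if math.isnan(d):
                log.warning("no shared typed loci between %s and %s", labels[x], labels[y])
            D[x, y] = D[y, x] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def _haversine(lat1, lon1, lat2, lon2) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distances(ds: GenotypeDataset, level: str = "population",
                         partition: dict[str, list[str]] | None = None,
                         centers: dict | None = None) -> pd.DataFrame:
    """Great-circle distance matrix in km.

    At population level, each group's location is the centroid of its member
    coordinates unless explicit ``centers`` (label -> (lat, lon)) are given.
    Missing coordinates raise an error naming the unit.
    """
    if ds.coords is None and centers is None:
        raise DataError("dataset has no coordinates")
    if level == "population":
        if partition is None:
            partition = {p: [] for p in ds.populations()}
            for sid, pop in zip(ds.sample_ids, ds.population):
                partition[pop].append(sid)
        labels = list(partition)
        points = []
        for g in labels:
            if centers is not None and g in centers:
                points.append(tuple(centers[g]))
                continue
            idx = [ds.sample_index(s) for s in partition[g]]
            xy = ds.coords[idx]
            if np.isnan(xy).any():
                raise DataError(f"missing coordinates in population {g}")
            points.append((float(xy[:, 0].mean()), float(xy[:, 1].mean())))
    elif level == "individual":
        labels = list(ds.sample_ids)
        points = []
        for i, sid in enumerate(labels):
            if np.isnan(ds.coords[i]).any():
                raise DataError(f"missing coordinates for sample {sid}")
            points.append((float(ds.coords[i, 0]), float(ds.coords[i, 1])))
    else:
        raise DataError("level must be 'population' or 'individual'")
    n = len(labels)
    D = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            D[x, y] = D[y, x] = _haversine(*points[x], *points[y])
    return pd.DataFrame(D, index=labels, columns=labels)


def mantel_test(genetic, geographic, n_perm: int = 10000,
                seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; significance
    comes from jointly permuting rows/columns of one matrix,
    p = (#{perm r >= observed} + 1) / (n_perm + 1).
    """
    A = np.asarray(genetic, dtype=float)
    B = np.asarray(geographic, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise DataError("matrices must be square and of equal shape")
    n = A.shape[0]
    if n < 3:
        raise DataError("Mantel test needs >= 3 units")
    if isinstance(genetic, pd.DataFrame) and isinstance(geographic, pd.DataFrame):
        if list(genetic.index) != list(geographic.index):
            raise DataError("matrix label orders differ")
    iu = np.triu_indices(n, 1)
    va, vb = A[iu], B[iu]
    if va.std() == 0 or vb.std() == 0:
        raise DataError("zero variance in a distance matrix; r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    if n_perm == 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    za = (va - va.mean()) / va.std()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = B[np.ix_(perm, perm)][iu]
        r_perm = float(np.mean(za * (vp - vp.mean()) / vp.std()))
        if r_perm >= r_obs - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)
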