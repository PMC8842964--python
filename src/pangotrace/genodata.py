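"""Data model, file I/O and QC filters for microsatellite genotypes and aligned sequences.

Genotypes are diploid allele-size calls (opaque non-negative integers; no binning
or size calling is done here — alleles are scored upstream).  A call is an
unordered pair of alleles, stored sorted; missing data applies to a whole
locus call, never to a single allele slot.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import DataError

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "HaplotypeAlignment",
    "read_genotype_table",
    "write_genotype_table",
    "read_alignment",
    "consensus_from_replicates",
    "filter_by_completeness",
    "allele_frequencies",
]

log = logging.getLogger(__name__)

#: Sentinel for a missing (untyped) locus call.
MISSING = -1

_ALLOWED_BASES = frozenset("ACGTN-")
_SITE_CLASSES = ("forest", "market")


@dataclass
class GenotypeDataset:
    """Samples x loci diploid genotype calls with per-sample metadata.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, row order fixed.
    locus_names : list of str
        Locus identifiers, column order fixed.
    calls : ndarray of shape (n_samples, n_loci, 2), dtype int64
        Allele pairs stored canonically (sorted ascending); ``MISSING`` in
        both slots marks an untyped call.
    population : list of str
        Population / forest / market label per sample (non-empty).
    site_class : list of str
        ``"forest"`` (reference) or ``"market"`` (to be traced) per sample.
    coords : ndarray of shape (n_samples, 2) or None
        Optional (lat, lon) in decimal degrees; NaN where unknown.
    """

    sample_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    population: list[str]
    site_class: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.sample_ids), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {L} loci"
            )
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicated sample_id in dataset")
        if any(not p for p in self.population):
            raise DataError("empty population label")
        for sc in self.site_class:
            if sc not in _SITE_CLASSES:
                raise DataError(f"site_class must be one of {_SITE_CLASSES}, got {sc!r}")
        # canonicalize: sort each pair; a half-missing pair is malformed
        lo = np.minimum(self.calls[:, :, 0], self.calls[:, :, 1])
        hi = np.maximum(self.calls[:, :, 0], self.calls[:, :, 1])
        half = (lo == MISSING) & (hi != MISSING)
        if half.any():
            i, j = np.argwhere(half)[0]
            raise DataError(
                f"half-missing call at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_names[j]!r}"
            )
        self.calls = np.stack([lo, hi], axis=2)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise DataError("coords must have shape (n_samples, 2)")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def typed(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): call present."""
        return self.calls[:, :, 0] != MISSING

    def completeness(self) -> np.ndarray:
        """Fraction of typed loci per sample."""
        return self.typed.mean(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DataError(f"unknown sample_id {sample_id!r}") from None

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise DataError(f"unknown locus {locus!r}") from None

    def subset(self, indices) -> "GenotypeDataset":
        """New dataset restricted to the given sample indices (order kept)."""
        idx = list(indices)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_names=list(self.locus_names),
            calls=self.calls[idx].copy(),
            population=[self.population[i] for i in idx],
            site_class=[self.site_class[i] for i in idx],
            coords=None if self.coords is None else self.coords[idx].copy(),
        )

    def by_site_class(self, site_class: str) -> "GenotypeDataset":
        return self.subset(
            [i for i, sc in enumerate(self.site_class) if sc == site_class]
        )

    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "population", "site_class", "lat", "lon"]


def read_genotype_table(path, dialect: str = "native") -> GenotypeDataset:
    """Read a wide genotype CSV.

    Two dialects are accepted:

    ``native``
        Columns ``sample_id, population, site_class, lat, lon`` then one
        column per locus holding ``a1/a2`` (``./.`` for missing).
    ``genalex``
        Same metadata columns, then *two adjacent* integer columns per locus
        (the locus name is taken from the first of the pair); ``0`` codes a
        missing allele and a ``(0, 0)`` pair is a missing call.

    Lines starting with ``#`` are treated as comments.
    """
    if dialect not in ("native", "genalex"):
        raise DataError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise DataError(f"{path}: empty genotype table")
    header, body = rows[0], rows[1:]
    header = [h.strip() for h in header]
    if header[: len(_META_COLS)] != _META_COLS:
        raise DataError(
            f"{path}: header must start with {','.join(_META_COLS)}"
        )
    locus_cols = header[len(_META_COLS):]
    if dialect == "native":
        loci = locus_cols
    else:
        if len(locus_cols) % 2:
            raise DataError(f"{path}: genalex dialect needs paired allele columns")
        loci = locus_cols[0::2]
    n_fields = len(_META_COLS) + (len(loci) if dialect == "native" else 2 * len(loci))

    ids, pops, classes, coords = [], [], [], []
    calls = np.full((len(body), len(loci), 2), MISSING, dtype=np.int64)
    for r, row in enumerate(body, start=2):
        if len(row) != n_fields:
            raise DataError(f"{path}:{r}: expected {n_fields} fields, got {len(row)}")
        sid, pop, sc, lat, lon = (x.strip() for x in row[:5])
        ids.append(sid)
        pops.append(pop)
        classes.append(sc)
        coords.append(
            (float(lat) if lat else np.nan, float(lon) if lon else np.nan)
        )
        cells = row[5:]
        for j, locus in enumerate(loci):
            if dialect == "native":
                cell = cells[j].strip()
                if cell in ("./.", "", "."):
                    continue
                parts = cell.split("/")
                if len(parts) != 2:
                    raise DataError(
                        f"{path}:{r}: malformed allele cell {cell!r} at locus {locus!r}"
                    )
                try:
                    a, b = int(parts[0]), int(parts[1])
                except ValueError:
                    raise DataError(
                        f"{path}:{r}: non-integer allele in {cell!r} at locus {locus!r}"
                    ) from None
                if a < 0 or b < 0:
                    raise DataError(
                        f"{path}:{r}: negative allele in {cell!r} at locus {locus!r}"
                    )
            else:
                c1, c2 = cells[2 * j].strip(), cells[2 * j + 1].strip()
                try:
                    a, b = int(c1), int(c2)
                except ValueError:
                    raise DataError(
                        f"{path}:{r}: non-integer allele cell at locus {locus!r}"
                    ) from None
                if a == 0 and b == 0:
                    continue
                if a == 0 or b == 0:
                    raise DataError(
                        f"{path}:{r}: half-missing call at locus {locus!r}"
                    )
            calls[r - 2, j] = sorted((a, b))
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"{path}: duplicated sample_id(s): {', '.join(dup)}")
    coords_arr = np.array(coords, dtype=float)
    if np.isnan(coords_arr).all():
        coords_arr = None
    return GenotypeDataset(ids, list(loci), calls, pops, classes, coords_arr)


def write_genotype_table(ds: GenotypeDataset, path, header_note: str | None = None) -> None:
    """Write a dataset in the native CSV dialect (round-trip safe)."""
    from . import __version__

    with open(path, "w", newline="") as fh:
        fh.write(f"# pangotrace {__version__}")
        if header_note:
            fh.write(f" {header_note}")
        fh.write("\n")
        w = csv.writer(fh)
        w.writerow(_META_COLS + ds.locus_names)
        for i, sid in enumerate(ds.sample_ids):
            if ds.coords is None or np.isnan(ds.coords[i]).any():
                lat = lon = ""
            else:
                lat, lon = (repr(float(x)) for x in ds.coords[i])
            cells = []
            for j in range(ds.n_loci):
                a, b = ds.calls[i, j]
                cells.append("./." if a == MISSING else f"{a}/{b}")
            w.writerow([sid, ds.population[i], ds.site_class[i], lat, lon] + cells)


# ---------------------------------------------------------------------------
# Aligned sequences
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Aligned DNA sequences (equal length, alphabet A/C/G/T/N/-)."""

    sequence_ids: list[str]
    sequences: list[str]
    population: list[str] | None = None
    site_class: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DataError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        ragged = [
            sid for sid, s in zip(self.sequence_ids, self.sequences)
            if len(s) != length
        ]
        if ragged:
            raise DataError(f"ragged alignment; offending ids: {', '.join(ragged)}")
        for sid, s in zip(self.sequence_ids, self.sequences):
            bad = set(s) - _ALLOWED_BASES
            if bad:
                raise DataError(
                    f"sequence {sid!r} contains disallowed symbols {sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def subset(self, indices) -> "HaplotypeAlignment":
        idx = list(indices)
        return HaplotypeAlignment(
            sequence_ids=[self.sequence_ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            population=None if self.population is None
            else [self.population[i] for i in idx],
            site_class=None if self.site_class is None
            else [self.site_class[i] for i in idx],
        )


def read_alignment(path) -> HaplotypeAlignment:
    """Read an aligned FASTA file (alignment is an input, never computed here)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return HaplotypeAlignment(
        sequence_ids=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sequence_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def consensus_from_replicates(replicates: list[GenotypeDataset]) -> GenotypeDataset:
    """Consensus genotype from three PCR replicates.

    An allele enters the consensus call iff it is present in at least two of
    the three replicate calls for that sample x locus.  If exactly one allele
    qualifies the call is homozygous for it; if none qualify the call is
    missing; if more than two qualify (a tie across replicates) the call is
    flagged, logged and set missing.
    """
    if len(replicates) != 3:
        raise DataError("exactly 3 replicate datasets are required")
    ref = replicates[0]
    for rep in replicates[1:]:
        if rep.sample_ids != ref.sample_ids or rep.locus_names != ref.locus_names:
            raise DataError("replicates must share sample ids and loci (same order)")
    calls = np.full_like(ref.calls, MISSING)
    n_flagged = 0
    for i in range(ref.n_samples):
        for j in range(ref.n_loci):
            support: dict[int, int] = {}
            for rep in replicates:
                a, b = rep.calls[i, j]
                if a == MISSING:
                    continue
                for allele in {a, b}:
                    support[allele] = support.get(allele, 0) + 1
            winners = sorted(al for al, k in support.items() if k >= 2)
            if len(winners) == 1:
                calls[i, j] = (winners[0], winners[0])
            elif len(winners) == 2:
                calls[i, j] = winners
            elif len(winners) > 2:
                n_flagged += 1
                log.warning(
                    "consensus tie (%d alleles qualify) at sample %s locus %s; "
                    "call set missing",
                    len(winners), ref.sample_ids[i], ref.locus_names[j],
                )
    if n_flagged:
        log.warning("%d consensus calls flagged missing due to ties", n_flagged)
    return GenotypeDataset(
        list(ref.sample_ids), list(ref.locus_names), calls,
        list(ref.population), list(ref.site_class),
        None if ref.coords is None else ref.coords.copy(),
    )


def filter_by_completeness(ds: GenotypeDataset, min_fraction: float = 0.75) -> GenotypeDataset:
    """Keep samples typed at >= ``min_fraction`` of loci (idempotent).

    With 20 loci and the 0.75 default this keeps samples with >= 15 typed loci.
    """
    if not 0 < min_fraction <= 1:
        raise DataError("min_fraction must be in (0, 1]")
    keep = np.nonzero(ds.completeness() >= min_fraction)[0]
    removed = ds.n_samples - len(keep)
    log.info("completeness filter: retained %d, removed %d samples", len(keep), removed)
    if len(keep) == 0:
        log.warning("completeness filter removed every sample")
    return ds.subset(keep)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-partition, per-locus allele gene-copy counts.

    ``counts[group][locus]`` maps allele -> gene-copy count over non-missing
    calls; ``n_genes[group][locus]`` is twice the number of typed individuals.
    Groups with zero typed individuals at a locus are flagged in ``undefined``.
    """

    partition: dict[str, list[str]]
    locus_names: list[str]
    counts: dict[str, dict[str, dict[int, int]]]
    n_genes: dict[str, dict[str, int]]
    undefined: set = field(default_factory=set)  # {(group, locus)}

    @property
    def groups(self) -> list[str]:
        return list(self.partition)

    def freqs(self, group: str, locus: str) -> dict[int, float]:
        """Allele -> relative frequency; empty dict where undefined."""
        n = self.n_genes[group][locus]
        if n == 0:
            return {}
        return {a: c / n for a, c in self.counts[group][locus].items()}

    def pooled(self) -> "AlleleFrequencyTable":
        """Collapse all groups into a single group ``"all"``."""
        samples = [s for grp in self.partition.values() for s in grp]
        counts: dict[str, dict[int, int]] = {l: {} for l in self.locus_names}
        n_genes = {l: 0 for l in self.locus_names}
        for grp in self.partition:
            for l in self.locus_names:
                n_genes[l] += self.n_genes[grp][l]
                for a, c in self.counts[grp][l].items():
                    counts[l][a] = counts[l].get(a, 0) + c
        undefined = {("all", l) for l in self.locus_names if n_genes[l] == 0}
        return AlleleFrequencyTable(
            {"all": samples}, list(self.locus_names),
            {"all": counts}, {"all": n_genes}, undefined,
        )


def allele_frequencies(ds: GenotypeDataset, partition: dict[str, list[str]] | None = None,
                       ) -> AlleleFrequencyTable:
    """Count alleles per group x locus over non-missing calls.

    ``partition`` maps group label -> sample ids (each sample in at most one
    group); by default samples are grouped by their population label.
    """
    if partition is None:
        partition = {p: [] for p in ds.populations()}
        for sid, pop in zip(ds.sample_ids, ds.population):
            partition[pop].append(sid)
    assigned = [s for grp in partition.values() for s in grp]
    if len(assigned) != len(set(assigned)):
        raise DataError("partition assigns a sample to more than one group")
    counts: dict[str, dict[str, dict[int, int]]] = {}
    n_genes: dict[str, dict[str, int]] = {}
    undefined: set = set()
    for grp, members in partition.items():
        idx = [ds.sample_index(s) for s in members]
        counts[grp] = {}
        n_genes[grp] = {}
        for j, locus in enumerate(ds.locus_names):
            c: dict[int, int] = {}
            typed = 0
            for i in idx:
                a, b = ds.calls[i, j]
                if a == MISSING:
                    continue
                typed += 1
                c[a] = c.get(a, 0) + 1
                c[b] = c.get(b, 0) + 1
            counts[grp][locus] = c
            n_genes[grp][locus] = 2 * typed
            if typed == 0:
                undefined.add((grp, locus))
                log.warning("no typed individuals for group %s at locus %s", grp, locus)
    return AlleleFrequencyTable(
        {g: list(m) for g, m in partition.items()},
        list(ds.locus_names), counts, n_genes, undefined,
    )
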