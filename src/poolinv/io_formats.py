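"""Readers and writers for the external file formats.

All genomic coordinates inside the package are 1-based inclusive. The single
exception is BED input, which is 0-based half-open on disk and converted on
read (:func:`bed_to_one_based`).

Sync files follow the PoPoolation2 dialect: whitespace-separated
``chrom pos ref`` columns followed by one ``A:T:C:G:N:del`` count column per
pool. ``N`` and deletion counts are carried through but downstream
allele-frequency denominators use the four nucleotide counts only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Nucleotide order of a sync count column.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: The four true nucleotides, in sync order.
NUCLEOTIDES = ("A", "T", "C", "G")

_NUC_INDEX = {a: i for i, a in enumerate(NUCLEOTIDES)}


class FormatError(ValueError):
    """Malformed input file (reported with the offending line number)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


def allele_index(allele: str) -> int:
    """Column index of ``allele`` within a sync count 6-tuple."""
    try:
        return _NUC_INDEX[allele]
    except KeyError:
        raise ValidationError(f"not a nucleotide: {allele!r}") from None


# ---------------------------------------------------------------------------
# sync format
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyncRecord:
    """Per-position pooled nucleotide counts.

    Attributes
    ----------
    chrom : str
        Chromosome-arm name (release-5 style, e.g. ``2L``).
    pos : int
        1-based reference position.
    ref : str
        Reference nucleotide.
    counts : numpy.ndarray
        ``(n_pools, 6)`` array of non-negative integers ordered
        A, T, C, G, N, deletion.
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 6:
            raise ValidationError("counts must have shape (n_pools, 6)")
        if (counts < 0).any():
            raise ValidationError(f"negative count at {self.chrom}:{self.pos}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]

    def nucleotide_coverage(self, pool: int) -> int:
        """A+T+C+G coverage of ``pool`` (N and deletions excluded)."""
        return int(self.counts[pool, :4].sum())


class SyncTable:
    """An ordered collection of :class:`SyncRecord` with a fixed pool count."""

    def __init__(self, records: Iterable[SyncRecord] = ()):
        self.records: list[SyncRecord] = []
        self._n_pools: int | None = None
        for rec in records:
            self.append(rec)

    def append(self, rec: SyncRecord) -> None:
        if self._n_pools is None:
            self._n_pools = rec.n_pools
        elif rec.n_pools != self._n_pools:
            raise ValidationError(
                f"record at {rec.chrom}:{rec.pos} has {rec.n_pools} pools, "
                f"table has {self._n_pools}"
            )
        self.records.append(rec)

    @property
    def n_pools(self) -> int:
        return 0 if self._n_pools is None else self._n_pools

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_position(self) -> dict[tuple[str, int], SyncRecord]:
        """Index records by ``(chrom, pos)``."""
        return {(r.chrom, r.pos): r for r in self.records}

    def coverage_matrix(self) -> np.ndarray:
        """``(n_records, n_pools)`` A+T+C+G coverage matrix."""
        if not self.records:
            return np.zeros((0, self.n_pools), dtype=np.int64)
        return np.stack([r.counts[:, :4].sum(axis=1) for r in self.records])


_COUNT_RE = re.compile(r"^\d+(:\d+){5}$")


def read_sync(path: str | Path, min_pools: int = 1) -> SyncTable:
    """Parse a PoPoolation2 sync file.

    Parameters
    ----------
    path : path-like
        Sync file with columns chrom, pos, ref and >= ``min_pools``
        colon-separated count 6-tuples.
    min_pools : int
        Minimum number of pool columns each line must carry.

    Raises
    ------
    FormatError
        On ragged pool counts across lines, malformed count tuples, or a
        negative/short line; the message carries the 1-based line number.
    """
    if min_pools < 1:
        raise ValueError("min_pools must be positive")
    table = SyncTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3 + min_pools:
                raise FormatError(
                    f"line {lineno}: expected >= {3 + min_pools} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            pools = fields[3:]
            for tup in pools:
                if not _COUNT_RE.match(tup):
                    raise FormatError(f"line {lineno}: malformed count tuple {tup!r}")
            counts = np.array(
                [[int(x) for x in tup.split(":")] for tup in pools], dtype=np.int64
            )
            try:
                rec = SyncRecord(chrom=chrom, pos=int(pos_s), ref=ref, counts=counts)
                table.append(rec)
            except ValidationError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return table


def write_sync(table: SyncTable, path: str | Path) -> None:
    """Write ``table`` in the PoPoolation2 sync dialect."""
    with open(path, "w") as fh:
        for rec in table:
            pools = "\t".join(":".join(str(c) for c in row) for row in rec.counts)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{pools}\n")


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    """An inversion-diagnostic SNP: a fixed difference between arrangements."""

    inversion: str
    chrom: str
    pos: int
    inverted_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        for a in (self.inverted_allele, self.other_allele):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"allele must be one of ACGT, got {a!r}")
        if self.inverted_allele == self.other_allele:
            raise ValidationError(
                f"marker {self.inversion} {self.chrom}:{self.pos}: "
                "inverted and other allele are identical"
            )
        if self.pos < 1:
            raise ValidationError("marker position must be >= 1")


class MarkerSet:
    """Markers grouped per inversion, unique by (inversion, chrom, pos)."""

    def __init__(self, markers: Iterable[Marker] = ()):
        self._by_inversion: dict[str, list[Marker]] = {}
        self._seen: set[tuple[str, str, int]] = set()
        for m in markers:
            self.add(m)

    def add(self, marker: Marker) -> None:
        key = (marker.inversion, marker.chrom, marker.pos)
        if key in self._seen:
            raise ValidationError(f"duplicate marker {key}")
        self._seen.add(key)
        self._by_inversion.setdefault(marker.inversion, []).append(marker)

    @property
    def inversions(self) -> list[str]:
        return list(self._by_inversion)

    def markers_for(self, inversion: str) -> list[Marker]:
        try:
            return list(self._by_inversion[inversion])
        except KeyError:
            raise KeyError(f"no markers for inversion {inversion!r}") from None

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_inversion.values())

    def __iter__(self):
        for ms in self._by_inversion.values():
            yield from ms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerSet):
            return NotImplemented
        return sorted(self, key=_marker_key) == sorted(other, key=_marker_key)


def _marker_key(m: Marker) -> tuple:
    return (m.inversion, m.chrom, m.pos)


_MARKER_COLUMNS = ["inversion", "chrom", "pos", "inverted_allele", "other_allele"]


def read_marker_table(path: str | Path) -> MarkerSet:
    """Read a marker TSV (inversion, chrom, pos, inverted_allele, other_allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"marker table missing columns: {sorted(missing)}")
    markers = MarkerSet()
    for row in df.itertuples(index=False):
        markers.add(
            Marker(
                inversion=row.inversion,
                chrom=row.chrom,
                pos=int(row.pos),
                inverted_allele=row.inverted_allele,
                other_allele=row.other_allele,
            )
        )
    return markers


def write_marker_table(markers: MarkerSet, path: str | Path) -> None:
    rows = [
        (m.inversion, m.chrom, m.pos, m.inverted_allele, m.other_allele)
        for m in sorted(markers, key=_marker_key)
    ]
    pd.DataFrame(rows, columns=_MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# breakpoints (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointInterval:
    """Inversion breakpoint span in 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"{self.name}: start must be < end, got [{self.start}, {self.end}]"
            )
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def bed_to_one_based(bed_start: int, bed_end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    if bed_start < 0 or bed_end <= bed_start:
        raise ValidationError(f"invalid BED interval [{bed_start}, {bed_end})")
    return bed_start + 1, bed_end


def read_breakpoints_bed(path: str | Path) -> list[BreakpointInterval]:
    """Read inversion breakpoint intervals from a BED file (chrom start end name)."""
    out: list[BreakpointInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"line {lineno}: BED needs chrom, start, end, name"
                )
            chrom, start_s, end_s, name = fields[:4]
            start, end = bed_to_one_based(int(start_s), int(end_s))
            out.append(BreakpointInterval(name=name, chrom=chrom, start=start, end=end))
    return out


# ---------------------------------------------------------------------------
# karyotype count tables
# ---------------------------------------------------------------------------


@dataclass
class KaryotypeCountTable:
    """Per-population karyotype counts: one row per population sample.

    ``data`` has a ``population`` column, an ``n`` column (chromosomes
    sampled) and one integer count column per inversion.
    """

    data: pd.DataFrame
    inversions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.inversions:
            self.inversions = [
                c for c in self.data.columns if c not in ("population", "n")
            ]
        if (self.data["n"] <= 0).any():
            raise ValidationError("sample size n must be positive")
        for inv in self.inversions:
            if (self.data[inv] > self.data["n"]).any():
                raise ValidationError(f"count for {inv} exceeds sample size n")
            if (self.data[inv] < 0).any():
                raise ValidationError(f"negative count for {inv}")

    def row(self, population: str) -> pd.Series:
        sel = self.data[self.data["population"] == population]
        if sel.empty:
            raise KeyError(f"unknown population {population!r}")
        return sel.iloc[0]


def read_karyotype_counts(path: str | Path) -> KaryotypeCountTable:
    """Read a karyotype count TSV: population, n, then one column per inversion."""
    df = pd.read_csv(path, sep="\t")
    if "population" not in df.columns or "n" not in df.columns:
        raise FormatError("karyotype table needs 'population' and 'n' columns")
    return KaryotypeCountTable(data=df)


# ---------------------------------------------------------------------------
# chromosome-arm conventions
# ---------------------------------------------------------------------------

#: Release-5 style chromosome-arm labels.
STANDARD_ARMS = ("2L", "2R", "3L", "3R", "X", "4")

_INVERSION_ARM_RE = re.compile(r"^In\(([^)]+)\)")


def arm_of_inversion(inversion: str) -> str:
    """Chromosome arm an inversion lies on, parsed from names like ``In(3R)C``."""
    m = _INVERSION_ARM_RE.match(inversion)
    if not m:
        raise ValidationError(
            f"cannot parse chromosome arm from inversion name {inversion!r}"
        )
    return m.group(1)


def normalize_arm(name: str, alias_map: dict[str, str] | None = None) -> str:
    """Map a chromosome name onto release-5 arm labels via an alias map."""
    if alias_map and name in alias_map:
        return alias_map[name]
    return name
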