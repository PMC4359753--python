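"""Inversion-frequency estimation from pooled allele counts.

The frequency of an inversion in a pool is estimated as the unweighted
arithmetic mean, over its marker SNPs, of the inverted-allele frequency at
each marker (inverted-allele count divided by the A+T+C+G coverage). Markers
are dropped at positions with coverage below a minimum (default 10-fold;
a 3-fold preset suits low-coverage data) or above the 95th percentile of the
pool's genome-wide coverage distribution, both guards against sampling error
and mismapping/duplication artifacts. When no marker survives, the estimate
is reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolinv.haplorecon import per_arm_coverage_percentile
from poolinv.io_formats import (
    KaryotypeCountTable,
    MarkerSet,
    SyncTable,
    allele_index,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageFilterConfig:
    """Coverage bounds applied per marker position and pool.

    min_coverage
        Lower A+T+C+G coverage bound; the default of 10 suits typical
        Pool-Seq depth, ``low_coverage()`` gives the 3-fold preset.
    max_coverage_percentile
        Upper bound as a quantile of the pool's genome-wide coverage
        distribution (computed over all sync records of that pool, not just
        marker positions).
    """

    min_coverage: int = 10
    max_coverage_percentile: float = 0.95

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.max_coverage_percentile < 1:
            raise ValueError("max_coverage_percentile must be in (0, 1)")

    @classmethod
    def low_coverage(cls) -> "CoverageFilterConfig":
        return cls(min_coverage=3)


@dataclass
class MarkerObservation:
    """Per-marker detail behind one frequency estimate."""

    pos: int
    inverted_count: int
    coverage: int
    frequency: float


@dataclass
class InversionFrequencyEstimate:
    """Mean marker-allele frequency of one inversion in one pool.

    ``frequency`` is NaN when no marker survived the coverage filters
    (an explicitly missing estimate, distinct from frequency zero).
    """

    pool: int
    inversion: str
    frequency: float
    n_markers_used: int
    n_markers_total: int
    n_missing_from_sync: int = 0
    per_marker: list[MarkerObservation] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_markers_used > 0


def pool_max_coverage(sync: SyncTable, pool: int, percentile: float = 0.95) -> int:
    """Genome-wide upper coverage threshold for one pool (nearest rank)."""
    cov = sync.coverage_matrix()[:, pool]
    return per_arm_coverage_percentile(cov, q=percentile)


def estimate_frequency(
    sync: SyncTable,
    markers: MarkerSet,
    cfg: CoverageFilterConfig = CoverageFilterConfig(),
    pools: list[int] | None = None,
    inversions: list[str] | None = None,
    coverage_weighted: bool = False,
) -> list[InversionFrequencyEstimate]:
    """Estimate per-pool inversion frequencies from sync counts.

    Parameters
    ----------
    coverage_weighted
        If true, weight each marker's frequency by its coverage instead of
        the default unweighted mean over markers.

    Marker positions absent from the sync table are dropped and counted in
    ``n_missing_from_sync`` (also logged).
    """
    if pools is None:
        pools = list(range(sync.n_pools))
    if inversions is None:
        inversions = markers.inversions
    index = sync.by_position()
    max_cov = {
        p: pool_max_coverage(sync, p, cfg.max_coverage_percentile) for p in pools
    }

    out: list[InversionFrequencyEstimate] = []
    for inversion in inversions:
        inv_markers = markers.markers_for(inversion)
        for pool in pools:
            obs: list[MarkerObservation] = []
            missing = 0
            for m in inv_markers:
                rec = index.get((m.chrom, m.pos))
                if rec is None:
                    missing += 1
                    continue
                cov = rec.nucleotide_coverage(pool)
                if cov < cfg.min_coverage or cov > max_cov[pool]:
                    continue
                k = int(rec.counts[pool, allele_index(m.inverted_allele)])
                obs.append(MarkerObservation(m.pos, k, cov, k / cov))
            if missing:
                logger.warning(
                    "%s pool %d: %d of %d marker positions absent from sync",
                    inversion, pool, missing, len(inv_markers),
                )
            if obs:
                freqs = np.array([o.frequency for o in obs])
                if coverage_weighted:
                    w = np.array([o.coverage for o in obs], dtype=float)
                    freq = float(np.average(freqs, weights=w))
                else:
                    freq = float(freqs.mean())
            else:
                freq = float("nan")
            out.append(
                InversionFrequencyEstimate(
                    pool=pool,
                    inversion=inversion,
                    frequency=freq,
                    n_markers_used=len(obs),
                    n_markers_total=len(inv_markers),
                    n_missing_from_sync=missing,
                    per_marker=obs,
                )
            )
    return out


def estimates_to_table(estimates: list[InversionFrequencyEstimate]) -> pd.DataFrame:
    """Tidy DataFrame (pool, inversion, n_markers_used, frequency)."""
    return pd.DataFrame(
        [
            (e.pool, e.inversion, e.n_markers_used, e.frequency)
            for e in estimates
        ],
        columns=["pool", "inversion", "n_markers_used", "frequency"],
    )


def karyotype_frequency(
    table: KaryotypeCountTable, population: str, inversion: str
) -> float:
    """Inversion frequency count/n from a karyotype count table row.

    Full precision is kept; rounding happens only at output formatting.
    """
    row = table.row(population)
    if inversion not in table.inversions:
        raise KeyError(f"unknown inversion {inversion!r}")
    return float(row[inversion]) / float(row["n"])
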