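"""Paternal-haplotype reconstruction from F1-hybrid sequencing.

Karyotyped males of unknown genotype are crossed to females of a reference
strain that is homozygous standard at every site. Sequencing an F1 larva then
exposes the father's contributed haplotype: at any site where the larva is
heterozygous, the non-reference allele must be paternal; where the larva is
homozygous reference, the paternal allele equals the reference.

Reliable calls require aggressive site filtering. Five criteria are applied
per site, in order, after removing sites that are residually polymorphic in
the maternal reference strain (minor allele frequency > 10% in reads from a
pool of reference females):

(i)   per-larva coverage below a minimum (default 15) — filtered;
(ii)  per-larva coverage above the 95th percentile of that larva's
      genome-wide coverage distribution on the same chromosome arm
      (mapping errors, duplications) — filtered;
(iii) alleles whose summed count across all larvae is below 20 — dropped;
(iv)  sites with more than two surviving alleles — reduced to the two most
      frequent (ties between rank 2 and 3 are flagged and filtered);
(v)   at heterozygous larvae, both retained allele counts must fall within
      the central 90% exact binomial interval for an expected frequency of
      50% at that larva's coverage — otherwise filtered.

Boundary counts of the binomial interval are retained (inclusive limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from poolinv.io_formats import NUCLEOTIDES, ValidationError

#: Filter criteria labels, in application order.
CRITERIA = ("ref_poly", "i", "ii", "iii", "iv", "v", "inconsistent")


@dataclass(frozen=True)
class FilterParams:
    """Tunables of the five-criterion site filter.

    min_coverage
        Criterion (i) lower coverage bound; a site needs at least this many
        reads in a larva to be callable there.
    max_ref_maf
        Sites with reference-strain minor allele frequency above this are
        excluded outright (residual maternal heterozygosity).
    min_allele_count
        Criterion (iii): alleles below this summed count across all larvae
        are dropped as probable sequencing error.
    binom_level
        Criterion (v): central exact binomial interval mass at p = 0.5.
    coverage_percentile
        Criterion (ii): per-arm upper coverage quantile.
    """

    min_coverage: int = 15
    max_ref_maf: float = 0.10
    min_allele_count: int = 20
    binom_level: float = 0.90
    coverage_percentile: float = 0.95


@dataclass(frozen=True)
class F1SiteCounts:
    """Per-larva nucleotide counts at one site.

    ``counts`` has shape ``(n_larvae, 4)`` in A, T, C, G order.
    """

    chrom: str
    pos: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValidationError("F1 counts must have shape (n_larvae, 4)")
        if (counts < 0).any():
            raise ValidationError("negative allele count")
        object.__setattr__(self, "counts", counts)

    @property
    def n_larvae(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SiteVerdict:
    """Per-larva filter outcome at one site.

    ``status`` is ``"pass"`` or the failing criterion label; ``alleles`` are
    the site-level retained alleles (at most two, A/T/C/G indices).
    """

    chrom: str
    pos: int
    status: tuple[str, ...]
    alleles: tuple[int, ...]


@dataclass(frozen=True)
class PaternalHaplotypeCall:
    chrom: str
    pos: int
    larva: int
    allele: str  # "N" when filtered
    status: str  # "called" or "filtered(<criterion>)"


def binomial_interval(coverage: int, level: float = 0.90, p: float = 0.5) -> tuple[int, int]:
    """Central equal-tailed exact binomial acceptance interval.

    Returns the inclusive ``(k_lo, k_hi)`` such that a count ``k`` is accepted
    iff ``P(X <= k) >= alpha/2`` and ``P(X >= k) >= alpha/2`` for
    ``X ~ Binomial(coverage, p)``. For p = 0.5 the interval is symmetric
    around ``coverage / 2``.
    """
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    alpha = 1.0 - level
    dist = stats.binom(coverage, p)
    ks = np.arange(coverage + 1)
    cdf = dist.cdf(ks)
    # P(X >= k) = 1 - CDF(k-1) = sf(k-1)
    sf = dist.sf(ks - 1)
    ok = (cdf >= alpha / 2) & (sf >= alpha / 2)
    accepted = ks[ok]
    if accepted.size == 0:  # cannot happen for level < 1
        raise ValueError("empty acceptance region")
    return int(accepted[0]), int(accepted[-1])


def per_arm_coverage_percentile(coverages: Sequence[int], q: float = 0.95) -> int:
    """Nearest-rank (inclusive) percentile of an integer coverage stream.

    Returns the smallest observed coverage value ``t`` such that at least a
    fraction ``q`` of the observations are ``<= t``. Being an observed value,
    the threshold is exactly reproducible on integer data.
    """
    arr = np.sort(np.asarray(coverages))
    if arr.size == 0:
        raise ValueError("empty coverage stream")
    if not 0 < q <= 1:
        raise ValueError("percentile must be in (0, 1]")
    rank = int(np.ceil(q * arr.size)) - 1
    return int(arr[rank])


def filter_site(
    counts: F1SiteCounts,
    coverage_p95: Sequence[int],
    params: FilterParams = FilterParams(),
    ref_maf: float | None = None,
) -> SiteVerdict:
    """Apply the five filter criteria at one site.

    Parameters
    ----------
    counts
        Per-larva allele counts.
    coverage_p95
        Per-larva upper coverage threshold for this site's chromosome arm
        (criterion ii), one value per larva.
    ref_maf
        Minor allele frequency of this position in the reference-strain
        pool, if the position is polymorphic there; ``None`` otherwise.
    """
    n = counts.n_larvae
    thresholds = np.asarray(coverage_p95, dtype=np.int64)
    if thresholds.shape != (n,):
        raise ValueError(
            f"need one per-arm coverage threshold per larva ({n}), "
            f"got shape {thresholds.shape}"
        )
    status = ["pass"] * n

    if ref_maf is not None and ref_maf > params.max_ref_maf:
        return SiteVerdict(counts.chrom, counts.pos, ("ref_poly",) * n, ())

    cov = counts.coverage
    for larva in range(n):
        if cov[larva] < params.min_coverage:
            status[larva] = "i"
        elif cov[larva] > thresholds[larva]:
            status[larva] = "ii"

    # (iii) allele support summed over all larvae sequenced
    totals = counts.counts.sum(axis=0)
    alive = totals >= params.min_allele_count
    present = totals > 0
    kept = np.where(alive & present)[0]

    # (iv) more than two alleles: keep the two most frequent; tie between the
    # 2nd and 3rd ranked allele is ambiguous -> site filtered
    if kept.size > 2:
        order = kept[np.argsort(totals[kept])[::-1]]
        if totals[order[1]] == totals[order[2]]:
            return SiteVerdict(
                counts.chrom, counts.pos, tuple("iv" if s == "pass" else s for s in status), ()
            )
        kept = np.sort(order[:2])

    if kept.size == 0:
        return SiteVerdict(
            counts.chrom, counts.pos, tuple("iii" if s == "pass" else s for s in status), ()
        )

    # (v) heterozygote plausibility per larva, on the retained alleles only
    for larva in range(n):
        if status[larva] != "pass":
            continue
        c = counts.counts[larva, kept]
        observed = c > 0
        if observed.sum() < 2:
            continue  # homozygous for one retained allele: (v) not applicable
        total = int(c.sum())
        k_lo, k_hi = binomial_interval(total, level=params.binom_level)
        if not all(k_lo <= int(x) <= k_hi for x in c):
            status[larva] = "v"

    return SiteVerdict(
        counts.chrom,
        counts.pos,
        tuple(status),
        tuple(int(k) for k in kept),
    )


def call_paternal_allele(
    counts: F1SiteCounts,
    verdict: SiteVerdict,
    ref_allele: str,
    params: FilterParams = FilterParams(),
) -> list[PaternalHaplotypeCall]:
    """Call the paternal allele for every larva passing the site filter.

    The mother is homozygous ``ref_allele``; a heterozygous larva therefore
    received the non-reference allele from the father, a homozygous-reference
    larva received the reference. A larva homozygous for a non-reference
    allele contradicts maternal homozygosity and is flagged inconsistent.

    A larva with any read support for an allele that criteria (iii)/(iv)
    dropped at the site level is filtered rather than coerced to a
    homozygous-reference call: its genotype may hinge on the untrusted
    allele (e.g. a heterozygote whose paternal allele fell below the
    site-wide minimum count). This keeps calls exact in the noiseless limit
    at the price of discarding larvae carrying stray error reads.
    """
    ref_idx = NUCLEOTIDES.index(ref_allele)
    calls: list[PaternalHaplotypeCall] = []

    def _filtered(larva: int, crit: str) -> PaternalHaplotypeCall:
        return PaternalHaplotypeCall(
            counts.chrom, counts.pos, larva, "N", f"filtered({crit})"
        )

    def _called(larva: int, allele_idx: int) -> PaternalHaplotypeCall:
        return PaternalHaplotypeCall(
            counts.chrom, counts.pos, larva, NUCLEOTIDES[allele_idx], "called"
        )

    for larva in range(counts.n_larvae):
        st = verdict.status[larva]
        if st != "pass":
            calls.append(_filtered(larva, st))
            continue
        row = counts.counts[larva]
        if any(row[k] > 0 for k in range(4) if k not in verdict.alleles):
            calls.append(_filtered(larva, "iii"))
            continue
        kept = [k for k in verdict.alleles if row[k] > 0]
        if len(kept) == 2:
            if ref_idx not in kept:
                # two non-reference alleles: inconsistent with maternal genotype
                calls.append(_filtered(larva, "inconsistent"))
            else:
                alt = next(k for k in kept if k != ref_idx)
                calls.append(_called(larva, alt))
        elif len(kept) == 1:
            if kept[0] == ref_idx:
                calls.append(_called(larva, ref_idx))
            else:
                calls.append(_filtered(larva, "inconsistent"))
        else:  # no retained allele observed in this larva
            calls.append(_filtered(larva, "iii"))
    return calls


def reconstruct_haplotypes(
    sites: Iterable[F1SiteCounts],
    ref_alleles: dict[tuple[str, int], str],
    coverage_thresholds: dict[str, Sequence[int]],
    params: FilterParams = FilterParams(),
    ref_polymorphisms: dict[tuple[str, int], float] | None = None,
) -> list[PaternalHaplotypeCall]:
    """Run the full per-site pipeline over a stream of F1 count records.

    ``coverage_thresholds`` maps chromosome arm -> per-larva criterion (ii)
    thresholds; ``ref_polymorphisms`` maps (chrom, pos) -> reference-strain
    minor allele frequency for positions polymorphic in the maternal strain.
    """
    ref_polymorphisms = ref_polymorphisms or {}
    calls: list[PaternalHaplotypeCall] = []
    for site in sites:
        key = (site.chrom, site.pos)
        try:
            thresholds = coverage_thresholds[site.chrom]
        except KeyError:
            raise ValueError(
                f"no per-arm coverage percentile configured for arm {site.chrom!r}"
            ) from None
        verdict = filter_site(
            site, thresholds, params=params, ref_maf=ref_polymorphisms.get(key)
        )
        calls.extend(call_paternal_allele(site, verdict, ref_alleles[key], params=params))
    return calls


def calls_to_table(calls: Sequence[PaternalHaplotypeCall]):
    """Long-format DataFrame (chrom, pos, larva, allele, status) of calls."""
    import pandas as pd

    return pd.DataFrame(
        [(c.chrom, c.pos, c.larva, c.allele, c.status) for c in calls],
        columns=["chrom", "pos", "larva", "allele", "status"],
    )
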