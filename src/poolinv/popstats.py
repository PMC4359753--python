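"""Arrangement-stratified diversity and linkage-disequilibrium statistics.

All functions operate on haplotype alignments: 2-D character arrays of shape
``(n_haplotypes, n_sites)`` over ``{A, C, G, T, N}`` with ``N`` as missing
data, plus a parallel vector of 1-based positions. Within-arrangement
nucleotide diversity (π) uses the unbiased site-frequency form

    π = (1 / L) * Σ_sites  n/(n-1) * (1 - Σ_a p_a²),

with ``n`` the informative haplotypes at the site and ``L`` the number of
accessible sites (those with ≥ 2 informative haplotypes); for a biallelic
site the summand reduces to ``n/(n-1) * 2 p (1-p)`` and the whole expression
to the mean pairwise difference per site. F_ST between arrangements is the
π-based Hudson-style estimator (π_total − π_within) / π_total with π_within
the unweighted mean of the two group diversities. LD is measured by r², and
the overall excess of LD inside an inverted region is summarized by the
ratio of mean r² between inverted and standard haplotypes after subsampling
the more frequent arrangement to match group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from poolinv.io_formats import BreakpointInterval
from poolinv.markers import MISSING

#: Warn below this group size; the estimators remain defined down to 2.
SMALL_GROUP_WARN = 5


def _as_alignment(haps) -> np.ndarray:
    arr = np.asarray(haps, dtype="<U1")
    if arr.ndim != 2:
        raise ValueError("haplotype alignment must be 2-D (haplotypes x sites)")
    return arr


def pi_per_site(haps) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased heterozygosity and accessibility mask.

    Returns ``(pi, accessible)`` where ``pi[j] = n/(n-1) (1 - Σ p²)`` at
    sites with ``n >= 2`` informative haplotypes, 0 elsewhere, and
    ``accessible[j]`` flags sites with ``n >= 2``.
    """
    arr = _as_alignment(haps)
    n_hap, n_sites = arr.shape
    pi = np.zeros(n_sites)
    accessible = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        col = arr[:, j]
        col = col[col != MISSING]
        n = col.size
        if n < 2:
            continue
        accessible[j] = True
        _, counts = np.unique(col, return_counts=True)
        p = counts / n
        pi[j] = n / (n - 1) * (1.0 - np.sum(p * p))
    return pi, accessible


def nucleotide_diversity(haps, denominator: int | None = None) -> float:
    """π of an alignment: summed per-site heterozygosity over the accessible
    site count (or an explicit ``denominator``, e.g. a nominal window length).

    Raises ``ValueError`` on fewer than two haplotypes; returns NaN when no
    site is accessible.
    """
    arr = _as_alignment(haps)
    if arr.shape[0] < 2:
        raise ValueError("pi requires at least 2 haplotypes")
    pi, accessible = pi_per_site(arr)
    L = int(accessible.sum()) if denominator is None else denominator
    if L == 0:
        return float("nan")
    return float(pi.sum() / L)


def _window_edges(positions: np.ndarray, window: int, arm_length: int | None):
    if window <= 0:
        raise ValueError("window must be positive")
    if arm_length is None:
        arm_length = int(positions.max()) if positions.size else window
    n_windows = int(np.ceil(arm_length / window))
    starts = np.arange(n_windows, dtype=np.int64) * window + 1
    return starts, starts + window - 1


def window_pi(
    haps,
    positions: Sequence[int],
    window: int = 100_000,
    arm_length: int | None = None,
    nominal_length: bool = False,
) -> pd.DataFrame:
    """π in nonoverlapping windows tiling the arm.

    ``nominal_length`` divides by the window size instead of the accessible
    site count (useful when the alignment truly covers every unmasked base).
    Windows without accessible sites carry NaN.
    """
    arr = _as_alignment(haps)
    if arr.shape[0] < 2:
        raise ValueError("pi requires at least 2 haplotypes")
    pos = np.asarray(positions, dtype=np.int64)
    starts, ends = _window_edges(pos, window, arm_length)
    pi, accessible = pi_per_site(arr)
    rows = []
    for s, e in zip(starts, ends):
        in_w = (pos >= s) & (pos <= e)
        L = window if nominal_length else int((accessible & in_w).sum())
        total = pi[in_w].sum()
        rows.append(
            {
                "start": int(s),
                "end": int(e),
                "pi": total / L if L > 0 else float("nan"),
                "n_sites": int((accessible & in_w).sum()),
            }
        )
    return pd.DataFrame(rows)


def hudson_fst(haps_a, haps_b) -> float:
    """π-based F_ST between two arrangement groups.

    F_ST = (π_total − π_within) / π_total with π_within the unweighted mean
    of the group diversities and π_total the diversity of the pooled
    haplotypes, all over the pooled accessible sites. Negative estimates are
    clamped to 0 (with a warning); NaN when π_total = 0.
    """
    a = _as_alignment(haps_a)
    b = _as_alignment(haps_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 haplotypes")
    if a.shape[0] < SMALL_GROUP_WARN or b.shape[0] < SMALL_GROUP_WARN:
        warnings.warn("group with fewer than 5 haplotypes: F_ST will be noisy")
    pooled = np.concatenate([a, b], axis=0)
    pi_pool, acc = pi_per_site(pooled)
    L = int(acc.sum())
    if L == 0:
        return float("nan")
    pi_a, _ = pi_per_site(a)
    pi_b, _ = pi_per_site(b)
    pi_total = pi_pool.sum() / L
    pi_within = (pi_a.sum() / L + pi_b.sum() / L) / 2.0
    if pi_total == 0:
        return float("nan")
    fst = (pi_total - pi_within) / pi_total
    if fst < 0:
        warnings.warn(f"negative F_ST estimate {fst:.4g} clamped to 0")
        return 0.0
    return float(fst)


def window_fst(
    haps_a,
    haps_b,
    positions: Sequence[int],
    window: int = 100_000,
    arm_length: int | None = None,
) -> pd.DataFrame:
    """Hudson-style F_ST in nonoverlapping windows tiling the arm."""
    a = _as_alignment(haps_a)
    b = _as_alignment(haps_b)
    pos = np.asarray(positions, dtype=np.int64)
    starts, ends = _window_edges(pos, window, arm_length)
    rows = []
    for s, e in zip(starts, ends):
        in_w = (pos >= s) & (pos <= e)
        if not in_w.any():
            rows.append({"start": int(s), "end": int(e), "fst": float("nan"), "n_sites": 0})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fst = hudson_fst(a[:, in_w], b[:, in_w])
        rows.append(
            {"start": int(s), "end": int(e), "fst": fst, "n_sites": int(in_w.sum())}
        )
    return pd.DataFrame(rows)


def _binary_encode(col: np.ndarray) -> np.ndarray | None:
    """Encode a biallelic column as 0/1 with NaN for missing; None if the
    column is not biallelic-polymorphic among informative haplotypes."""
    informative = col != MISSING
    alleles = np.unique(col[informative])
    if alleles.size != 2:
        return None
    x = np.full(col.shape, np.nan)
    x[informative] = (col[informative] == alleles[1]).astype(float)
    return x


def ld_r2(haps, site_i: int, site_j: int) -> float:
    """Squared allelic correlation r² between two sites.

    Haplotypes missing either allele are dropped pairwise. Returns NaN when
    either site is monomorphic among the retained haplotypes (r² is
    undefined there; such sites are excluded from sampling upstream).

        r² = (p_AB − p_A p_B)² / (p_A (1−p_A) p_B (1−p_B))
    """
    arr = _as_alignment(haps)
    x = _binary_encode(arr[:, site_i])
    y = _binary_encode(arr[:, site_j])
    if x is None or y is None:
        return float("nan")
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        return float("nan")
    p_a, p_b = x.mean(), y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (x * y).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def polymorphic_sites(haps) -> np.ndarray:
    """Indices of biallelic polymorphic sites (over informative haplotypes)."""
    arr = _as_alignment(haps)
    idx = [
        j for j in range(arr.shape[1]) if _binary_encode(arr[:, j]) is not None
    ]
    return np.asarray(idx, dtype=np.int64)


def mean_r2(haps, site_indices: Sequence[int]) -> float:
    """Mean r² over all pairs of the given sites (NaN pairs excluded)."""
    vals = [
        ld_r2(haps, i, j) for i, j in combinations(list(site_indices), 2)
    ]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class LDRatioResult:
    ratio: float
    mean_r2_inverted: float
    mean_r2_standard: float
    n_haplotypes: int
    n_snps: int


def ld_ratio(
    inverted_haps,
    standard_haps,
    positions: Sequence[int],
    interval: BreakpointInterval,
    n_snps: int = 5_000,
    seed: int | None = None,
) -> LDRatioResult:
    """Ratio of mean r² inside an inverted region, inverted over standard.

    r² depends strongly on sample size, so the more frequent arrangement is
    first subsampled (seeded) to match the other group. Polymorphic SNPs
    inside ``interval`` are then sampled (up to ``n_snps``, shared positions
    for both groups where possible) and mean pairwise r² is computed per
    group.
    """
    inv = _as_alignment(inverted_haps)
    std = _as_alignment(standard_haps)
    if min(inv.shape[0], std.shape[0]) < 2:
        raise ValueError("each arrangement group needs at least 2 haplotypes")
    rng = np.random.default_rng(seed)
    n = min(inv.shape[0], std.shape[0])
    if inv.shape[0] > n:
        inv = inv[rng.choice(inv.shape[0], size=n, replace=False)]
    if std.shape[0] > n:
        std = std[rng.choice(std.shape[0], size=n, replace=False)]

    pos = np.asarray(positions, dtype=np.int64)
    in_interval = (pos >= interval.start) & (pos <= interval.end)
    poly_inv = set(polymorphic_sites(inv).tolist())
    poly_std = set(polymorphic_sites(std).tolist())
    candidates_inv = [j for j in np.where(in_interval)[0] if j in poly_inv]
    candidates_std = [j for j in np.where(in_interval)[0] if j in poly_std]

    def _sample(cands: list[int]) -> list[int]:
        if len(cands) > n_snps:
            return sorted(rng.choice(cands, size=n_snps, replace=False).tolist())
        return cands

    r2_inv = mean_r2(inv, _sample(candidates_inv))
    r2_std = mean_r2(std, _sample(candidates_std))
    return LDRatioResult(
        ratio=r2_inv / r2_std,
        mean_r2_inverted=r2_inv,
        mean_r2_standard=r2_std,
        n_haplotypes=n,
        n_snps=n_snps,
    )


def ld_long_table(haps, site_indices: Sequence[int], positions, group: str) -> pd.DataFrame:
    """Long-format r² table (pos1, pos2, r2, group) for heatmap plotting."""
    pos = np.asarray(positions, dtype=np.int64)
    rows = []
    for i, j in combinations(list(site_indices), 2):
        rows.append((int(pos[i]), int(pos[j]), ld_r2(haps, i, j), group))
    return pd.DataFrame(rows, columns=["pos1", "pos2", "r2", "group"])
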