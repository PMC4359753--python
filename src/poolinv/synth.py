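"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage gets a generator that emulates the corresponding real
data while recording the truth needed to score results exactly:

* :func:`make_panel` — karyotyped haplotype panels carrying planted
  inversion-diagnostic fixed differences (breakpoint-clustered or uniform
  within the inverted region) on a background of shared polymorphism that is
  guaranteed non-diagnostic, with optional missing data;
* :func:`make_pools` — pooled nucleotide counts in sync layout, with
  Poisson (or negative-binomial) coverage and binomial sampling of the
  inverted allele at marker positions;
* :func:`make_f1` — per-larva read counts of F1 hybrids from a cross of a
  karyotyped father to a homozygous-reference mother, with a symmetric
  sequencing-error model;
* :func:`make_ld_panel` — arrangement groups with contrasting LD structure:
  inverted haplotypes copy whole founder haplotypes (recombination fully
  suppressed inside the inversion), standard haplotypes assort every site
  independently (free recombination);
* :func:`selection_trajectory` — replicated Wright--Fisher trajectories
  with a selection coefficient, for generating non-neutral test data.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from poolinv.io_formats import (
    BreakpointInterval,
    Marker,
    MarkerSet,
    NUCLEOTIDES,
    SyncRecord,
    SyncTable,
    arm_of_inversion,
)
from poolinv.haplorecon import F1SiteCounts
from poolinv.markers import MISSING, STANDARD, HaplotypePanel


@dataclass(frozen=True)
class SynthPanelConfig:
    """Layout of a synthetic karyotyped haplotype panel.

    arm_length
        Length of the chromosome arm in bp.
    n_standard, n_inverted
        Chromosomes per arrangement class.
    interval
        Inversion breakpoint interval (must lie within the arm).
    n_planted
        Number of planted diagnostic fixed differences.
    placement
        ``"uniform"`` spreads planted sites over the inverted region;
        ``"breakpoint"`` clusters them within ``cluster_bp`` of either
        breakpoint, mimicking inversions whose divergence is confined to
        the breakpoints.
    shared_snps
        Number of shared (non-diagnostic) polymorphic sites across the arm.
    missing_rate
        Independent per-genotype missing-data probability.
    """

    arm_length: int
    n_standard: int
    n_inverted: int
    interval: BreakpointInterval
    n_planted: int = 30
    placement: str = "uniform"
    cluster_bp: int = 100_000
    shared_snps: int = 1_000
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.interval.start < self.interval.end <= self.arm_length):
            raise ValueError("inversion interval must lie within the arm")
        if self.n_planted < 0 or self.shared_snps < 0:
            raise ValueError("site counts must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.placement not in ("uniform", "breakpoint"):
            raise ValueError("placement must be 'uniform' or 'breakpoint'")


@dataclass
class PanelTruth:
    """Ground truth behind a synthetic panel."""

    inversion: str
    planted: list[Marker] = field(default_factory=list)
    shared_positions: list[int] = field(default_factory=list)


def _draw_positions(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    """n distinct positions in [lo, hi]."""
    if hi - lo + 1 < n:
        raise ValueError("interval too small for requested number of sites")
    return rng.choice(np.arange(lo, hi + 1), size=n, replace=False)


def _is_diagnostic(col: np.ndarray, inv_mask: np.ndarray, informative_min: float) -> bool:
    """Would this panel column qualify as a fixed difference?"""
    inv = col[inv_mask]
    oth = col[~inv_mask]
    inv_inf = inv[inv != MISSING]
    oth_inf = oth[oth != MISSING]
    if inv_inf.size < informative_min * inv.size:
        return False
    if oth_inf.size < informative_min * oth.size:
        return False
    if inv_inf.size == 0 or oth_inf.size == 0:
        return False
    a_inv = set(inv_inf.tolist())
    a_oth = set(oth_inf.tolist())
    return len(a_inv) == 1 == len(a_oth) and a_inv != a_oth


def make_panel(
    cfg: SynthPanelConfig, inversion: str = "In(2L)t"
) -> tuple[HaplotypePanel, PanelTruth]:
    """Generate a karyotyped panel with planted fixed differences.

    Planted sites are fixed-different between the arrangement classes before
    masking. Shared sites get an allele frequency independent of karyotype
    and are re-drawn (keeping their missing-data mask) if sampling noise
    would leave them diagnostic, so the planted set is exactly the set of
    true markers.
    """
    rng = np.random.default_rng(cfg.seed)
    arm = arm_of_inversion(inversion)
    n_chrom = cfg.n_standard + cfg.n_inverted
    inv_mask = np.array([False] * cfg.n_standard + [True] * cfg.n_inverted)

    if cfg.placement == "uniform":
        planted_pos = _draw_positions(
            rng, cfg.n_planted, cfg.interval.start, cfg.interval.end
        )
    else:
        half = cfg.n_planted // 2
        left = _draw_positions(
            rng, half, cfg.interval.start,
            min(cfg.interval.start + cfg.cluster_bp, cfg.interval.end),
        )
        right = _draw_positions(
            rng, cfg.n_planted - half,
            max(cfg.interval.end - cfg.cluster_bp, cfg.interval.start),
            cfg.interval.end,
        )
        planted_pos = np.concatenate([left, right])

    taken = set(planted_pos.tolist())
    shared_pos: list[int] = []
    while len(shared_pos) < cfg.shared_snps:
        cand = int(rng.integers(1, cfg.arm_length + 1))
        if cand not in taken:
            taken.add(cand)
            shared_pos.append(cand)
    shared_pos_arr = np.array(sorted(shared_pos), dtype=np.int64)

    positions = np.sort(np.concatenate([planted_pos, shared_pos_arr]))
    pos_index = {int(p): i for i, p in enumerate(positions)}
    alleles = np.empty((positions.size, n_chrom), dtype="<U1")

    nucs = np.array(NUCLEOTIDES)
    truth = PanelTruth(inversion=inversion, shared_positions=shared_pos_arr.tolist())

    for p in sorted(int(x) for x in planted_pos):
        a, b = rng.choice(4, size=2, replace=False)
        i = pos_index[p]
        alleles[i, inv_mask] = nucs[a]
        alleles[i, ~inv_mask] = nucs[b]
        truth.planted.append(
            Marker(
                inversion=inversion,
                chrom=arm,
                pos=p,
                inverted_allele=str(nucs[a]),
                other_allele=str(nucs[b]),
            )
        )

    def _shared_column() -> np.ndarray:
        a, b = rng.choice(4, size=2, replace=False)
        f = rng.uniform(0.05, 0.95)
        return np.where(rng.random(n_chrom) < f, nucs[a], nucs[b])

    for p in shared_pos_arr:
        alleles[pos_index[int(p)], :] = _shared_column()

    mask = (
        rng.random(alleles.shape) < cfg.missing_rate
        if cfg.missing_rate > 0
        else np.zeros(alleles.shape, dtype=bool)
    )
    alleles[mask] = MISSING

    # guarantee shared sites stay non-diagnostic after masking
    for p in shared_pos_arr:
        i = pos_index[int(p)]
        for _ in range(1000):
            if not _is_diagnostic(alleles[i], inv_mask, informative_min=0.0):
                break
            col = _shared_column()
            col[mask[i]] = MISSING
            alleles[i] = col
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not de-diagnose a shared site")

    karyotypes = [STANDARD] * cfg.n_standard + [inversion] * cfg.n_inverted
    panel = HaplotypePanel(
        chrom=arm, positions=positions, alleles=alleles, karyotypes=karyotypes
    )
    return panel, truth


# ---------------------------------------------------------------------------
# pooled counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthPoolConfig:
    """Pooled-sequencing read model.

    frequencies
        True inversion frequency per pool.
    mean_coverage
        Mean depth; per-position coverage is Poisson (or negative binomial
        with ``nb_dispersion`` for overdispersion robustness checks).
    """

    frequencies: tuple[float, ...]
    mean_coverage: float = 30.0
    nb_dispersion: float | None = None
    n_background: int = 200
    background_freq: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def n_pools(self) -> int:
        return len(self.frequencies)


def _draw_coverage(rng: np.random.Generator, cfg: SynthPoolConfig, size: int) -> np.ndarray:
    if cfg.nb_dispersion is None:
        return rng.poisson(cfg.mean_coverage, size=size)
    r = cfg.nb_dispersion
    p = r / (r + cfg.mean_coverage)
    return rng.negative_binomial(r, p, size=size)


def make_pools(markers: MarkerSet, cfg: SynthPoolConfig) -> SyncTable:
    """Simulate a sync table over marker positions plus background sites.

    At a marker the inverted-allele count is Binomial(coverage, pool truth
    frequency) and the remainder goes to the marker's other allele.
    Background positions (on the same arm, outside the marker set) segregate
    at ``background_freq`` independent of the inversion and give the
    genome-wide coverage distribution some mass away from markers.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SyncRecord] = []

    all_markers = sorted(markers, key=lambda m: (m.chrom, m.pos))
    for m in all_markers:
        counts = np.zeros((cfg.n_pools, 6), dtype=np.int64)
        for pool, f in enumerate(cfg.frequencies):
            cov = int(_draw_coverage(rng, cfg, 1)[0])
            k = rng.binomial(cov, f)
            counts[pool, NUCLEOTIDES.index(m.inverted_allele)] = k
            counts[pool, NUCLEOTIDES.index(m.other_allele)] = cov - k
        records.append(
            SyncRecord(chrom=m.chrom, pos=m.pos, ref=m.other_allele, counts=counts)
        )

    if all_markers and cfg.n_background > 0:
        arm = all_markers[0].chrom
        used = {m.pos for m in all_markers}
        max_pos = max(used) + cfg.n_background * 10
        bg_pos = []
        while len(bg_pos) < cfg.n_background:
            cand = int(rng.integers(1, max_pos))
            if cand not in used:
                used.add(cand)
                bg_pos.append(cand)
        for p in sorted(bg_pos):
            a, b = rng.choice(4, size=2, replace=False)
            counts = np.zeros((cfg.n_pools, 6), dtype=np.int64)
            for pool in range(cfg.n_pools):
                cov = int(_draw_coverage(rng, cfg, 1)[0])
                k = rng.binomial(cov, cfg.background_freq)
                counts[pool, a] = k
                counts[pool, b] = cov - k
            records.append(
                SyncRecord(chrom=arm, pos=p, ref=str(np.array(NUCLEOTIDES)[b]), counts=counts)
            )

    records.sort(key=lambda r: (r.chrom, r.pos))
    return SyncTable(records)


# ---------------------------------------------------------------------------
# F1 hybrid read counts
# ---------------------------------------------------------------------------


def make_f1(
    fathers: np.ndarray,
    mother_ref: Sequence[str],
    positions: Sequence[int],
    chrom: str,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> list[F1SiteCounts]:
    """Simulate per-larva nucleotide counts for F1 hybrids.

    ``fathers`` is an ``(n_larvae, n_sites)`` array of paternal alleles;
    ``mother_ref`` the homozygous maternal (reference) allele per site.
    Reads at each site draw the paternal or maternal allele with equal
    probability; each read is then flipped to one of the three other bases
    with probability ``error_rate``. Coverage is Poisson(``coverage``) per
    larva and site.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    fathers = np.asarray(fathers, dtype="<U1")
    mother = np.asarray(mother_ref, dtype="<U1")
    n_larvae, n_sites = fathers.shape
    if mother.shape != (n_sites,) or len(positions) != n_sites:
        raise ValueError("fathers, mother_ref and positions disagree on n_sites")

    out: list[F1SiteCounts] = []
    nuc_idx = {a: i for i, a in enumerate(NUCLEOTIDES)}
    for s in range(n_sites):
        counts = np.zeros((n_larvae, 4), dtype=np.int64)
        for larva in range(n_larvae):
            cov = rng.poisson(coverage)
            n_pat = rng.binomial(cov, 0.5)
            for allele, n_reads in (
                (fathers[larva, s], n_pat),
                (mother[s], cov - n_pat),
            ):
                if n_reads == 0:
                    continue
                n_err = rng.binomial(n_reads, error_rate) if error_rate else 0
                counts[larva, nuc_idx[allele]] += n_reads - n_err
                if n_err:
                    others = [i for i in range(4) if i != nuc_idx[allele]]
                    err_alloc = rng.multinomial(n_err, [1 / 3] * 3)
                    for o, c in zip(others, err_alloc):
                        counts[larva, o] += c
        out.append(F1SiteCounts(chrom=chrom, pos=int(positions[s]), counts=counts))
    return out


# ---------------------------------------------------------------------------
# LD-structured panels
# ---------------------------------------------------------------------------


def make_ld_panel(
    n_haplotypes: int,
    n_sites: int,
    seed: int | None = None,
    suppressed_recombination: bool = True,
) -> np.ndarray:
    """Haplotype alignment with or without recombination structure.

    With suppressed recombination every haplotype is an intact copy of one
    of two founder haplotypes (differing at every site), as inside an
    inversion where crossing over in heterokaryotypes is eliminated: all
    site pairs are in complete LD. With free recombination each site
    assorts independently at frequency 0.5: site pairs are uncorrelated.
    """
    rng = np.random.default_rng(seed)
    nucs = np.array(NUCLEOTIDES)
    pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(n_sites)])
    founder_a = nucs[pairs[:, 0]]
    founder_b = nucs[pairs[:, 1]]
    if suppressed_recombination:
        which = rng.random(n_haplotypes) < 0.5
        # guarantee both founders present so sites stay polymorphic
        which[0], which[1 % n_haplotypes] = True, False
        return np.where(which[:, None], founder_a[None, :], founder_b[None, :])
    choose_a = rng.random((n_haplotypes, n_sites)) < 0.5
    return np.where(choose_a, founder_a[None, :], founder_b[None, :])


# ---------------------------------------------------------------------------
# trajectories with selection
# ---------------------------------------------------------------------------


def selection_trajectory(
    N: int,
    p0: float,
    s: float,
    generations: int,
    replicates: int = 3,
    seed: int | None = None,
    diploid: bool = True,
) -> np.ndarray:
    """Replicated Wright--Fisher trajectories with genic selection.

    Deterministic update p* = p(1+s) / (1 + p s) followed by binomial
    drift over the population's chromosome copies. Returns an array of
    shape ``(replicates, generations + 1)``; s = 0 recovers neutrality.
    """
    rng = np.random.default_rng(seed)
    n_copies = 2 * N if diploid else N
    traj = np.empty((replicates, generations + 1))
    traj[:, 0] = p0
    for r in range(replicates):
        p = p0
        for t in range(1, generations + 1):
            p_sel = p * (1 + s) / (1 + p * s)
            p = rng.binomial(n_copies, p_sel) / n_copies
            traj[r, t] = p
    return traj
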