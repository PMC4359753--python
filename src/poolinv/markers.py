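"""Discovery of inversion-diagnostic marker SNPs.

A marker for an inversion is a fixed difference on the inversion's
chromosome arm between all karyotyped chromosomes carrying the inversion and
all chromosomes not carrying it (standard arrangements pooled with any
overlapping inversions on the same arm). A position qualifies only when at
least a configurable fraction (default 80%) of chromosomes in *each*
arrangement class are informative (non-missing) there; missing data counts
against informativeness but never against fixation, which is evaluated over
the non-missing chromosomes only. Sites showing more than two alleles across
the pooled comparison are excluded — a fixed difference is biallelic by
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolinv.io_formats import (
    BreakpointInterval,
    Marker,
    MarkerSet,
    NUCLEOTIDES,
    ValidationError,
    arm_of_inversion,
)

#: Missing-data symbol in haplotype panels.
MISSING = "N"

#: Karyotype label of chromosomes without any inversion.
STANDARD = "Std"


@dataclass
class HaplotypePanel:
    """Karyotyped haplotypes over a set of variable positions.

    Attributes
    ----------
    chrom : str
        Chromosome arm of every position (one panel per arm).
    positions : numpy.ndarray
        1-based positions, strictly increasing, shape ``(n_sites,)``.
    alleles : numpy.ndarray
        ``(n_sites, n_chromosomes)`` array of single characters in
        ``{A, C, G, T, N}`` with ``N`` denoting missing data.
    karyotypes : list of str
        Per-chromosome arrangement label: ``"Std"`` or an inversion name
        whose arm matches ``chrom`` (e.g. ``"In(3R)C"``).
    ids : list of str
        Per-chromosome identifiers.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    karyotypes: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        n_sites, n_chrom = self.alleles.shape
        if self.positions.shape != (n_sites,):
            raise ValidationError("positions and allele matrix disagree on n_sites")
        if len(self.karyotypes) != n_chrom:
            raise ValidationError("one karyotype label required per chromosome")
        if not self.ids:
            self.ids = [f"hap{i}" for i in range(n_chrom)]
        valid = set(NUCLEOTIDES) | {MISSING}
        if not set(np.unique(self.alleles)) <= valid:
            bad = set(np.unique(self.alleles)) - valid
            raise ValidationError(f"invalid allele symbols in panel: {sorted(bad)}")
        for k in self.karyotypes:
            if k != STANDARD and arm_of_inversion(k) != self.chrom:
                raise ValidationError(
                    f"karyotype {k!r} does not belong to arm {self.chrom!r}"
                )

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[1]

    def group_mask(self, inversion: str) -> np.ndarray:
        """Boolean mask of chromosomes carrying ``inversion``."""
        return np.array([k == inversion for k in self.karyotypes])

    def subset(self, mask: np.ndarray) -> np.ndarray:
        """Allele matrix restricted to the chromosomes selected by ``mask``."""
        return self.alleles[:, mask]


def find_fixed_differences(
    panel: HaplotypePanel,
    inversion: str,
    informative_min: float = 0.80,
) -> list[Marker]:
    """Scan a panel for fixed differences diagnostic of ``inversion``.

    A site is returned iff (a) at least ``informative_min`` of chromosomes in
    each arrangement class are non-missing, (b) every informative inverted
    chromosome carries one allele, (c) every informative non-inverted
    chromosome carries one allele, and (d) the two alleles differ.

    Raises
    ------
    ValueError
        If the panel contains no carrier of ``inversion``, or no
        non-inverted chromosome on the arm.
    """
    if arm_of_inversion(inversion) != panel.chrom:
        raise ValueError(
            f"inversion {inversion} lies on arm {arm_of_inversion(inversion)}, "
            f"panel covers {panel.chrom}"
        )
    inv_mask = panel.group_mask(inversion)
    oth_mask = ~inv_mask  # standard plus overlapping inversions on this arm
    n_inv, n_oth = int(inv_mask.sum()), int(oth_mask.sum())
    if n_inv == 0:
        raise ValueError(f"panel contains no chromosome carrying {inversion}")
    if n_oth == 0:
        raise ValueError(f"panel contains no non-{inversion} chromosome")

    inv = panel.alleles[:, inv_mask]
    oth = panel.alleles[:, oth_mask]
    inv_inf = (inv != MISSING).sum(axis=1)
    oth_inf = (oth != MISSING).sum(axis=1)
    informative = (inv_inf >= informative_min * n_inv) & (
        oth_inf >= informative_min * n_oth
    )

    markers: list[Marker] = []
    for i in np.where(informative & (inv_inf > 0) & (oth_inf > 0))[0]:
        inv_alleles = set(inv[i][inv[i] != MISSING])
        oth_alleles = set(oth[i][oth[i] != MISSING])
        if len(inv_alleles) != 1 or len(oth_alleles) != 1:
            continue
        (a_inv,) = inv_alleles
        (a_oth,) = oth_alleles
        if a_inv == a_oth:
            continue
        markers.append(
            Marker(
                inversion=inversion,
                chrom=panel.chrom,
                pos=int(panel.positions[i]),
                inverted_allele=str(a_inv),
                other_allele=str(a_oth),
            )
        )
    return markers


def discover_markers(
    panels: dict[str, HaplotypePanel],
    inversions: list[str],
    informative_min: float = 0.80,
) -> MarkerSet:
    """Run :func:`find_fixed_differences` for several inversions at once."""
    out = MarkerSet()
    for inversion in inversions:
        arm = arm_of_inversion(inversion)
        for m in find_fixed_differences(panels[arm], inversion, informative_min):
            out.add(m)
    return out


def summarize_marker_distribution(
    markers: list[Marker] | MarkerSet,
    breakpoints: BreakpointInterval,
    window: int = 100_000,
    arm_length: int | None = None,
) -> pd.DataFrame:
    """Bin markers into nonoverlapping windows and tally inside vs outside
    the breakpoint interval.

    Returns a DataFrame with one row per window (``start``, ``end``,
    ``n_markers``) and attrs ``inside`` / ``outside`` carrying the tally
    against ``[breakpoints.start, breakpoints.end]``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ms = [m for m in markers]
    positions = np.array([m.pos for m in ms], dtype=np.int64)
    if arm_length is None:
        arm_length = int(max([breakpoints.end, *positions.tolist()] or [window]))
    n_windows = int(np.ceil(arm_length / window))
    counts = np.zeros(n_windows, dtype=np.int64)
    if positions.size:
        idx = (positions - 1) // window
        for i in idx:
            counts[i] += 1
    starts = np.arange(n_windows, dtype=np.int64) * window + 1
    df = pd.DataFrame(
        {"start": starts, "end": starts + window - 1, "n_markers": counts}
    )
    inside = int(sum(breakpoints.contains(int(p)) for p in positions))
    df.attrs["inside"] = inside
    df.attrs["outside"] = int(positions.size) - inside
    return df
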