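"""Statistical inference on inversion-frequency change.

Three procedures cover the study designs that arise in inversion
monitoring:

* replicated time-series (experimental evolution): a Cochran--Mantel--
  Haenszel test per marker SNP, stratified by replicate population, on the
  2x2 table of (inverted allele, other allele) x (time point 1, time
  point 2); per-marker p-values are summarized by their arithmetic mean;
* unreplicated spatial series (latitudinal clines): a two-sided Fisher's
  exact test per marker between the lowest-latitude population and each
  other population, p-values combined across markers;
* karyotype counts across selection regimes: a fully factorial fixed-effects
  two-way ANOVA, frequency ~ inversion + regime + inversion x regime, on
  per-replicate count/n frequencies.

The mean of p-values is a descriptive summary, not a calibrated combined
test; it is labelled ``summary_p`` accordingly. Fisher's method is available
behind a flag for a calibrated alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from poolinv.io_formats import KaryotypeCountTable, MarkerSet, SyncTable, allele_index


# ---------------------------------------------------------------------------
# Cochran–Mantel–Haenszel
# ---------------------------------------------------------------------------


@dataclass
class CmhResult:
    statistic: float
    p_value: float
    n_strata_used: int
    n_strata_dropped: int = 0


def _validate_2x2(table: np.ndarray) -> None:
    if table.shape != (2, 2):
        raise ValueError("each stratum must be a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative cell count")


def cmh_test(strata: Sequence[np.ndarray], correction: bool = False) -> CmhResult:
    """Cochran--Mantel--Haenszel chi-square test over K 2x2 strata.

    Each stratum is a 2x2 array with rows = alleles (inverted, other) and
    columns = time points. The statistic is

        chi² = (|Σ_k (a_k − E_k)| − c)² / Σ_k Var_k,  1 df,

    with a_k the top-left cell, E_k = row1_k col1_k / n_k,
    Var_k = row1_k row2_k col1_k col2_k / (n_k² (n_k − 1)), and c = 1/2 with
    the continuity correction, 0 without (the default).

    Strata with an empty margin carry no information and are dropped with a
    warning; if all strata are dropped the result is NaN/NaN.
    """
    num = 0.0
    var = 0.0
    used = dropped = 0
    for table in strata:
        t = np.asarray(table, dtype=float)
        _validate_2x2(t)
        n = t.sum()
        r1, r2 = t.sum(axis=1)
        c1, c2 = t.sum(axis=0)
        if n <= 1 or 0 in (r1, r2, c1, c2):
            dropped += 1
            continue
        num += t[0, 0] - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    if dropped:
        warnings.warn(f"dropped {dropped} stratum/strata with an empty margin")
    if used == 0 or var == 0:
        return CmhResult(float("nan"), float("nan"), used, dropped)
    c = 0.5 if correction else 0.0
    stat = (max(abs(num) - c, 0.0)) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return CmhResult(float(stat), p, used, dropped)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fet_clinal(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 allele-count table.

    Rows are (inverted, other) alleles, columns the two populations
    compared (lowest-latitude baseline vs another population). A table with
    an empty margin is uninformative and returns p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    _validate_2x2(t)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("2x2 table with an empty margin: p set to 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def combine_p(p_values: Sequence[float], method: str = "mean") -> float:
    """Combine per-marker p-values.

    ``method="mean"`` (default) returns the arithmetic mean — a summary of
    the per-marker evidence, not a calibrated test. ``method="fisher"``
    applies Fisher's method (-2 Σ log p against chi²_{2k}).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "mean":
        return float(p.mean())
    if method == "fisher":
        return float(stats.combine_pvalues(p, method="fisher")[1])
    raise ValueError(f"unknown combination method {method!r}")


@dataclass
class TestSummary:
    """Per-inversion marker-test results with their mean-p summary."""

    inversion: str
    per_marker_p: list[float] = field(default_factory=list)
    per_marker_stat: list[float] = field(default_factory=list)
    summary_p: float = float("nan")


def _marker_counts(rec, pool: int, marker) -> tuple[int, int]:
    k = int(rec.counts[pool, allele_index(marker.inverted_allele)])
    cov = rec.nucleotide_coverage(pool)
    return k, cov - k


def cmh_per_marker(
    sync: SyncTable,
    markers: MarkerSet,
    strata_pools: Sequence[tuple[int, int]],
    inversion: str,
    correction: bool = False,
) -> TestSummary:
    """CMH test per marker across replicate strata, summarized by mean p.

    ``strata_pools`` lists, per replicate, the (time point 1, time point 2)
    pool column indices in the sync table.
    """
    index = sync.by_position()
    out = TestSummary(inversion=inversion)
    for m in markers.markers_for(inversion):
        rec = index.get((m.chrom, m.pos))
        if rec is None:
            continue
        tables = []
        for p0, p1 in strata_pools:
            inv0, oth0 = _marker_counts(rec, p0, m)
            inv1, oth1 = _marker_counts(rec, p1, m)
            tables.append(np.array([[inv0, inv1], [oth0, oth1]]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cmh_test(tables, correction=correction)
        if not np.isnan(res.p_value):
            out.per_marker_p.append(res.p_value)
            out.per_marker_stat.append(res.statistic)
    if out.per_marker_p:
        out.summary_p = combine_p(out.per_marker_p, method="mean")
    return out


def fet_per_marker(
    sync: SyncTable,
    markers: MarkerSet,
    baseline_pool: int,
    other_pool: int,
    inversion: str,
) -> TestSummary:
    """Per-marker FET between a baseline pool and one other pool."""
    index = sync.by_position()
    out = TestSummary(inversion=inversion)
    for m in markers.markers_for(inversion):
        rec = index.get((m.chrom, m.pos))
        if rec is None:
            continue
        inv0, oth0 = _marker_counts(rec, baseline_pool, m)
        inv1, oth1 = _marker_counts(rec, other_pool, m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fet_clinal(np.array([[inv0, inv1], [oth0, oth1]]))
        out.per_marker_p.append(p)
    if out.per_marker_p:
        out.summary_p = combine_p(out.per_marker_p, method="mean")
    return out


# ---------------------------------------------------------------------------
# Two-way ANOVA on karyotype frequencies
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """F statistics of the balanced two-way fixed-effects fit.

    For the 6 inversions x 2 regimes x 3 replicates layout the degrees of
    freedom are (5, 1, 5; 24); the design is balanced so the
    sums-of-squares type is immaterial.
    """

    f_inversion: float
    f_regime: float
    f_interaction: float
    df_inversion: int
    df_regime: int
    df_interaction: int
    df_residual: int
    p_inversion: float
    p_regime: float
    p_interaction: float


def anova_2way(frequencies: pd.DataFrame) -> AnovaResult:
    """Fully factorial fixed-effects two-way ANOVA on a balanced layout.

    ``frequencies`` needs columns ``inversion``, ``regime``, ``replicate``
    and ``frequency``, forming a complete balanced design (every inversion x
    regime cell with the same number of replicates).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"inversion", "regime", "replicate", "frequency"}
    if not required <= set(frequencies.columns):
        raise ValueError(f"need columns {sorted(required)}")
    cell_sizes = frequencies.groupby(["inversion", "regime"]).size()
    n_inv = frequencies["inversion"].nunique()
    n_reg = frequencies["regime"].nunique()
    if len(cell_sizes) != n_inv * n_reg or cell_sizes.nunique() != 1:
        raise ValueError("unbalanced or incomplete design")

    model = smf.ols("frequency ~ C(inversion) * C(regime)", data=frequencies).fit()
    table = sm.stats.anova_lm(model, typ=2)
    # an effect with zero sum of squares explains nothing: F = 0 by convention
    # (avoids 0/0 when the residual variance also vanishes)
    zero = table["sum_sq"] <= 1e-12 * max(float(table["sum_sq"].sum()), 1.0)
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "PR(>F)"] = 1.0
    inv_row = table.loc["C(inversion)"]
    reg_row = table.loc["C(regime)"]
    int_row = table.loc["C(inversion):C(regime)"]
    res_row = table.loc["Residual"]
    return AnovaResult(
        f_inversion=float(inv_row["F"]),
        f_regime=float(reg_row["F"]),
        f_interaction=float(int_row["F"]),
        df_inversion=int(inv_row["df"]),
        df_regime=int(reg_row["df"]),
        df_interaction=int(int_row["df"]),
        df_residual=int(res_row["df"]),
        p_inversion=float(inv_row["PR(>F)"]),
        p_regime=float(reg_row["PR(>F)"]),
        p_interaction=float(int_row["PR(>F)"]),
    )


def replicate_frequencies(
    table: KaryotypeCountTable,
    regimes: dict[str, Sequence[str]],
    round_to: int | None = None,
) -> pd.DataFrame:
    """Long-format per-replicate frequency table from karyotype counts.

    ``regimes`` maps a regime label to its replicate population labels,
    e.g. ``{"cold": ["Cold - R1", ...], "hot": [...]}``. Frequencies are
    exact count/n; ``round_to`` optionally rounds them (e.g. 2 to mimic
    published 2-decimal tables).
    """
    rows = []
    for regime, pops in regimes.items():
        for i, pop in enumerate(pops, start=1):
            row = table.row(pop)
            for inv in table.inversions:
                f = float(row[inv]) / float(row["n"])
                if round_to is not None:
                    f = round(f, round_to)
                rows.append(
                    {
                        "inversion": inv,
                        "regime": regime,
                        "replicate": i,
                        "frequency": f,
                    }
                )
    return pd.DataFrame(rows)
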