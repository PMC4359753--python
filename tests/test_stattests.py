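import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolinv.datasets import LNS_REGIMES, lns_karyotype_counts
from poolinv.stattests import (
    anova_2way,
    cmh_test,
    combine_p,
    fet_clinal,
    replicate_frequencies,
)


def random_null_strata(rng, k=3, n=50, p=0.3):
    tables = []
    for _ in range(k):
        k0, k1 = rng.binomial(n, p), rng.binomial(n, p)
        tables.append(np.array([[k0, k1], [n - k0, n - k1]]))
    return tables


class TestCmh:
    def test_no_change_gives_zero_statistic(self):
        t = np.array([[10, 10], [20, 20]])
        res = cmh_test([t, t, t])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_stratum_equals_chi_square(self, rng):
        """With one stratum the CMH score statistic is (n-1)/n times the
        Pearson chi-square; both are checked against scipy."""
        for _ in range(200):
            t = random_null_strata(rng, k=1)[0]
            if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            res = cmh_test([t])
            chi2 = stats.chi2_contingency(t, correction=False)[0]
            n = t.sum()
            assert res.statistic == pytest.approx(chi2 * (n - 1) / n, rel=1e-10)

    def test_matches_statsmodels_stratified_table(self, rng):
        from statsmodels.stats.contingency_tables import StratifiedTable

        for _ in range(50):
            tables = random_null_strata(rng, k=4)
            if any(0 in t.sum(axis=0) or 0 in t.sum(axis=1) for t in tables):
                continue
            res = cmh_test(tables)
            sm_res = StratifiedTable(
                [t.tolist() for t in tables]
            ).test_null_odds(correction=False)
            assert res.statistic == pytest.approx(float(sm_res.statistic), rel=1e-9)
            assert res.p_value == pytest.approx(float(sm_res.pvalue), rel=1e-9)

    def test_invariant_to_stratum_order_and_label_swaps(self, rng):
        tables = random_null_strata(rng, k=3)
        base = cmh_test(tables)
        shuffled = cmh_test(tables[::-1])
        assert base.statistic == pytest.approx(shuffled.statistic)
        swapped = cmh_test([t[::-1, ::-1] for t in tables])
        assert base.statistic == pytest.approx(swapped.statistic)

    def test_zero_margin_stratum_dropped(self):
        good = np.array([[12, 5], [8, 15]])
        degenerate = np.array([[0, 0], [10, 10]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cmh_test([good, degenerate])
        assert res.n_strata_dropped == 1
        assert res.statistic == pytest.approx(cmh_test([good]).statistic)

    def test_all_strata_dropped_gives_undefined(self):
        degenerate = np.array([[0, 0], [10, 10]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cmh_test([degenerate])
        assert np.isnan(res.p_value)

    def test_continuity_correction_flag(self):
        t = np.array([[12, 5], [8, 15]])
        assert cmh_test([t], correction=True).statistic < cmh_test([t]).statistic

    def test_type_i_error_calibration(self):
        """Empirical size at alpha=0.05 under the null, 10 000 simulations
        of 3 strata with 50-deep margins."""
        rng = np.random.default_rng(123)
        n_tests = 10_000
        rejections = 0
        for _ in range(n_tests):
            res = cmh_test(random_null_strata(rng))
            if not np.isnan(res.p_value) and res.p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_tests <= 0.065


class TestFet:
    def test_identical_proportions(self):
        assert fet_clinal(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_extreme_table_hypergeometric(self):
        p = fet_clinal(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / comb(20, 10))

    def test_empty_margin_is_one_with_flag(self):
        with pytest.warns(UserWarning):
            assert fet_clinal(np.array([[0, 0], [5, 7]])) == 1.0

    def test_transpose_symmetry(self, rng):
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            assert fet_clinal(t) == pytest.approx(fet_clinal(t.T))

    def test_matches_full_enumeration(self, rng):
        """Two-sided p equals summing probabilities of all tables at fixed
        margins that are no more likely than the observed one."""
        for _ in range(100):
            t = rng.integers(0, 13, size=(2, 2))
            r1, r2 = t.sum(axis=1)
            c1, c2 = t.sum(axis=0)
            if 0 in (r1, r2, c1, c2):
                continue
            n = t.sum()
            probs = {}
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs[a] = (
                    comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)
                )
            p_obs = probs[t[0, 0]]
            expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
            assert fet_clinal(t) == pytest.approx(expected, rel=1e-9)


class TestCombineP:
    def test_mean(self):
        assert combine_p([0.2, 0.4]) == pytest.approx(0.3)

    def test_single_value(self):
        assert combine_p([0.7]) == pytest.approx(0.7)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            combine_p([])

    def test_fisher_method_flag(self):
        p = combine_p([0.01, 0.02, 0.03], method="fisher")
        assert p == pytest.approx(
            stats.combine_pvalues([0.01, 0.02, 0.03], method="fisher")[1]
        )

    def test_mean_of_uniforms_concentrates_at_half(self, rng):
        means = [combine_p(rng.uniform(size=100)) for _ in range(1000)]
        assert 0.49 <= np.mean(means) <= 0.51


def anova_ss_oracle(y: np.ndarray):
    """Oracle: classical balanced two-way sums-of-squares decomposition.

    ``y`` has shape (a, b, r): factor A levels x factor B levels x reps.
    """
    a, b, r = y.shape
    grand = y.mean()
    ss_a = b * r * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
    ss_b = a * r * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
    cell = y.mean(axis=2)
    ss_ab = r * (
        (cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand) ** 2
    ).sum()
    ss_err = ((y - cell[:, :, None]) ** 2).sum()
    df_a, df_b = a - 1, b - 1
    df_ab, df_err = df_a * df_b, a * b * (r - 1)
    f_a = (ss_a / df_a) / (ss_err / df_err)
    f_b = (ss_b / df_b) / (ss_err / df_err)
    f_ab = (ss_ab / df_ab) / (ss_err / df_err)
    return f_a, f_b, f_ab


def _frame_from_cube(y):
    rows = []
    a, b, r = y.shape
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append(
                    {
                        "inversion": f"inv{i}",
                        "regime": f"reg{j}",
                        "replicate": k,
                        "frequency": y[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_equal_cells_give_zero_f(self):
        y = np.full((6, 2, 3), 0.25)
        y += np.array([0.0, 0.01, -0.01])[None, None, :]  # replicate noise only
        res = anova_2way(_frame_from_cube(y))
        assert res.f_inversion == 0.0
        assert res.f_interaction == 0.0

    def test_degrees_of_freedom_for_6x2x3(self, rng):
        y = rng.uniform(size=(6, 2, 3))
        res = anova_2way(_frame_from_cube(y))
        assert (res.df_inversion, res.df_regime, res.df_interaction, res.df_residual) == (
            5, 1, 5, 24,
        )

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(20):
            y = rng.uniform(size=(6, 2, 3))
            res = anova_2way(_frame_from_cube(y))
            f_a, f_b, f_ab = anova_ss_oracle(y)
            assert res.f_inversion == pytest.approx(f_a, rel=1e-9)
            assert res.f_regime == pytest.approx(f_b, rel=1e-9)
            assert res.f_interaction == pytest.approx(f_ab, rel=1e-9)

    def test_invariant_to_adding_constant(self, rng):
        y = rng.uniform(size=(6, 2, 3))
        r1 = anova_2way(_frame_from_cube(y))
        r2 = anova_2way(_frame_from_cube(y + 5.0))
        assert r1.f_inversion == pytest.approx(r2.f_inversion)
        assert r1.f_interaction == pytest.approx(r2.f_interaction)

    def test_unbalanced_design_rejected(self, rng):
        df = _frame_from_cube(rng.uniform(size=(6, 2, 3))).iloc[:-1]
        with pytest.raises(ValueError):
            anova_2way(df)

    def test_replicate_frequencies_layout(self):
        df = replicate_frequencies(lns_karyotype_counts(), LNS_REGIMES)
        assert len(df) == 36
        assert df["inversion"].nunique() == 6
        assert df["regime"].nunique() == 2
        # spot value: Hot - R1 In(3R)C = 19/42
        val = df.query("inversion == 'In(3R)C' and regime == 'hot' and replicate == 1")
        assert val["frequency"].iloc[0] == pytest.approx(19 / 42)
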