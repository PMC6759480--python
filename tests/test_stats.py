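"""ANOVA, Tukey letters and pairwise-complete correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rumenferm.stats import (
    anova_by_analyte,
    compact_letter_display,
    one_way_anova,
    pearson_pairwise,
    tukey_hsd,
)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 5), (1, 7), (0.5, 6), (2, 4)]]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert (res.df_between, res.df_within) == (3, 18)

    def test_identical_constant_groups_guarded(self):
        res = one_way_anova([np.full(5, 2.0), np.full(6, 2.0)])
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_rejects_degenerate_layouts(self):
        with pytest.raises(ValueError):
            one_way_anova([np.ones(5)])
        with pytest.raises(ValueError):
            one_way_anova([np.ones(5), np.array([1.0])])

    def test_type_one_error_near_nominal(self):
        """Under the null, rejection rate at alpha=0.05 stays near 0.05."""
        rng = np.random.default_rng(20190918)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 6) for _ in range(5)]
            if one_way_anova(groups).p_value < 0.05 :
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        pvals = [
            one_way_anova([rng.normal(0, 1, 6) for _ in range(4)]).p_value
            for _ in range(1000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def random_cld_case(rng):
    k = int(rng.integers(2, 7))
    shift = rng.choice([0.0, 1.0, 4.0], size=k)
    groups = {
        f"g{i}": rng.normal(shift[i], 1.0, int(rng.integers(3, 9))) for i in range(k)
    }
    return groups


class TestTukey:
    def test_identical_groups_share_single_letter(self):
        groups = {g: np.array([5.0, 5.1, 4.9, 5.0]) for g in "abc"}
        res = tukey_hsd(groups)
        assert set(res.letters.values()) == {"a"}

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(5)
        groups = {"lo": rng.normal(0, 0.1, 6), "hi": rng.normal(10, 0.1, 6)}
        res = tukey_hsd(groups)
        assert res.letters["hi"] != res.letters["lo"]
        assert {res.letters["hi"], res.letters["lo"]} == {"a", "b"}

    def test_pairwise_p_matches_studentized_range(self):
        """Tukey-Kramer p recomputed directly from the studentized-range law."""
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(i, 1.0, 5 + i) for i, g in enumerate("abc")}
        res = tukey_hsd(groups)
        samples = list(groups.values())
        k = len(samples)
        df = sum(len(s) - 1 for s in samples)
        mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
        for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
            si, sj = samples[i], samples[j]
            q = abs(si.mean() - sj.mean()) / np.sqrt(
                mse / 2 * (1 / len(si) + 1 / len(sj))
            )
            expected = sps.studentized_range.sf(q, k, df)
            assert res.pairwise_p[(gi, gj)] == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_tukey_not_more_liberal_than_t(self):
        """Adjusted pairwise p is >= the unadjusted pairwise t-test p
        computed from the same pooled error variance."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = random_cld_case(rng)
            res = tukey_hsd(groups)
            samples = list(groups.values())
            df = sum(len(s) - 1 for s in samples)
            mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
            for gi, gj in itertools.combinations(groups, 2):
                a, b = groups[gi], groups[gj]
                t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
                t_p = 2 * sps.t.sf(t, df)
                assert res.pairwise_p[(gi, gj)] >= t_p - 1e-10

    def test_letters_respect_pairwise_verdicts_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            groups = random_cld_case(rng)
            res = tukey_hsd(groups, alpha=0.05)
            for (gi, gj), p in res.pairwise_p.items():
                shared = set(res.letters[gi]) & set(res.letters[gj])
                if p < res.alpha:
                    assert not shared, (res.letters, gi, gj, p)
                else:
                    assert shared, (res.letters, gi, gj, p)

    def test_secondary_alpha_tier(self):
        rng = np.random.default_rng(9)
        groups = {"a": rng.normal(0, 1, 6), "b": rng.normal(1.2, 1, 6)}
        strict = tukey_hsd(groups, alpha=0.05)
        lax = tukey_hsd(groups, alpha=0.10)
        # a smaller alpha can only merge letters, never split further
        assert len(set(strict.letters.values())) <= len(set(lax.letters.values())) + 1

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": np.ones(4)})


def test_compact_letter_display_absorbs_subsets():
    letters = compact_letter_display(["a", "b", "c"], {frozenset(("a", "c"))})
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])


class TestPearsonPairwise:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df.x + 1
        res = pearson_pairwise(df)
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.n.loc["x", "y"] == 10

    def test_missing_cell_reduces_n(self):
        x = np.arange(10.0)
        y = -x.copy()
        y[3] = np.nan
        res = pearson_pairwise(pd.DataFrame({"x": x, "y": y}))
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)
        assert res.n.loc["x", "y"] == 9

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pearson_pairwise(df)
        assert np.allclose(res.r, res.r.T)
        assert np.allclose(np.diag(res.r), 1.0)

    def test_too_few_pairs_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                           "y": [1.0, 2.5, 3.0, 4.0]})
        res = pearson_pairwise(df)
        assert np.isnan(res.r.loc["x", "y"])
        assert res.n.loc["x", "y"] == 2

    def test_recovers_true_correlation(self):
        """Bivariate normal rho=0.7: mean estimate near 0.7 over repeats."""
        rng = np.random.default_rng(11)
        cov = [[1, 0.7], [0.7, 1]]
        rs = []
        for _ in range(300):
            xy = rng.multivariate_normal([0, 0], cov, size=60)
            res = pearson_pairwise(pd.DataFrame(xy, columns=["x", "y"]))
            rs.append(res.r.loc["x", "y"])
        assert np.mean(rs) == pytest.approx(0.7, abs=0.02)


def test_anova_by_analyte_long_output(default_simulation):
    _, records, _ = default_simulation
    anova, letters = anova_by_analyte(records, ["acetic_mM", "nh3_mM"])
    assert set(anova.analyte) == {"acetic_mM", "nh3_mM"}
    assert sorted(anova.time_h.unique()) == [4.0, 10.0, 24.0]
    assert anova.df_between.eq(9).all()  # 10 treatments
    one = letters[(letters.analyte == "acetic_mM") & (letters.time_h == 24.0)]
    assert len(one) == 10 and one.letters.str.len().ge(1).all()
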