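"""ANOVA, Tukey HSD, compact letters, Spearman, and the smoother."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aarisk import comparative


def _sig_frame(names, sig_pairs):
    mat = pd.DataFrame(False, index=names, columns=names)
    for a, b in sig_pairs:
        mat.loc[a, b] = mat.loc[b, a] = True
    return mat


def letters_ok(assignments, sig):
    """Defining CLD property: share a letter iff non-significant."""
    by_group = {a.group: a.letters for a in assignments}
    for a, b in itertools.combinations(by_group, 2):
        share = bool(by_group[a] & by_group[b])
        if sig.loc[a, b]:
            if share:
                return False
        elif not share:
            return False
    return all(by_group[g] for g in by_group)


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        groups = {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 7], "c": [5.0, 6, 8, 9]}
        res = comparative.anova_oneway(groups)
        # explicit between/within decomposition
        allv = np.concatenate([np.asarray(v, float) for v in groups.values()])
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 9)
        assert res.f == pytest.approx(f_oracle, rel=1e-12)
        assert res.p == pytest.approx(stats.f.sf(f_oracle, 2, 9), rel=1e-12)
        assert (res.df_between, res.df_resid) == (2, 9)

    def test_two_groups_f_is_t_squared(self):
        a, b = [1.0, 2, 3, 5], [4.0, 6, 7, 9]
        res = comparative.anova_oneway({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, rel=1e-12)

    def test_all_equal_is_degenerate_error(self):
        with pytest.raises(ValueError, match="identical"):
            comparative.anova_oneway({"a": [5.0, 5], "b": [5.0, 5]})

    def test_zero_residual_variance_flags_degenerate(self):
        res = comparative.anova_oneway({"a": [1.0, 1], "b": [2.0, 2]})
        assert res.degenerate and res.p == 0.0 and np.isinf(res.f)

    @pytest.mark.parametrize("groups", [
        {"a": [1.0, 2]},                       # one group
        {"a": [1.0], "b": [2.0, 3.0]},         # group with n < 2
    ])
    def test_invalid_groups_rejected(self, groups):
        with pytest.raises(ValueError):
            comparative.anova_oneway(groups)


class TestTukey:
    def test_far_separated_tight_groups_significant(self):
        res = comparative.tukey_hsd({"lo": [1.0, 1.1, 0.9], "hi": [10.0, 10.1, 9.9]},
                                    alpha=0.01)
        assert res.significant.loc["lo", "hi"]

    def test_diagonal_never_significant(self):
        res = comparative.tukey_hsd({"a": [1.0, 2, 3], "b": [2.0, 3, 4]})
        assert not np.diag(res.significant.values).any()

    def test_matrix_symmetry(self):
        res = comparative.tukey_hsd({"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [9.0, 8, 7]})
        assert res.pvalues.equals(res.pvalues.T)

    def test_matches_studentized_range_critical_value_oracle(self):
        """Tukey–Kramer decisions agree with direct critical-value lookup."""
        groups = {"a": [1.0, 2, 3, 4], "b": [2.5, 3.5, 4.5], "c": [8.0, 9, 10, 11]}
        alpha = 0.05
        res = comparative.tukey_hsd(groups, alpha=alpha)
        arrays = {k: np.asarray(v, float) for k, v in groups.items()}
        df = sum(a.size for a in arrays.values()) - len(arrays)
        msw = sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()) / df
        qcrit = stats.studentized_range.ppf(1 - alpha, len(arrays), df)
        for g1, g2 in itertools.combinations(arrays, 2):
            a, b = arrays[g1], arrays[g2]
            q = abs(a.mean() - b.mean()) / np.sqrt(msw / 2 * (1 / a.size + 1 / b.size))
            assert res.significant.loc[g1, g2] == (q > qcrit)


class TestCompactLetters:
    def test_no_separation_single_letter(self):
        sig = _sig_frame(list("abcd"), [])
        out = comparative.compact_letters(sig)
        assert all(a.label == "a" for a in out)

    def test_complete_separation_distinct_letters(self):
        names = list("wxyz")
        sig = _sig_frame(names, itertools.combinations(names, 2))
        out = comparative.compact_letters(sig)
        assert sorted(a.label for a in out) == ["a", "b", "c", "d"]
        assert [a.group for a in out] == names

    def test_survey_like_pattern(self, rng):
        """Three soft-bread-like groups share a letter; neither shares with
        the two far higher twice-baked-like groups."""
        means = {"g1": 57, "g2": 52, "g3": 61, "g4": 358, "g5": 384}
        sds = {"g1": 18, "g2": 8, "g3": 10, "g4": 36, "g5": 37}
        ns = {"g1": 22, "g2": 22, "g3": 22, "g4": 18, "g5": 18}
        groups = {k: rng.normal(means[k], sds[k], ns[k]) for k in means}
        res = comparative.tukey_hsd(groups, alpha=0.01)
        letters = {a.group: a.letters for a in comparative.compact_letters(res.significant)}
        assert letters["g1"] & letters["g2"] & letters["g3"]
        for low, high in itertools.product(("g1", "g2", "g3"), ("g4", "g5")):
            assert not (letters[low] & letters[high])

    def test_asymmetric_matrix_rejected(self):
        mat = _sig_frame(list("ab"), [])
        mat.loc["a", "b"] = True
        with pytest.raises(ValueError, match="symmetric"):
            comparative.compact_letters(mat)

    def test_self_significance_rejected(self):
        mat = _sig_frame(list("ab"), [])
        mat.loc["a", "a"] = True
        with pytest.raises(ValueError):
            comparative.compact_letters(mat)

    def test_chain_pattern_sound_and_complete(self):
        # a~b, b~c significant; a-c not: needs overlapping letter classes
        sig = _sig_frame(list("abc"), [("a", "b"), ("b", "c")])
        out = comparative.compact_letters(sig)
        assert letters_ok(out, sig)


class TestSpearman:
    def test_perfect_monotone_decreasing(self):
        rho, _ = comparative.spearman([1, 2, 3, 4, 5], [10, 8, 5, 3, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        rho, _ = comparative.spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_independent_inputs_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        rho, _ = comparative.spearman(x, y)
        assert abs(rho) < 0.1

    def test_rank_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho, _ = comparative.spearman(x, y)
        rho_ranks, _ = comparative.spearman(stats.rankdata(x), stats.rankdata(y))
        rho_neg, _ = comparative.spearman(x, -y)
        assert rho_ranks == pytest.approx(rho, rel=1e-12)
        assert rho_neg == pytest.approx(-rho, rel=1e-12)

    def test_exact_permutation_p_for_small_n(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        rho_t, p_t = comparative.spearman(x, y, method="t")
        rho_e, p_e = comparative.spearman(x, y, method="exact")
        assert rho_e == rho_t
        assert 0 < p_e <= 1
        # perfectly monotone n=4: only 2 of 4! orderings reach |rho|=1
        _, p_extreme = comparative.spearman([1, 2, 3, 4], [1, 2, 3, 4],
                                            method="exact")
        assert p_extreme == pytest.approx(2 / 24)

    @pytest.mark.parametrize("x,y", [
        ([1, 2], [3, 4]),            # too short
        ([1, 1, 1], [1, 2, 3]),      # constant x
        ([1, 2, 3], [5, 5, 5]),      # constant y
    ])
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            comparative.spearman(x, y)


class TestSmoother:
    def test_reproduces_linear_data(self):
        x = np.linspace(0, 10, 40)
        y = 3.0 * x + 1.0
        fit = comparative.fit_smoother(x, y, span=0.5, grid=np.linspace(1, 9, 9))
        assert np.allclose(fit.fitted, 3.0 * fit.grid + 1.0, atol=1e-6)

    def test_band_brackets_fit_pointwise(self, rng):
        x = rng.uniform(0, 10, 60)
        y = np.sin(x) + rng.normal(0, 0.2, 60)
        fit = comparative.fit_smoother(x, y)
        assert (fit.ci_low <= fit.fitted).all() and (fit.fitted <= fit.ci_high).all()

    def test_moisture_like_shape_recovered(self, rng):
        """Steep rise below 43% moisture, plateau above: the fitted curve is
        higher at 40% than at 46%."""
        x = rng.uniform(36, 48, 120)
        y = np.where(x < 43, 400 - 40 * (x - 36), 120.0) + rng.normal(0, 15, 120)
        fit = comparative.fit_smoother(x, y, span=0.4, grid=[40.0, 46.0])
        assert fit.fitted[0] > fit.fitted[1]

    def test_band_shrinks_with_tenfold_n(self, rng):
        def width(n):
            x = np.linspace(0, 10, n)
            y = 2 * x + rng.normal(0, 1.0, n)
            fit = comparative.fit_smoother(x, y, span=0.75, grid=[5.0])
            return float(fit.ci_high[0] - fit.ci_low[0])

        assert width(400) < width(40)

    def test_extrapolation_refused(self):
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="extrapolation"):
            comparative.fit_smoother(x, x, grid=[-1.0])

    @pytest.mark.parametrize("span", [0.0, -0.5, 1.5])
    def test_bad_span_rejected(self, span):
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError, match="span"):
            comparative.fit_smoother(x, x, span=span)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            comparative.fit_smoother([1, 2, 3], [1, 2, 3])
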