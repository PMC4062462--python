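"""One-way ANOVA, Duncan's multiple range test, t-test, chi-square."""

import math

import numpy as np
import pytest
from scipy import stats

from polyacomp.errors import DegenerateInputError
from polyacomp.group_stats import (
    GroupSample,
    anova_oneway,
    chi_square_2x2,
    duncan_critical_q,
    duncan_letters_protected,
    duncan_mrt,
    t_test_equal_var,
)

OFFSETS = [-4, -2, 0, 2, 4]  # per-group deviations: SS = 40, df = 4


def group(name, mean, offsets=OFFSETS):
    return GroupSample(name, [mean + o for o in offsets])


class TestAnova:
    def test_identical_groups_give_F_zero(self):
        r = anova_oneway([GroupSample("a", [1, 2, 3]), GroupSample("b", [1, 2, 3])])
        assert r.F == 0.0 and r.p == 1.0

    def test_hand_computed_sums_of_squares(self):
        r = anova_oneway([GroupSample("a", [1, 2, 3]), GroupSample("b", [4, 5, 6])])
        assert r.F == pytest.approx(13.5)
        assert r.mse == pytest.approx(1.0)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        samples = [rng.normal(i * 0.3, 1, size=6) for i in range(4)]
        mine = anova_oneway([GroupSample(str(i), list(s))
                             for i, s in enumerate(samples)])
        ref = stats.f_oneway(*samples)
        assert mine.F == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_zero_both_variances_flagged_degenerate(self):
        r = anova_oneway([GroupSample("a", [2, 2]), GroupSample("b", [2, 2])])
        assert r.degenerate and r.F == 0 and r.p == 1

    def test_type_one_error_rate(self):
        """Null rejection rate at alpha=0.05 stays in [0.035, 0.065]."""
        rng = np.random.default_rng(2024)
        reps, k, n = 1000, 4, 8
        data = rng.normal(size=(reps, k, n))
        gm = data.mean(axis=2)
        grand = data.mean(axis=(1, 2))
        ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        F = (ssb / (k - 1)) / (ssw / (k * n - k))
        p = stats.f.sf(F, k - 1, k * n - k)
        rate = (p < 0.05).mean()
        assert 0.035 <= rate <= 0.065
        # spot-check the vectorized oracle against the implementation
        r0 = anova_oneway([GroupSample(str(i), list(data[0, i])) for i in range(k)])
        assert r0.F == pytest.approx(F[0])


class TestDuncan:
    def test_hand_stepped_textbook_fixture(self):
        """k=5 equal-n groups, MSE=10, df=20; ranges hand-stepped with
        published Duncan critical values (2.95/3.10/3.18/3.25) give
        letters A | B B B | C for means 30, 24, 23, 22, 14."""
        groups = [group("g30", 30), group("g24", 24), group("g23", 23),
                  group("g22", 22), group("g14", 14)]
        r = duncan_mrt(groups)
        assert r.mse == pytest.approx(10.0)
        assert r.df_error == 20
        assert r.order == ["g30", "g24", "g23", "g22", "g14"]
        assert r.letters == {"g30": "A", "g24": "B", "g23": "B",
                             "g22": "B", "g14": "C"}

    def test_two_well_separated_groups(self):
        r = duncan_mrt([group("lo", 0), group("hi", 1000)])
        assert r.letters == {"hi": "A", "lo": "B"}

    def test_degenerate_identical_groups_share_one_letter(self):
        gs = [GroupSample("a", [5, 5, 5]), GroupSample("b", [5, 5, 5])]
        r = duncan_mrt(gs)
        assert set(r.letters.values()) == {"A"}

    def test_letters_invariant_to_relabeling_and_shift(self):
        gs = [group("a", 30), group("b", 24), group("c", 23), group("d", 14)]
        base = duncan_mrt(gs)
        shifted = duncan_mrt([GroupSample(g.group_id, [v + 100 for v in g.values])
                              for g in gs])
        assert base.letters == shifted.letters
        relabeled = duncan_mrt([GroupSample("x" + g.group_id, g.values) for g in gs])
        assert {k[1:]: v for k, v in relabeled.letters.items()} == base.letters

    def test_letters_consistent_with_pairwise_decisions(self):
        """Groups share a letter iff not significantly different."""
        gs = [group("a", 30), group("b", 26), group("c", 23), group("d", 21),
              group("e", 14)]
        r = duncan_mrt(gs)
        for (g1, g2), nonsig in r.nonsig.items():
            shared = set(r.letters[g1]) & set(r.letters[g2])
            assert bool(shared) == nonsig

    def test_narrowest_range_matches_adjusted_lsd(self):
        """For balanced designs the p=2 Duncan decision equals an LSD
        comparison using the Duncan-adjusted critical value."""
        gs = [group("a", 24.0), group("b", 21.5), group("c", 10.0)]
        anova = anova_oneway(gs)
        r = duncan_mrt(gs, anova=anova)
        q2 = duncan_critical_q(0.05, 2, anova.df_within)
        lsd = q2 * math.sqrt(anova.mse / 5)
        assert r.nonsig[("a", "b")] == (24.0 - 21.5 <= lsd)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt([group("only", 1)])

    def test_published_studentized_range_quantile(self):
        # q(0.05, 2, 16) = 3.00 in standard tables
        assert stats.studentized_range.ppf(0.95, 2, 16) == pytest.approx(3.00, abs=5e-3)

    def test_unequal_n_uses_harmonic_mean(self):
        """Kramer extension: critical range uses the harmonic mean of
        the two compared group sizes."""
        a = GroupSample("a", [10 + o for o in OFFSETS])           # n=5
        b = GroupSample("b", [13 + o for o in [-2, 0, 2]])        # n=3
        anova = anova_oneway([a, b])
        r = duncan_mrt([a, b], anova=anova)
        n_h = 2 / (1 / 5 + 1 / 3)
        r2 = duncan_critical_q(0.05, 2, anova.df_within) * math.sqrt(anova.mse / n_h)
        assert r.nonsig[("b", "a")] == (3 <= r2)

    def test_protected_null_level_over_100_reps(self):
        """Groups drawn from one distribution share a single letter in
        >= 93% of seeded replicates (ANOVA-protected display)."""
        rng = np.random.default_rng(0)
        share = 0
        reps = 100
        for _ in range(reps):
            gs = [GroupSample(str(i), list(rng.normal(0, 1, size=6)))
                  for i in range(4)]
            r = duncan_letters_protected(gs)
            if len(set(r.letters.values())) == 1:
                share += 1
        assert share >= 93


class TestTTest:
    def test_identical_samples(self):
        r = t_test_equal_var([1, 2, 3], [1, 2, 3])
        assert r.t == 0 and r.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        r1, r2 = t_test_equal_var(a, b), t_test_equal_var(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == len(a) + len(b) - 2

    def test_zero_pooled_variance_convention(self):
        r = t_test_equal_var([2, 2], [2, 2])
        assert r.degenerate and r.p == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_equal_var([1], [1, 2])


class TestChiSquare:
    def test_closed_form_2x2(self):
        r = chi_square_2x2([[90, 10], [60, 40]])
        assert r.chi2 == pytest.approx(24.0)
        assert r.df == 1
        assert r.p == pytest.approx(stats.chi2.sf(24.0, 1))

    def test_identical_rows_give_zero(self):
        r = chi_square_2x2([[7, 3], [7, 3]])
        assert r.chi2 == 0 and r.p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square_2x2([[0, 5], [0, 7]])

    def test_null_p_values_roughly_uniform(self):
        """A-count contingency from two site sets with equal A rates."""
        rng = np.random.default_rng(77)
        ps = []
        n = 600
        for _ in range(400):
            a1 = rng.binomial(n, 0.3)
            a2 = rng.binomial(n, 0.3)
            ps.append(chi_square_2x2([[a1, n - a1], [a2, n - a2]]).p)
        d, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 1e-3

    def test_F_equals_t_squared_for_two_groups(self):
        a, b = [1.0, 3.0, 4.0, 6.0], [2.0, 5.0, 8.0]
        t = t_test_equal_var(a, b)
        f = anova_oneway([GroupSample("a", a), GroupSample("b", b)])
        assert f.F == pytest.approx(t.t ** 2)
        assert f.p == pytest.approx(t.p)
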