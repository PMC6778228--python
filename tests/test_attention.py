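"""AUROC, Cohen's D, factorial ANOVA and FDR against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from fefattn import (
    auroc,
    auroc_folding,
    bh_fdr,
    classify_modulation,
    cohens_d,
    factorial_anova,
)


class TestAuroc:
    def test_symmetry_on_identical_samples(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert auroc(x, x) == 0.5

    def test_fully_separated(self):
        assert auroc(np.array([10.0, 11.0]), np.array([1.0, 2.0])) == 1.0

    def test_hand_enumerated_pairs(self):
        # RF=[3,5,7], away=[2,4,6]: 6 of 9 pairs have RF > away
        assert auroc(np.array([3, 5, 7]), np.array([2, 4, 6])) == pytest.approx(6 / 9)

    def test_equals_rank_sum_statistic(self):
        """Pair counting agrees with U/(n1*n2) on random instances."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, 2)
            a = np.round(rng.normal(0, 1, n1), 1)  # rounding makes ties
            b = np.round(rng.normal(0.3, 1, n2), 1)
            u = mannwhitneyu(a, b, alternative="two-sided").statistic
            assert auroc(a, b) == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        assert auroc(np.exp(a), np.exp(b)) == pytest.approx(auroc(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([]), np.array([1.0]))


class TestAurocFolding:
    @pytest.mark.parametrize("x,expected", [(0.3, 0.7), (0.5, 0.5), (0.9, 0.9)])
    def test_fold(self, x, expected):
        assert auroc_folding(x) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            auroc_folding(1.2)


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])) == 0.0

    def test_hand_computed_unit_effect(self):
        # pooled SD of [2,3,4] vs [1,2,3] is 1, means differ by 1
        assert cohens_d(np.array([2, 3, 4]), np.array([1, 2, 3])) == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_flagged(self):
        assert np.isnan(cohens_d(np.array([1.0, 1.0]), np.array([1.0, 1.0])))


def _balanced_anova_oracle(df):
    """Brute-force sums of squares for a balanced full-factorial design.

    For balanced data Type-I/II/III coincide, so plain mean-contrast SS
    computed from condition means is an independent oracle for the
    statsmodels path.
    """
    y = df["y"].to_numpy()
    grand = y.mean()
    factors = ["A", "B", "C"]
    means = {}
    ss = {}
    for f in factors:
        m = df.groupby(f)["y"].mean()
        n_per = len(df) / len(m)
        ss[f] = float(n_per * ((m - grand) ** 2).sum())
        means[f] = m
    for i, f in enumerate(factors):
        for g in factors[i + 1:]:
            m2 = df.groupby([f, g])["y"].mean()
            n_per = len(df) / len(m2)
            raw = float(n_per * ((m2 - grand) ** 2).sum())
            ss[f + ":" + g] = raw - ss[f] - ss[g]
    m3 = df.groupby(factors)["y"].mean()
    n_per = len(df) / len(m3)
    raw3 = float(n_per * ((m3 - grand) ** 2).sum())
    ss["A:B:C"] = raw3 - sum(
        ss[k] for k in ("A", "B", "C", "A:B", "A:C", "B:C")
    )
    ss_resid = float(((y - df.groupby(factors)["y"].transform("mean")) ** 2).sum())
    df_resid = len(df) - len(m3)
    dfs = {"A": 2, "B": 1, "C": 1, "A:B": 2, "A:C": 2, "B:C": 1, "A:B:C": 2}
    f_stats = {
        k: (ss[k] / dfs[k]) / (ss_resid / df_resid) for k in ss
    }
    return f_stats


class TestFactorialAnova:
    def test_matches_brute_force_ss_on_balanced_table(self):
        rng = np.random.default_rng(21)
        rows = []
        for a in ("a1", "a2", "a3"):
            for b in ("b1", "b2"):
                for c in ("c1", "c2"):
                    for _ in range(5):
                        rows.append(dict(A=a, B=b, C=c, y=rng.normal()))
        df = pd.DataFrame(rows)
        f, p = factorial_anova(df["y"].to_numpy(), df[["A", "B", "C"]])
        oracle = _balanced_anova_oracle(df)
        for k, fv in oracle.items():
            assert f[k] == pytest.approx(fv, abs=1e-8), k

    def test_additive_balanced_design_has_zero_interaction(self):
        rows = []
        for i, a in enumerate(("a1", "a2")):
            for j, b in enumerate(("b1", "b2")):
                for r in range(3):
                    rows.append(dict(A=a, B=b, y=2.0 * i + 3.0 * j + 0.1 * r))
        df = pd.DataFrame(rows)
        f, _ = factorial_anova(df["y"].to_numpy(), df[["A", "B"]])
        assert f["A:B"] == pytest.approx(0.0, abs=1e-10)

    def test_single_level_factor_dropped(self):
        df = pd.DataFrame(
            dict(A=["a1", "a1", "a2", "a2"], B=["b"] * 4, y=[1.0, 2.0, 4.0, 5.0])
        )
        with pytest.warns(UserWarning, match="single level"):
            f, p = factorial_anova(df["y"].to_numpy(), df[["A", "B"]])
        assert set(f) == {"A"}


class TestClassifyModulation:
    def test_interaction_alone_flags_attention(self):
        p = {"attention": 0.2, "drug": 0.5, "attention:drug": 0.01}
        s = classify_modulation({}, p)
        assert s.attention_modulated and s.drug_modulated

    def test_marginal_p_does_not_flag(self):
        p = {"attention": 0.06, "drug": 0.3, "attention:drug": 0.05,
             "attention:direction": 0.9}
        s = classify_modulation({}, p)
        assert not s.attention_modulated

    def test_direction_effect_flags_neither(self):
        p = {"attention": 0.4, "drug": 0.6, "direction": 0.001,
             "attention:direction": 0.8}
        s = classify_modulation({}, p)
        assert not s.attention_modulated and not s.drug_modulated


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_matches_hand_step_up_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 20))
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            np.testing.assert_allclose(bh_fdr(p), adj, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
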