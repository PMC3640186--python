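"""Statistics layer: Spearman, transforms, ANOVA, filters, signatures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from landuse16s.stats import (
    AnalysisConfig,
    abundance_filter,
    arcsine_sqrt,
    fold_change,
    one_way_anova,
    signature_genera,
    spearman,
    two_way_anova,
    venn_partition,
)

from oracles import oracle_spearman_exact_p, oracle_two_way_ss


class TestSpearman:
    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)  # 1 - 6*4/(5*24)

    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_exact_p_for_n5(self):
        _, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert p == pytest.approx(16 / 120)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_exact_p_matches_enumeration(self, n, rng):
        for _ in range(3):
            x = rng.integers(0, 4, size=n).astype(float)  # ties on purpose
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            _, p = spearman(x, y)
            assert p == pytest.approx(oracle_spearman_exact_p(x, y))

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.permutations(list(range(6))))
    def test_monotone_transform_invariance(self, y):
        x = np.arange(6, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]):
            return
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y * 3 + 1)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)


class TestArcsine:
    def test_boundary_and_quarter(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(math.pi / 2)
        assert arcsine_sqrt(0.25) == pytest.approx(math.pi / 6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.5)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(arcsine_sqrt(grid)) > 0)


class TestOneWayAnova:
    def test_hand_decomposition(self):
        f, df, p = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)
        assert df == (1, 4)

    def test_identical_groups(self):
        f, _, _ = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0

    def test_zero_within_variance(self):
        f, _, p = one_way_anova([[1, 1], [2, 2]])
        assert math.isinf(f) and p == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])

    def test_equals_squared_t_statistic(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        f, _, p_f = one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic**2)
        assert p_f == pytest.approx(t.pvalue)


class TestTwoWayAnova:
    def test_additive_means_no_interaction(self):
        vals, fa, fb = [], [], []
        for a, row in enumerate([(10, 20), (30, 40)]):
            for b, mu in enumerate(row):
                vals += [mu, mu]
                fa += [a, a]
                fb += [b, b]
        tab = two_way_anova(vals, fa, fb)
        assert tab.loc["A:B", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_all_equal_values(self):
        tab = two_way_anova([5.0] * 8, [0, 0, 0, 0, 1, 1, 1, 1], [0, 0, 1, 1] * 2)
        assert (tab.loc[["A", "B", "A:B"], "F"] == 0).all()

    def test_matches_direct_ss_oracle(self, rng):
        fa = np.repeat([0, 1], 9)
        fb = np.tile(np.repeat([0, 1, 2], 3), 2)
        vals = rng.normal(size=18) + fa * 0.5 + fb * 0.2
        tab = two_way_anova(vals, fa, fb)
        ref = oracle_two_way_ss(vals, fa, fb)
        for eff in ("A", "B", "A:B"):
            assert tab.loc[eff, "F"] == pytest.approx(ref[eff])

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova([1, 2, 3, 4, 5], [0, 0, 1, 1, 1], [0, 1, 0, 1, 1])


class TestFilters:
    def test_abundance_floor(self):
        counts = pd.DataFrame({"s1": [6, 4], "s2": [0, 0]}, index=["hi", "lo"])
        sets = abundance_filter({"site": counts}, {"s1": 5000, "s2": 5000}, 0.0005)
        assert sets["site"] == {"hi"}  # 6/10000 passes, 4/10000 does not

    def test_zero_floor_keeps_everything(self):
        counts = pd.DataFrame({"s1": [1, 0]}, index=["a", "b"])
        sets = abundance_filter({"x": counts}, {"s1": 100}, 1e-12)
        assert sets["x"] == {"a"}  # never-observed genera have zero abundance


class TestVenn:
    def test_enumerated_regions(self):
        regions, shared = venn_partition(
            {"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g3"}}
        )
        assert regions == {"A": 1, "B": 0, "C": 0, "A&B": 1, "A&C": 0, "B&C": 0, "A&B&C": 1}
        assert shared == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        r, s = venn_partition({"A": {1}, "B": {1}, "C": {1}})
        assert r["A&B&C"] == 1 and s == 1.0
        r, s = venn_partition({"A": {1}, "B": {2}, "C": {3}})
        assert r["A&B&C"] == 0 and s == 0.0

    def test_requires_three_sets(self):
        with pytest.raises(ValueError):
            venn_partition({"A": set(), "B": set()})


class TestSignatures:
    def _tables(self, rhos, p=1e-4):
        sites = ["S1", "S2", "S3"]
        return {
            s: pd.DataFrame({"rho": [rhos[i]], "p": [p]}, index=["g"]) for i, s in enumerate(sites)
        }

    def test_positive_signature(self):
        sig = signature_genera(self._tables((0.7, 0.8, 0.6)), {s: {"g"} for s in "S1 S2 S3".split()})
        assert sig.loc["g", "direction"] == "positive"

    def test_one_weak_site_disqualifies(self):
        sig = signature_genera(self._tables((0.7, 0.8, 0.4)), {s: {"g"} for s in "S1 S2 S3".split()})
        assert sig.empty

    def test_negative_signature(self):
        sig = signature_genera(self._tables((-0.6, -0.7, -0.9)), {s: {"g"} for s in "S1 S2 S3".split()})
        assert sig.loc["g", "direction"] == "negative"

    def test_must_pass_abundance_filter_everywhere(self):
        abundant = {"S1": {"g"}, "S2": {"g"}, "S3": set()}
        sig = signature_genera(self._tables((0.7, 0.8, 0.9)), abundant)
        assert sig.empty


class TestFoldChange:
    def test_sevenfold_direction_down(self):
        ratio, fold, direction = fold_change(0.09, 0.63)
        assert ratio == pytest.approx(7.0)
        assert fold == 7 and direction == -1

    def test_equal_means(self):
        assert fold_change(0.5, 0.5) == (1.0, 1, 0)

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError, match="undefined fold"):
            fold_change(0.0, 1.0)

    def test_rounding_half_away(self):
        assert fold_change(2.5, 1.0)[1] == 3


def test_analysis_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(abundance_floor=0)
    with pytest.raises(ValueError):
        AnalysisConfig(rho_floor=1.5)
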