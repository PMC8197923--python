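import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from oracles import exact_kw_permutation_p, gg_epsilon_eig
from phenofish import stats as st


class TestKruskalWallis:
    def test_textbook_three_groups(self):
        kw = st.kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6],
                                "c": [7, 8, 9]})
        assert kw["H"] == pytest.approx(7.2)
        assert kw["df"] == 2

    def test_all_identical_values(self):
        kw = st.kruskal_wallis({"a": [5, 5], "b": [5, 5, 5]})
        assert kw["H"] == 0.0
        assert kw["p"] == 1.0

    def test_tie_correction_matches_scipy(self, rng):
        for _ in range(20):
            groups = {f"g{i}": rng.integers(0, 5, rng.integers(3, 8)).astype(float)
                      for i in range(3)}
            if all(len(set(np.concatenate(list(groups.values())))) == 1
                   for _ in [0]):
                continue
            ours = st.kruskal_wallis(groups)
            ref = sps.kruskal(*groups.values())
            assert ours["H"] == pytest.approx(ref.statistic, abs=1e-10)
            assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_permutation_p_matches_enumeration(self, seed):
        """Exact-permutation p equals an independent full enumeration of
        label assignments (N <= 9)."""
        rng = np.random.default_rng(seed)
        sizes = [3, 3, 2]
        values = rng.integers(0, 6, sum(sizes)).astype(float)
        labels = sum(([f"g{i}"] * n for i, n in enumerate(sizes)), [])
        groups = {f"g{i}": [] for i in range(3)}
        for v, l in zip(values, labels):
            groups[l].append(v)
        ours = st.kruskal_wallis(groups, method="exact")
        H_oracle, p_oracle = exact_kw_permutation_p(values, labels)
        assert ours["H"] == pytest.approx(H_oracle, abs=1e-10)
        assert ours["p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 8) for i in range(3)}
        h1 = st.kruskal_wallis(groups)["H"]
        h2 = st.kruskal_wallis({k: np.exp(v) for k, v in groups.items()})["H"]
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestDunn:
    def test_identical_groups_z_zero(self):
        out = st.dunn_uncorrected({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_antisymmetry_under_label_swap(self, rng):
        g = {"a": rng.normal(0, 1, 6), "b": rng.normal(1, 1, 7)}
        z1 = st.dunn_uncorrected(g)["z"].iloc[0]
        z2 = st.dunn_uncorrected({"a": g["b"], "b": g["a"]})["z"].iloc[0]
        # labels resorted alphabetically, so swapping data flips the sign
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_hand_expanded_formula_with_ties(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0], "c": [4.0, 5.0]}
        pooled = [1, 2, 2, 2, 3, 4, 5]
        ranks = sps.rankdata(pooled)       # [1, 3, 3, 3, 5, 6, 7]
        N = 7
        Ra, Rb, Rc = np.mean(ranks[:3]), np.mean(ranks[3:5]), np.mean(ranks[5:])
        T = 3 ** 3 - 3                     # one tie group of size 3
        var_core = N * (N + 1) / 12 - T / (12 * (N - 1))
        z_ab = (Ra - Rb) / np.sqrt(var_core * (1 / 3 + 1 / 2))
        out = st.dunn_uncorrected(groups).set_index(["group_1", "group_2"])
        assert out.loc[("a", "b"), "z"] == pytest.approx(z_ab, abs=1e-12)

    def test_null_type_i_error_near_alpha(self):
        """Uncorrected Dunn per-pair rejection rate under the omnibus null
        stays within the binomial band around alpha over 2000 replicates."""
        rng = np.random.default_rng(11)
        B, rejections = 2000, 0
        for _ in range(B):
            g = {k: rng.normal(0, 1, 10) for k in ("a", "b", "c")}
            p = st.dunn_uncorrected(g).set_index(["group_1", "group_2"])
            rejections += p.loc[("a", "b"), "p"] < 0.05
        rate = rejections / B
        band = 3 * np.sqrt(0.05 * 0.95 / B)
        assert abs(rate - 0.05) < band


class TestRmAnovaGG:
    @staticmethod
    def _make(rng, n_per_group=8, k=4, groups=("X", "Y"), effect=0.0,
              cov=None):
        rows = []
        for gl in groups:
            for s in range(n_per_group):
                if cov is None:
                    eps = rng.normal(0, 1, k)
                else:
                    eps = rng.multivariate_normal(np.zeros(k), cov)
                base = rng.normal(0, 1)
                for b in range(k):
                    shift = effect * b if gl == "Y" else 0.0
                    rows.append({"subject": f"{gl}{s}", "group": gl,
                                 "bin": b, "value": base + shift + eps[b]})
        return pd.DataFrame(rows)

    def test_epsilon_identically_one_for_two_bins(self, rng):
        res = st.rm_anova_gg(self._make(rng, k=2))
        assert res["epsilon"] == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_matches_formula_oracle(self, rng):
        d = self._make(rng, k=5)
        res = st.rm_anova_gg(d)
        # rebuild the pooled within-group covariance independently
        wide = d.pivot_table(index=["subject", "group"], columns="bin",
                             values="value")
        resids = []
        for gl, sub in wide.groupby(level="group"):
            resids.append(sub.to_numpy() - sub.to_numpy().mean(axis=0))
        R = np.vstack(resids)
        S = R.T @ R / (len(wide) - wide.index.get_level_values("group")
                       .nunique())
        assert res["epsilon"] == pytest.approx(gg_epsilon_eig(S), abs=1e-10)

    def test_epsilon_near_one_under_compound_symmetry(self, rng):
        cov = 0.5 * np.ones((4, 4)) + 0.5 * np.eye(4)
        d = self._make(rng, n_per_group=150, k=4, cov=cov)
        res = st.rm_anova_gg(d)
        assert res["epsilon"] > 0.93

    def test_sum_of_squares_partitions_exactly(self, rng):
        res = st.rm_anova_gg(self._make(rng, k=4, effect=0.5))
        assert res["partition_check"] < 1e-9

    def test_detects_interaction(self, rng):
        res = st.rm_anova_gg(self._make(rng, n_per_group=20, k=4, effect=1.0))
        tab = res["anova"].set_index("effect")
        assert tab.loc["group x bin", "p"] < 0.01

    def test_epsilon_bounds(self, rng):
        for k in (3, 4, 6):
            res = st.rm_anova_gg(self._make(rng, k=k))
            assert 1.0 / (k - 1) - 1e-9 <= res["epsilon"] <= 1.0 + 1e-9


class TestLetters:
    def test_all_pairs_significant_distinct_letters(self):
        pp = pd.DataFrame([{"group_1": a, "group_2": b, "p": 0.001}
                           for a, b in itertools.combinations("abcd", 2)])
        lets = st.letters(pp)
        assert len({v for v in lets.values()}) == 4
        assert all(len(v) == 1 for v in lets.values())

    def test_no_pair_significant_single_letter(self):
        pp = pd.DataFrame([{"group_1": a, "group_2": b, "p": 0.9}
                           for a, b in itertools.combinations("abcd", 2)])
        lets = st.letters(pp)
        assert set(lets.values()) == {"a"}

    @given(hst.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_sharing_invariant_random_p_matrices(self, seed):
        """Groups share a letter iff their pairwise p >= alpha."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        names = [f"g{i}" for i in range(k)]
        rows = [{"group_1": a, "group_2": b, "p": float(rng.random())}
                for a, b in itertools.combinations(names, 2)]
        pp = pd.DataFrame(rows)
        lets = st.letters(pp, alpha=0.5)
        pmap = {(r["group_1"], r["group_2"]): r["p"] for r in rows}
        for (a, b), p in pmap.items():
            share = bool(set(lets[a]) & set(lets[b]))
            assert share == (p >= 0.5), (lets, pmap)


class TestCV:
    def test_constant_values(self):
        assert st.coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_computed(self):
        assert st.coefficient_of_variation([1, 3]) == pytest.approx(70.71068,
                                                                    abs=1e-4)

    def test_scale_invariance(self, rng):
        v = rng.uniform(1, 5, 20)
        assert st.coefficient_of_variation(v) == pytest.approx(
            st.coefficient_of_variation(3.7 * v), rel=1e-12)

    def test_zero_mean_flagged(self):
        assert np.isnan(st.coefficient_of_variation([-1, 1]))
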