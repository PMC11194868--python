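import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spatialprev.esda import (
    ClusterCrossTab,
    DegenerateInputError,
    DegenerateTableError,
    DegenerateTableWarning,
    chi_square_test,
    classify_lisa,
    crosstab_clusters,
    global_moran,
    local_moran,
    moran_mc,
)
from spatialprev.graph import generate_lattice
from spatialprev.synthetic import sample_leroux_field
from spatialprev.weights import build_weights


class TestGlobalMoran:
    def test_constant_vector_degenerate(self, w_grid33_row):
        with pytest.raises(DegenerateInputError):
            global_moran(np.ones(9), w_grid33_row)

    def test_alternating_cycle_is_minus_one(self, cycle4):
        w = build_weights(cycle4, "row_standardised")
        assert global_moran([1.0, -1.0, 1.0, -1.0], w) == pytest.approx(-1.0)

    def test_strong_leroux_field_is_positively_autocorrelated(self):
        g = generate_lattice(30, 30)
        wb = build_weights(g, "binary")
        wr = build_weights(g, "row_standardised")
        phi = sample_leroux_field(wb, rho=0.98, tau2=1.0, seed=7)
        assert global_moran(phi, wr) > 0.3

    def test_invariant_under_area_relabelling(self, rng):
        g = generate_lattice(5, 5)
        w = build_weights(g, "row_standardised")
        x = rng.standard_normal(25)
        I0 = global_moran(x, w)
        perm = rng.permutation(25)
        sub = g.subgraph(list(perm))
        wp = build_weights(sub, "row_standardised")
        assert global_moran(x[perm], wp) == pytest.approx(I0, rel=1e-12)


class TestMoranMC:
    def test_minimum_pseudo_p(self):
        # strongly clustered field: no permutation can beat it
        g = generate_lattice(6, 6)
        w = build_weights(g, "row_standardised")
        x = np.repeat([0.0, 10.0], 18) + np.arange(36) * 1e-3
        res = moran_mc(x, w, n_perm=999, seed=0)
        assert res.pseudo_p == pytest.approx(1 / 1000)
        assert res.n_perm == 999 and len(res.perm_values) == 999

    def test_determinism(self, w_grid33_row, rng):
        x = rng.standard_normal(9)
        p1 = moran_mc(x, w_grid33_row, 199, seed=42).pseudo_p
        p2 = moran_mc(x, w_grid33_row, 199, seed=42).pseudo_p
        assert p1 == p2

    def test_pseudo_p_bounds(self, w_grid33_row, rng):
        for _ in range(10):
            x = rng.standard_normal(9)
            p = moran_mc(x, w_grid33_row, 99, seed=1).pseudo_p
            assert 1 / 100 <= p <= 1

    def test_invalid_n_perm(self, w_grid33_row):
        with pytest.raises(ValueError):
            moran_mc(np.arange(9.0), w_grid33_row, n_perm=0)

    def test_exhaustive_matches_brute_force_enumeration(self):
        """Pseudo-p over all n! permutations equals an independently coded
        enumeration of the Moran statistic."""
        g = generate_lattice(2, 3)
        w = build_weights(g, "row_standardised")
        x = np.array([1.3, -0.2, 0.7, 2.1, -1.5, 0.4])
        res = moran_mc(x, w, exhaustive=True)

        # oracle: direct double-sum formula, explicit loops
        W = w.W.toarray()
        s0 = W.sum()
        n = x.size

        def moran(v):
            z = v - v.mean()
            num = sum(
                W[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
            )
            return n / s0 * num / (z @ z)

        obs = moran(x)
        expected = -1 / (n - 1)
        stats = [moran(np.array(p)) for p in itertools.permutations(x)]
        if obs >= expected:
            r = sum(s >= obs - 1e-12 for s in stats)
        else:
            r = sum(s <= obs + 1e-12 for s in stats)
        oracle_p = (r + 1) / (len(stats) + 1)
        assert res.pseudo_p == pytest.approx(oracle_p, abs=0)


class TestLocalMoran:
    def test_mean_of_local_equals_global(self, rng):
        g = generate_lattice(7, 7)
        w = build_weights(g, "row_standardised")
        for _ in range(3):
            x = rng.standard_normal(49)
            lisa = local_moran(x, w, n_perm=19, seed=0)
            assert lisa.local_i.mean() == pytest.approx(
                global_moran(x, w), rel=1e-10
            )

    def test_high_value_high_neighbourhood_positive(self):
        g = generate_lattice(3, 3)
        w = build_weights(g, "row_standardised")
        x = np.array([9.0, 9.0, 0.0, 9.0, 9.0, 0.0, 0.0, 0.0, 0.0])
        lisa = local_moran(x, w, n_perm=99, seed=0)
        assert lisa.local_i[0] > 0  # all of area 0's neighbours are high
        assert lisa.quadrant[0] == "HH"

    def test_exhaustive_conditional_matches_enumeration(self, path3):
        """Conditional-permutation p for a 6-node path equals exhaustive
        enumeration over all 5! arrangements of the other values."""
        g = generate_lattice(1, 6)
        w = build_weights(g, "row_standardised")
        x = np.array([0.3, 1.9, -0.7, 0.2, -1.4, 1.1])
        res = local_moran(x, w, exhaustive=True)

        z = (x - x.mean()) / x.std()
        n = x.size
        W = w.W.toarray()
        for i in range(n):
            others = np.delete(z, i)
            nbrs = np.flatnonzero(W[i])
            obs = z[i] * sum(W[i, j] * z[j] for j in nbrs)
            expected = -z[i] ** 2 / (n - 1)
            stats = []
            for perm in itertools.permutations(others):
                arranged = np.asarray(perm)
                full = np.insert(arranged, i, z[i])
                stats.append(z[i] * sum(W[i, j] * full[j] for j in nbrs))
            if obs >= expected:
                r = sum(s >= obs - 1e-12 for s in stats)
            else:
                r = sum(s <= obs + 1e-12 for s in stats)
            oracle_p = (r + 1) / (len(stats) + 1)
            assert res.pseudo_p[i] == pytest.approx(oracle_p, abs=1e-12), i


class TestClassifyLisa:
    def _mk(self, local_i, p, quadrant):
        from spatialprev.esda import LisaResult

        return LisaResult(
            local_i=np.asarray(local_i, float),
            pseudo_p=np.asarray(p, float),
            quadrant=np.asarray(quadrant, dtype=object),
            n_perm=999,
        )

    def test_significant_quadrants_labelled(self):
        lisa = self._mk([1.0, 1.0], [0.001, 0.2], ["HH", "HH"])
        out = classify_lisa(lisa, alpha=0.05)
        assert list(out.label) == ["high_high", "non_significant"]

    def test_invalid_alpha(self):
        lisa = self._mk([1.0], [0.01], ["HH"])
        for alpha in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                classify_lisa(lisa, alpha=alpha)

    def test_labels_partition_all_areas(self, rng):
        g = generate_lattice(6, 6)
        w = build_weights(g, "row_standardised")
        x = rng.standard_normal(36)
        out = classify_lisa(local_moran(x, w, 99, seed=3))
        allowed = {"high_high", "low_low", "high_low", "low_high", "non_significant"}
        assert set(out.label) <= allowed
        assert len(out.label) == 36


class TestCrossTab:
    def test_counts_only_hot_and_cold(self):
        labels = ["high_high", "low_low", "high_low", "non_significant"]
        cats = ["a", "a", "b", "b"]
        tab = crosstab_clusters(labels, cats, ["a", "b"])
        assert tab.counts.loc["a", "hot_spot"] == 1
        assert tab.counts.loc["a", "cold_spot"] == 1
        assert tab.counts.to_numpy().sum() == 2  # outliers/ns excluded

    def test_degenerate_margin_warns(self):
        with pytest.warns(DegenerateTableWarning):
            crosstab_clusters(
                ["non_significant", "non_significant"], ["a", "b"], ["a", "b"]
            )

    def test_published_hotspot_column_sums(self):
        from spatialprev.reference_tables import (
            indigenous_crosstab,
            interaction_crosstab,
            seifa_crosstab,
        )

        for tab in (seifa_crosstab(), indigenous_crosstab(), interaction_crosstab()):
            assert tab.counts["hot_spot"].sum() == 465
            assert tab.counts["cold_spot"].sum() == 548


class TestChiSquare:
    def test_perfect_independence(self):
        tab = ClusterCrossTab(
            counts=pd.DataFrame(
                {"cold_spot": [10, 10], "hot_spot": [10, 10]}, index=["x", "y"]
            )
        )
        out = chi_square_test(tab)
        assert out.chi2 == pytest.approx(0.0)
        assert out.p_value == pytest.approx(1.0)
        assert out.df == 1

    def test_zero_margin_rejected(self):
        tab = ClusterCrossTab(
            counts=pd.DataFrame(
                {"cold_spot": [1, 0], "hot_spot": [0, 0]}, index=["x", "y"]
            )
        )
        with pytest.raises(DegenerateTableError):
            chi_square_test(tab)

    def test_matches_scipy_oracle_on_published_tables(self):
        from spatialprev.reference_tables import indigenous_crosstab, seifa_crosstab

        for tab in (seifa_crosstab(), indigenous_crosstab()):
            out = chi_square_test(tab)
            c2, p, dof, _ = sps.chi2_contingency(
                tab.counts.to_numpy(), correction=False
            )
            assert out.chi2 == pytest.approx(c2, rel=1e-9)
            assert out.df == dof
            assert out.p_value == pytest.approx(p, rel=1e-9)

    def test_chi_square_calibrated_under_independence(self, rng):
        """With categories independent of labels, the p-value is uniform:
        check the rejection rate at the 10% level over replications."""
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            labels = rng.choice(["high_high", "low_low"], size=60)
            cats = rng.choice(["u", "v"], size=60)
            tab = crosstab_clusters(labels, cats, ["u", "v"])
            if (tab.counts.to_numpy().sum(axis=1) == 0).any():
                continue
            out = chi_square_test(tab)
            rejections += out.p_value <= 0.10
        rate = rejections / n_reps
        assert abs(rate - 0.10) < 2.5 * np.sqrt(0.1 * 0.9 / n_reps) + 0.01
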