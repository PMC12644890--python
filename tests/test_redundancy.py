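import itertools

import numpy as np
import pandas as pd
import pytest

from soilsucc import (SampleFrame, TraitMatrix, decoupling_regression,
                      functional_distances, hierarchical_partitioning, rao_q,
                      scale_traits, ternary_decompose, ternary_group_test)
from soilsucc.redundancy_framework import ScalingError

TOY_D = np.array([[0.0, 0.2, 1.0],
                  [0.2, 0.0, 0.5],
                  [1.0, 0.5, 0.0]])


def rao_oracle(p, d):
    """Brute-force O(n^2) double sum, independent of the vectorized path."""
    total = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            total += p[i] * p[j] * d[i][j]
    return total


class TestScaleTraits:
    def test_min_max_column(self):
        tm = TraitMatrix(values=pd.DataFrame({"g": [0.0, 5.0, 10.0]},
                                             index=list("abc")))
        out = scale_traits(tm)
        assert list(out.values["g"]) == [0.0, 0.5, 1.0]

    def test_constant_column_zeroed_with_warning(self):
        tm = TraitMatrix(values=pd.DataFrame({"g": [3.0, 3.0]},
                                             index=list("ab")))
        with pytest.warns(UserWarning):
            out = scale_traits(tm)
        assert (out.values["g"] == 0.0).all()

    def test_output_bounded(self, rng):
        tm = TraitMatrix(values=pd.DataFrame(
            rng.uniform(0, 10, size=(10, 6)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"g{j}" for j in range(6)]))
        out = scale_traits(tm).values.to_numpy()
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestFunctionalDistances:
    def test_identical_traits_zero_distance(self):
        tm = TraitMatrix(values=pd.DataFrame([[0.5, 0.5], [0.5, 0.5]],
                                             index=["a", "b"],
                                             columns=["g1", "g2"]))
        fdm = functional_distances(tm, ["a", "b"])
        assert fdm.degenerate and np.allclose(fdm.values, 0.0)

    def test_two_taxa_distance_forced_to_one(self):
        tm = TraitMatrix(values=pd.DataFrame([[0.0], [0.3]],
                                             index=["a", "b"], columns=["g"]))
        fdm = functional_distances(tm, ["a", "b"])
        assert fdm.values[0, 1] == pytest.approx(1.0)

    def test_triangle_scaled_by_maximum(self, triangle_traits):
        fdm = functional_distances(triangle_traits, ["A", "B", "C"])
        # raw distances 0.6, 1.0, 0.8 -> scaled by max 1.0
        assert fdm.values[0, 1] == pytest.approx(0.6, abs=1e-12)
        assert fdm.values[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert fdm.values[1, 2] == pytest.approx(0.8, abs=1e-12)

    def test_single_taxon_degenerate(self, triangle_traits):
        assert functional_distances(triangle_traits, ["A"]).degenerate


class TestRaoQ:
    def test_zero_distances_zero_q(self):
        assert rao_q([0.5, 0.5], np.zeros((2, 2))) == 0.0

    def test_two_taxa_closed_form(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_q([0.5, 0.5], d) == pytest.approx(0.5, abs=1e-12)

    def test_hand_value(self):
        assert rao_q([0.5, 0.3, 0.2], TOY_D) == pytest.approx(0.32, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 50))
            p = rng.dirichlet(np.ones(n))
            d = rng.uniform(0, 1, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            assert rao_q(p, d) == pytest.approx(rao_oracle(p, d), abs=1e-12)

    def test_invariant_to_zero_abundance_taxa(self, rng):
        p = np.array([0.6, 0.4, 0.0])
        q3 = rao_q(p, TOY_D)
        q2 = rao_q(p[:2], TOY_D[:2, :2])
        assert q3 == pytest.approx(q2, abs=1e-12)

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            rao_q([0.5, 0.5], np.zeros((3, 3)))


class TestTernaryDecompose:
    def test_single_taxon_limit(self):
        tc = ternary_decompose([1.0], np.zeros((1, 1)))
        assert tc.D == 1.0 and tc.Q == 0.0 and tc.R == 0.0 and tc.U is None

    def test_hand_decomposition(self):
        tc = ternary_decompose([0.5, 0.3, 0.2], TOY_D)
        assert tc.D == pytest.approx(0.38, abs=1e-12)
        assert tc.Q == pytest.approx(0.32, abs=1e-12)
        assert tc.R == pytest.approx(0.30, abs=1e-12)
        assert tc.U == pytest.approx(0.32 / 0.62, abs=1e-9)

    def test_identical_traits_maximal_redundancy(self):
        p = [0.4, 0.4, 0.2]
        tc = ternary_decompose(p, np.zeros((3, 3)))
        assert tc.Q == 0.0
        assert tc.R == pytest.approx(1.0 - tc.D, abs=1e-12)

    def test_closure_on_random_draws(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(n))
            d = rng.uniform(0, 1, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            d /= max(d.max(), 1e-12)
            tc = ternary_decompose(p, d)
            assert tc.D + tc.Q + tc.R == pytest.approx(1.0, abs=1e-12)
            assert tc.R >= 0.0

    def test_unscaled_distances_rejected(self):
        d = np.array([[0.0, 1.4], [1.4, 0.0]])
        with pytest.raises(ScalingError):
            ternary_decompose([0.5, 0.5], d)


class TestTernaryGroupTest:
    def test_identical_groups_degenerate(self):
        coords = pd.DataFrame({"D": [0.2] * 6, "Q": [0.5] * 6,
                               "R": [0.3] * 6},
                              index=[f"s{i}" for i in range(6)])
        res = ternary_group_test(coords, ["g"] * 3 + ["f"] * 3, n_perm=99,
                                 seed=0)
        assert res.degenerate

    def test_separated_groups_detected(self, rng):
        rows = []
        for i in range(8):
            q = 0.2 + rng.normal(0, 0.01)
            rows.append(("g%d" % i, 0.1, q, 0.9 - q, "grassland"))
        for i in range(8):
            q = 0.6 + rng.normal(0, 0.01)
            rows.append(("f%d" % i, 0.1, q, 0.9 - q, "forest"))
        df = pd.DataFrame(rows, columns=["sample_id", "D", "Q", "R", "eco"]
                          ).set_index("sample_id")
        res = ternary_group_test(df, df["eco"], n_perm=999, seed=0)
        assert res.p < 0.01


def _eco_frame(n_per: int) -> SampleFrame:
    rows = []
    for i in range(n_per):
        rows.append({"sample_id": f"g{i}", "stage": "managed"})
        rows.append({"sample_id": f"f{i}", "stage": "forest"})
    return SampleFrame(pd.DataFrame(rows).set_index("sample_id"))


class TestDecouplingRegression:
    def test_recovers_constructed_slope(self, rng):
        sf = _eco_frame(20)
        tax = pd.Series(rng.uniform(2, 5, size=40), index=sf.sample_ids)
        fun = 0.5 * tax + rng.normal(0, 1e-6, size=40)
        res = decoupling_regression(tax, fun, sf)
        for r in res:
            assert r.slope == pytest.approx(0.5, abs=1e-4)
            assert r.p_slope < 1e-6

    def test_identical_slopes_give_null_interaction(self, rng):
        sf = _eco_frame(20)
        tax = pd.Series(rng.uniform(2, 5, size=40), index=sf.sample_ids)
        fun = 1.0 + 0.3 * tax + pd.Series(rng.normal(0, 0.1, 40),
                                          index=sf.sample_ids)
        res = decoupling_regression(tax, fun, sf)
        assert res[0].p_difference > 0.05

    def test_ags_covariate_flag(self, rng):
        sf = _eco_frame(10)
        tax = pd.Series(rng.uniform(2, 5, size=20), index=sf.sample_ids)
        fun = 0.5 * tax + rng.normal(0, 0.1, size=20)
        ags = pd.Series(rng.uniform(3, 6, size=20), index=sf.sample_ids)
        res = decoupling_regression(tax, fun, sf, ags=ags)
        assert all(r.ags_adjusted for r in res)

    def test_constant_predictor_rejected(self, rng):
        sf = _eco_frame(10)
        tax = pd.Series(3.0, index=sf.sample_ids)
        fun = pd.Series(rng.normal(size=20), index=sf.sample_ids)
        with pytest.raises(ValueError):
            decoupling_regression(tax, fun, sf)


def hp_oracle(y, X):
    """Average marginal R^2 gain over all predictor orderings (LMG)."""
    y = np.asarray(y, float)
    X = (X - X.mean(0)) / X.std(0)
    n, k = X.shape
    ss_tot = ((y - y.mean()) ** 2).sum()

    def r2(cols):
        if not cols:
            return 0.0
        M = np.column_stack([np.ones(n), X[:, list(cols)]])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        return 1.0 - ((y - M @ beta) ** 2).sum() / ss_tot

    contrib = np.zeros(k)
    orders = list(itertools.permutations(range(k)))
    for order in orders:
        seen = []
        for i in order:
            gain = r2(seen + [i]) - r2(seen)
            contrib[i] += gain
            seen.append(i)
    return contrib / len(orders)


class TestHierarchicalPartitioning:
    def test_single_predictor_contribution_is_r2(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        out = hierarchical_partitioning(y, pd.DataFrame({"x": x}))
        resid_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out["x"] == pytest.approx(resid_r2, abs=1e-10)

    def test_orthogonal_predictors_get_marginal_r2(self):
        # orthogonal +-1 contrasts plus an orthogonal unmodeled component:
        # marginal R^2 0.3 and 0.2 -> contributions (0.3, 0.2), sum 0.5
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        x3 = x1 * x2  # orthogonal to both, plays the role of noise
        y = np.sqrt(0.3) * x1 + np.sqrt(0.2) * x2 + np.sqrt(0.5) * x3
        out = hierarchical_partitioning(y, pd.DataFrame({"a": x1, "b": x2}))
        assert out["a"] == pytest.approx(0.3, abs=1e-10)
        assert out["b"] == pytest.approx(0.2, abs=1e-10)
        assert out.sum() == pytest.approx(0.5, abs=1e-10)

    def test_matches_all_orderings_oracle(self, rng):
        for k in (2, 3, 4):
            X = rng.normal(size=(40, k))
            y = X @ rng.normal(size=k) + rng.normal(size=40)
            ours = hierarchical_partitioning(
                y, pd.DataFrame(X, columns=[f"p{i}" for i in range(k)]))
            oracle = hp_oracle(y, X)
            assert np.allclose(ours.to_numpy(), oracle, atol=1e-10)

    def test_contributions_sum_to_full_r2(self, rng):
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=60)
        out = hierarchical_partitioning(
            y, pd.DataFrame(X, columns=list("abcde")))
        M = np.column_stack([np.ones(60), (X - X.mean(0)) / X.std(0)])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        full = 1 - ((y - M @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert out.sum() == pytest.approx(full, abs=1e-10)

    def test_refuses_more_than_six(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 7)),
                         columns=[f"p{i}" for i in range(7)])
        with pytest.raises(ValueError, match="6"):
            hierarchical_partitioning(rng.normal(size=40), X)
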