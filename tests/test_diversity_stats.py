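import math

import numpy as np
import pandas as pd
import pytest

from soilsucc import (SampleFrame, bh_adjust, bray_curtis, hedges_g,
                      paired_anova_omega, partial_omega_sq, pcoa, permanova,
                      response_shape, shannon, simpson_dominance,
                      stage_comparisons)
from soilsucc.diversity_stats import (DegenerateDataError, DistanceMatrix,
                                      euclidean_matrix, kruskal_wallis)


class TestAlphaDiversity:
    @pytest.mark.parametrize("p, expected", [
        ([1, 0, 0], 0.0),
        ([0.25] * 4, math.log(4)),
        ([0.5, 0.25, 0.25], 1.0397207708399179),  # counts (2,1,1)
    ])
    def test_shannon_closed_forms(self, p, expected):
        assert shannon(p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("p, expected", [
        ([1.0], 1.0),
        ([0.2] * 5, 0.2),
        ([0.5, 0.3, 0.2], 0.38),
    ])
    def test_simpson_closed_forms(self, p, expected):
        assert simpson_dominance(p) == pytest.approx(expected, abs=1e-9)

    def test_shannon_bounded_by_log_richness(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(2, 30)))
            assert shannon(p) <= math.log((p > 0).sum()) + 1e-9

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            shannon([1.2, -0.2])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2], [1, 2]) == 0.0
        assert bray_curtis([1, 0], [0, 3]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([2, 1, 0], [1, 2, 1]) == pytest.approx(3 / 7, abs=1e-9)

    def test_both_zero_undefined(self):
        with pytest.raises(DegenerateDataError):
            bray_curtis([0, 0], [0, 0])


class TestPcoa:
    def test_recovers_line_configuration(self):
        pts = np.array([[0.0], [3.0], [4.0]])
        d = euclidean_matrix(pts, ["a", "b", "c"])
        res = pcoa(d, k=2)
        axis1 = res.coordinates["PCo1"].to_numpy()
        centered = pts[:, 0] - pts[:, 0].mean()
        assert np.allclose(np.abs(axis1), np.abs(centered), atol=1e-9)

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        pts = rng.normal(size=(6, 3))
        d = euclidean_matrix(pts, [f"s{i}" for i in range(6)])
        res = pcoa(d, k=2)
        a = -0.5 * d.values**2
        j = np.eye(6) - np.ones((6, 6)) / 6
        assert res.eigenvalues.sum() == pytest.approx(np.trace(j @ a @ j),
                                                      abs=1e-9)

    def test_identical_points_all_zero_eigenvalues(self):
        d = DistanceMatrix(values=np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(d, k=2)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_too_many_axes_rejected(self):
        d = DistanceMatrix(values=np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            pcoa(d, k=3)


def _toy_distance() -> DistanceMatrix:
    # groups AABB: within-group distance 1, between-group distance 2
    d = np.array([
        [0, 1, 2, 2],
        [1, 0, 2, 2],
        [2, 2, 0, 1],
        [2, 2, 1, 0],
    ], dtype=float)
    return DistanceMatrix(values=d, ids=list("abcd"))


class TestPermanova:
    def test_hand_partition_pseudo_F(self):
        res = permanova(_toy_distance(), ["A", "A", "B", "B"], n_perm=100,
                        seed=0)
        assert res.pseudo_F == pytest.approx(7.0, abs=1e-9)
        assert res.R2 == pytest.approx(3.5 / 4.5, abs=1e-9)

    def test_p_value_lower_bound(self):
        res = permanova(_toy_distance(), ["A", "A", "B", "B"], n_perm=99,
                        seed=0)
        assert res.p >= 1.0 / 100.0

    def test_degenerate_zero_distances_flagged(self):
        d = DistanceMatrix(values=np.zeros((4, 4)), ids=list("abcd"))
        res = permanova(d, ["A", "A", "B", "B"], n_perm=10, seed=0)
        assert res.degenerate and np.isnan(res.pseudo_F)

    def test_f_invariant_to_within_group_relabeling(self, rng):
        pts = rng.normal(size=(8, 3))
        d = euclidean_matrix(pts, [f"s{i}" for i in range(8)])
        labels = ["A"] * 4 + ["B"] * 4
        f1 = permanova(d, labels, n_perm=10, seed=0).pseudo_F
        # swap two samples within group A: distances permute consistently
        order = [1, 0, 2, 3, 4, 5, 6, 7]
        d2 = DistanceMatrix(values=d.values[np.ix_(order, order)],
                            ids=[d.ids[i] for i in order])
        f2 = permanova(d2, labels, n_perm=10, seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(_toy_distance(), ["A", "A", "A", "B"], n_perm=10, seed=0)

    def test_strata_restricts_permutations(self):
        # permuting only within pairs that hold one A and one B keeps group
        # sizes balanced; p must still honor its lower bound
        res = permanova(_toy_distance(), ["A", "B", "A", "B"], n_perm=99,
                        seed=1, strata=["p1", "p1", "p2", "p2"])
        assert 0 < res.p <= 1


class TestEffectSizes:
    def test_one_way_omega_toy(self):
        got = partial_omega_sq([1, 2, 3, 4, 5, 6],
                               ["a", "a", "a", "b", "b", "b"])
        assert got == pytest.approx(12.5 / 18.5, abs=1e-9)

    def test_omega_zero_point(self):
        # groups (0,2) and (sqrt2, 2+sqrt2): SS_eff = 2 = df_eff * MS_err,
        # the formula's zero point
        s2 = math.sqrt(2.0)
        got = partial_omega_sq([0.0, 2.0, s2, 2.0 + s2],
                               ["a", "a", "b", "b"])
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_paired_omega_blocks_absorb_pair_variance(self, paired_frame):
        values = pd.Series(
            {s: (10.0 if s.endswith("G") else 5.0) + int(s[1])
             for s in paired_frame.sample_ids})
        es = paired_anova_omega(values, paired_frame, "managed", n_boot=50,
                                seed=0)
        assert es.estimate > 0.9  # pure ecosystem effect within pairs
        assert es.ci_low <= es.estimate <= es.ci_high

    def test_paired_omega_constant_values_degenerate(self, paired_frame):
        values = pd.Series(1.0, index=paired_frame.sample_ids)
        with pytest.raises(DegenerateDataError):
            paired_anova_omega(values, paired_frame, "managed", n_boot=10,
                               seed=0)

    def test_hedges_toy_and_antisymmetry(self):
        es = hedges_g([1, 2, 3], [3, 4, 5])
        assert es.estimate == pytest.approx(-1.6, abs=1e-9)
        rev = hedges_g([3, 4, 5], [1, 2, 3])
        assert rev.estimate == pytest.approx(1.6, abs=1e-9)

    def test_hedges_identical_groups_zero(self):
        assert hedges_g([1, 2, 3], [2, 1, 3]).estimate == pytest.approx(0.0)

    def test_hedges_zero_spread_undefined(self):
        with pytest.raises(DegenerateDataError):
            hedges_g([1, 1], [1, 1])


class TestStageComparisons:
    def test_kruskal_hand_value(self):
        h, _ = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert h == pytest.approx(2.4, abs=1e-9)

    def test_two_stages_give_single_pairwise_row(self, paired_frame):
        values = pd.Series(np.arange(len(paired_frame.sample_ids), dtype=float),
                           index=paired_frame.sample_ids)
        sub = paired_frame.restrict(
            [s for s in paired_frame.sample_ids
             if paired_frame.stage[s] in ("managed", "forest")])
        out = stage_comparisons(values.loc[sub.sample_ids], sub,
                                test="wilcoxon_pairwise")
        assert len(out) == 1

    def test_all_tied_flagged_degenerate(self, paired_frame):
        values = pd.Series(1.0, index=paired_frame.sample_ids)
        out = stage_comparisons(values, paired_frame, test="kruskal_wallis")
        assert bool(out["degenerate"].iloc[0])


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03],
                           atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_order_equivariant(self, rng):
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _stage_frame(n_per_stage: int) -> SampleFrame:
    rows = []
    for st in ("managed", "recent", "late", "forest"):
        for i in range(n_per_stage):
            rows.append({"sample_id": f"{st}{i}", "stage": st})
    return SampleFrame(pd.DataFrame(rows).set_index("sample_id"))


class TestResponseShape:
    def test_equal_means_flat(self, rng):
        sf = _stage_frame(10)
        values = pd.Series(rng.normal(0, 1e-12, 40) + 5.0,
                           index=sf.sample_ids)
        assert response_shape(values, sf).shape == "flat"

    def test_linear_construction(self, rng):
        sf = _stage_frame(10)
        rank = sf.stage.cat.codes.astype(float)
        values = pd.Series(rank + rng.normal(0, 1e-6, 40),
                           index=sf.sample_ids)
        assert response_shape(values, sf).shape == "linear"

    def test_threshold_construction(self):
        sf = _stage_frame(10)
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            base = np.where(sf.stage == "forest", 3.0, 1.0)
            values = pd.Series(base + rng.normal(0, 0.1, 40),
                               index=sf.sample_ids)
            hits += response_shape(values, sf).shape == "threshold"
        assert hits >= 19

    def test_unimodal_construction(self, rng):
        sf = _stage_frame(10)
        rank = sf.stage.cat.codes.astype(float)
        values = pd.Series(-(rank - 1.5) ** 2 + rng.normal(0, 1e-6, 40),
                           index=sf.sample_ids)
        assert response_shape(values, sf).shape == "unimodal"

    def test_missing_stage_rejected(self, rng):
        sf = _stage_frame(5)
        keep = [s for s in sf.sample_ids if sf.stage[s] != "late"]
        sub = sf.restrict(keep)
        values = pd.Series(rng.normal(size=len(keep)), index=keep)
        with pytest.raises(ValueError):
            response_shape(values, sub)
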