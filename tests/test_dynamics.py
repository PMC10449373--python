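import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import exhaustive_mean_diff_p, exhaustive_permanova_p, pseudo_f_two_groups
from sodanet import (
    DistanceMatrix,
    OtuTable,
    bray_curtis,
    bc_matrix,
    collinearity_screen,
    compare_groups,
    distance_decay,
    mantel,
    permanova,
    turnover_series,
)


def _table(counts):
    return OtuTable(pd.DataFrame(counts, index=[f"S{i}" for i in range(len(counts))]))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 1, 0], [0, 0, 2], 1.0),
            ([1, 1, 0], [0, 1, 1], 0.5),
        ],
    )
    def test_closed_forms(self, u, v, expected):
        assert bray_curtis(u, v) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=10),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, u, data):
        v = data.draw(st.lists(st.integers(0, 50), min_size=len(u), max_size=len(u)))
        if sum(u) + sum(v) == 0:
            return
        d = bray_curtis(u, v)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(v, u))


class TestTurnover:
    def test_constant_community_zero(self):
        t = _table([[5, 5]] * 4)
        assert (turnover_series(t, [1, 2, 3, 4])["bc"] == 0).all()

    def test_missing_time_spans_gap(self):
        t = _table([[5, 5]] * 3)
        out = turnover_series(t, [6, 8, 9])  # time 7 missing
        assert list(zip(out["t1"], out["t2"])) == [(6, 8), (8, 9)]

    def test_complete_replacement_is_one(self):
        t = _table([[5, 0], [0, 5], [5, 0]])
        assert (turnover_series(t, [1, 2, 3])["bc"] == 1.0).all()

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            turnover_series(_table([[1, 1]]), [1])


class TestDistanceDecay:
    def test_lag_one_matches_turnover(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(1, 30, size=(6, 5)))
        decay = distance_decay(t, [1, 2, 3, 4, 5, 6])
        turn = turnover_series(t, [1, 2, 3, 4, 5, 6])["bc"].tolist()
        assert decay[1] == pytest.approx(turn)

    def test_group_sizes_count_all_pairs(self):
        t = _table(np.ones((5, 3)))
        decay = distance_decay(t, [1, 2, 4, 7, 8])
        assert sum(len(v) for v in decay.values()) == 5 * 4 // 2

    def test_periodic_community_dips_at_period(self):
        # period-4 composition cycle over 12 times: lag 4 pairs similar,
        # lag 2 pairs dissimilar
        cycle = [[10, 0, 0], [0, 10, 0], [0, 0, 10], [5, 5, 0]]
        t = _table([cycle[i % 4] for i in range(12)])
        decay = distance_decay(t, list(range(1, 13)))
        assert np.median(decay[4]) < np.median(decay[2])


class TestPermanova:
    def _separated(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(ids, d), ["A"] * 3 + ["B"] * 3

    def test_perfect_separation_r2_is_one(self):
        d, labels = self._separated()
        res = permanova(d, {"group": labels}, n_perm=99, seed=0)
        assert res.terms[0]["r2"] == pytest.approx(1.0)

    def test_single_level_rejected(self):
        d, _ = self._separated()
        with pytest.raises(ValueError, match="single level"):
            permanova(d, {"group": ["A"] * 6})

    def test_matches_classical_two_group_pseudo_f(self):
        rng = np.random.default_rng(3)
        x = rng.random((8, 4))
        d = bc_matrix(OtuTable(pd.DataFrame(x + 0.01, index=[f"S{i}" for i in range(8)])))
        labels = ["A"] * 4 + ["B"] * 4
        res = permanova(d, {"group": labels}, n_perm=9, seed=0)
        f_oracle, r2_oracle = pseudo_f_two_groups(d.d, labels)
        assert res.terms[0]["pseudo_f"] == pytest.approx(f_oracle)
        assert res.terms[0]["r2"] == pytest.approx(r2_oracle)

    def test_matches_skbio_one_way(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        x = rng.random((9, 5)) + 0.01
        ids = [f"S{i}" for i in range(9)]
        d = bc_matrix(OtuTable(pd.DataFrame(x, index=ids)))
        labels = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        res = permanova(d, {"group": labels}, n_perm=999, seed=1)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.d, ids), grouping=labels, permutations=999
        )
        assert res.terms[0]["pseudo_f"] == pytest.approx(sk["test statistic"])

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.random((6, 4)) + 0.01
        d = bc_matrix(OtuTable(pd.DataFrame(x, index=[f"S{i}" for i in range(6)])))
        labels = ["A", "A", "A", "B", "B", "B"]
        p_exact = exhaustive_permanova_p(d.d, labels)
        res = permanova(d, {"group": labels}, n_perm=19999, seed=2)
        assert res.terms[0]["p"] == pytest.approx(p_exact, abs=0.02)

    def test_two_way_r2_closes_to_one(self):
        rng = np.random.default_rng(9)
        x = rng.random((12, 6)) + 0.01
        d = bc_matrix(OtuTable(pd.DataFrame(x, index=[f"S{i}" for i in range(12)])))
        a = ["L1", "L2"] * 6
        b = ["sp"] * 6 + ["su"] * 6
        res = permanova(d, {"lake": a, "season": b}, n_perm=49, seed=0)
        total_r2 = sum(t["r2"] for t in res.terms) + res.residual_ss / res.total_ss
        assert total_r2 == pytest.approx(1.0)
        assert all(0 <= t["r2"] <= 1 for t in res.terms)

    def test_p_never_zero(self):
        d, labels = self._separated()
        res = permanova(d, {"group": labels}, n_perm=999, seed=0)
        assert res.terms[0]["p"] >= 1 / 1000


class TestMantel:
    def _dm(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((7, 4)) + 0.01
        return bc_matrix(OtuTable(pd.DataFrame(x, index=[f"S{i}" for i in range(7)])))

    def test_identity_r_one(self):
        d = self._dm(0)
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        d = self._dm(1)
        d2 = DistanceMatrix(d.ids, 0.5 * d.d + 0.1 * (1 - np.eye(len(d.ids))))
        r, _ = mantel(d, d2, n_perm=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d = self._dm(2)
        flat = DistanceMatrix(d.ids, 1 - np.eye(len(d.ids)))
        with pytest.raises(ValueError, match="constant"):
            mantel(d, flat)


class TestCollinearity:
    def test_duplicate_variable_flagged(self):
        env = pd.DataFrame({"x": [1.0, 2, 3, 4], "x_copy": [1.0, 2, 3, 4]})
        pairs = collinearity_screen(env)
        assert ("x", "x_copy", pytest.approx(1.0)) in pairs

    def test_orthogonal_design_not_flagged(self):
        env = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]}, dtype=float)
        assert collinearity_screen(env) == []

    def test_negative_correlation_flagged(self):
        env = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        pairs = collinearity_screen(env)
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(-1.0)

    def test_constant_variable_warns_and_excluded(self):
        env = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            pairs = collinearity_screen(env)
        assert pairs == []


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        v = [1.0, 2, 3, 1, 2, 3]
        p = compare_groups(v, ["a", "a", "a", "b", "b", "b"], n_perm=999, seed=0)
        assert p > 0.9

    def test_matches_exhaustive_enumeration(self):
        v = [0.0, 0, 0, 1, 1, 1]
        labels = ["a", "a", "a", "b", "b", "b"]
        p_exact = exhaustive_mean_diff_p(v, labels)
        p_mc = compare_groups(v, labels, n_perm=9999, seed=1)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.random(10)
        l1 = ["a"] * 5 + ["b"] * 5
        l2 = ["b"] * 5 + ["a"] * 5
        assert compare_groups(v, l1, n_perm=999, seed=3) == compare_groups(
            v, l2, n_perm=999, seed=3
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "a"])
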