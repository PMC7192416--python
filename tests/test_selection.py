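"""Pareto fronts, epsilon-dominance, behavioral classes and composite axes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmaens.criteria import CriterionTable
from gmaens.selection import (
    behavioral_class,
    composite_axis,
    enrich_front,
    epsilon_front,
    pareto_front,
)


def crit_table(arr, orientations=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    cols = [f"c{i}" for i in range(arr.shape[1])]
    orient = dict(zip(cols, orientations or ["min"] * arr.shape[1]))
    return CriterionTable(pd.DataFrame(arr, columns=cols), orient)


def brute_force_front(C):
    """O(n^2) dominance oracle on a minimization matrix."""
    n = len(C)
    eff = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            if np.all(C[j] <= C[i]) and np.any(C[j] < C[i]):
                dominated = True
                break
            if np.all(C[j] == C[i]) and j < i:
                dominated = True  # duplicate: first occurrence kept
                break
        if not dominated:
            eff.append(i)
    return np.array(eff)


class TestParetoFront:
    def test_dominated_point_removed(self):
        res = pareto_front(crit_table([[1, 2], [2, 1], [2, 2]]))
        assert set(res.indices) == {0, 1}

    def test_single_criterion_argmin_set(self):
        res = pareto_front(crit_table([[3], [1], [2], [1]]))
        assert res.indices.tolist() == [1]  # duplicate argmin flagged, first kept
        assert res.duplicate_of == {3: 1}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pareto_front(crit_table(np.empty((0, 2))))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10**6), st.integers(2, 60), st.integers(1, 4))
    def test_equals_bruteforce_oracle(self, seed, n, d):
        rng = np.random.default_rng(seed)
        C = rng.integers(0, 6, size=(n, d)).astype(float)  # ties are likely
        res = pareto_front(crit_table(C))
        assert sorted(res.indices.tolist()) == sorted(brute_force_front(C).tolist())

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(0)
        C = rng.normal(size=(100, 3))
        a = pareto_front(crit_table(C))
        flipped = C.copy()
        flipped[:, 1] = -flipped[:, 1]
        b = pareto_front(crit_table(flipped, ["min", "max", "min"]))
        assert np.array_equal(a.indices, b.indices)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0.1, 5.0, size=(200, 2))
        a = pareto_front(crit_table(C))
        T = np.stack([np.log(C[:, 0]), C[:, 1] ** 3], axis=1)
        b = pareto_front(crit_table(T))
        assert np.array_equal(a.indices, b.indices)


class TestEpsilonFront:
    def test_zero_eps_recovers_exact_front(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(150, 3))
        assert np.array_equal(
            epsilon_front(crit_table(C), eps=0.0).indices, pareto_front(crit_table(C)).indices
        )

    def test_eps_one_retains_everything(self):
        rng = np.random.default_rng(3)
        C = rng.normal(size=(50, 2))
        assert len(epsilon_front(crit_table(C), eps=1.0)) == 50

    def test_matches_bruteforce_eps_scan(self):
        rng = np.random.default_rng(4)
        C = rng.uniform(size=(120, 2))
        eps = 0.05
        res = epsilon_front(crit_table(C), eps=eps)
        exact = pareto_front(crit_table(C))
        assert set(exact.indices) <= set(res.indices)
        lo, hi = C.min(0), C.max(0)
        Cn = (C - lo) / (hi - lo)
        keep = []
        for i in range(len(Cn)):
            dominated = any(
                np.all(Cn[j] <= Cn[i] - eps) and np.any(Cn[j] < Cn[i] - eps)
                for j in range(len(Cn))
                if j != i
            )
            if not dominated:
                keep.append(i)
        assert res.indices.tolist() == keep

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            epsilon_front(crit_table([[1, 2]]), eps=-0.1)


class TestBehavioralClass:
    def test_median_split(self):
        vals = np.arange(101, dtype=float)
        mask = behavioral_class(crit_table(vals[:, None]), ["c0"], 50).mask
        assert mask.sum() == 51  # "at or better than" the cutoff is inclusive
        assert mask[:51].all() and not mask[51:].any()

    def test_independent_criteria_intersect(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(size=(20_000, 2))
        mask = behavioral_class(crit_table(C), ["c0", "c1"], 50).mask
        assert abs(mask.mean() - 0.25) < 0.02

    def test_exclusion_removes_worst_fraction_only(self):
        rng = np.random.default_rng(6)
        C = rng.uniform(size=(10_000, 2))
        cm = behavioral_class(crit_table(C), ["c0"], 50, exclusion=("c1", 0.03))
        kept_c1 = C[cm.mask, 1]
        assert kept_c1.max() <= np.percentile(C[:, 1], 97) + 1e-12
        assert abs(cm.mask.mean() - 0.5 * 0.97) < 0.02

    def test_unknown_criterion_rejected(self):
        with pytest.raises(KeyError):
            behavioral_class(crit_table([[1.0]]), ["nope"], 50)

    def test_order_independence(self):
        rng = np.random.default_rng(7)
        C = rng.uniform(size=(500, 2))
        perm = rng.permutation(500)
        a = behavioral_class(crit_table(C), ["c0", "c1"], 50).mask
        b = behavioral_class(crit_table(C[perm]), ["c0", "c1"], 50).mask
        assert np.array_equal(a[perm], b)


class TestCompositeAxis:
    def test_symmetric_front_weights(self):
        t = np.linspace(0, 1, 20)
        C = np.stack([t, 1 - t], axis=1)  # front on y = 1 - x, both minimized
        tab = crit_table(C)
        front = pareto_front(tab)
        axis = composite_axis(tab, ("c0", "c1"), front)
        assert np.allclose(np.abs(axis.weights.to_numpy()), 1 / np.sqrt(2), atol=1e-9)

    def test_utopian_corner_scores_highest(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 1, 60)
        C = np.stack([t, (1 - t) ** 1.3], axis=1) + rng.uniform(0, 0.5, size=(60, 2))
        tab = crit_table(C)
        axis = composite_axis(tab, ("c0", "c1"), pareto_front(tab))
        aligned = -C  # both criteria minimized
        corner = aligned.max(axis=0)
        assert axis.weights.to_numpy() @ corner >= axis.score.max() - 1e-12

    def test_degenerate_front_rejected(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        tab = crit_table(C)
        with pytest.raises(ValueError, match="degenerate"):
            composite_axis(tab, ("c0", "c1"), pareto_front(tab))


class TestEnrichment:
    @staticmethod
    def _linear_eval(designs: pd.DataFrame) -> CriterionTable:
        d = designs.to_numpy(dtype=float)
        return CriterionTable(
            pd.DataFrame({"c0": d[:, 0], "c1": 1.0 - d[:, 0]}), {"c0": "min", "c1": "min"}
        )

    def test_linear_front_combinations_all_efficient(self):
        designs = pd.DataFrame({"p": np.linspace(0, 1, 10), "q": np.zeros(10)})
        tab = self._linear_eval(designs)
        front = pareto_front(tab)
        res = enrich_front(designs, tab, front, self._linear_eval, n_new=50, seed=0, eps=0.01)
        assert len(res.enriched_designs) == 50

    def test_identical_pair_retained(self):
        designs = pd.DataFrame({"p": [0.5, 0.5]})
        tab = CriterionTable(
            pd.DataFrame({"c0": [1.0, 2.0], "c1": [2.0, 1.0]}), {"c0": "min", "c1": "min"}
        )
        front = pareto_front(tab)
        res = enrich_front(
            designs,
            tab,
            front,
            lambda d: CriterionTable(
                pd.DataFrame({"c0": np.full(len(d), 1.5), "c1": np.full(len(d), 1.5)}),
                {"c0": "min", "c1": "min"},
            ),
            n_new=20,
            seed=1,
            eps=0.3,
        )
        assert (res.enriched_designs["p"] == 0.5).all()

    def test_requires_two_members(self):
        designs = pd.DataFrame({"p": [0.1]})
        tab = crit_table([[1.0, 1.0]])
        front = pareto_front(tab)
        with pytest.raises(ValueError):
            enrich_front(designs, tab, front, self._linear_eval, n_new=5)
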