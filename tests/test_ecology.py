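import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from abxtol import CountTable, asv_dynamics, bray_curtis, pcoa, permanova, shannon, shannon_profile

from conftest import random_count_table


class TestShannon:
    def test_uniform_composition(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_taxon_is_zero(self):
        assert shannon([7, 0, 0]) == 0.0

    def test_direct_evaluation(self):
        # -sum p ln p for (0.5, 0.25, 0.25)
        assert shannon([2, 1, 1]) == pytest.approx(1.0397207708399179)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_maximized_at_uniform_for_fixed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = rng.integers(2, 8)
            comp = rng.integers(1, 100, size=k)
            assert shannon(comp) <= math.log(k) + 1e-12

    def test_profile_matches_per_sample(self, toy_table):
        prof = shannon_profile(toy_table)
        assert prof.loc["s1"] == pytest.approx(shannon([5, 3, 4]))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        t = CountTable(pd.DataFrame([[3, 4], [3, 4]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        t = CountTable(pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        t = CountTable(pd.DataFrame([[2, 2], [1, 3]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.25)

    def test_formula_on_random_tables(self):
        rng = np.random.default_rng(4)
        table = random_count_table(rng, n_samples=5, n_taxa=7, max_count=30)
        # regenerate until no zero-depth rows
        while (table.depths() == 0).any():
            table = random_count_table(rng, n_samples=5, n_taxa=7, max_count=30)
        dm = bray_curtis(table)
        x = table.counts
        for i, j in itertools.combinations(range(5), 2):
            expected = 1 - 2 * np.minimum(x[i], x[j]).sum() / (x[i].sum() + x[j].sum())
            assert dm[i, j] == pytest.approx(expected)
            assert 0 <= dm[i, j] <= 1

    def test_zero_depth_sample_rejected(self):
        t = CountTable(pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"], columns=["x", "y"]))
        with pytest.raises(ValueError):
            bray_curtis(t)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(arrays(np.int64, (4, 5), elements=st.integers(0, 40)))
    def test_identity_symmetry_bounds_properties(self, counts):
        counts[:, 0] += 1  # keep every sample non-empty
        t = CountTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(4)],
                                    columns=[f"t{j}" for j in range(5)]))
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # unequal depths are intentional here
            dm = bray_curtis(t)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


class TestPcoa:
    def test_two_points_at_unit_distance(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        res = pcoa(dm, n_axes=1)
        assert sorted(np.abs(res.coordinates["PC1"])) == pytest.approx([0.5, 0.5])
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_three_equidistant_points_degenerate_pair(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(dm, n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.proportion_explained[0] == pytest.approx(res.proportion_explained[1])

    def test_planar_points_distances_recovered(self):
        pts = np.array([[0, 0], [3, 0], [0, 4], [2, 2], [5, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(5)]), n_axes=2)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(recon - d).max() < 1e-9

    def test_truncation_warning_when_too_many_axes(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.warns(UserWarning, match="truncating"):
            pcoa(dm, n_axes=5)


def _brute_force_ss(d: np.ndarray, labels) -> tuple[float, float]:
    """Independent sums-of-squares oracle by direct pairwise summation."""
    labels = np.asarray(labels)
    n = len(labels)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    return sst, ssw


TOY_D = np.array([
    [0.0, 0.3, 0.4, 0.7, 0.8, 0.9],
    [0.3, 0.0, 0.35, 0.75, 0.7, 0.85],
    [0.4, 0.35, 0.0, 0.8, 0.9, 0.7],
    [0.7, 0.75, 0.8, 0.0, 0.25, 0.3],
    [0.8, 0.7, 0.9, 0.25, 0.0, 0.35],
    [0.9, 0.85, 0.7, 0.3, 0.35, 0.0],
])
TOY_LABELS = ["x", "x", "x", "y", "y", "y"]


class TestPermanova:
    def test_r2_and_f_match_brute_force_sums_of_squares(self):
        dm = DistanceMatrix(TOY_D, ids=[str(i) for i in range(6)])
        res = permanova(dm, TOY_LABELS, n_perm=99, seed=1)
        sst, ssw = _brute_force_ss(TOY_D, TOY_LABELS)
        ssb = sst - ssw
        assert res.r2 == pytest.approx(ssb / sst, rel=1e-12)
        assert res.f == pytest.approx((ssb / 1) / (ssw / 4), rel=1e-12)

    def test_f_statistic_agrees_with_skbio(self):
        rng = np.random.default_rng(2)
        table = random_count_table(rng, n_samples=8, n_taxa=10, max_count=60)
        dm = bray_curtis(table)
        labels = ["a"] * 4 + ["b"] * 4
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours.f == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        dm = DistanceMatrix(TOY_D, ids=[str(i) for i in range(6)])
        res = permanova(dm, TOY_LABELS, n_perm=4999, seed=3)
        # exhaustive oracle over all 6! label orderings (20 distinct splits)
        f_obs = res.f
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            labels = np.asarray(TOY_LABELS)[list(perm)]
            sst, ssw = _brute_force_ss(TOY_D, labels)
            f_p = ((sst - ssw) / 1) / (ssw / 4)
            hits += f_p >= f_obs - 1e-12
            total += 1
        exact = hits / total
        se = math.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p - exact) < 4 * se + 1 / 5000

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        runs = 120
        for r in range(runs):
            x = rng.normal(size=(12, 4))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            dm = DistanceMatrix(d, ids=[str(i) for i in range(12)])
            res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=r)
            rejections += res.p <= 0.05
        # binomial CI around 5%
        assert rejections / runs < 0.05 + 3 * math.sqrt(0.05 * 0.95 / runs)

    def test_saturated_effect_floors_p(self):
        # two tight, far-apart clusters; N large enough that random label
        # permutations essentially never reproduce the true partition
        n = 10
        a = np.zeros((n, 2))
        b = np.ones((n, 2)) * 100
        x = np.vstack([a, b]) + np.arange(2 * n)[:, None] * 0.01
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(2 * n)])
        res = permanova(dm, ["a"] * n + ["b"] * n, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)
        assert res.r2 > 0.99

    def test_r2_invariant_to_sample_reordering(self):
        dm = DistanceMatrix(TOY_D, ids=[str(i) for i in range(6)])
        base = permanova(dm, TOY_LABELS, n_perm=99, seed=0).r2
        order = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix(TOY_D[np.ix_(order, order)], ids=[str(i) for i in order])
        shuffled = permanova(dm2, list(np.asarray(TOY_LABELS)[order]), n_perm=99, seed=0).r2
        assert shuffled == pytest.approx(base, rel=1e-12)

    def test_singleton_group_rejected_by_name(self):
        dm = DistanceMatrix(TOY_D[:5, :5], ids=[str(i) for i in range(5)])
        with pytest.raises(ValueError, match="lonely"):
            permanova(dm, ["x", "x", "x", "x", "lonely"], n_perm=99, seed=0)


def _dyn_meta(samples):
    return pd.DataFrame(samples).set_index("sample_id")


class TestAsvDynamics:
    @staticmethod
    def _table(first_counts, last_counts, taxa):
        return CountTable(pd.DataFrame([first_counts, last_counts],
                                       index=["d0", "d9"], columns=taxa))

    META = _dyn_meta([
        {"sample_id": "d0", "mouse_id": "m", "day": 0, "group": "antibiotic",
         "antibiotic_window": False, "diet": "chow"},
        {"sample_id": "d9", "mouse_id": "m", "day": 9, "group": "antibiotic",
         "antibiotic_window": False, "diet": "chow"},
    ])

    def test_set_arithmetic_example(self):
        # first {A,B,C}, last {A,D}
        t = self._table([1, 2, 3, 0], [4, 0, 0, 5], ["A", "B", "C", "D"])
        dyn = asv_dynamics(t, self.META).loc["m"]
        assert (dyn["persistent"], dyn["lost"], dyn["gained"]) == (1, 2, 1)
        assert dyn["frac_persistent"] == pytest.approx(1 / 3)
        assert dyn["frac_lost"] == pytest.approx(2 / 3)
        assert dyn["frac_gained"] == pytest.approx(1 / 2)

    def test_identical_endpoints(self):
        t = self._table([1, 1, 0], [2, 3, 0], ["A", "B", "C"])
        dyn = asv_dynamics(t, self.META).loc["m"]
        assert dyn["lost"] == 0 and dyn["gained"] == 0
        assert dyn["frac_persistent"] == pytest.approx(1.0)

    def test_complete_turnover(self):
        t = self._table([1, 1, 0, 0], [0, 0, 2, 2], ["A", "B", "C", "D"])
        dyn = asv_dynamics(t, self.META).loc["m"]
        assert dyn["persistent"] == 0
        assert dyn["lost"] == dyn["richness_first"] == 2
        assert dyn["gained"] == dyn["richness_last"] == 2

    def test_conservation_identities_on_random_tables(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            t = self._table(rng.integers(0, 3, 6), rng.integers(0, 3, 6),
                            [f"t{i}" for i in range(6)])
            dyn = asv_dynamics(t, self.META)
            if dyn.empty:
                continue
            row = dyn.loc["m"]
            assert row["persistent"] + row["lost"] == row["richness_first"]
            assert row["persistent"] + row["gained"] == row["richness_last"]

    def test_single_time_point_mouse_skipped(self):
        t = CountTable(pd.DataFrame([[1, 2]], index=["d0"], columns=["A", "B"]))
        meta = _dyn_meta([{"sample_id": "d0", "mouse_id": "m", "day": 0,
                           "group": "antibiotic", "antibiotic_window": False, "diet": "chow"}])
        assert asv_dynamics(t, meta).empty
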