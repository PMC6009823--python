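"""Group comparisons, Bray-Curtis dissimilarity and ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from spikequant.stats import bray_curtis_matrix, compare_groups, ordinate


def _frame(rows, taxa=None):
    arr = np.asarray(rows, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=taxa)


class TestCompareGroups:
    def test_identical_groups_no_stars(self):
        rng = np.random.default_rng(0)
        a = _frame(rng.normal(10, 1, size=(6, 4)))
        res = compare_groups(a, a.copy())
        assert (res["tier"] == "ns").all()

    def test_constant_equal_taxon_untestable(self):
        a = _frame([[1, 5], [1, 6], [1, 7]])
        b = _frame([[1, 5], [1, 7], [1, 6]])
        res = compare_groups(a, b)
        assert res.loc["t0", "untestable"]
        assert res.loc["t0", "tier"] == "ns"

    def test_planted_shift_detected_only_where_planted(self):
        """A 5-SD shift in one taxon of twenty is starred after Bonferroni;
        the other nineteen stay unstarred (checked over repeated draws)."""
        rng = np.random.default_rng(1)
        hits, false_hits = 0, 0
        reps = 50
        for _ in range(reps):
            a = _frame(rng.normal(0, 1, size=(10, 20)))
            b = _frame(rng.normal(0, 1, size=(10, 20)))
            b["t7"] += 5.0
            res = compare_groups(a, b)
            starred = res.index[res["tier"] != "ns"]
            if "t7" in starred:
                hits += 1
            if len(set(starred) - {"t7"}):
                false_hits += 1
        assert hits / reps > 0.95
        assert false_hits / reps <= 0.1

    def test_direction_labels(self):
        a = _frame([[10.0, 1.0]] * 4) + np.random.default_rng(2).normal(
            0, 0.1, size=(4, 2)
        )
        b = _frame([[1.0, 10.0]] * 4) + np.random.default_rng(3).normal(
            0, 0.1, size=(4, 2)
        )
        res = compare_groups(a, b, group_names=("B", "W"))
        assert res.loc["t0", "direction"] == "B"
        assert res.loc["t1", "direction"] == "W"

    def test_mismatched_taxa_raise(self):
        with pytest.raises(ValueError):
            compare_groups(_frame([[1, 2]] * 3), _frame([[1, 2]] * 3, ["x", "y"]))

    def test_bonferroni_is_capped_multiple(self):
        rng = np.random.default_rng(4)
        a = _frame(rng.normal(0, 1, size=(5, 8)))
        b = _frame(rng.normal(0, 1, size=(5, 8)))
        res = compare_groups(a, b)
        expected = np.minimum(res["pvalue"] * 8, 1.0)
        assert np.allclose(res["pvalue_bonferroni"], expected)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        prof = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        dm, _ = bray_curtis_matrix(prof, standardise=False, sqrt_transform=False)
        assert dm.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        prof = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"])
        dm, _ = bray_curtis_matrix(prof, standardise=False, sqrt_transform=False)
        assert dm.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_example(self):
        prof = pd.DataFrame([[1, 3], [3, 1]], index=["x", "y"])
        dm, _ = bray_curtis_matrix(prof, standardise=False, sqrt_transform=False)
        assert dm.loc["x", "y"] == pytest.approx(0.5)

    def test_bounds_symmetry_identity(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.gamma(1.0, size=(6, 12)))
        dm, _ = bray_curtis_matrix(prof)
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all() and (arr <= 1).all()

    def test_standardisation_absorbs_sample_scaling(self):
        """With per-sample standardisation, rescaling any sample (e.g.
        removing a constant spike share) leaves distances unchanged."""
        rng = np.random.default_rng(6)
        prof = pd.DataFrame(rng.gamma(1.0, size=(5, 10)))
        scaled = prof.mul(rng.uniform(0.1, 10.0, size=5), axis=0)
        d1, _ = bray_curtis_matrix(prof, standardise=True)
        d2, _ = bray_curtis_matrix(scaled, standardise=True)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_all_zero_sample_excluded_and_reported(self):
        prof = pd.DataFrame([[1, 2], [0, 0], [2, 1]], index=["a", "z", "b"])
        dm, excluded = bray_curtis_matrix(prof)
        assert excluded == ["z"]
        assert list(dm.index) == ["a", "b"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_matrix(pd.DataFrame([[1, -1], [1, 1]]))


class TestOrdination:
    def test_classical_mds_euclidean_round_trip(self):
        rng = np.random.default_rng(7)
        planted = rng.normal(size=(9, 2))
        ids = [f"s{i}" for i in range(9)]
        dm = pd.DataFrame(squareform(pdist(planted)), index=ids, columns=ids)
        coords = ordinate(dm, dimensions=2)
        recovered = squareform(pdist(coords.to_numpy()))
        assert np.abs(recovered - dm.to_numpy()).max() < 1e-6

    def test_three_equidistant_samples_form_equilateral_triangle(self):
        ids = ["a", "b", "c"]
        dm = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
        coords = ordinate(dm, dimensions=2)
        sides = pdist(coords.to_numpy())
        assert np.allclose(sides, sides[0], atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(
            rng.gamma(1.0, size=(6, 10)), index=[f"s{i}" for i in range(6)]
        )
        dm, _ = bray_curtis_matrix(prof)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        dm_p = dm.loc[perm, perm]
        d_orig = squareform(pdist(ordinate(dm, 2).to_numpy()))
        d_perm = squareform(
            pdist(ordinate(dm_p, 2).loc[dm.index].to_numpy())
        )
        assert np.allclose(d_orig, d_perm, atol=1e-8)

    def test_nonmetric_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        prof = pd.DataFrame(rng.gamma(1.0, size=(5, 8)))
        dm, _ = bray_curtis_matrix(prof)
        c1 = ordinate(dm, method="nonmetric", seed=3)
        c2 = ordinate(dm, method="nonmetric", seed=3)
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_unknown_method_rejected(self):
        dm = pd.DataFrame(1.0 - np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ordinate(dm, method="bogus")


class TestSoilSeparation:
    def test_groups_separate_but_spike_level_does_not_cluster(self):
        """Two simulated soils at several spike levels: between-soil
        ordination distance exceeds within-soil spread, and spike level
        explains little of the layout (the spike rows are excluded before
        ordination, mirroring practice)."""
        from spikequant.quantitation import relative_profiles
        from spikequant.simulate import make_community, sequence_sample
        from spikequant.copy_number import default_level_table

        levels = default_level_table()
        p_levels = levels[levels.family == "P"].copies.tolist()[3:7]
        cols, meta = {}, []
        for soil, seed in (("A", 100), ("B", 200)):
            truth = make_community({"P": 25}, {"P": 1.9e9 * (2 if soil == "B" else 1)},
                                   seed=seed)
            for li, dose in enumerate(p_levels):
                t = truth.__class__(truth.taxa, {"P": dose})
                name = f"{soil}{li}"
                tab = sequence_sample(t, 30_000, seed=seed + li, sample=name)
                cols[name] = tab.counts[name]
                meta.append((name, soil, li))
        counts = pd.DataFrame(cols)
        from spikequant.read_processing import CountTable

        table = CountTable(counts, pd.Series("P", index=counts.index))
        prof = relative_profiles(table, "P")
        dm, _ = bray_curtis_matrix(prof)
        coords = ordinate(dm, 2)
        a = coords.loc[[m[0] for m in meta if m[1] == "A"]].to_numpy()
        b = coords.loc[[m[0] for m in meta if m[1] == "B"]].to_numpy()
        within = max(pdist(a).max(), pdist(b).max())
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > within
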