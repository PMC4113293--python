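import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streambeta import (
    CommunityMatrix,
    PermDisp,
    distances_to_centroid,
    euclidean_std_matrix,
    habitat_heterogeneity,
    pcoa,
    permdisp,
    sorensen_matrix,
)
from streambeta.data_model import StructuralError, ValidationError
from streambeta.dispersion import DistanceMatrix

from conftest import random_community


def brute_sorensen(counts):
    """Exhaustive pairwise set-operation oracle for presence/absence Sørensen."""
    n = counts.shape[0]
    out = np.zeros((n, n))
    sets = [frozenset(np.flatnonzero(counts[i] > 0)) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        a = len(sets[i] & sets[j])
        b = len(sets[i] - sets[j])
        c = len(sets[j] - sets[i])
        out[i, j] = out[j, i] = 1 - 2 * a / (2 * a + b + c)
    return out


class TestSorensen:
    def test_identical_and_disjoint_sites(self):
        data = pd.DataFrame(
            [[1, 1, 0, 0], [2, 3, 0, 0], [0, 0, 1, 1]],
            index=list("abc"),
            columns=list("WXYZ"),
        )
        dm = sorensen_matrix(CommunityMatrix(data))
        v = dm.to_frame()
        assert v.loc["a", "b"] == 0.0
        assert v.loc["a", "c"] == 1.0

    def test_hand_counted_half(self):
        data = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["a", "b"], columns=list("ABC")
        )
        dm = sorensen_matrix(CommunityMatrix(data))
        assert dm.to_frame().loc["a", "b"] == pytest.approx(0.5)

    def test_matches_set_operation_oracle(self, rng):
        cm = random_community(rng, 20, 30, lam=0.8)
        dm = sorensen_matrix(cm)
        np.testing.assert_allclose(dm.values, brute_sorensen(cm.counts), atol=1e-12)

    def test_empty_site_rejected(self):
        data = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["A", "B"])
        with pytest.raises(ValidationError, match="b"):
            sorensen_matrix(CommunityMatrix(data))


class TestEuclideanStd:
    def test_identical_sites_zero(self):
        env = pd.DataFrame({"x": [1.0, 1.0, 3.0], "y": [2.0, 2.0, 4.0]}, index=list("abc"))
        dm = euclidean_std_matrix(env, ["x", "y"])
        assert dm.to_frame().loc["a", "b"] == 0.0

    def test_single_variable_hand_arithmetic(self):
        env = pd.DataFrame({"x": [0.0, 2.0]}, index=["a", "b"])
        dm = euclidean_std_matrix(env, ["x"])
        sd = np.std([0.0, 2.0], ddof=1)
        assert dm.to_frame().loc["a", "b"] == pytest.approx(2.0 / sd)

    def test_affine_invariance(self, rng):
        env = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("xyz"))
        scaled = env * np.array([3.0, -2.0, 0.5]) + np.array([10.0, 0.0, -4.0])
        d1 = euclidean_std_matrix(env, list("xyz")).values
        d2 = euclidean_std_matrix(scaled, list("xyz")).values
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_zero_variance_variable_named(self):
        env = pd.DataFrame({"x": [1.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="x"):
            euclidean_std_matrix(env, ["x", "y"])

    def test_missing_values_rejected(self):
        env = pd.DataFrame({"x": [1.0, np.nan]})
        with pytest.raises(ValidationError):
            euclidean_std_matrix(env, ["x"])


class TestPCoA:
    def test_equilateral_triangle_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"), 1 - np.eye(3), "sorensen")
        space = pcoa(dm)
        np.testing.assert_allclose(space.eigvals_pos, [0.5, 0.5], atol=1e-12)
        assert space.eigvals_neg.size == 0

    def test_euclidean_input_has_no_negative_axes(self, rng):
        x = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(
            tuple(f"s{i}" for i in range(10)), squareform(pdist(x)), "euclidean_std"
        )
        assert pcoa(dm).eigvals_neg.size == 0

    def test_sorensen_reconstruction_identity(self, rng):
        cm = random_community(rng, 12, 18, lam=0.7)
        dm = sorensen_matrix(cm)
        space = pcoa(dm)
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                assert space.squared_distance(i, j) == pytest.approx(
                    dm.values[i, j] ** 2, abs=1e-8
                )


class TestCentroidDistances:
    def test_identical_group_all_zero(self):
        env = pd.DataFrame({"x": [1.0, 1.0, 5.0, 5.0], "y": [0.0, 0.0, 2.0, 2.0]},
                           index=list("abcd"))
        dm = euclidean_std_matrix(env, ["x", "y"])
        z = distances_to_centroid(pcoa(dm), {"g1": ["a", "b"], "g2": ["c", "d"]})
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-10)

    def test_pair_gives_half_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]), "euclidean_std")
        z = distances_to_centroid(pcoa(dm), {"g": ["a", "b"]})
        np.testing.assert_allclose(z.to_numpy(), 1.5, atol=1e-10)

    def test_euclidean_matches_raw_space_oracle(self, rng):
        x = rng.normal(size=(12, 5))
        labels = [f"s{i}" for i in range(12)]
        env = pd.DataFrame(x, index=labels, columns=list("abcde"))
        groups = {"g1": labels[:6], "g2": labels[6:]}
        dm = euclidean_std_matrix(env, list("abcde"))
        z = distances_to_centroid(pcoa(dm), groups)
        zscored = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        for name, sites in groups.items():
            idx = [labels.index(s) for s in sites]
            centroid = zscored[idx].mean(axis=0)
            direct = np.linalg.norm(zscored[idx] - centroid, axis=1)
            np.testing.assert_allclose(z.loc[sites].to_numpy(), direct, atol=1e-8)

    def test_matches_anderson_reference_implementation(self):
        # frozen values computed once with vegan::betadisper (type="centroid")
        # on this 8x10 matrix, Sorensen dissimilarity, two groups of 4
        counts = np.array(
            [[1, 2, 3, 1, 3, 0, 1, 2, 0, 3],
             [1, 0, 3, 0, 1, 0, 1, 1, 2, 2],
             [0, 1, 0, 0, 2, 1, 1, 0, 1, 1],
             [1, 1, 0, 0, 0, 0, 1, 0, 0, 0],
             [1, 2, 1, 0, 0, 1, 0, 1, 1, 0],
             [0, 1, 0, 0, 3, 3, 0, 0, 1, 0],
             [0, 1, 3, 1, 1, 0, 0, 1, 0, 0],
             [1, 2, 1, 2, 0, 1, 2, 0, 0, 1]]
        )
        labels = [f"s{i}" for i in range(8)]
        cm = CommunityMatrix(pd.DataFrame(counts, index=labels, columns=list("ABCDEFGHIJ")))
        groups = {"g1": labels[:4], "g2": labels[4:]}
        res = permdisp(sorensen_matrix(cm), groups, n_perm=9, seed=0)
        expected_z = [0.1721707, 0.2430098, 0.2865879, 0.3753464,
                      0.1903978, 0.3549878, 0.3145307, 0.3291475]
        np.testing.assert_allclose(res.distances.to_numpy(), expected_z, atol=1e-7)
        assert res.f_statistic == pytest.approx(0.2490771, abs=1e-6)


class TestPermDisp:
    def test_identical_z_multisets_give_f_zero(self):
        # two groups of two points, equal within-pair distance -> all z equal
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 2.0
        d[2, 3] = d[3, 2] = 2.0
        d[0, 2] = d[2, 0] = d[0, 3] = d[3, 0] = 9.0
        d[1, 2] = d[2, 1] = d[1, 3] = d[3, 1] = 9.0
        dm = DistanceMatrix(tuple("abcd"), d, "euclidean_std")
        res = permdisp(dm, {"g1": ["a", "b"], "g2": ["c", "d"]}, n_perm=99, seed=1)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0

    def test_f_equals_anova_oracle(self, rng):
        cm = random_community(rng, 12, 15, lam=1.0)
        groups = {"g1": cm.site_ids[:6], "g2": cm.site_ids[6:]}
        res = permdisp(sorensen_matrix(cm), groups, n_perm=49, seed=2)
        z1 = res.distances.loc[groups["g1"]]
        z2 = res.distances.loc[groups["g2"]]
        assert res.f_statistic == pytest.approx(
            stats.f_oneway(z1, z2).statistic, abs=1e-10
        )
        assert (res.df_between, res.df_within) == (1, 10)

    def test_small_group_rejected(self, rng):
        cm = random_community(rng, 5, 10, lam=1.0)
        with pytest.raises(StructuralError):
            permdisp(
                sorensen_matrix(cm),
                {"g1": cm.site_ids[:1], "g2": cm.site_ids[1:]},
                n_perm=9,
            )

    def test_raw_permutation_mode_runs(self, rng):
        cm = random_community(rng, 10, 12, lam=1.0)
        groups = {"g1": cm.site_ids[:5], "g2": cm.site_ids[5:]}
        res = permdisp(sorensen_matrix(cm), groups, n_perm=99, seed=3, permute="raw")
        assert 0 < res.p_value <= 1.0

    def test_estimator_reproducible(self, rng):
        cm = random_community(rng, 10, 12, lam=1.0)
        groups = {"g1": cm.site_ids[:5], "g2": cm.site_ids[5:]}
        dm = sorensen_matrix(cm)
        a = PermDisp(n_perm=99, random_state=7).fit(dm, groups)
        b = PermDisp(n_perm=99, random_state=7).fit(dm, groups)
        assert a.p_value_ == b.p_value_ and a.f_statistic_ == b.f_statistic_


class TestHabitatHeterogeneity:
    def test_identical_habitat_rows_score_zero(self, metadata_frame):
        env = metadata_frame.set_index("site_id").copy()
        cols = ["depth", "velocity", "slope", "canopy", "substrate_index", "macrophytes"]
        env.loc[env["region"] == "R1", cols] = [0.3, 0.5, 2.0, 50.0, 100.0, 10.0]
        groups = {r: g.index.tolist() for r, g in env.groupby("region")}
        z, summary = habitat_heterogeneity(env, cols, groups)
        np.testing.assert_allclose(z.loc[groups["R1"]].to_numpy(), 0.0, atol=1e-10)
        assert summary.loc["R1", "mean"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_raw_space_oracle(self, metadata_frame):
        env = metadata_frame.set_index("site_id")
        cols = ["depth", "velocity", "slope", "canopy", "substrate_index", "macrophytes"]
        groups = {r: g.index.tolist() for r, g in env.groupby("region")}
        z, _ = habitat_heterogeneity(env, cols, groups)
        x = env[cols].to_numpy(float)
        zs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        labels = env.index.tolist()
        for name, sites in groups.items():
            idx = [labels.index(s) for s in sites]
            centroid = zs[idx].mean(axis=0)
            direct = np.linalg.norm(zs[idx] - centroid, axis=1)
            np.testing.assert_allclose(z.loc[sites].to_numpy(), direct, atol=1e-8)

    def test_inflating_spread_raises_group_mean(self, metadata_frame):
        env = metadata_frame.set_index("site_id")
        cols = ["depth", "velocity", "slope", "canopy", "substrate_index", "macrophytes"]
        groups = {r: g.index.tolist() for r, g in env.groupby("region")}
        _, before = habitat_heterogeneity(env, cols, groups)
        inflated = env.copy()
        mask = inflated["region"] == "R1"
        centered = inflated.loc[mask, cols] - inflated.loc[mask, cols].mean()
        inflated.loc[mask, cols] = inflated.loc[mask, cols] + 3.0 * centered
        inflated["canopy"] = inflated["canopy"].clip(0, 100)
        inflated["macrophytes"] = inflated["macrophytes"].clip(0, 100)
        _, after = habitat_heterogeneity(inflated, cols, groups)
        assert after.loc["R1", "mean"] > before.loc["R1", "mean"]
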