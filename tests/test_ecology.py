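import itertools
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.isotonic import IsotonicRegression

from mosquito_microgeo import (NMDS, DistanceMatrix, OtuTable, cooccurrence,
                               distance_matrix, hierarchical_cluster,
                               horn_dissimilarity, nmds, permanova)
from mosquito_microgeo.ecology import (_classical_mds, _config_distances,
                                       _kruskal_stress)


def table_from_rows(rows):
    rows = np.asarray(rows)
    return OtuTable(tuple(f"s{i}" for i in range(rows.shape[0])),
                    tuple(f"o{j}" for j in range(rows.shape[1])), rows)


def stress_of(coords, dissim_square):
    """Independent Kruskal stress-1 evaluator for a given configuration."""
    from scipy.spatial.distance import squareform
    delta = squareform(dissim_square, checks=False)
    dist = _config_distances(np.asarray(coords, float))
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(dist)
    dhat[order] = iso.fit_transform(delta[order], dist[order])
    return _kruskal_stress(dhat, dist)


class TestHorn:
    def test_identical_vectors_give_zero(self):
        assert horn_dissimilarity([3, 1, 9], [3, 1, 9]) == pytest.approx(0.0)

    def test_disjoint_support_gives_one(self):
        assert horn_dissimilarity([3, 0], [0, 7]) == pytest.approx(1.0)

    def test_two_vector_formula_oracle(self):
        # x=(1,1), y=(1,0): 1 - 2*1/((2/4 + 1/1)*2*1) = 1/3
        assert horn_dissimilarity([1, 1], [1, 0]) == pytest.approx(1 / 3)

    def test_zero_sum_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            horn_dissimilarity([0, 0], [1, 2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8),
           st.lists(st.integers(0, 50), min_size=2, max_size=8),
           st.integers(1, 9))
    def test_symmetry_and_depth_invariance(self, x, y, c):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]) + 1, np.array(y[:n]) + 1  # ensure positive sums
        d_xy = horn_dissimilarity(x, y)
        assert d_xy == pytest.approx(horn_dissimilarity(y, x))
        assert d_xy == pytest.approx(horn_dissimilarity(c * x, y), abs=1e-12)
        assert 0.0 <= d_xy <= 1.0


class TestDistanceMatrix:
    def test_duplicated_samples_are_at_distance_zero(self):
        t = table_from_rows([[5, 5, 1], [5, 5, 1], [1, 0, 9]])
        d = distance_matrix(t)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.values[0, 2] > 0

    def test_matches_pairwise_op_brute_force(self):
        rng = np.random.default_rng(3)
        t = table_from_rows(rng.integers(1, 60, size=(6, 9)))
        d = distance_matrix(t)
        for i, j in itertools.combinations(range(6), 2):
            assert d.values[i, j] == pytest.approx(
                horn_dissimilarity(t.counts[i], t.counts[j]), abs=1e-10)

    def test_zero_depth_sample_named_in_error(self):
        t = table_from_rows([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            distance_matrix(t)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = distance_matrix(table_from_rows(rng.integers(1, 30, size=(4, 5))))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


def test_horn_and_permanova_match_vegan():
    """Independent oracle: the reference community-ecology R package
    (vegan: vegdist method='horn', adonis2) must reproduce our distances
    and pseudo-F on a random table."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 50, size=(5, 6))
    X[0, 0] += 3
    t = table_from_rows(X)
    d = distance_matrix(t)
    f_obs, _ = permanova(d, ["a", "a", "b", "b", "b"], n_perm=99, seed=0)
    r_code = (
        "suppressMessages(library(vegan));"
        f"X <- matrix(c({','.join(map(str, X.T.ravel()))}), nrow=5);"
        "d <- vegdist(X, method='horn');"
        "grp <- factor(c('a','a','b','b','b'));"
        "a <- adonis2(d ~ grp, permutations=99);"
        "cat(paste(round(as.vector(as.matrix(d)), 8), collapse=' '));"
        "cat(' ');cat(a$F[1])"
    )
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                         text=True, check=True).stdout.split()
    vegan_d = np.array(out[:25], dtype=float).reshape(5, 5)
    vegan_f = float(out[25])
    assert np.allclose(d.values, vegan_d, atol=1e-6)
    assert f_obs == pytest.approx(vegan_f, rel=1e-4)


class TestHierarchicalCluster:
    def test_two_points_merge_at_their_distance(self):
        d = DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]))
        z = hierarchical_cluster(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.4)

    def test_tight_pair_merges_first(self):
        v = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        z = hierarchical_cluster(DistanceMatrix(("a", "b", "c"), v))
        assert sorted(z[0, :2].astype(int)) == [0, 1]

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_brute_force_agglomeration(self, linkage):
        rng = np.random.default_rng(5)
        pts = rng.random((6, 3))
        v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = DistanceMatrix(tuple("abcdef"), v)
        z = hierarchical_cluster(d, linkage=linkage)
        # naive agglomeration oracle tracking merge heights
        clusters = {i: [i] for i in range(6)}
        heights = []
        work = v.copy()
        agg = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]
        while len(clusters) > 1:
            keys = list(clusters)
            best = min(
                ((a, b) for a, b in itertools.combinations(keys, 2)),
                key=lambda ab: agg([work[i, j] for i in clusters[ab[0]]
                                    for j in clusters[ab[1]]]),
            )
            h = agg([work[i, j] for i in clusters[best[0]] for j in clusters[best[1]]])
            heights.append(h)
            clusters[best[0]] = clusters[best[0]] + clusters.pop(best[1])
        assert np.allclose(np.sort(z[:, 2]), np.sort(heights))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestNmds:
    def test_exactly_embeddable_distances_reach_near_zero_stress(self):
        rng = np.random.default_rng(2)
        pts = rng.random((8, 2)) * 3
        v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = nmds(DistanceMatrix(tuple(f"s{i}" for i in range(8)), v), seed=0)
        assert res.stress < 0.01

    def test_stress_invariant_under_rotation_and_reflection(self):
        rng = np.random.default_rng(3)
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        res = nmds(DistanceMatrix(tuple("abcdef"), v), seed=1)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        refl = np.array([[1, 0], [0, -1]])
        base = stress_of(res.coordinates, v)
        assert stress_of(res.coordinates @ rot, v) == pytest.approx(base, abs=1e-9)
        assert stress_of(res.coordinates @ refl, v) == pytest.approx(base, abs=1e-9)
        assert base == pytest.approx(res.stress, abs=1e-6)

    def test_five_point_toy_matches_many_restart_reference(self):
        rng = np.random.default_rng(8)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        d = DistanceMatrix(tuple("abcde"), v)
        reference = nmds(d, n_starts=60, max_iter=800, seed=99)  # restart oracle
        res = nmds(d, seed=0)
        assert res.stress <= reference.stress + 1e-3

    def test_stress_never_exceeds_metric_start(self):
        rng = np.random.default_rng(11)
        t = table_from_rows(rng.integers(1, 50, size=(9, 12)))
        d = distance_matrix(t)
        metric_cfg = _classical_mds(d.values, 2)
        res = nmds(d, seed=4)
        assert res.stress <= stress_of(metric_cfg, d.values) + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        t = table_from_rows(rng.integers(1, 50, size=(7, 8)))
        d = distance_matrix(t)
        a, b = nmds(d, seed=5), nmds(d, seed=5)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            NMDS(n_components=2).fit(np.zeros((2, 2)))


class TestPermanova:
    def test_separated_clusters_reach_minimum_p(self):
        # groups of 10 so that label permutations recreating the same
        # partition (which tie the maximal F) are essentially never drawn
        rng = np.random.default_rng(0)
        a = rng.integers(90, 110, size=(10, 3)) * np.array([1, 0, 0]) + 1
        b = rng.integers(90, 110, size=(10, 3)) * np.array([0, 1, 0]) + 1
        d = distance_matrix(table_from_rows(np.vstack([a, b])))
        _, p = permanova(d, ["x"] * 10 + ["y"] * 10, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        t = table_from_rows(rng.integers(1, 40, size=(6, 8)))
        d = distance_matrix(t)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        from mosquito_microgeo.ecology import _permanova_f
        d2 = d.values ** 2
        f_obs = _permanova_f(d2, labels, np.array(["a", "b"]))
        # exhaustive: all C(6,3)=20 assignments of "a"
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            fs.append(_permanova_f(d2, lab, np.array(["a", "b"])))
        p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-12)
        _, p_sampled = permanova(d, labels, n_perm=9999, seed=3)
        assert abs(p_sampled - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 9999) + 2e-4

    def test_p_invariant_to_group_renaming(self):
        rng = np.random.default_rng(9)
        t = table_from_rows(rng.integers(1, 40, size=(8, 6)))
        d = distance_matrix(t)
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        renamed = ["zebra" if l == "a" else "ant" for l in labels]
        f1, p1 = permanova(d, labels, n_perm=499, seed=2)
        f2, p2 = permanova(d, renamed, n_perm=499, seed=2)
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_matches_skbio_pseudo_f(self):
        # independent implementation cross-check
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(10)
        t = table_from_rows(rng.integers(1, 40, size=(9, 7)))
        d = distance_matrix(t)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f_obs, _ = permanova(d, labels, n_perm=9, seed=0)
        dm = skbio_stats.DistanceMatrix(d.values.copy(), ids=list(d.ids))
        res = skbio_stats.permanova(dm, grouping=labels, permutations=9)
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-10)

    def test_null_p_values_are_uniform(self):
        """Random labels on exchangeable samples: p ~ U(0,1) over 200 sims."""
        from scipy.stats import kstest
        rng = np.random.default_rng(0)
        ps = []
        for i in range(200):
            t = table_from_rows(rng.integers(1, 50, size=(10, 6)))
            d = distance_matrix(t)
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            _, p = permanova(d, labels, n_perm=199, seed=i)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        d = DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            permanova(d, ["x", "x"], n_perm=9)


class TestCooccurrence:
    def test_duplicated_feature_correlates_perfectly(self):
        t = table_from_rows([[5, 5, 2], [1, 1, 8], [4, 4, 4]])
        corr = cooccurrence(t)
        assert corr.loc["o0", "o1"] == pytest.approx(1.0)

    def test_two_otu_fixed_depth_complement(self):
        t = table_from_rows([[30, 70], [60, 40], [10, 90]])
        corr = cooccurrence(t)
        assert corr.loc["o0", "o1"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(13)
        t = table_from_rows(rng.integers(1, 30, size=(4, 4)))
        corr = cooccurrence(t)
        rel = t.counts / t.counts.sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(4), 2):
            x, y = rel[:, i], rel[:, j]
            manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert corr.iloc[i, j] == pytest.approx(manual, abs=1e-10)

    def test_zero_variance_feature_marked_missing(self):
        t = table_from_rows([[5, 5], [10, 10], [2, 2]])  # o0 rel ab constant 0.5
        corr = cooccurrence(t)
        assert np.isnan(corr.loc["o0", "o1"])

    def test_genus_aggregation(self, toy_table):
        corr = cooccurrence(toy_table, level="genus")
        assert set(corr.columns) == {"Acinetobacter", "Wolbachia", "Bacillus"}
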