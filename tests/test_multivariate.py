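"""PERMANOVA and CAP against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import f_oneway

from trophiso.errors import InputError, ValidationError
from trophiso.multivariate_stats import (
    DistanceMatrix,
    cap_assign,
    cap_fit,
    cap_loo,
    cap_permutation_test,
    euclidean_distances,
    pairwise_permanova,
    permanova_oneway,
)


def _clusters(rng, centers, n_per, spread=0.1):
    vals = np.vstack([c + spread * rng.standard_normal((n_per, len(c)))
                      for c in centers])
    labels = [lab for lab in "abcdefgh"[: len(centers)] for _ in range(n_per)]
    return vals, labels


class TestDistances:
    def test_identical_rows_zero(self):
        D = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D.data[0, 1] == 0.0

    def test_three_four_five(self):
        D = euclidean_distances(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert D.data[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(6, 3))
        D = euclidean_distances(x)
        for i in range(6):
            for j in range(6):
                assert D.data[i, j] == pytest.approx(
                    math.sqrt(sum((x[i, k] - x[j, k]) ** 2 for k in range(3))),
                    abs=1e-12,
                )

    def test_missing_value_names_sample(self):
        x = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(InputError, match="mouse-b"):
            euclidean_distances(x, ids=["mouse-a", "mouse-b"])

    def test_asymmetry_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(bad, ("a", "b"))


class TestPermanova:
    def test_univariate_equals_anova_f(self, rng):
        """Euclidean pseudo-F on one variable is the classical ANOVA F."""
        for _ in range(10):
            x = rng.normal(size=18)
            groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
            res = permanova_oneway(
                euclidean_distances(x[:, None]), groups, n_perm=99, seed=0
            )
            F = f_oneway(x[:6], x[6:12], x[12:]).statistic
            assert res.pseudo_F == pytest.approx(F, abs=1e-10)
            assert res.df_among == 2 and res.df_within == 15

    def test_matches_scikit_bio(self, rng):
        """Cross-check the multivariate statistic against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        x = rng.normal(size=(15, 3))
        x[5:10] += 1.5
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        ids = [f"s{i}" for i in range(15)]
        ours = permanova_oneway(euclidean_distances(x, ids), groups,
                                n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(
            euclidean_distances(x, ids).data, ids
        )
        theirs = skbio_stats.permanova(dm, grouping=list(groups),
                                       permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-8)

    def test_identical_observations(self):
        x = np.ones((8, 2))
        res = permanova_oneway(euclidean_distances(x), ["a"] * 4 + ["b"] * 4,
                               n_perm=99, seed=0)
        assert res.pseudo_F == 0.0 and res.p_perm == 1.0

    def test_perfect_separation_floor_p(self, rng):
        vals, groups = _clusters(rng, [[0, 0], [50, 50]], 6, spread=0.01)
        res = permanova_oneway(euclidean_distances(vals), groups,
                               n_perm=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_singleton_group_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(InputError, match="b"):
            permanova_oneway(euclidean_distances(x), ["a", "a", "a", "a", "b"])

    def test_too_few_permutations_rejected(self, rng):
        x = rng.normal(size=(6, 2))
        with pytest.raises(InputError):
            permanova_oneway(euclidean_distances(x), ["a"] * 3 + ["b"] * 3,
                             n_perm=10)

    def test_seed_determinism(self, rng):
        x = rng.normal(size=(12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        D = euclidean_distances(x)
        r1 = permanova_oneway(D, groups, n_perm=199, seed=5)
        r2 = permanova_oneway(D, groups, n_perm=199, seed=5)
        assert r1 == r2

    def test_p_matches_exhaustive_enumeration(self, rng):
        """Monte-Carlo p agrees with full enumeration of label assignments."""
        x = rng.normal(size=8)
        x[4:] += 1.0
        groups = ["a"] * 4 + ["b"] * 4
        D = euclidean_distances(x[:, None])
        d2 = D.data**2

        def f_of(idx_a):
            idx_a = np.asarray(idx_a)
            idx_b = np.array([i for i in range(8) if i not in set(idx_a.tolist())])
            ss_t = d2.sum() / 16.0
            ss_w = (d2[np.ix_(idx_a, idx_a)].sum() / 8.0
                    + d2[np.ix_(idx_b, idx_b)].sum() / 8.0)
            return (ss_t - ss_w) / (ss_w / 6.0)

        f_obs = f_of(np.arange(4))
        perms = list(itertools.combinations(range(8), 4))
        p_exact = sum(f_of(c) >= f_obs - 1e-12 for c in perms) / len(perms)
        res = permanova_oneway(D, groups, n_perm=1999, seed=3)
        assert res.pseudo_F == pytest.approx(f_obs, abs=1e-10)
        mc_err = 3 * math.sqrt(p_exact * (1 - p_exact) / 1999) + 1e-3
        assert abs(res.p_perm - p_exact) < mc_err


class TestPairwise:
    def test_t_squared_is_two_group_f(self, rng):
        x = rng.normal(size=(18, 3))
        x[6:12] += 1.0
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        D = euclidean_distances(x)
        for pw in pairwise_permanova(D, groups, n_perm=99, seed=0):
            ia = [i for i, g in enumerate(groups) if g == pw.pair[0]]
            ib = [i for i, g in enumerate(groups) if g == pw.pair[1]]
            ix = np.array(ia + ib)
            sub = D.submatrix(ix)
            res = permanova_oneway(sub, [groups[i] for i in ix], n_perm=99, seed=0)
            assert pw.t**2 == pytest.approx(res.pseudo_F, abs=1e-10)

    def test_identical_groups_t_near_zero(self):
        x = np.tile(np.arange(5.0)[:, None], (2, 1))
        groups = ["a"] * 5 + ["b"] * 5
        (pw,) = pairwise_permanova(euclidean_distances(x), groups, n_perm=99,
                                   seed=0)
        assert pw.t == pytest.approx(0.0, abs=1e-6)


class TestCap:
    def test_separated_clusters_trace_and_loo(self, rng):
        centers = [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]]
        vals, groups = _clusters(rng, centers, 6)
        D = euclidean_distances(vals)
        model = cap_fit(D, groups, m=3, values=vals)
        assert model.trace == pytest.approx(3.0, abs=0.05)  # ≈ g − 1
        conf = cap_loo(vals, groups, m=3)
        assert conf.overall_percent_correct == 100.0
        trace, p = cap_permutation_test(D, groups, m=3, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_automatic_m_selection_ties_to_smallest(self, rng):
        from trophiso.multivariate_stats import _loo_success

        vals, groups = _clusters(rng, [[0, 0, 0], [10, 0, 0], [0, 10, 0],
                                       [0, 0, 10]], 6)
        D = euclidean_distances(vals)
        model = cap_fit(D, groups)
        successes = {m: _loo_success(D, groups, m) for m in range(1, 4)}
        best = max(successes.values())
        assert successes[model.m] == best == 1.0
        # smallest m on ties
        assert model.m == min(m for m, s in successes.items() if s == best)

    def test_null_labels_small_trace(self, rng):
        vals = rng.normal(size=(24, 3))
        groups = [lab for lab in "abcd" for _ in range(6)]
        model = cap_fit(euclidean_distances(vals), groups, m=3)
        assert model.trace < 1.5  # far from the separable limit of 3

    def test_trace_invariant_to_copermutation(self, rng):
        vals, groups = _clusters(rng, [[0, 0], [4, 0], [0, 4]], 5, spread=0.5)
        D = euclidean_distances(vals)
        model = cap_fit(D, groups, m=3)
        perm = rng.permutation(D.n)
        D2 = DistanceMatrix(D.data[np.ix_(perm, perm)],
                            tuple(D.ids[i] for i in perm))
        model2 = cap_fit(D2, [groups[i] for i in perm], m=3)
        assert model2.trace == pytest.approx(model.trace, abs=1e-9)

    def test_full_rank_equals_lda_allocation(self, rng):
        """With Euclidean distances and all axes retained, nearest-centroid
        allocation in canonical space reproduces classical LDA."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        centers = [[0, 0, 0], [2.5, 1.0, 0], [0, 2.5, 1.0]]
        vals, groups = _clusters(rng, centers, 15, spread=1.0)
        D = euclidean_distances(vals)
        model = cap_fit(D, groups, m=3, values=vals)
        lda = sklearn_da.LinearDiscriminantAnalysis(
            priors=[1 / 3, 1 / 3, 1 / 3]
        ).fit(vals, groups)
        expected = lda.predict(vals)
        ours = [cap_assign(model, v)[0] for v in vals]
        assert list(expected) == ours

    def test_add_a_point_self_consistency(self, rng):
        vals, groups = _clusters(rng, [[0, 0, 0], [5, 0, 0], [0, 5, 0]], 6,
                                 spread=1.0)
        D = euclidean_distances(vals)
        model = cap_fit(D, groups, m=4, values=vals)
        for i in [0, 7, 13]:
            _, coords, _, _ = cap_assign(model, vals[i])
            assert np.allclose(coords, model.canonical_coords[i], atol=1e-8)

    def test_training_point_classified_to_own_group(self, rng):
        vals, groups = _clusters(rng, [[0, 0], [8, 0], [0, 8]], 6)
        model = cap_fit(euclidean_distances(vals), groups, m=2, values=vals)
        for i in range(0, 18, 5):
            assert cap_assign(model, vals[i])[0] == groups[i]

    def test_equidistant_tie_flagged_lexicographic(self):
        # two mirrored pairs; the origin is equidistant from both centroids
        vals = np.array([[-2.0, 1.0], [-2.0, -1.0], [2.0, 1.0], [2.0, -1.0]])
        groups = ["right", "right", "left", "left"]  # reverse-alphabetical on x
        model = cap_fit(euclidean_distances(vals), groups, m=1, values=vals)
        pred, _, dists, tie = cap_assign(model, [0.0, 0.0])
        assert tie is True
        assert pred == "left"  # lexicographically first label
        assert dists["left"] == pytest.approx(dists["right"], abs=1e-9)

    def test_new_sample_inside_other_cluster(self, rng):
        """A held-out summit-like animal lands in the cluster it resembles."""
        vals, groups = _clusters(rng, [[-17, 19, -1.5], [-22, 7.6, 1.5],
                                       [-21, 10, 1.0]], 8, spread=0.5)
        groups = (["2000-3000"] * 8 + ["4000-5000"] * 8 + [">5000"] * 8)
        model = cap_fit(euclidean_distances(vals), groups, m=2, values=vals)
        pred, _, _, _ = cap_assign(model, [-21.5, 7.0, 2.0])
        assert pred == "4000-5000"

    def test_dimension_mismatch(self, rng):
        vals, groups = _clusters(rng, [[0, 0], [5, 5]], 5)
        model = cap_fit(euclidean_distances(vals), groups, m=1, values=vals)
        with pytest.raises(InputError, match="dimension"):
            cap_assign(model, [1.0, 2.0, 3.0])

    def test_duplicated_cluster_rows_near_half(self, rng):
        """Two labels drawn from the same cluster classify ≈ 50% each."""
        shared = rng.normal(size=(24, 2))
        far = rng.normal(size=(12, 2)) + 20
        vals = np.vstack([shared, far])
        groups = ["a1"] * 12 + ["a2"] * 12 + ["b"] * 12
        conf = cap_loo(vals, groups, m=2)
        idx = {lab: i for i, lab in enumerate(conf.labels)}
        for lab in ("a1", "a2"):
            frac = conf.counts[idx[lab], idx[lab]] / 12
            assert 0.1 <= frac <= 0.9
        assert conf.counts[idx["b"], idx["b"]] == 12
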