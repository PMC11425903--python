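import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microstab import (
    CountTable,
    bray_curtis_matrix,
    chao1,
    group_compare,
    group_trend,
    pcoa,
    permanova,
    shannon,
)


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([7, 0, 0], 0.0),
            # -sum p ln p with p = 1/6, 1/3, 1/2 evaluated directly
            ([1, 2, 3], -(1 / 6 * np.log(1 / 6) + 1 / 3 * np.log(1 / 3)
                          + 1 / 2 * np.log(1 / 2))),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestChao1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([2, 2, 3], 3.0),  # no singletons
            ([1, 1, 2], 3.5),  # 3 + 2*1/(2*2)
            ([1, 1], 3.0),  # 2 + 2*1/(2*1)
        ],
    )
    def test_known_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chao1([0.5, 0.5])


class TestAgainstReferenceImplementation:
    def test_alpha_matches_scikit_bio_on_random_tables(self):
        from skbio.diversity.alpha import chao1 as sk_chao1
        from skbio.diversity.alpha import shannon as sk_shannon

        rng = np.random.default_rng(42)
        for _ in range(100):
            counts = rng.poisson(3, size=20)
            if counts.sum() == 0:
                counts[0] = 1
            assert shannon(counts) == pytest.approx(sk_shannon(counts), abs=1e-10)
            assert chao1(counts) == pytest.approx(
                sk_chao1(counts, bias_corrected=True), abs=1e-10
            )

    def test_bray_curtis_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(10, size=(15, 6)).astype(float) + 1
        table = CountTable(
            [f"t{i}" for i in range(15)], [f"s{j}" for j in range(6)], counts
        )
        d = bray_curtis_matrix(table).to_numpy()
        for a in range(6):
            for b in range(6):
                num = np.abs(counts[:, a] - counts[:, b]).sum()
                den = (counts[:, a] + counts[:, b]).sum()
                assert d[a, b] == pytest.approx(num / den, abs=1e-10)


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        table = CountTable(
            ["a", "b"], ["s1", "s2", "s3"],
            np.array([[2.0, 2.0, 0.0], [0.0, 0.0, 5.0]]),
        )
        d = bray_curtis_matrix(table)
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_worked_example(self):
        table = CountTable(
            ["a", "b"], ["s1", "s2"], np.array([[2.0, 1.0], [2.0, 3.0]])
        )
        assert bray_curtis_matrix(table).iloc[0, 1] == pytest.approx(0.25)

    def test_all_zero_sample_rejected(self):
        table = CountTable(["a"], ["s1", "s2"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValueError):
            bray_curtis_matrix(table)


class TestPcoa:
    def test_colinear_points_recover_distances(self):
        # 3 points on a line at 0, 3, 5: Euclidean distance matrix
        pos = np.array([0.0, 3.0, 5.0])
        d = pd.DataFrame(np.abs(pos[:, None] - pos[None, :]),
                         index=list("abc"), columns=list("abc"))
        res = pcoa(d, n_axes=2)
        positive = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(positive) == 1
        coords = res.coordinates[:, 0]
        recon = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-9)

    def test_identical_samples_give_zero_eigenvalues(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"),
                         columns=list("abcd"))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_input_reproduced_in_full_rank(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(6)])
        res = pcoa(d, n_axes=6)
        recon = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-8)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)

    def test_matches_scikit_bio_eigenvalues(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 4))
        ids = [f"s{i}" for i in range(7)]
        dm = squareform(pdist(pts))
        ours = pcoa(pd.DataFrame(dm, index=ids, columns=ids), n_axes=4)
        theirs = sk_pcoa(DistanceMatrix(dm, ids))
        np.testing.assert_allclose(
            ours.eigenvalues[:4], theirs.eigvals.values[:4], atol=1e-8
        )


class TestPermanova:
    def test_maximal_separation_gives_smallest_p(self):
        # two tight groups far apart; with 6+6 samples the chance a random
        # permutation recreates the split is ~2e-6, so p hits its floor
        d = np.ones((12, 12))
        d[:6, :6] = 0.001
        d[6:, 6:] = 0.001
        np.fill_diagonal(d, 0.0)
        f, p = permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_one_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4)

    def test_singleton_group_warns(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.warns(UserWarning):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=49, seed=0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        groups = ["a"] * 5 + ["b"] * 5
        assert permanova(d, groups, n_perm=199, seed=5) == permanova(
            d, groups, n_perm=199, seed=5
        )

    def test_statistic_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(2)
        dm = squareform(pdist(rng.normal(size=(12, 4))))
        ids = [f"s{i}" for i in range(12)]
        groups = ["a"] * 6 + ["b"] * 6
        f, _ = permanova(dm, groups, n_perm=9, seed=0)
        res = sk_permanova(DistanceMatrix(dm, ids), grouping=list(groups),
                           permutations=9)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)


class TestGroupTrend:
    def test_perfect_line(self):
        tps = ["S1", "S2", "S3", "S4"]
        slope, p, adj = group_trend([2.0, 4.0, 6.0, 8.0], tps)
        assert slope == pytest.approx(2.0)
        assert adj == pytest.approx(1.0)

    def test_constant_series_has_zero_slope(self):
        slope, _, _ = group_trend([3.0, 3.0, 3.0, 3.0], ["S1", "S2", "S3", "S4"])
        assert slope == pytest.approx(0.0)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            group_trend([1.0, 2.0], ["S1", "S2"])


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        _, p = group_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_smallest_exact_two_sided_p_for_n3_n3(self):
        # complete separation; exact enumeration over C(6,3)=20 assignments
        _, p = group_compare([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2, 3])
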