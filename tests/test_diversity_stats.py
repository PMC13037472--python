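import numpy as np
import pytest
from scipy import stats

from phyloneutral import diversity_stats as ds
from phyloneutral.io_core import FeatureTable
from phyloneutral.synthetic_data import PhyloSimSpec, simulate_phylogeny

from conftest import make_phylogeny


def table_from(counts):
    counts = np.asarray(counts)
    return FeatureTable(
        [f"t{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


# ---------------------------------------------------------------------------
# independent oracles


def unifrac_oracle(table, phylogeny, weighted):
    """Brute-force per-branch walk: recompute tip sets under every branch by
    explicit subtree enumeration (independent of the postorder/matrix route)."""
    counts = {t: table.counts[i] for i, t in enumerate(table.taxon_ids)}
    totals = table.counts.sum(axis=0).astype(float)
    n = table.n_samples
    branches = []
    for node in phylogeny.tree.traverse(include_self=False):
        tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        branches.append((node.length or 0.0, tips))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = den = 0.0
                for length, tips in branches:
                    ai = sum(counts[t][i] for t in tips if t in counts) / totals[i]
                    aj = sum(counts[t][j] for t in tips if t in counts) / totals[j]
                    num += length * abs(ai - aj)
                    den += length * (ai + aj)
                D[i, j] = D[j, i] = num / den if den else 0.0
            else:
                uniq = both = 0.0
                for length, tips in branches:
                    pi = any(counts[t][i] > 0 for t in tips if t in counts)
                    pj = any(counts[t][j] > 0 for t in tips if t in counts)
                    if pi or pj:
                        both += length
                        if pi != pj:
                            uniq += length
                D[i, j] = D[j, i] = uniq / both if both else 0.0
    return D


def random_fixture(seed):
    spec = PhyloSimSpec(n_reference_tips=10, n_focal_clades=0, tips_per_clade=0, seed=seed)
    phy, _ = simulate_phylogeny(spec)
    rng = np.random.default_rng(seed + 500)
    counts = rng.integers(0, 20, size=(10, 4))
    counts[:, counts.sum(axis=0) == 0] += 1
    table = FeatureTable(phy.tip_names, [f"s{j}" for j in range(4)], counts)
    return table, phy


# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = ds.bray_curtis(table_from([[3, 3], [5, 5]]))
        assert dm.between("s0", "s1") == 0.0

    def test_disjoint_supports_one(self):
        dm = ds.bray_curtis(table_from([[3, 0], [0, 5]]))
        assert dm.between("s0", "s1") == 1.0

    def test_hand_value(self):
        dm = ds.bray_curtis(table_from([[1, 3], [2, 0]]))
        assert dm.between("s0", "s1") == pytest.approx(1 - 2 * 1 / 6)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="s1"):
            ds.bray_curtis(table_from([[1, 0], [2, 0]]))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        dm = ds.bray_curtis(table_from(rng.integers(0, 30, size=(12, 6)) + 1))
        d = dm.data
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestAitchison:
    def test_identical_samples_zero(self):
        dm = ds.aitchison(table_from([[3, 3], [5, 5]]))
        assert dm.between("s0", "s1") == pytest.approx(0.0, abs=1e-12)

    def test_clr_scale_invariance(self):
        # counts+pseudocount of one sample scaled by a constant: CLR unchanged
        t1 = table_from([[1, 1], [3, 3], [9, 9]])
        t2 = table_from([[1, 13], [3, 27], [9, 69]])  # s1 col: (c+1)*7 - 1
        d1 = ds.aitchison(t1, pseudocount=1.0)
        d2 = ds.aitchison(t2, pseudocount=1.0)
        assert d2.between("s0", "s1") == pytest.approx(d1.between("s0", "s1"), abs=1e-9)

    def test_two_step_oracle(self):
        counts = np.array([[4, 1], [2, 9], [7, 3]])
        dm = ds.aitchison(table_from(counts), pseudocount=1.0)
        logs = np.log(counts + 1.0)
        clr = logs - logs.mean(axis=0, keepdims=True)
        expected = np.sqrt(((clr[:, 0] - clr[:, 1]) ** 2).sum())
        assert dm.between("s0", "s1") == pytest.approx(expected, rel=1e-12)


class TestUniFrac:
    def test_identical_samples_zero(self):
        phy = make_phylogeny("(A:1,B:1);")
        table = FeatureTable(["A", "B"], ["s0", "s1"], np.array([[2, 2], [3, 3]]))
        for weighted in (False, True):
            dm = ds.unifrac(table, phy, weighted=weighted)
            assert dm.between("s0", "s1") == pytest.approx(0.0, abs=1e-12)

    def test_star_disjoint_unweighted_one(self):
        phy = make_phylogeny("(A:1,B:1);")
        table = FeatureTable(["A", "B"], ["s0", "s1"], np.array([[2, 0], [0, 3]]))
        dm = ds.unifrac(table, phy, weighted=False)
        assert dm.between("s0", "s1") == 1.0

    def test_nested_half(self):
        # sample0 = {A,B}, sample1 = {A}: one of two branches unique
        phy = make_phylogeny("(A:1,B:1);")
        table = FeatureTable(["A", "B"], ["s0", "s1"], np.array([[1, 1], [1, 0]]))
        dm = ds.unifrac(table, phy, weighted=False)
        assert dm.between("s0", "s1") == pytest.approx(0.5)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_brute_force_oracle(self, weighted):
        for seed in range(10):
            table, phy = random_fixture(seed)
            dm = ds.unifrac(table, phy, weighted=weighted)
            oracle = unifrac_oracle(table, phy, weighted)
            np.testing.assert_allclose(dm.data, oracle, atol=1e-10)

    def test_missing_taxon_errors(self):
        phy = make_phylogeny("(A:1,B:1);")
        table = FeatureTable(["A", "Z"], ["s0"], np.array([[1], [1]]))
        with pytest.raises(ValueError, match="Z"):
            ds.unifrac(table, phy)

    def test_raw_weighted_unnormalized(self):
        table, phy = random_fixture(0)
        raw = ds.unifrac(table, phy, weighted=True, raw=True)
        norm = ds.unifrac(table, phy, weighted=True, raw=False)
        assert not np.allclose(raw.data, norm.data)
        assert np.all(norm.data <= 1.0 + 1e-12)


class TestFaithPD:
    def test_single_tip(self):
        phy = make_phylogeny("(A:1,B:1);")
        assert ds.faith_pd({"A"}, phy) == 1.0

    def test_all_tips_total_length(self):
        phy = make_phylogeny("(A:1,B:1);")
        assert ds.faith_pd({"A", "B"}, phy) == 2.0

    def test_monotone_in_taxa(self):
        spec = PhyloSimSpec(n_reference_tips=12, n_focal_clades=0, tips_per_clade=0, seed=2)
        phy, _ = simulate_phylogeny(spec)
        tips = phy.tip_names
        small = ds.faith_pd(set(tips[:4]), phy)
        large = ds.faith_pd(set(tips[:9]), phy)
        assert small <= large

    def test_empty_set_warns_zero(self, two_tip_phylogeny):
        with pytest.warns(UserWarning):
            assert ds.faith_pd(set(), two_tip_phylogeny) == 0.0


class TestPCoA:
    def test_collinear_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        dm = ds.DistanceMatrix(["a", "b", "c"], D)
        res = ds.pcoa(dm)
        assert np.sum(res.eigenvalues > 1e-10) == 1
        coords = res.coordinates
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_duplicated_sample_coincident(self):
        D = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        res = ds.pcoa(ds.DistanceMatrix(["a", "b", "c"], D))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_proportions_sum_at_most_one(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = ds.pcoa(ds.DistanceMatrix([f"s{i}" for i in range(8)], D))
        assert res.proportion_explained.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            ds.pcoa(ds.DistanceMatrix(["a"], np.zeros((1, 1))))


def metadata_dm(within, between):
    """4 samples, 2 groups: within-group distances then between-group."""
    D = np.array(
        [
            [0.0, within[0], between[0], between[1]],
            [within[0], 0.0, between[2], between[3]],
            [between[0], between[2], 0.0, within[1]],
            [between[1], between[3], within[1], 0.0],
        ]
    )
    dm = ds.DistanceMatrix(["a1", "a2", "b1", "b2"], D)
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return dm, groups


class TestANOSIM:
    def test_perfect_separation_r_one(self):
        # all within < all between: rank arithmetic gives R = 1 exactly
        dm, groups = metadata_dm(within=[0.1, 0.2], between=[0.5, 0.6, 0.7, 0.8])
        res = ds.anosim(dm, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_duplicated_groups_r_nonpositive(self):
        dm, groups = metadata_dm(within=[0.9, 0.9], between=[0.1, 0.2, 0.3, 0.4])
        res = ds.anosim(dm, groups, n_perm=99, seed=0)
        assert res.statistic <= 0

    def test_null_centered_at_zero(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        dm = ds.DistanceMatrix(ids, D)
        stats_ = []
        for draw in range(200):
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            res = ds.anosim(dm, dict(zip(ids, labels)), n_perm=1, seed=draw)
            stats_.append(res.statistic)
        assert abs(np.mean(stats_)) < 0.05

    def test_single_sample_group_errors(self):
        dm, groups = metadata_dm(within=[0.1, 0.2], between=[0.5, 0.6, 0.7, 0.8])
        groups = dict(groups, a2="C", b2="C")  # A becomes singleton
        with pytest.raises(ValueError, match="single"):
            ds.anosim(dm, groups, n_perm=9, seed=0)

    def test_p_value_in_unit_interval(self):
        dm, groups = metadata_dm(within=[0.3, 0.4], between=[0.2, 0.5, 0.45, 0.35])
        res = ds.anosim(dm, groups, n_perm=99, seed=1)
        assert 0 < res.p_value <= 1


class TestDispersion:
    @staticmethod
    def coords_dm(pts):
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(len(pts))]
        return ds.DistanceMatrix(ids, D), ids

    def test_mirror_groups_f_zero(self):
        square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        pts = np.vstack([square, square + 10.0])
        dm, ids = self.coords_dm(pts)
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(ids)}
        res = ds.dispersion_test(dm, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.9

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 2))
        pts = np.vstack([base, base * 10.0 + 30.0])
        dm, ids = self.coords_dm(pts)
        groups = {s: ("A" if i < 6 else "B") for i, s in enumerate(ids)}
        res = ds.dispersion_test(dm, groups, n_perm=999, seed=0)
        assert res.p_value <= 0.01

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        dm, ids = self.coords_dm(pts)
        groups = {s: ("A" if i % 2 else "B") for i, s in enumerate(ids)}
        res = ds.dispersion_test(dm, groups, n_perm=49, seed=2)
        assert 0 < res.p_value <= 1


class TestRankTests:
    def test_exact_enumeration_example(self):
        stat, p = ds.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = ds.rank_sum_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_exact_close_to_asymptotic(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(0.5, size=10)
        _, p_exact = ds.rank_sum_test(x, y)  # n=20, no ties -> exact
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p_exact == pytest.approx(res.pvalue, abs=0.02)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ds.rank_sum_test([], [1.0])

    def test_kruskal_identical_groups(self):
        h, p = ds.kruskal_wallis([[3, 3], [3, 3, 3]])
        assert h == 0.0
        assert p == 1.0

    def test_kruskal_two_groups_tracks_rank_sum(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(0.8, size=12)
        _, p_rs = ds.rank_sum_test(x, y)
        _, p_kw = ds.kruskal_wallis([x, y])
        assert p_kw == pytest.approx(p_rs, abs=0.02)

    def test_kruskal_hand_example(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        h, p = ds.kruskal_wallis(groups)
        # direct H formula, no ties: 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        ranks = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        n = 9
        expected = 12 / (n * (n + 1)) * sum(
            3 * (np.mean(r) - (n + 1) / 2) ** 2 for r in ranks
        )
        assert h == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, 2))

    def test_kruskal_empty_group_errors(self):
        with pytest.raises(ValueError):
            ds.kruskal_wallis([[1.0], []])


class TestDistanceMatrixType:
    def test_asymmetric_rejected(self):
        M = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ds.DistanceMatrix(["a", "b"], M)

    def test_nonzero_diagonal_rejected(self):
        M = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            ds.DistanceMatrix(["a", "b"], M)

    def test_negative_rejected(self):
        M = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            ds.DistanceMatrix(["a", "b"], M)
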