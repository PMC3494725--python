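"""Tree-comparison features: mirror, ToL correction, MAST and congruence."""

import numpy as np
import pytest
from scipy import stats

from _oracles import mast_exhaustive, patristic_path_walk, random_topology
from coevoppi import (
    DistanceMatrix,
    GeneTree,
    NotComputable,
    TolModel,
    ValidationError,
    icong,
    mast_size,
    mirror,
    patristic_matrix,
    simulate_species_tree,
    tol_correct,
    tol_mirror,
    tree_feature_block,
)


def _random_matrix(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    labels = labels or tuple(f"L{i}" for i in range(n))
    d = rng.uniform(0.5, 3.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(labels), d)


class TestPatristic:
    def test_two_leaf_path_sum(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2);")
        from coevoppi import read_newick

        m = patristic_matrix(read_newick(p))
        assert m.d[0, 1] == pytest.approx(3.0)

    def test_three_leaf(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);")
        from coevoppi import read_newick

        m = patristic_matrix(read_newick(p))
        i = {l: k for k, l in enumerate(m.labels)}
        assert m.d[i["A"], i["B"]] == pytest.approx(2.0)
        assert m.d[i["A"], i["C"]] == pytest.approx(4.0)
        assert m.d[i["B"], i["C"]] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_walk_oracle(self, seed):
        labels = [f"X{i}" for i in range(12)]
        gt = random_topology(12, labels, seed=seed)
        m = patristic_matrix(gt)
        olabels, od = patristic_path_walk(gt)
        assert list(m.labels) == olabels
        np.testing.assert_allclose(m.d, od, atol=1e-9)

    def test_single_leaf_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1);")
        from coevoppi import read_newick

        with pytest.raises(ValidationError):
            patristic_matrix(read_newick(p))


class TestMirror:
    def test_self_correlation_is_one(self):
        m = _random_matrix(8, seed=1)
        assert mirror(m, m) == pytest.approx(1.0)

    def test_affine_negative_slope(self):
        m = _random_matrix(8, seed=2)
        neg = DistanceMatrix(m.labels, np.where(np.eye(8) > 0, 0.0, 10.0 - m.d))
        assert mirror(m, neg) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        a = _random_matrix(10, seed=3)
        b = _random_matrix(10, seed=4)
        x, y = a.upper(), b.upper()
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert mirror(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self):
        a = _random_matrix(9, seed=5)
        b = _random_matrix(9, seed=6)
        assert mirror(a, b) == pytest.approx(mirror(b, a))

    def test_too_few_common_labels_not_computable(self):
        a = _random_matrix(6, seed=7)
        b = _random_matrix(6, seed=8)
        with pytest.raises(NotComputable):
            mirror(a, b)

    def test_zero_variance_not_computable(self):
        labels = tuple(f"L{i}" for i in range(8))
        const = DistanceMatrix(labels, np.where(np.eye(8) > 0, 0.0, 2.0))
        with pytest.raises(NotComputable):
            mirror(const, _random_matrix(8, seed=9))


class TestTolCorrect:
    def test_proportional_matrix_gives_zero_residuals(self):
        t = _random_matrix(8, seed=10)
        m = DistanceMatrix(t.labels, 2.5 * t.d)
        r = tol_correct(m, TolModel(t))
        np.testing.assert_allclose(r.d, 0.0, atol=1e-12)

    def test_constant_matrices(self):
        labels = tuple(f"L{i}" for i in range(8))
        m = DistanceMatrix(labels, np.where(np.eye(8) > 0, 0.0, 4.0))
        t = DistanceMatrix(labels, np.where(np.eye(8) > 0, 0.0, 2.0))
        r = tol_correct(m, t)
        np.testing.assert_allclose(r.d, 0.0, atol=1e-12)

    def test_entrywise_recomputation(self):
        m = _random_matrix(9, seed=11)
        t = _random_matrix(9, seed=12)
        r = tol_correct(m, t)
        s = m.upper().mean() / t.upper().mean()
        np.testing.assert_allclose(r.d, m.d - s * t.d, atol=1e-12)

    def test_idempotent_residual_mean_zero(self):
        m = _random_matrix(9, seed=13)
        t = _random_matrix(9, seed=14)
        r = tol_correct(m, t)
        # mean residual is exactly zero, so re-correcting contributes s ~ 0
        assert abs(r.upper().mean()) < 1e-12
        r2 = tol_correct(r, t)
        np.testing.assert_allclose(r2.d, r.d, atol=1e-12)

    def test_zero_tol_mean_rejected(self):
        labels = tuple(f"L{i}" for i in range(8))
        zero = DistanceMatrix(labels, np.zeros((8, 8)))
        with pytest.raises(ValidationError):
            tol_correct(_random_matrix(8, seed=15), zero)


class TestTolMirror:
    def test_both_proportional_to_tol_degenerate(self):
        t = _random_matrix(8, seed=16)
        a = DistanceMatrix(t.labels, 2.0 * t.d)
        b = DistanceMatrix(t.labels, 3.0 * t.d)
        with pytest.raises(NotComputable):
            tol_mirror(a, b, TolModel(t))

    def test_identical_distortion_gives_one(self):
        t = _random_matrix(8, seed=17)
        noise = _random_matrix(8, seed=18, labels=t.labels)
        a = DistanceMatrix(t.labels, 2.0 * t.d + noise.d)
        b = DistanceMatrix(t.labels, 5.0 * t.d + noise.d)
        # shared additive distortion on top of scaled tol: residuals align
        assert tol_mirror(a, b, TolModel(t)) == pytest.approx(1.0, abs=1e-9)

    def test_compositional_oracle(self):
        t = _random_matrix(9, seed=19)
        a = _random_matrix(9, seed=20, labels=t.labels)
        b = _random_matrix(9, seed=21, labels=t.labels)
        ra = tol_correct(a, t)
        rb = tol_correct(b, t)
        assert tol_mirror(a, b, TolModel(t)) == pytest.approx(mirror(ra, rb))


class TestMast:
    def test_identical_topologies(self):
        labels = [f"X{i}" for i in range(8)]
        t = random_topology(8, labels, seed=30)
        assert mast_size(t, t) == 8

    def test_unrooted_invariance_caterpillar(self):
        import dendropy

        def caterpillar(order):
            inner = f"({order[0]}:1,{order[1]}:1)"
            for l in order[2:]:
                inner = f"({inner}:1,{l}:1)"
            return GeneTree(
                "cat",
                dendropy.Tree.get(data=inner + ";", schema="newick"),
            )

        labels = [f"X{i}" for i in range(8)]
        a = caterpillar(labels)
        b = caterpillar(labels[::-1])
        assert mast_size(a, b) == 8

    @pytest.mark.parametrize("n_leaves", [8, 10, 12])
    def test_matches_exhaustive_oracle(self, n_leaves):
        """Exact agreement with brute-force subset search, >= 50 pairs total."""
        labels = [f"X{i}" for i in range(n_leaves)]
        for s in range(17):
            a = random_topology(n_leaves, labels, seed=1000 + 10 * n_leaves + s)
            b = random_topology(n_leaves, labels, seed=5000 + 10 * n_leaves + s)
            assert mast_size(a, b) == mast_exhaustive(a, b), f"seed set {s}"

    def test_symmetric_and_bounded(self):
        labels = [f"X{i}" for i in range(9)]
        a = random_topology(9, labels, seed=40)
        b = random_topology(9, labels, seed=41)
        m = mast_size(a, b)
        assert m == mast_size(b, a)
        assert 3 <= m <= 9

    def test_invariant_under_consistent_relabelling(self):
        labels = [f"X{i}" for i in range(9)]
        a = random_topology(9, labels, seed=42)
        b = random_topology(9, labels, seed=43)
        m0 = mast_size(a, b)
        mapping = {l: f"Y{i}" for i, l in enumerate(labels)}
        for t in (a, b):
            for lf in t.tree.leaf_node_iter():
                lf.taxon.label = mapping[lf.taxon.label]
        assert mast_size(a, b) == m0

    def test_too_few_common_leaves(self):
        a = random_topology(6, [f"X{i}" for i in range(6)], seed=44)
        b = random_topology(6, [f"X{i}" for i in range(6)], seed=45)
        with pytest.raises(NotComputable):
            mast_size(a, b)

    def test_multifurcating_trees_supported(self):
        import dendropy

        a = GeneTree(
            "m1",
            dendropy.Tree.get(
                data="((A:1,B:1,C:1):1,(D:1,E:1):1,(F:1,G:1):1);",
                schema="newick",
            ),
        )
        assert mast_size(a, a) == 7
        b = random_topology(7, list("ABCDEFG"), seed=46)
        m = mast_size(a, b)
        assert 3 <= m <= 7
        assert m == mast_exhaustive(a, b)


class TestIcong:
    def test_identical_trees_minimal_pvalue(self):
        labels = [f"X{i}" for i in range(10)]
        t = random_topology(10, labels, seed=50)
        res = icong(t, t, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.icong > 1.0
        assert res.mast_size == 10

    def test_deterministic_given_seed(self):
        labels = [f"X{i}" for i in range(10)]
        a = random_topology(10, labels, seed=51)
        b = random_topology(10, labels, seed=52)
        r1 = icong(a, b, n_permutations=150, seed=123)
        r2 = icong(a, b, n_permutations=150, seed=123)
        assert r1 == r2

    def test_pvalue_floor(self):
        labels = [f"X{i}" for i in range(10)]
        a = random_topology(10, labels, seed=53)
        b = random_topology(10, labels, seed=54)
        res = icong(a, b, n_permutations=100, seed=1)
        assert res.p_value >= 1 / 101
        assert res.mast_size <= res.n_common

    def test_null_calibration_ks_uniform(self):
        """Observed drawn from the label-shuffle null: randomized p-values
        are uniform (KS at the 1% level, 200 replicates) and the congruence
        index averages ~1."""
        labels = [f"X{i}" for i in range(10)]
        t1 = random_topology(10, labels, seed=60)
        t2 = random_topology(10, labels, seed=61)
        rng = np.random.default_rng(62)
        pvals, indices = [], []
        for _ in range(200):
            # draw the observation from the null itself
            for lf, lab in zip(
                t2.tree.leaf_node_iter(),
                np.array(labels)[rng.permutation(10)],
            ):
                lf.taxon.label = str(lab)
            res, null = icong(
                t1, t2, n_permutations=100, seed=int(rng.integers(2**31)),
                return_null=True,
            )
            obs = res.mast_size
            # randomized p-value: exactly uniform for a discrete statistic
            u = rng.random()
            p = (np.sum(null > obs) + u * (1 + np.sum(null == obs))) / (
                len(null) + 1
            )
            pvals.append(p)
            indices.append(res.icong)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        assert np.mean(indices) == pytest.approx(1.0, abs=0.1)


class TestTreeFeatureBlock:
    def test_tree_equals_tol_restriction(self):
        st = simulate_species_tree(10, seed=70)
        block = tree_feature_block(st, st, st, n_permutations=100, seed=0)
        assert block["mirror"] == pytest.approx(1.0)
        assert block["mirror_A"] == pytest.approx(1.0)
        assert block["tol_mirror"] is None  # zero-variance residuals
        assert block["icong"] > 1.0

    def test_compositional_against_standalone_ops(self, small_dataset):
        trees = small_dataset["trees"]
        tol = small_dataset["species_tree"]
        (pa, pb) = small_dataset["labels"][0].pair
        ta, tb = trees[pa], trees[pb]
        block = tree_feature_block(ta, tb, tol, n_permutations=100, seed=0)
        assert all(v is not None for v in block.values())
        ma, mb = patristic_matrix(ta), patristic_matrix(tb)
        tol_model = TolModel.from_tree(tol)
        assert block["mirror"] == pytest.approx(mirror(ma, mb))
        assert block["mirror_A"] == pytest.approx(mirror(ma, tol_model.tol_matrix))
        assert block["mirror_B"] == pytest.approx(mirror(mb, tol_model.tol_matrix))
        assert block["tol_mirror"] == pytest.approx(tol_mirror(ma, mb, tol_model))
        # congruence slots equal the standalone index recomputed with the
        # same generator consumed in the same order
        rng = np.random.default_rng(0)
        for name, (t1, t2) in {
            "icong": (ta, tb),
            "icong_A": (ta, tol),
            "icong_B": (tb, tol),
        }.items():
            assert block[name] == pytest.approx(
                icong(t1, t2, n_permutations=100, seed=rng).icong
            )

    def test_partial_failure_masks_only_affected_slots(self):
        st = simulate_species_tree(12, seed=71)
        labels = sorted(st.leaf_labels())
        a = GeneTree("a", st.tree.extract_tree_with_taxa_labels(labels=set(labels[:8])))
        b = GeneTree("b", st.tree.extract_tree_with_taxa_labels(labels=set(labels[4:])))
        # only 4 common species: pairwise features masked, per-protein kept
        block = tree_feature_block(a, b, st, n_permutations=100, seed=0)
        assert block["mirror"] is None
        assert block["icong"] is None
        assert block["mirror_A"] is not None
        assert block["icong_B"] is not None
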