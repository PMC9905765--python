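import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given
from hypothesis import strategies as st

from oramark.containers import OtuTable, ValidationError
from oramark.diversity import (
    accumulation_curve,
    alpha_diversity,
    bray_curtis,
    kruskal_stress,
    nmds,
    otu_overlap,
    pca,
    pcoa,
    rarefy,
    unweighted_unifrac,
)


def one_sample(counts) -> OtuTable:
    return OtuTable(
        pd.DataFrame([counts], index=["s"], columns=[f"o{i}" for i in range(len(counts))])
    )


class TestAlphaDiversity:
    def test_uniform_composition(self):
        """Shannon of four equal counts is ln 4; Simpson complement matches
        the finite-sample closed form."""
        res = alpha_diversity(one_sample([5, 5, 5, 5])).iloc[0]
        assert res["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert res["simpson"] == pytest.approx(1 - 4 * (5 * 4) / (20 * 19), abs=1e-12)

    def test_single_otu_sample(self):
        res = alpha_diversity(one_sample([10])).iloc[0]
        assert res["shannon"] == 0.0
        assert res["simpson"] == 0.0

    def test_hand_computed_chao_and_shannon(self):
        """Counts (1,1,2,3,5): F1=2, F2=1 so chao = 5 + 2*1/(2*2) = 5.5;
        Shannon by direct summation of -sum p ln p."""
        res = alpha_diversity(one_sample([1, 1, 2, 3, 5])).iloc[0]
        assert res["chao"] == pytest.approx(5.5, abs=1e-12)
        p = np.array([1, 1, 2, 3, 5]) / 12
        assert res["shannon"] == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)

    def test_ace_matches_hand_derivation(self):
        """All-rare sample (1,1,2,3,5): C_ace = 5/6, gamma^2 = 3/11,
        ACE = 6 + 2*(3/11)*(6/5) = 6.6545..."""
        res = alpha_diversity(one_sample([1, 1, 2, 3, 5])).iloc[0]
        expected = 5 / (5 / 6) + 2 * (3 / 11) / (5 / 6)
        assert res["ace"] == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio_estimators(self):
        counts = np.array([1, 1, 1, 2, 2, 4, 9, 11, 15, 30])
        import skbio.diversity.alpha as ska

        res = alpha_diversity(one_sample(counts)).iloc[0]
        assert res["chao"] == pytest.approx(ska.chao1(counts, bias_corrected=True))
        assert res["ace"] == pytest.approx(ska.ace(counts))
        assert res["shannon"] == pytest.approx(ska.shannon(counts, base=np.e))

    def test_simpson_undefined_below_two_reads(self):
        with pytest.raises(ValidationError, match="N < 2"):
            alpha_diversity(one_sample([1]))

    def test_relative_table_refused_by_richness_estimators(self):
        table = OtuTable(
            pd.DataFrame([[0.5, 0.5]], index=["s"], columns=["a", "b"]), relative=True
        )
        with pytest.raises(ValidationError, match="integer"):
            alpha_diversity(table)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=12).filter(
            lambda c: sum(c) >= 2
        )
    )
    def test_invariants(self, counts):
        """Shannon <= ln(observed); chao >= observed with equality at F1=0;
        zero-count OTUs change nothing."""
        res = alpha_diversity(one_sample(counts)).iloc[0]
        obs = res["observed_otus"]
        if obs >= 1:
            assert res["shannon"] <= np.log(max(obs, 1)) + 1e-12
        assert res["chao"] >= obs - 1e-12
        if (np.array(counts) == 1).sum() == 0:
            assert res["chao"] == pytest.approx(obs)
        padded = alpha_diversity(one_sample(list(counts) + [0])).iloc[0]
        assert padded["shannon"] == pytest.approx(res["shannon"], abs=1e-12)
        assert padded["chao"] == pytest.approx(res["chao"], abs=1e-12)


class TestAccumulation:
    def test_endpoint_equals_total_richness_any_seed(self, toy_table):
        for seed in (0, 1, 99):
            curve = accumulation_curve(toy_table, n_perm=20, seed=seed)
            total = int((toy_table.counts > 0).any(axis=0).sum())
            assert curve.mean_otus[-1] == total
            assert curve.sd_otus[-1] == 0.0
            assert np.all(np.diff(curve.mean_otus) >= -1e-12)

    def test_disjoint_samples_mean_at_n1(self):
        """Two disjoint samples with 3 and 4 OTUs: E[richness at n=1] = 3.5."""
        table = OtuTable(
            pd.DataFrame(
                [[1, 1, 1, 0, 0, 0, 0], [0, 0, 0, 1, 1, 1, 1]],
                index=["a", "b"],
                columns=list("pqrstuv"),
            )
        )
        curve = accumulation_curve(table, n_perm=4000, seed=3)
        se = 0.5 / np.sqrt(4000)  # sd of a fair 3/4 coin
        assert abs(curve.mean_otus[0] - 3.5) < 3 * se

    def test_identical_samples_flat(self):
        table = OtuTable(
            pd.DataFrame([[2, 3], [2, 3], [2, 3]], index=list("abc"), columns=["x", "y"])
        )
        curve = accumulation_curve(table, n_perm=10, seed=0)
        assert np.all(curve.mean_otus == 2)

    def test_bad_n_perm(self, toy_table):
        with pytest.raises(ValueError):
            accumulation_curve(toy_table, n_perm=0)


class TestRarefy:
    def test_even_depth_and_subset(self, toy_table):
        rare = rarefy(toy_table, depth=10, seed=1)
        assert (rare.counts.sum(axis=1) == 10).all()
        assert (rare.counts.to_numpy() <= toy_table.counts.to_numpy()).all()


class TestBrayCurtis:
    def test_boundaries_and_hand_value(self):
        table = OtuTable(
            pd.DataFrame(
                [[5, 5, 0], [5, 5, 0], [0, 5, 5], [9, 0, 0]],
                index=["a", "a2", "b", "c"],
                columns=["x", "y", "z"],
            )
        )
        dm = bray_curtis(table)
        assert dm["a", "a2"] == pytest.approx(0.0, abs=1e-12)
        assert dm["a", "b"] == pytest.approx(0.5, abs=1e-12)  # hand computation
        assert dm["b", "c"] == pytest.approx(1.0, abs=1e-12)  # disjoint support
        assert np.allclose(dm.data, dm.data.T)
        assert dm.data.min() >= 0 and dm.data.max() <= 1


class TestUnifrac:
    @staticmethod
    def oracle(tree, p1: set, p2: set) -> float:
        """Brute-force edge enumeration: unique / union branch length over
        edges leading to observed leaves."""
        total = unique = 0.0
        for node in tree.traverse(include_self=False):
            tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
            in1, in2 = bool(tips & p1), bool(tips & p2)
            if in1 or in2:
                total += node.length
                if in1 != in2:
                    unique += node.length
        return unique / total

    def test_four_leaf_hand_case(self):
        """Tree ((A:1,B:1):1,(C:1,D:1):1); samples {A,B} vs {A,C}:
        unique = B + C + right-inner = 3, union = 5 -> 0.6."""
        tree = skbio.TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        table = OtuTable(
            pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0]], index=["s1", "s2"], columns=list("ABCD"))
        )
        dm = unweighted_unifrac(table, tree)
        assert dm["s1", "s2"] == pytest.approx(0.6, abs=1e-12)
        assert dm["s1", "s2"] == pytest.approx(self.oracle(tree, {"A", "B"}, {"A", "C"}))

    def test_identical_and_disjoint_subtree_boundaries(self):
        tree = skbio.TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        table = OtuTable(
            pd.DataFrame(
                [[3, 1, 0, 0], [1, 2, 0, 0], [0, 0, 1, 1]],
                index=["s1", "s1b", "s2"],
                columns=list("ABCD"),
            )
        )
        dm = unweighted_unifrac(table, tree)
        assert dm["s1", "s1b"] == pytest.approx(0.0, abs=1e-12)
        assert dm["s1", "s2"] == pytest.approx(1.0, abs=1e-12)

    def test_random_trees_match_oracle(self):
        from oramark.synthetic import random_tree

        rng = np.random.default_rng(5)
        for seed in range(4):
            leaves = [f"L{i}" for i in range(8)]
            tree = random_tree(leaves, seed=seed)
            presence = rng.integers(0, 2, size=(3, 8))
            presence[presence.sum(axis=1) == 0, 0] = 1
            table = OtuTable(pd.DataFrame(presence, index=["x", "y", "z"], columns=leaves))
            dm = unweighted_unifrac(table, tree)
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                ids = table.sample_ids
                p1 = set(table.counts.columns[presence[i] > 0])
                p2 = set(table.counts.columns[presence[j] > 0])
                assert dm[ids[i], ids[j]] == pytest.approx(
                    self.oracle(tree, p1, p2), abs=1e-10
                )

    def test_missing_leaf_is_keyed_error(self):
        tree = skbio.TreeNode.read(_io.StringIO("(A:1,B:1);"))
        table = OtuTable(
            pd.DataFrame([[1, 1], [1, 0]], index=["s1", "s2"], columns=["A", "Z"])
        )
        with pytest.raises(KeyError, match="Z"):
            unweighted_unifrac(table, tree)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        dm = skbio.DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = pcoa(dm, k=2)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = skbio.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        res = pcoa(dm, k=3)
        coords = res.coordinates.to_numpy()
        d_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d_hat, d, atol=1e-9)

    def test_equidistant_points_equal_eigenvalues(self):
        dm = skbio.DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = pcoa(dm, k=2)
        assert res.explained[0] == pytest.approx(res.explained[1], abs=1e-9)


class TestNmds:
    def test_representable_configuration_low_stress(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = skbio.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        res = nmds(dm, k=2, seed=0, n_restarts=4)
        assert res.stress < 0.01

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(9, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = skbio.DistanceMatrix(d, ids=[str(i) for i in range(9)])
        s1 = nmds(dm, k=1, seed=2, n_restarts=4).stress
        s2 = nmds(dm, k=2, seed=2, n_restarts=4).stress
        assert s1 > 0
        assert s2 <= s1 + 1e-9

    def test_kruskal_stress_zero_for_perfect_embedding(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = skbio.DistanceMatrix(d, ids=list("abc"))
        assert kruskal_stress(dm, pts) == pytest.approx(0.0, abs=1e-12)


class TestPca:
    def test_rank_one_data(self):
        counts = np.array([[10, 0, 0, 0], [0, 10, 0, 0], [5, 5, 0, 0]])
        table = OtuTable(pd.DataFrame(counts, index=list("abc"), columns=list("wxyz")))
        res = pca(table, k=2)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_samples_identical_coordinates(self, toy_table):
        counts = pd.concat([toy_table.counts, toy_table.counts.iloc[[0]].rename(index={"s1": "s1b"})])
        res = pca(OtuTable(counts), k=2)
        assert np.allclose(
            res.coordinates.loc["s1"].to_numpy(), res.coordinates.loc["s1b"].to_numpy()
        )

    def test_explained_sums_to_one_at_full_rank(self, toy_table):
        res = pca(toy_table, k=4)
        assert res.explained.sum() <= 1 + 1e-9
        full = pca(toy_table, k=min(toy_table.n_samples, toy_table.n_otus))
        assert full.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_zero_rejected(self, toy_table):
        with pytest.raises(ValueError):
            pca(toy_table, k=0)


class TestOverlap:
    def test_hand_enumerated_counts(self, toy_table, toy_meta):
        """Cases s1,s2 see o1..o4 (o5 absent in s1? no: s1 has o1-o4, s2 has
        o1); controls s3,s4 see all five.  Shared = {o1..o4}, case-unique
        none, control-unique {o5}."""
        res = otu_overlap(toy_table, toy_meta)
        assert res["shared"] == 4
        assert res["unique_case"] == 0
        assert res["unique_control"] == 1
        assert res["unique_control_ids"] == ["o5"]
        assert res["shared"] + res["unique_case"] + res["unique_control"] == res["total_observed"]

    def test_disjoint_and_identical_supports(self):
        counts = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 2, 2]], index=["c1", "h1"], columns=list("abcd")
        )
        meta = pd.DataFrame({"group": ["case", "control"]}, index=["c1", "h1"])
        from oramark.containers import CohortMetadata

        res = otu_overlap(OtuTable(counts), CohortMetadata(meta))
        assert res["shared"] == 0
        assert res["unique_case"] == 2 and res["unique_control"] == 2

    def test_empty_group_rejected(self, toy_table):
        from oramark.containers import CohortMetadata

        meta = CohortMetadata(
            pd.DataFrame({"group": ["case"] * 4}, index=["s1", "s2", "s3", "s4"])
        )
        with pytest.raises(ValidationError):
            otu_overlap(toy_table, meta)
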