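import numpy as np
import pandas as pd
import pytest

from metabonet.io import FeatureTable, PreprocessConfig, preprocess
from metabonet.modules import (COLOR_PALETTE, GREY, DetectionConfig,
                               ModuleAssignment, assign_colors,
                               cluster_features, detect_modules,
                               eigenmetabolites, enforce_min_kme,
                               initial_labels, kme, merge_close_modules)
from metabonet.network import (NetworkConfig, TOMMatrix, adjacency,
                               correlation_matrix, topological_overlap)
from metabonet.simulate import SyntheticSpec, adjusted_rand_index, generate


def tom_from(values, ids):
    return TOMMatrix(pd.DataFrame(values, index=ids, columns=ids))


def block_tom(sizes, within=0.9, between=0.1):
    ids, blocks = [], []
    for b, size in enumerate(sizes):
        ids += [f"b{b}_{j:02d}" for j in range(size)]
        blocks += [b] * size
    n = len(ids)
    T = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if blocks[i] == blocks[j]:
                T[i, j] = within
    np.fill_diagonal(T, 1.0)
    return tom_from(T, ids)


class TestClusterFeatures:
    def test_within_block_merges_first(self):
        tom = block_tom([5, 5])
        tree = cluster_features(tom)
        # the first 8 merges (building two 5-blocks) happen at height 0.1
        assert np.allclose(tree[:8, 2], 0.1)
        assert tree[-1, 2] == pytest.approx(0.9)

    def test_average_linkage_hand_example(self):
        # dissimilarities: d(a,b)=0.1, d(a,c)=0.5, d(b,c)=0.6
        ids = ["a", "b", "c"]
        T = np.array([[1.0, 0.9, 0.5],
                      [0.9, 1.0, 0.4],
                      [0.5, 0.4, 1.0]])
        tree = cluster_features(tom_from(T, ids))
        assert tree[0, 2] == pytest.approx(0.1)
        assert tree[1, 2] == pytest.approx((0.5 + 0.6) / 2)

    def test_permutation_gives_same_height_multiset(self, rng):
        tom = block_tom([6, 4, 3], within=0.8, between=0.2)
        tree = cluster_features(tom)
        perm = rng.permutation(list(tom.values.index))
        tree_p = cluster_features(tom_from(
            tom.values.loc[perm, perm].to_numpy(), list(perm)))
        np.testing.assert_allclose(np.sort(tree[:, 2]),
                                   np.sort(tree_p[:, 2]), atol=1e-12)

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            cluster_features(block_tom([2]))


class TestInitialLabels:
    def test_two_planted_blocks_found(self):
        tom = block_tom([30, 30])
        tree = cluster_features(tom)
        labels = initial_labels(tree, tom, DetectionConfig(min_cluster_size=20))
        assert len(labels.module_names) == 2
        sizes = labels.sizes()
        assert all(sizes[m] == 30 for m in labels.module_names)

    def test_small_block_goes_grey(self):
        tom = block_tom([10, 30])
        tree = cluster_features(tom)
        labels = initial_labels(tree, tom, DetectionConfig(min_cluster_size=20))
        assert len(labels.module_names) == 1
        assert (labels.labels == GREY).sum() == 10

    def test_degenerate_cut_single_cluster(self):
        tom = block_tom([15, 15])
        tree = cluster_features(tom)
        labels = initial_labels(tree, tom,
                                DetectionConfig(min_cluster_size=20,
                                                cut_quantile=1.0))
        # cut at max height keeps everything in one cluster of 30
        assert len(labels.module_names) == 1
        assert labels.sizes()[labels.module_names[0]] == 30

    def test_every_feature_labelled(self):
        tom = block_tom([25, 10, 5])
        labels = initial_labels(cluster_features(tom), tom)
        assert set(labels.labels.index) == set(tom.values.index)
        assert labels.labels.notna().all()


class TestEigenmetabolites:
    def make_module_table(self, rng, n=20, p=6):
        factor = rng.standard_normal(n)
        cols = {f"f{j}": 0.9 * factor + 0.3 * rng.standard_normal(n)
                for j in range(p)}
        ab = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        labels = ModuleAssignment(pd.Series("blue", index=list(cols)))
        return FeatureTable(ab, None), labels

    def test_identical_profiles_rank_one(self, rng):
        x = rng.standard_normal(12)
        ab = pd.DataFrame({f"f{j}": x * (j + 1) for j in range(3)},
                          index=[f"S{i}" for i in range(12)])
        table = FeatureTable(ab, None)
        labels = ModuleAssignment(pd.Series("blue", index=ab.columns))
        me = eigenmetabolites(table, labels)
        assert me.variance_explained["blue"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(me.values["blue"].to_numpy(), z, atol=1e-10)

    def test_variance_explained_matches_eigendecomposition(self, rng):
        for _ in range(5):
            table, labels = self.make_module_table(rng)
            me = eigenmetabolites(table, labels)
            C = np.corrcoef(table.values(), rowvar=False)
            eig = np.linalg.eigvalsh(C)
            expected = eig[-1] / eig.sum()
            assert me.variance_explained["blue"] == pytest.approx(expected,
                                                                  abs=1e-10)

    def test_unit_variance_zero_mean(self, rng):
        table, labels = self.make_module_table(rng)
        me = eigenmetabolites(table, labels)
        v = me.values["blue"]
        assert v.mean() == pytest.approx(0.0, abs=1e-10)
        assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_sign_orientation_stable_under_feature_negation(self, rng):
        table, labels = self.make_module_table(rng)
        me1 = eigenmetabolites(table, labels)
        flipped = FeatureTable(-table.abundance, None)
        me2 = eigenmetabolites(flipped, labels)
        # orientation anchors to the mean profile, which also flips, so the
        # ME flips with it; correlation magnitude with the original is 1
        r = np.corrcoef(me1.values["blue"], me2.values["blue"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestKME:
    def test_feature_equal_to_me_and_orthogonal(self, rng):
        n = 30
        factor = rng.standard_normal(n)
        fc = factor - factor.mean()
        noise = rng.standard_normal(n)
        noise = noise - noise.mean()
        noise = noise - fc * (fc @ noise) / (fc @ fc)
        ab = pd.DataFrame({
            "a": factor, "b": factor * 2, "c": factor * 1.5, "orth": noise},
            index=[f"S{i}" for i in range(n)])
        table = FeatureTable(ab, None)
        labels = ModuleAssignment(pd.Series(
            {"a": "blue", "b": "blue", "c": "blue", "orth": GREY}))
        me = eigenmetabolites(table, labels)
        mm = kme(table, me, labels)
        assert mm.values.at["a", "blue"] == pytest.approx(1.0, abs=1e-3)
        assert mm.values.at["orth", "blue"] == pytest.approx(0.0, abs=1e-9)
        assert ((mm.values.to_numpy() >= -1) & (mm.values.to_numpy() <= 1)).all()

    def test_me_against_itself_is_one(self, rng):
        n = 25
        factor = rng.standard_normal(n)
        ab = pd.DataFrame({f"f{j}": factor + 0.2 * rng.standard_normal(n)
                           for j in range(4)},
                          index=[f"S{i}" for i in range(n)])
        table = FeatureTable(ab, None)
        labels = ModuleAssignment(pd.Series("blue", index=ab.columns))
        me = eigenmetabolites(table, labels)
        ab2 = ab.copy()
        ab2["me_copy"] = me.values["blue"]
        labels2 = ModuleAssignment(pd.Series(
            {**{f"f{j}": "blue" for j in range(4)}, "me_copy": GREY}))
        mm = kme(FeatureTable(ab2, None), me, labels2)
        assert mm.values.at["me_copy", "blue"] == pytest.approx(1.0, abs=1e-12)


class TestEnforceMinKme:
    def test_low_membership_feature_reassigned_grey(self, rng):
        n = 30
        factor = rng.standard_normal(n)
        cols = {f"f{j}": factor + 0.2 * rng.standard_normal(n)
                for j in range(10)}
        cols["weak"] = 0.3 * factor + rng.standard_normal(n)  # kME well below 0.7
        ab = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        table = FeatureTable(ab, None)
        labels = ModuleAssignment(pd.Series("M1", index=ab.columns))
        out = enforce_min_kme(table, labels,
                              DetectionConfig(min_cluster_size=3))
        assert out.labels["weak"] == GREY
        assert (out.labels.drop("weak") == "M1").all()

    def test_strong_module_is_fixed_point(self, rng):
        n = 30
        factor = rng.standard_normal(n)
        ab = pd.DataFrame({f"f{j}": factor + 0.1 * rng.standard_normal(n)
                           for j in range(8)},
                          index=[f"S{i}" for i in range(n)])
        table = FeatureTable(ab, None)
        labels = ModuleAssignment(pd.Series("M1", index=ab.columns))
        out = enforce_min_kme(table, labels, DetectionConfig(min_cluster_size=3))
        assert out.converged
        assert (out.labels == "M1").all()

    def test_postcondition_holds_exhaustively(self):
        spec = SyntheticSpec(groups=(({"g": 0}, 12), ({"g": 1}, 12)),
                             module_sizes=(40, 30, 25, 20, 15),
                             n_background=170, seed=5)
        table, _, _ = generate(spec)
        table = preprocess(table, PreprocessConfig(transform="log2"))
        cor = correlation_matrix(table)
        tom = topological_overlap(adjacency(cor, NetworkConfig(4)))
        cfg = DetectionConfig(min_cluster_size=10)
        labels = detect_modules(table, tom, cfg)
        me = eigenmetabolites(table, labels)
        mm = kme(table, me, labels)
        own = mm.own_module_kme()
        assert (own >= cfg.min_kme_to_stay).all()


class TestMergeCloseModules:
    def build_two_module_table(self, rng, cor_factor):
        n = 40
        f1 = rng.standard_normal(n)
        f2 = cor_factor * f1 + np.sqrt(1 - cor_factor ** 2) * rng.standard_normal(n)
        cols = {}
        for j in range(6):
            cols[f"a{j}"] = f1 + 0.05 * rng.standard_normal(n)
        for j in range(6):
            cols[f"b{j}"] = f2 + 0.05 * rng.standard_normal(n)
        ab = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        labels = ModuleAssignment(pd.Series(
            {**{f"a{j}": "M1" for j in range(6)},
             **{f"b{j}": "M2" for j in range(6)}}))
        return FeatureTable(ab, None), labels

    def test_highly_correlated_modules_merge(self, rng):
        table, labels = self.build_two_module_table(rng, 0.95)
        out = merge_close_modules(table, labels,
                                  DetectionConfig(merge_cut_height=0.25))
        assert len(out.module_names) == 1

    def test_distinct_modules_stay(self, rng):
        table, labels = self.build_two_module_table(rng, 0.5)
        out = merge_close_modules(table, labels,
                                  DetectionConfig(merge_cut_height=0.25))
        assert len(out.module_names) == 2


class TestAssignColors:
    def test_paper_size_order(self):
        sizes = [305, 207, 183, 59, 51, 41, 35]
        labels = {}
        fid = 0
        for m, size in enumerate(sizes):
            for _ in range(size):
                labels[f"F{fid:04d}"] = f"M{m}"
                fid += 1
        labels[f"F{fid:04d}"] = GREY
        out = assign_colors(ModuleAssignment(pd.Series(labels)))
        got = out.sizes().drop(GREY)
        expected = dict(zip(["turquoise", "blue", "brown", "yellow", "green",
                             "red", "black"], sizes))
        assert dict(got) == expected

    def test_single_module_is_turquoise(self):
        out = assign_colors(ModuleAssignment(
            pd.Series({"a": "M9", "b": "M9", "c": GREY})))
        assert set(out.labels) == {"turquoise", GREY}

    def test_equal_sizes_tie_broken_by_feature_id(self):
        labels = pd.Series({"z1": "MA", "z2": "MA", "a1": "MB", "a2": "MB"})
        out = assign_colors(ModuleAssignment(labels))
        # MB holds the lexicographically smallest member (a1) -> turquoise
        assert out.labels["a1"] == "turquoise"
        assert out.labels["z1"] == "blue"

    def test_palette_overflow_gets_indexed_names(self):
        labels = {}
        for m in range(len(COLOR_PALETTE) + 2):
            labels[f"f{m:03d}a"] = f"M{m:03d}"
            labels[f"f{m:03d}b"] = f"M{m:03d}"
        out = assign_colors(ModuleAssignment(pd.Series(labels)))
        names = set(out.labels)
        assert f"module{len(COLOR_PALETTE) + 1}" in names


class TestEndToEndRecovery:
    def test_planted_modules_recovered(self):
        """Median ARI >= 0.8 for 5 planted modules over 300 background."""
        aris = []
        for seed in range(10):
            spec = SyntheticSpec(groups=(({"g": 0}, 12), ({"g": 1}, 12)),
                                 module_sizes=(60, 50, 40, 30, 20),
                                 n_background=300, seed=seed)
            table, _, truth = generate(spec)
            table = preprocess(table, PreprocessConfig(transform="log2"))
            cor = correlation_matrix(table)
            tom = topological_overlap(adjacency(cor, NetworkConfig(4)))
            labels = detect_modules(table, tom)
            aris.append(adjusted_rand_index(truth.labels, labels.labels))
        assert np.median(aris) >= 0.8
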