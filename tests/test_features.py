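"""Contrastive objective formulas, the extractor network, and training."""

import numpy as np
import pytest

from fluorosep import features
from fluorosep.features import (
    FeatureExtractorConfig,
    FeatureVectorSet,
    LabeledPatchSet,
    build_feature_extractor,
    contrastive_loss,
    extract_features,
    interclass_distance,
    intraclass_distance,
    mixed_norm,
)


def brute_force_inter(fvs):
    """Independent double-loop implementation of the interclass distance."""
    labels = fvs.labels
    total, count = 0.0, 0
    for p1 in labels:
        for p2 in labels:
            if p1 == p2:
                continue
            d = fvs.center(p1) - fvs.center(p2)
            total += 0.5 * (np.abs(d).sum() + np.linalg.norm(d))
            count += 1
    return total / count


def brute_force_intra(fvs):
    total = 0.0
    for label in fvs.labels:
        arr = fvs.vectors(label)
        c = arr.mean(axis=0)
        s = 0.0
        for v in arr:
            d = c - v
            s += 0.5 * (np.abs(d).sum() + np.linalg.norm(d))
        total += s / len(arr)
    return total / len(fvs.labels)


class TestMixedNorm:
    def test_three_four_five(self):
        assert mixed_norm(np.array([3.0, 4.0])) == pytest.approx(6.0)

    def test_zero(self):
        assert mixed_norm(np.zeros(5)) == 0.0

    def test_1d_equals_abs(self):
        assert mixed_norm(np.array([-2.5])) == pytest.approx(2.5)

    def test_homogeneous(self, rng):
        v = rng.standard_normal(8)
        assert mixed_norm(3 * v) == pytest.approx(3 * mixed_norm(v))


class TestClassDistances:
    def test_two_cluster_1d(self):
        fvs = FeatureVectorSet({"P1": [[0.0], [2.0]], "P2": [[4.0], [6.0]]})
        assert interclass_distance(fvs) == pytest.approx(4.0)
        assert intraclass_distance(fvs) == pytest.approx(1.0)

    def test_identical_centers(self):
        fvs = FeatureVectorSet({"a": [[1.0], [3.0]], "b": [[0.0], [4.0]]})
        assert interclass_distance(fvs) == pytest.approx(0.0)

    def test_three_centers(self):
        """Centers 0, 1, 3 in 1-D: mean over six ordered pairs is 2."""
        fvs = FeatureVectorSet({"a": [[0.0]], "b": [[1.0]], "c": [[3.0]]})
        assert interclass_distance(fvs) == pytest.approx(2.0)

    def test_singletons_have_zero_intra(self):
        fvs = FeatureVectorSet({"a": [[1.0, 2.0]], "b": [[5.0, 1.0]]})
        assert intraclass_distance(fvs) == 0.0

    def test_asymmetric_cluster(self):
        """{0, 0, 3}: center 1, distances {1, 1, 2}, mean 4/3."""
        fvs = FeatureVectorSet({"a": [[0.0], [0.0], [3.0]], "b": [[9.0]]})
        per_a = (1 + 1 + 2) / 3
        assert intraclass_distance(fvs) == pytest.approx(per_a / 2)  # b adds 0

    def test_matches_brute_force(self, rng):
        """Vectorized distances agree with an independent double loop."""
        for _ in range(5):
            fvs = FeatureVectorSet(
                {f"p{i}": rng.standard_normal((rng.integers(1, 6), 7))
                 for i in range(4)}
            )
            assert interclass_distance(fvs) == pytest.approx(
                brute_force_inter(fvs), abs=1e-10)
            assert intraclass_distance(fvs) == pytest.approx(
                brute_force_intra(fvs), abs=1e-10)

    def test_single_protein_errors(self):
        fvs = FeatureVectorSet({"a": [[1.0]]})
        with pytest.raises(ValueError):
            interclass_distance(fvs)


class TestContrastiveLoss:
    def test_two_cluster_example(self):
        feats = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = ["P1", "P1", "P2", "P2"]
        assert contrastive_loss(feats, labels) == pytest.approx(1.0 - 4.0)

    def test_all_equal(self):
        feats = np.ones((4, 3))
        assert contrastive_loss(feats, ["a", "a", "b", "b"]) == 0.0

    def test_positive_homogeneity(self, rng):
        feats = rng.standard_normal((8, 5))
        labels = list("aabbccdd")
        l1 = contrastive_loss(feats, labels)
        l2 = contrastive_loss(2 * feats, labels)
        assert l2 == pytest.approx(2 * l1)

    def test_relabeling_invariance(self, rng):
        feats = rng.standard_normal((9, 4))
        labels = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        swapped = ["y"] * 3 + ["x"] * 3 + ["z"] * 3
        assert contrastive_loss(feats, labels) == pytest.approx(
            contrastive_loss(feats, swapped))

    def test_single_label_errors(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.ones((3, 2)), ["a", "a", "a"])

    def test_autodiff_matches_numpy(self, rng):
        """The training-graph loss equals the reference implementation."""
        from fluorosep.features import _contrastive_loss_graph
        from fluorosep.nn.autograd import Tensor

        feats = rng.standard_normal((10, 6)).astype(np.float32)
        labels = list("aabbbccdda")
        for form in ("difference", "ratio"):
            ref = contrastive_loss(feats, labels, loss_form=form)
            got = _contrastive_loss_graph(Tensor(feats), labels, form)
            assert float(got.data) == pytest.approx(ref, rel=1e-4)


class TestNetwork:
    def test_output_dim(self, rng):
        cfg = FeatureExtractorConfig(embed_dim=16, patch_size=32, seed=0)
        net = build_feature_extractor(cfg)
        out = net(rng.random((3, 1, 32, 32)).astype(np.float32))
        assert out.data.shape == (3, 16)

    def test_builds_reproducible(self, rng):
        cfg = FeatureExtractorConfig(patch_size=32, seed=7)
        a, b = build_feature_extractor(cfg), build_feature_extractor(cfg)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(a(x).data, b(x).data)

    def test_zero_input_gives_bias_path(self):
        """All-zero input: only the head bias survives the ReLU stack when
        conv biases are zero-initialised."""
        cfg = FeatureExtractorConfig(patch_size=32, seed=1)
        net = build_feature_extractor(cfg)
        out = net(np.zeros((1, 1, 32, 32), np.float32))
        np.testing.assert_allclose(out.data[0], net.head.b.data, atol=1e-6)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError):
            FeatureExtractorConfig(patch_size=48)  # 48 % 32 != 0

    def test_nonincreasing_channels_rejected(self):
        with pytest.raises(ValueError):
            FeatureExtractorConfig(channels=(8, 8, 16, 32, 48))

    def test_wrong_patch_size_at_call(self, rng):
        net = build_feature_extractor(FeatureExtractorConfig(patch_size=32))
        with pytest.raises(ValueError):
            net(rng.random((1, 1, 64, 64)).astype(np.float32))


class TestExtractFeatures:
    @pytest.fixture()
    def tiny_net(self):
        return build_feature_extractor(
            FeatureExtractorConfig(patch_size=32, embed_dim=8, seed=0))

    def test_one_vector_per_patch(self, tiny_net, rng):
        ps = LabeledPatchSet(
            patches=[rng.random((32, 32)) for _ in range(5)],
            labels=["a", "a", "b", "b", "b"],
        )
        fvs = extract_features(tiny_net, ps)
        assert fvs.vectors("a").shape == (2, 8)
        assert fvs.vectors("b").shape == (3, 8)

    def test_duplicate_patch_identical_vector(self, tiny_net, rng):
        p = rng.random((32, 32))
        fvs = extract_features(
            tiny_net, LabeledPatchSet(patches=[p, p], labels=["a", "a"]))
        np.testing.assert_array_equal(fvs.vectors("a")[0], fvs.vectors("a")[1])

    def test_augmentations_not_invariant(self, tiny_net, rng):
        """The CNN makes no rotation-invariance claim: augmented copies of
        one patch may embed differently."""
        from fluorosep.volume import augment

        p = rng.random((32, 32))
        fvs = extract_features(
            tiny_net,
            LabeledPatchSet(patches=[p, augment(p, rotation_k=1)], labels=["a", "a"]),
        )
        assert not np.allclose(fvs.vectors("a")[0], fvs.vectors("a")[1])


class TestTraining:
    def test_loss_trace_reproducible(self, panel4):
        cfg = FeatureExtractorConfig(seed=3, epochs=4, batch_size=16)
        r1 = features.PatternEmbedder(panel4, cfg).fit()
        r2 = features.PatternEmbedder(panel4, cfg).fit()
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)

    def test_training_improves_objective(self, embedder4):
        """The tracked contrastive objective improves over training."""
        trace = embedder4.loss_trace
        assert trace[-1] < trace[0]

    def test_feature_vector_set_shapes(self, embedder4):
        fvs = embedder4.extract_features(n_patches=6, seed=0)
        assert set(fvs.labels) == {"fibA", "fibB", "nucA", "nucB"}
        assert all(fvs.vectors(l).shape == (6, 16) for l in fvs.labels)

    def test_separates_families(self, embedder4):
        """Held-out patches embed with d_inter/d_intra > 1 — the clustering
        premise of the whole pairing approach."""
        fvs = embedder4.extract_features(n_patches=12, seed=1)
        assert interclass_distance(fvs) / max(intraclass_distance(fvs), 1e-12) > 1

    def test_similar_families_closer_than_distinct(self, embedder4):
        """Average-linkage distance between the two filament proteins is
        smaller than between a filament and a blob protein."""
        from fluorosep.pairing import average_linkage_distance

        fvs = embedder4.extract_features(n_patches=12, seed=2)
        within_fib = average_linkage_distance(fvs.vectors("fibA"), fvs.vectors("fibB"))
        cross = average_linkage_distance(fvs.vectors("fibA"), fvs.vectors("nucA"))
        assert within_fib < cross

    def test_fewer_than_two_labels_rejected(self, panel4):
        with pytest.raises(ValueError):
            features.PatternEmbedder({"only": panel4["fibA"]})

    def test_summary_mentions_proteins(self, embedder4):
        s = embedder4.summary()
        assert "fibA" in s and "final loss" in s
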