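"""Kernel, merging, region and hypergraph tests against brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import pathomix as px
from pathomix import nn
from pathomix.errors import ValidationError
from pathomix.wsi import HypergraphConv, _pool_matrix


def random_bag(n=10, d=5, seed=0):
    rng = np.random.default_rng(seed)
    return px.PatchBag(features=rng.standard_normal((n, d)),
                       coords=rng.uniform(0, 100, (n, 2)), slide_id="t")


class TestSimilarityKernel:
    def test_identity_is_one(self):
        params = px.KernelParams()
        h = np.array([1.0, 2.0]); g = np.array([3.0, 4.0])
        assert px.similarity_kernel(h, g, h, g, params) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # lambda_h = lambda_g = 1, ||dh||^2 = ln 2, ||dg||^2 = 0 -> exp(-ln 2) = 0.5
        params = px.KernelParams(lambda_h=1.0, lambda_g=1.0)
        h1 = np.zeros(1); h2 = np.array([np.sqrt(np.log(2.0))])
        g = np.array([5.0, 5.0])
        assert px.similarity_kernel(h1, g, h2, g, params) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        params = px.KernelParams(lambda_h=0.7, lambda_g=0.3)
        for _ in range(100):
            h1, h2 = rng.standard_normal((2, 4))
            g1, g2 = rng.uniform(0, 10, (2, 2))
            k12 = px.similarity_kernel(h1, g1, h2, g2, params)
            k21 = px.similarity_kernel(h2, g2, h1, g1, params)
            assert k12 == pytest.approx(k21)
            assert 0 < k12 <= 1

    def test_nonfinite_rejected(self):
        params = px.KernelParams()
        with pytest.raises(ValidationError):
            px.similarity_kernel(np.array([np.nan]), np.zeros(2),
                                 np.array([1.0]), np.zeros(2), params)


class TestMergePatches:
    def test_no_merge_when_threshold_unreachable(self):
        bag = random_bag(8, seed=1)
        merged = px.merge_patches(bag, px.KernelParams(delta_c=1.0))
        assert merged.n_merged == 8
        np.testing.assert_allclose(merged.reps, bag.features)

    def test_identical_patches_merge(self):
        feats = np.tile(np.array([[1.0, 2.0]]), (2, 1))
        coords = np.tile(np.array([[0.0, 0.0]]), (2, 1))
        bag = px.PatchBag(features=feats, coords=coords, slide_id="x")
        merged = px.merge_patches(bag, px.KernelParams(delta_c=0.99))
        assert merged.n_merged == 1
        assert merged.member_counts.tolist() == [2]
        np.testing.assert_allclose(merged.reps[0], [1.0, 2.0])

    def test_reps_equal_bruteforce_member_means(self):
        bag = random_bag(10, seed=2)
        params = px.KernelParams(lambda_h=0.05, lambda_g=1e-4, delta_c=0.3)
        merged = px.merge_patches(bag, params)
        assert merged.member_counts.sum() == 10
        for k in range(merged.n_merged):
            members = merged.labels == k
            np.testing.assert_allclose(merged.reps[k], bag.features[members].mean(axis=0),
                                       atol=1e-10)
            np.testing.assert_allclose(merged.centers[k], bag.coords[members].mean(axis=0),
                                       atol=1e-10)


class TestAssignRegions:
    def test_k_equals_one(self):
        merged = px.merge_patches(random_bag(6), px.KernelParams(delta_c=1.0))
        assert set(px.assign_regions(merged, 1, seed=0)) == {0}

    def test_k_equals_m_is_permutation(self):
        merged = px.merge_patches(random_bag(5, seed=4), px.KernelParams(delta_c=1.0))
        labels = px.assign_regions(merged, 5, seed=0)
        assert sorted(labels) == list(range(5))

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob = np.concatenate([rng.standard_normal((10, 3)) + 20,
                               rng.standard_normal((10, 3)) - 20])
        truth = np.array([0] * 10 + [1] * 10)
        bag = px.PatchBag(features=blob, coords=rng.uniform(0, 1, (20, 2)), slide_id="b")
        merged = px.merge_patches(bag, px.KernelParams(delta_c=1.0))
        labels = px.assign_regions(merged, 2, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_m_less_than_k_errors(self):
        merged = px.merge_patches(random_bag(3), px.KernelParams(delta_c=1.0))
        with pytest.raises(ValidationError, match="lower K"):
            px.assign_regions(merged, 5, seed=0)


class TestBuildHypergraph:
    def test_tiny_threshold_gives_all_ones(self):
        merged = px.merge_patches(random_bag(6, seed=5), px.KernelParams(delta_c=1.0))
        hg = px.build_hypergraph(merged, px.KernelParams(lambda_h=1e-9, delta_h=1e-6))
        np.testing.assert_array_equal(hg.incidence, np.ones((6, 6)))

    def test_large_threshold_gives_identity(self):
        merged = px.merge_patches(random_bag(6, seed=6), px.KernelParams(delta_c=1.0))
        hg = px.build_hypergraph(merged, px.KernelParams(lambda_h=5.0, delta_h=1.0))
        np.testing.assert_array_equal(hg.incidence, np.eye(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 30))
        merged = px.merge_patches(random_bag(m, d=4, seed=seed + 100),
                                  px.KernelParams(delta_c=1.0))
        params = px.KernelParams(lambda_h=float(rng.uniform(0.05, 2)),
                                 delta_h=float(rng.uniform(0.05, 0.95)))
        hg = px.build_hypergraph(merged, params)
        oracle = np.zeros((m, m))
        for k in range(m):
            for j in range(m):
                kh = np.exp(-params.lambda_h * np.sum(
                    (merged.reps[k] - merged.reps[j]) ** 2))
                oracle[j, k] = 1.0 if kh >= params.delta_h else 0.0
        np.testing.assert_array_equal(hg.incidence, oracle)


class TestEncodeRegions:
    def test_identity_init_recovers_region_means(self):
        rng = np.random.default_rng(0)
        merged = px.merge_patches(random_bag(9, d=4, seed=7), px.KernelParams(delta_c=1.0))
        params = px.KernelParams(lambda_h=5.0, delta_h=1.0)  # identity incidence
        assignment = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        hg = px.build_hypergraph(merged, params, assignment)
        conv = HypergraphConv(4, 4, rng, activation=False, identity_init=True)

        class OneLayer(px.HypergraphEncoder):
            def __init__(self):
                nn.Module.__init__(self)
                self.layers = [conv]
                self.zdim = 4

        emb = px.encode_regions(merged, hg, OneLayer(), k_regions=3)
        for r in range(3):
            np.testing.assert_allclose(
                emb.values[r], merged.reps[assignment == r].mean(axis=0), atol=1e-10)

    def test_patch_permutation_invariance(self, prepared_small):
        slide = prepared_small.slides[0]
        rng = np.random.default_rng(0)
        enc = px.HypergraphEncoder(slide.merged.reps.shape[1], 6, rng)
        enc.eval()
        ref = enc(slide).numpy()
        perm = np.random.default_rng(1).permutation(slide.merged.n_merged)
        permuted = px.wsi.SlideStructure(
            slide_id="p",
            merged=px.MergedPatchSet(reps=slide.merged.reps[perm],
                                     centers=slide.merged.centers[perm],
                                     member_counts=slide.merged.member_counts[perm]),
            hypergraph=px.HypergraphStructure(
                incidence=slide.hypergraph.incidence[np.ix_(perm, perm)],
                region_assignment=slide.hypergraph.region_assignment[perm]),
            pool=slide.pool[:, perm], region_mask=slide.region_mask)
        np.testing.assert_allclose(enc(permuted).numpy(), ref, atol=1e-10)

    def test_gradient_flows_to_input(self, prepared_small):
        slide = prepared_small.slides[0]
        rng = np.random.default_rng(2)
        enc = px.HypergraphEncoder(slide.merged.reps.shape[1], 6, rng)
        enc.train()
        out = enc(slide)
        loss = (out ** 2).sum()
        loss.backward()
        grads = [p.grad for p in enc.parameters() if p.grad is not None]
        assert grads and all(np.isfinite(g).all() for g in grads)
        assert any(np.abs(g).max() > 0 for g in grads)


def test_pool_matrix_handles_empty_region():
    pool, mask = _pool_matrix(np.array([0, 0, 2]), 3)
    assert mask.tolist() == [True, False, True]
    np.testing.assert_allclose(pool[1], 0.0)
    np.testing.assert_allclose(pool[0].sum(), 1.0)


def test_end_to_end_region_recovery(small_cohort, prepared_small):
    """K-means regions recover the planted spatial clusters at high separation."""
    scores = []
    for i in range(6):
        slide = prepared_small.slides[i]
        learned = slide.hypergraph.region_assignment[slide.merged.labels]
        truth = small_cohort.truth["patch_region_labels"][i]
        scores.append(adjusted_rand_score(truth, learned))
    assert np.mean(scores) > 0.8
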