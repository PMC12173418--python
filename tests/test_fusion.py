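"""Bilinear fusion oracle, MoE gating and modality dropout contracts."""

import numpy as np
import pytest

import pathomix as px
from pathomix import nn
from pathomix.errors import ConfigurationError, ValidationError
from pathomix.fusion import GatingNetwork, MFBFusion


def mfb_oracle(x, o, u, v, rank, out_dim):
    """Explicit per-(k, p) loop over the MFB definition."""
    k_n, p_n = x.shape[0], o.shape[0]
    out = np.zeros((k_n, p_n, out_dim))
    for k in range(k_n):
        for p in range(p_n):
            ux = x[k] @ u  # (out_dim * rank,)
            vo = o[p] @ v
            prod = (ux * vo).reshape(out_dim, rank).sum(axis=1)
            signed = prod * (np.abs(prod) + 1e-4) ** -0.5
            norm = np.sqrt((signed ** 2).sum() + 1e-12)
            out[k, p] = signed / norm
    return out


class TestBilinearFusion:
    def test_zero_row_annihilates(self):
        rng = np.random.default_rng(0)
        fus = MFBFusion(zdim=5, rank=3, rng=rng)
        x = rng.standard_normal((4, 5)); x[2] = 0.0
        o = rng.standard_normal((3, 5))
        ft = px.bilinear_fuse(x, o, fus)
        np.testing.assert_allclose(ft.values[2], 0.0, atol=1e-12)

    def test_rank_one_hand_value(self):
        # r=1, 1-dim inputs x=2, o=3 with unit projections -> pooled 6
        rng = np.random.default_rng(0)
        fus = MFBFusion(zdim=1, rank=1, rng=rng)
        fus.u.weight.data = np.array([[1.0]])
        fus.v.weight.data = np.array([[1.0]])
        x = nn.Tensor(np.array([[[2.0]]]))
        o = nn.Tensor(np.array([[[3.0]]]))
        ux = (x @ fus.u.weight).numpy()
        vo = (o @ fus.v.weight).numpy()
        assert float((ux * vo).ravel()[0]) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_batched_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k_n, p_n = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        z = int(rng.integers(2, 17))
        rank = int(rng.integers(1, 5))
        fus = MFBFusion(zdim=z, rank=rank, rng=rng)
        x = rng.standard_normal((k_n, z))
        o = rng.standard_normal((p_n, z))
        got = px.bilinear_fuse(x, o, fus).values
        want = mfb_oracle(x, o, fus.u.weight.data, fus.v.weight.data, rank, z)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_rank_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            MFBFusion(zdim=4, rank=0, rng=np.random.default_rng(0))

    def test_mismatched_zdim_rejected(self):
        fus = MFBFusion(zdim=4, rank=2, rng=np.random.default_rng(0))
        with pytest.raises(ValidationError):
            px.bilinear_fuse(np.ones((2, 4)), np.ones((2, 3)), fus)


class TestMoEPhase1:
    def test_single_region_weight_one(self):
        rng = np.random.default_rng(0)
        gate = GatingNetwork(4, 4, rng)
        fused = nn.Tensor(rng.standard_normal((1, 1, 3, 4)))
        emb, w = px.moe_phase1(fused, gate)
        np.testing.assert_allclose(w.numpy(), 1.0)
        np.testing.assert_allclose(emb.numpy(), fused.numpy()[:, 0])

    def test_identical_regions_uniform_weights(self):
        rng = np.random.default_rng(1)
        gate = GatingNetwork(4, 4, rng)
        cell = rng.standard_normal((1, 1, 2, 4))
        fused = nn.Tensor(np.tile(cell, (1, 5, 1, 1)))
        _, w = px.moe_phase1(fused, gate)
        np.testing.assert_allclose(w.numpy(), 0.2, atol=1e-12)

    def test_hand_set_logits_softmax(self):
        # logits (0, ln 3) over K=2 -> weights (0.25, 0.75)
        class TwoLogit(nn.Module):
            def forward(self, x):
                out = np.zeros(x.shape[:-1])
                out[..., 1, :] = np.log(3.0)
                return nn.Tensor(out)

        fused = nn.Tensor(np.random.default_rng(0).standard_normal((1, 2, 1, 4)))
        _, w = px.moe_phase1(fused, TwoLogit())
        np.testing.assert_allclose(w.numpy().ravel(), [0.25, 0.75], atol=1e-12)

    def test_masked_region_gets_zero_weight(self):
        rng = np.random.default_rng(2)
        gate = GatingNetwork(4, 4, rng)
        fused = nn.Tensor(rng.standard_normal((1, 3, 2, 4)))
        mask = np.array([[True, False, True]])
        _, w = px.moe_phase1(fused, gate, mask)
        assert np.allclose(w.numpy()[0, 1, :], 0.0)
        np.testing.assert_allclose(w.numpy().sum(axis=1), 1.0, atol=1e-9)

    def test_all_masked_errors(self):
        rng = np.random.default_rng(2)
        gate = GatingNetwork(4, 4, rng)
        fused = nn.Tensor(rng.standard_normal((1, 3, 2, 4)))
        with pytest.raises(ValidationError):
            px.moe_phase1(fused, gate, np.zeros((1, 3), bool))


class TestMoEPhase2:
    def test_single_pathway_weight_one(self):
        rng = np.random.default_rng(0)
        gate = GatingNetwork(4, 4, rng)
        emb = nn.Tensor(rng.standard_normal((1, 1, 4)))
        _, w = px.moe_phase2(emb, gate)
        np.testing.assert_allclose(w.numpy(), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        gate = GatingNetwork(5, 4, rng)
        emb = rng.standard_normal((1, 6, 5))
        z1, w1 = px.moe_phase2(nn.Tensor(emb), gate)
        perm = np.random.default_rng(0).permutation(6)
        z2, w2 = px.moe_phase2(nn.Tensor(emb[:, perm]), gate)
        np.testing.assert_allclose(w2.numpy()[:, :], w1.numpy()[:, perm], atol=1e-10)
        np.testing.assert_allclose(z2.numpy(), z1.numpy(), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_weights_normalized(self, seed):
        rng = np.random.default_rng(seed)
        gate = GatingNetwork(5, 4, rng)
        emb = nn.Tensor(rng.standard_normal((10, 7, 5)) * 5)
        _, w = px.moe_phase2(emb, gate)
        np.testing.assert_allclose(w.numpy().sum(axis=1), 1.0, atol=1e-6)
        assert (w.numpy() >= 0).all()


class TestModalityDropout:
    def inputs(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return {"wsi": rng.standard_normal((n, 4)),
                "rna": rng.standard_normal((n, 6))}

    def test_zero_rate_identity(self):
        x = self.inputs()
        out, keep = px.apply_modality_dropout(x, px.DropoutPolicy(rate=0.0), "train",
                                              rng=np.random.default_rng(0))
        for k in x:
            np.testing.assert_array_equal(out[k], x[k])
            assert keep[k].all()

    def test_drop_frequency(self):
        x = self.inputs(n=10_000, seed=1)
        _, keep = px.apply_modality_dropout(x, px.DropoutPolicy(rate=0.5), "train",
                                            rng=np.random.default_rng(2))
        # redrawing all-dropped rows gives marginal p(1-p^{M-1})/(1-p^M);
        # at p=0.5 with M=2 modalities that is 1/3
        expected = 0.5 * (1 - 0.5) / (1 - 0.25)
        for k in keep:
            drop_rate = 1.0 - keep[k].mean()
            assert drop_rate == pytest.approx(expected, abs=0.02)

    def test_never_drops_everything(self):
        x = self.inputs(n=5000, seed=3)
        _, keep = px.apply_modality_dropout(x, px.DropoutPolicy(rate=0.9), "train",
                                            rng=np.random.default_rng(4))
        stacked = np.stack(list(keep.values()), axis=1)
        assert stacked.any(axis=1).all()

    def test_expectation_preserved(self):
        rng = np.random.default_rng(5)
        base = {"wsi": np.ones((10_000, 3)), "rna": np.full((10_000, 2), 2.0)}
        out, _ = px.apply_modality_dropout(base, px.DropoutPolicy(rate=0.4), "train",
                                           rng=rng)
        for k, arr in out.items():
            np.testing.assert_allclose(arr.mean(axis=0), base[k][0], rtol=0.02)

    def test_eval_zeroes_missing_without_rescale(self):
        x = self.inputs()
        out, keep = px.apply_modality_dropout(x, px.DropoutPolicy(rate=0.4), "eval",
                                              missing={"rna"})
        np.testing.assert_array_equal(out["wsi"], x["wsi"])
        np.testing.assert_array_equal(out["rna"], 0.0)
        assert not keep["rna"].any()

    def test_rate_one_rejected(self):
        with pytest.raises(ConfigurationError):
            px.DropoutPolicy(rate=1.0)


def test_forward_pass_finite_with_missing_modality(tiny_model, prepared_small):
    """The robustness contract: inference completes with either modality absent."""
    idx = np.arange(6)
    for missing in [frozenset({"wsi"}), frozenset({"source0", "source1"})]:
        out = tiny_model.forward(prepared_small, idx, mode="eval", missing=missing)
        assert np.isfinite(out.output.numpy()).all()
        np.testing.assert_allclose(out.pathway_weights.numpy().sum(axis=1), 1.0,
                                   atol=1e-6)


def test_gating_records_are_pure_reads(tiny_model, prepared_small):
    idx = np.arange(5)
    out1 = tiny_model.forward(prepared_small, idx, mode="eval")
    rec1 = out1.gating_records()
    rec2 = out1.gating_records()
    out2 = tiny_model.forward(prepared_small, idx, mode="eval")
    for a, b in zip(rec1, rec2):
        np.testing.assert_array_equal(a.region_weights, b.region_weights)
    np.testing.assert_array_equal(out1.output.numpy(), out2.output.numpy())
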