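"""Interpretability: SHAP contracts, PES/MIS reads, KS enrichment, stability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ks_2samp

import pathomix as px
from pathomix.errors import ValidationError
from pathomix.fusion import GatingRecord
from pathomix.interpret import PathwayScore


def make_gating(n=3, k=2, p=4, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        rw = rng.random((k, p)); rw /= rw.sum(axis=0, keepdims=True)
        pw = rng.random(p); pw /= pw.sum()
        records.append(GatingRecord(region_weights=rw, pathway_weights=pw,
                                    pathway_embeddings=rng.standard_normal((p, 3)),
                                    patient_embedding=rng.standard_normal(3)))
    return records


class TestPesMis:
    def test_pes_is_verbatim_read(self):
        recs = make_gating()
        pes = px.extract_pes(recs)
        for i, r in enumerate(recs):
            np.testing.assert_array_equal(pes.r[i], r.pathway_weights)

    def test_single_pathway_r_one(self):
        recs = make_gating(p=1)
        assert np.allclose(px.extract_pes(recs).r, 1.0)

    def test_cohort_mean_is_arithmetic_mean(self):
        recs = make_gating(n=3)
        pes = px.extract_pes(recs)
        np.testing.assert_allclose(pes.cohort_mean(),
                                   np.mean([r.pathway_weights for r in recs], axis=0))

    def test_mis_columns_sum_to_one(self):
        mis = px.extract_mis(make_gating(n=4))
        np.testing.assert_allclose(mis.values.sum(axis=1), 1.0, atol=1e-12)

    def test_extraction_is_idempotent(self):
        recs = make_gating()
        a, b = px.extract_mis(recs), px.extract_mis(recs)
        np.testing.assert_array_equal(a.values, b.values)


class TestNormalizeShap:
    def table(self):
        return px.GeneImportance(
            table=pd.DataFrame({
                "patient_id": ["s0", "s0", "s1", "s1"],
                "gene": ["g1", "g2", "g1", "g2"],
                "source": ["rna"] * 4,
                "pathway": ["P0", "P1", "P0", "P1"],
                "shap": [2.0, 4.0, 1.0, -2.0],
            }),
            base_values=np.zeros(2), outputs=np.zeros(2))

    def test_identity_when_r_is_one(self):
        ps = PathwayScore(r=np.ones((2, 1)), pathway_names=["P0"])
        gi = self.table()
        gi.table = gi.table[gi.table.pathway == "P0"]
        out = px.normalize_shap(gi, ps, ["s0", "s1"])
        np.testing.assert_array_equal(out["shap_normalized"], out["shap"])

    def test_arithmetic(self):
        ps = PathwayScore(r=np.array([[0.25, 0.75], [0.5, 0.5]]),
                          pathway_names=["P0", "P1"])
        out = px.normalize_shap(self.table(), ps, ["s0", "s1"])
        np.testing.assert_allclose(out["shap_normalized"],
                                   [0.25 * 2.0, 0.75 * 4.0, 0.5 * 1.0, 0.5 * -2.0])

    def test_unknown_pathway_rejected(self):
        ps = PathwayScore(r=np.ones((2, 1)), pathway_names=["OTHER"])
        with pytest.raises(ValidationError):
            px.normalize_shap(self.table(), ps, ["s0", "s1"])


class TestKsEnrichment:
    def make_table(self, scores_by_pathway):
        rows = []
        for pname, scores in scores_by_pathway.items():
            for j, s in enumerate(scores):
                rows.append(("s0", f"{pname}_G{j}", "rna", pname, s))
        return pd.DataFrame(rows, columns=["patient_id", "gene", "source",
                                           "pathway", "shap_normalized"])

    def test_perfect_separation_statistic_one(self):
        table = self.make_table({
            "HI": np.linspace(10, 11, 10),
            "LO": np.linspace(0, 1, 40),
        })
        sets = px.GeneSetCollection(pathways=[
            ("HI", [f"HI_G{j}" for j in range(10)]),
            ("LO", [f"LO_G{j}" for j in range(40)]),
        ])
        out = px.ks_enrichment(table, sets)
        assert out.loc[out.pathway == "HI", "ks_statistic"].item() == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        table = self.make_table({"A": rng.random(4), "B": rng.random(4)})
        sets = px.GeneSetCollection(pathways=[
            ("A", [f"A_G{j}" for j in range(4)]),
            ("B", [f"B_G{j}" for j in range(4)]),
        ])
        out = px.ks_enrichment(table, sets)
        a_scores = np.abs(table[table.pathway == "A"]["shap_normalized"])
        b_scores = np.abs(table[table.pathway == "B"]["shap_normalized"])
        want = ks_2samp(a_scores, b_scores, alternative="two-sided")
        got = out[out.pathway == "A"].iloc[0]
        assert got["p_value"] == pytest.approx(want.pvalue)
        assert got["ks_statistic"] == pytest.approx(want.statistic)

    def test_degenerate_pathway_skipped(self, caplog):
        table = self.make_table({"A": [1.0], "B": np.linspace(0, 1, 10)})
        sets = px.GeneSetCollection(pathways=[
            ("A", ["A_G0"]),
            ("B", [f"B_G{j}" for j in range(10)]),
        ])
        with caplog.at_level("WARNING"):
            out = px.ks_enrichment(table, sets)
        assert "A" not in set(out.pathway)

    def test_null_calibration(self):
        """Under exchangeable scores the p-values are approximately uniform."""
        rng = np.random.default_rng(7)
        pvals = []
        # 30/120 genes keep the exact KS p-value distribution fine-grained
        # enough for a uniformity meta-test
        sets = px.GeneSetCollection(pathways=[
            ("IN", [f"IN_G{j}" for j in range(30)]),
            ("OUT", [f"OUT_G{j}" for j in range(120)]),
        ])
        for _ in range(200):
            table = self.make_table({"IN": rng.random(30), "OUT": rng.random(120)})
            out = px.ks_enrichment(table, sets)
            pvals.append(out[out.pathway == "IN"]["p_value"].item())
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestStability:
    def test_identical_models_correlation_one(self):
        ps = PathwayScore(r=np.random.default_rng(0).random((5, 8)),
                          pathway_names=[f"P{i}" for i in range(8)])
        out = px.stability_analysis([ps, ps, ps])
        np.testing.assert_allclose(out["matrix"], 1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        means = []
        for sim in range(100):
            a, b = rng.random(50), rng.random(50)
            means.append(px.stability_analysis([a, b])["mean"])
        assert abs(np.mean(means)) < 0.3

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(10), rng.random(10)
        base = px.stability_analysis([a, b])["mean"]
        trans = px.stability_analysis([np.exp(3 * a), np.exp(3 * b)])["mean"]
        assert base == pytest.approx(trans)

    def test_single_fold_rejected(self):
        with pytest.raises(ValidationError):
            px.stability_analysis([np.ones(3)])


class TestShapContracts:
    def test_constant_model_zero_attribution(self, prepared_small):
        model = px.MultimodalNetwork(
            prepared_small, task="classification", n_classes=2,
            config=px.ModelConfig(zdim=6, vae_hidden=(12, 8), gate_hidden=6,
                                  mfb_rank=2, batch_norm=False), seed=4)
        # zero the readout so the explained output ignores the input
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 1.0
        gi = px.compute_shap(model, prepared_small, [0, 1], np.arange(5, 10),
                             steps=5, seed=0)
        assert np.abs(gi.table["shap"]).max() < 1e-10

    def test_linear_model_exact_shapley(self):
        """y = 3*g1 with zero background: SHAP(g1) = 3*g1, SHAP(g2) = 0."""
        from pathomix import nn
        from pathomix.interpret import _integrated_gradients

        def f(x):  # x: Tensor (B, 2)
            w = nn.Tensor(np.array([[3.0], [0.0]]))
            return (x @ w).reshape((x.shape[0],))

        x = np.array([2.0, 5.0])
        bg = np.zeros((1, 2))
        attr = _integrated_gradients(f, x, bg, steps=4)
        np.testing.assert_allclose(attr, [6.0, 0.0], atol=1e-10)

    def test_additivity_on_untrained_model(self, tiny_model, prepared_small):
        idx = np.arange(4)
        gi = px.compute_shap(tiny_model, prepared_small, idx, np.arange(8, 16),
                             steps=200, seed=0)
        sums = gi.table.groupby("patient_id", sort=False)["shap"].sum().to_numpy()
        gap = gi.outputs - gi.base_values
        rel = np.abs(sums - gap) / (np.abs(gap) + 1e-12)
        assert rel.max() < 0.05


def test_km_high_low_risk_signal():
    rng = np.random.default_rng(0)
    n = 200
    risk = rng.standard_normal(n)
    times = rng.exponential(np.exp(-2 * risk))
    events = np.ones(n, int)
    out = px.km_high_low_risk(risk, times, events)
    assert out["p_value"] < 1e-6
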