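# pathomix

Interpretable multimodal integration of whole-slide histopathology images
and multi-omics data for oncology prediction tasks.

A patient is represented by two bags: a whole-slide image (WSI) reduced to
patch feature vectors with spatial coordinates, and S gene-level omics
matrices (expression, copy number, methylation, ...). `pathomix` fuses them
into one prediction — a tumor class or a survival risk — while exposing
*why* at three levels: genes, pathways, and (spatial region x pathway)
interactions.

## The model in brief

1. **WSI → K region embeddings.** Patches are merged by a combined
   morphological/spatial Gaussian kernel
   `kappa(i,j) = exp(-λ_h‖h_i−h_j‖²) · exp(-λ_g‖g_i−g_j‖²)`
   (average-linkage clustering, cut at similarity δ_c), partitioned into K
   regions by K-means, wired into a hypergraph (one hyperedge per merged
   patch, membership `kappa_h ≥ δ_h`), encoded by attention hypergraph
   convolutions and mean-pooled per region: `X^K ∈ R^{K×z}`.
2. **Omics → P pathway embeddings.** Each source is split by a GMT gene-set
   file into P pathway blocks; a multi-source variational autoencoder per
   pathway yields `O^P ∈ R^{P×z}`.
3. **Fusion + hierarchical mixture of experts.** Factorized bilinear
   pooling fuses every (region, pathway) pair into a `K×P×z` tensor
   `Z`; softmax gates weight regions within each pathway
   (`z_p^moe = Σ_k w_{k}^p z_{k,p}`, `Σ_k w_k^p = 1`) and then pathways
   (`z^moe = Σ_p w_p z_p^moe`), feeding linear task heads. Classification
   trains with cross-entropy; survival with the Cox negative partial
   log-likelihood `−Σ_{i:E_i=1}(r_i − log Σ_{T_j≥T_i} e^{r_j})`.
4. **Interpretability for free.** The phase-2 gate weights are per-patient
   pathway enrichment scores (PES); the phase-1 weights are the multimodal
   interaction score `MIS_{k,p}`; integrated-gradient SHAP values per gene
   are normalized by the PES and tested per pathway with a two-sample
   Kolmogorov–Smirnov statistic.
5. **Missing modalities.** Modality dropout during training (whole-modality
   zeroing with expectation-preserving rescaling, learned token for a
   missing WSI) keeps inference usable when a modality is absent.

## Worked example

```python
import numpy as np
import pathomix as px
from sklearn.metrics import roc_auc_score

# a synthetic cohort with a planted (region 0, pathway 0) signal
cfg = px.SyntheticConfig(n_patients=220, n_patches=40, feat_dim=32,
                         n_regions=4, n_pathways=6, genes_per_pathway=8,
                         effect_size=3.0, seed=11)
cohort = px.generate_cohort(cfg)

pc = px.prepare_cohort(cohort.patch_bags, cohort.omics, cohort.gene_sets,
                       px.KernelParams(delta_c=0.5, delta_h=0.5),
                       k_regions=4, seed=0, labels=cohort.labels,
                       auto_bandwidth=True)
model = px.MultimodalNetwork(pc, task="classification", n_classes=2,
                             config=px.ModelConfig(zdim=16, vae_hidden=(32, 16),
                                                   gate_hidden=8,
                                                   batch_norm=False), seed=0)
tc = px.TrainConfig(phase1_epochs=40, phase2_epochs=100, lr=5e-3,
                    batch_size=32, pathway_aux_weight=1.0,
                    gate_entropy_weight=0.05, seed=0)
px.train(model, pc, tc, train_idx=np.arange(120))

test = np.arange(120, 220)
auc = roc_auc_score(pc.labels[test], model.predict(pc, test)[:, 1])
fw = model.forward(pc, test, mode="eval")
pes = px.extract_pes(fw.gating_records(), pc.gene_sets.names)
print(f"test AUC          {auc:.3f}")
print(f"mean pathway PES  {np.round(pes.cohort_mean(), 3)}")
```

Typical output:

```
test AUC          0.738
mean pathway PES  [0.594 0.209 0.038 0.013 0.022 0.124]
```

The held-out AUC (0.74 here; the generative oracle caps at ≈ 0.92 because
the labels are intrinsically noisy) shows the planted multimodal signal is
recovered, and the first pathway — the planted one — receives almost three
times the mean gating weight of any other, which is what the PES is for.
`examples/` contains one short script per capability (simulation, WSI
encoding, omics encoding, fusion/gating, survival, interpretation,
missing-modality robustness).

## Command line

A thin CLI wraps the library for shell use:

```bash
pathomix simulate --out-dir demo --n-patients 60 --seed 1
pathomix run --config demo.yaml       # encode -> train -> predict -> interpret
pathomix encode-wsi --patches demo/patches --k-regions 4 --out enc.json
```

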