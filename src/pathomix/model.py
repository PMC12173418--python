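"""The full multimodal network and the prepared-cohort container.

``PreparedCohort`` holds everything static for a cohort: per-slide merged
patches, hypergraphs and pooling matrices, the per-(source, pathway) omics
blocks (per-gene standardized), and the outcome table.  ``MultimodalNetwork``
wires the hypergraph WSI encoder, the P pathway VAEs, factorized bilinear
fusion, the two-phase mixture of experts and the task head into one
differentiable forward pass with modality dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .fusion import (
    DropoutPolicy,
    GatingNetwork,
    GatingRecord,
    MFBFusion,
    apply_modality_dropout,
)
from .omics import GeneSetCollection, OmicsSource, PathwayVAE, partition_by_pathway
from .wsi import (
    HypergraphEncoder,
    KernelParams,
    PatchBag,
    SlideStructure,
    prepare_slide,
)

__all__ = ["ModelConfig", "PreparedCohort", "ForwardOutput", "MultimodalNetwork",
           "prepare_cohort"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (paper-scale values are the defaults of
    the underlying modules; these defaults are sized for desk-scale runs)."""

    zdim: int = 32
    mfb_rank: int = 4
    gate_hidden: int = 16
    vae_hidden: tuple[int, int] = (64, 32)
    gnn_layers: int = 2
    batch_norm: bool = True
    net_dropout: float = 0.0
    modality_dropout: float = 0.4
    chromosome_blocks: dict | None = None


@dataclass
class PreparedCohort:
    sample_ids: list[str]
    slides: list[SlideStructure]
    blocks: list[dict[str, np.ndarray]]  # per pathway: source -> (N, genes)
    block_genes: list[dict[str, list[str]]]
    gene_sets: GeneSetCollection
    source_names: list[str]
    feat_dim: int
    k_regions: int
    labels: np.ndarray | None = None  # (N,) int class labels
    times: np.ndarray | None = None  # (N,) positive durations
    events: np.ndarray | None = None  # (N,) 0/1
    standardizers: list[dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pathways(self) -> int:
        return self.gene_sets.n_pathways

    def source_dims(self) -> list[dict[str, int]]:
        return [
            {s: self.blocks[p][s].shape[1] for s in self.source_names}
            for p in range(self.n_pathways)
        ]

    def region_masks(self, idx: np.ndarray) -> np.ndarray:
        return np.stack([self.slides[i].region_mask for i in idx])

    def gene_layout(self) -> list[tuple[int, str, str]]:
        """Flattened (pathway_idx, source, gene) order of the omics input."""
        layout = []
        for p in range(self.n_pathways):
            for s in self.source_names:
                for g in self.block_genes[p][s]:
                    layout.append((p, s, g))
        return layout

    def flat_omics(self, idx: np.ndarray) -> np.ndarray:
        """Concatenate all blocks (gene_layout order) for the given samples."""
        parts = []
        for p in range(self.n_pathways):
            for s in self.source_names:
                parts.append(self.blocks[p][s][idx])
        return np.concatenate(parts, axis=1)


def prepare_cohort(patch_bags: list[PatchBag], sources: list[OmicsSource],
                   gene_sets: GeneSetCollection, kernel_params: KernelParams,
                   k_regions: int, seed: int, *,
                   labels: np.ndarray | None = None,
                   times: np.ndarray | None = None,
                   events: np.ndarray | None = None,
                   sample_ids: list[str] | None = None,
                   auto_bandwidth: bool = False,
                   standardize: bool = True,
                   standardizers: list | None = None) -> PreparedCohort:
    """Build all static per-cohort structures.

    Omics blocks are standardized per gene (train-set statistics can be
    passed back in via ``standardizers`` to transform held-out data with the
    training moments).
    """
    n = len(patch_bags)
    if sample_ids is None:
        sample_ids = [bag.slide_id or f"S{i:04d}" for i, bag in enumerate(patch_bags)]
    for src in sources:
        if src.matrix.shape[0] != n:
            raise ValidationError(
                f"source {src.name!r} has {src.matrix.shape[0]} rows for {n} patients"
            )
    slides = [
        prepare_slide(bag, kernel_params, k_regions, seed + i, auto_bandwidth)
        for i, bag in enumerate(patch_bags)
    ]
    from .wsi import canonicalize_regions

    canonicalize_regions(slides, k_regions, seed)
    raw = partition_by_pathway(sources, gene_sets)
    blocks: list[dict[str, np.ndarray]] = []
    block_genes: list[dict[str, list[str]]] = []
    stats: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for p, (pname, _) in enumerate(gene_sets.pathways):
        per_source = {}
        per_genes = {}
        per_stats = {}
        for src in sources:
            mat = raw[(src.name, pname)].matrix
            if standardize:
                if standardizers is not None:
                    mu, sd = standardizers[p][src.name]
                else:
                    mu, sd = mat.mean(axis=0), mat.std(axis=0)
                    sd = np.where(sd > 0, sd, 1.0)
                mat = (mat - mu) / sd
                per_stats[src.name] = (mu, sd)
            per_source[src.name] = mat
            per_genes[src.name] = raw[(src.name, pname)].gene_names
        blocks.append(per_source)
        block_genes.append(per_genes)
        stats.append(per_stats)
    return PreparedCohort(
        sample_ids=sample_ids, slides=slides, blocks=blocks, block_genes=block_genes,
        gene_sets=gene_sets, source_names=[s.name for s in sources],
        feat_dim=patch_bags[0].features.shape[1], k_regions=k_regions,
        labels=None if labels is None else np.asarray(labels, int),
        times=None if times is None else np.asarray(times, float),
        events=None if events is None else np.asarray(events, int),
        standardizers=stats,
    )


@dataclass
class ForwardOutput:
    output: nn.Tensor  # (B, C) class logits or (B, 1) risk
    region_weights: nn.Tensor  # (B, K, P)
    pathway_weights: nn.Tensor  # (B, P)
    pathway_embeddings: nn.Tensor  # (B, P, zdim)
    patient_embedding: nn.Tensor  # (B, zdim)
    pathway_predictions: nn.Tensor  # (B, P, C)
    mus: list[nn.Tensor]
    logvars: list[nn.Tensor]
    modality_keep: dict[str, np.ndarray]

    def gating_records(self) -> list[GatingRecord]:
        rw = self.region_weights.numpy()
        pw = self.pathway_weights.numpy()
        pe = self.pathway_embeddings.numpy()
        pa = self.patient_embedding.numpy()
        return [
            GatingRecord(region_weights=rw[i], pathway_weights=pw[i],
                         pathway_embeddings=pe[i], patient_embedding=pa[i])
            for i in range(rw.shape[0])
        ]


class MultimodalNetwork(nn.Module):
    """Hypergraph WSI encoder + pathway VAEs + MFB fusion + hierarchical MoE."""

    def __init__(self, cohort: PreparedCohort, task: str, n_classes: int = 2,
                 config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        if task not in ("classification", "survival"):
            raise ConfigurationError(f"unknown task {task!r}")
        self.task = task
        self.config = config = config or ModelConfig()
        self.n_outputs = n_classes if task == "classification" else 1
        self.pathway_names = cohort.gene_sets.names
        self.source_names = list(cohort.source_names)
        self.k_regions = cohort.k_regions
        rng = np.random.default_rng(seed)
        z = config.zdim
        self.wsi_encoder = HypergraphEncoder(cohort.feat_dim, z, rng,
                                             n_layers=config.gnn_layers)
        self.wsi_decoder = nn.Linear(z, cohort.feat_dim, rng)
        self.vaes = [
            PathwayVAE(dims, z, rng, hidden=config.vae_hidden,
                       batch_norm=config.batch_norm, dropout=config.net_dropout,
                       chromosome_blocks=config.chromosome_blocks)
            for dims in cohort.source_dims()
        ]
        # embeddings entering the bilinear map are standardized (so products
        # reflect across-patient variation, not constant offsets) and then
        # augmented with a constant coordinate: without it a centered
        # bilinear product has zero conditional mean in either input and
        # every main effect would be invisible to the task head
        self.fusion = MFBFusion(z, config.mfb_rank, rng, in_dim=z + 1)
        self.region_bn = nn.BatchNorm1d(z)
        self.omics_bn = nn.BatchNorm1d(z)
        self.gate1 = GatingNetwork(z, config.gate_hidden, rng)
        self.gate2 = GatingNetwork(z, config.gate_hidden, rng)
        self.pathway_head = nn.Linear(z, self.n_outputs, rng)
        self.head = nn.Linear(z, self.n_outputs, rng)
        # learned stand-in for a dropped/missing WSI: with it, phase-1 gating
        # degenerates to gating over omics-only fused blocks instead of the
        # all-zero tensor a zeroed X^K would produce through the bilinear map
        self.wsi_missing_token = nn.Tensor(0.1 * rng.standard_normal(z),
                                           requires_grad=True)
        self._rng = rng

    # -- modality handling -------------------------------------------------
    def _modality_factors(self, n: int, mode: str, missing: set[str],
                          rng: np.random.Generator) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        names = ["wsi"] + self.source_names
        indicators = {name: np.ones((n, 1)) for name in names}
        policy = DropoutPolicy(rate=self.config.modality_dropout if mode == "train" else 0.0,
                               modalities=tuple(names))
        if mode == "train" and self.config.modality_dropout > 0:
            out, keep = apply_modality_dropout(indicators, policy, "train", rng=rng,
                                               missing=missing)
            # a genuinely missing modality stays off regardless of the draw
            for name in missing:
                out[name] = np.zeros((n, 1))
                keep[name] = np.zeros(n, dtype=bool)
        else:
            out, keep = apply_modality_dropout(indicators, policy, "eval", missing=missing)
            out = {k: v.astype(float) for k, v in out.items()}
        return out, keep

    # -- forward -----------------------------------------------------------
    def forward(self, cohort: PreparedCohort, idx: np.ndarray, mode: str = "eval",
                rng: np.random.Generator | None = None,
                missing: set[str] | frozenset[str] = frozenset()) -> ForwardOutput:
        idx = np.asarray(idx, int)
        n = idx.shape[0]
        rng = rng if rng is not None else self._rng
        if mode == "train":
            self.train()
        else:
            self.eval()
        factors, keep = self._modality_factors(n, mode, set(missing), rng)

        # omics side: per-pathway VAE encodings
        z_list, mus, logvars = [], [], []
        for p, vae in enumerate(self.vaes):
            blk = {}
            for s in self.source_names:
                x = cohort.blocks[p][s][idx] * factors[s]
                blk[s] = nn.Tensor(x)
            mu, logvar = vae.encode(blk)
            zp = vae.reparameterize(mu, logvar, rng) if mode == "train" else mu
            z_list.append(zp)
            mus.append(mu)
            logvars.append(logvar)
        omics_bag = nn.stack(z_list, axis=1)  # (B, P, zdim)

        # WSI side: per-slide hypergraph encoding, then region pooling
        region_rows = [self.wsi_encoder(cohort.slides[i]) for i in idx]
        regions = nn.stack(region_rows, axis=0)  # (B, K, zdim)
        regions = regions * nn.Tensor(factors["wsi"].reshape(n, 1, 1))
        dropped = (~keep["wsi"]).astype(float).reshape(n, 1, 1)
        if dropped.any():
            token = self.wsi_missing_token.reshape((1, 1, self.config.zdim))
            regions = regions + token * nn.Tensor(dropped)
        region_mask = cohort.region_masks(idx)

        from .fusion import moe_phase1, moe_phase2

        z = self.config.zdim
        k = regions.shape[1]
        p = omics_bag.shape[1]
        regions = self.region_bn(regions.reshape((n * k, z))).reshape((n, k, z))
        omics_bag = self.omics_bn(omics_bag.reshape((n * p, z))).reshape((n, p, z))
        ones_k = nn.Tensor(np.ones((n, k, 1)))
        ones_p = nn.Tensor(np.ones((n, p, 1)))
        regions_aug = nn.concat([regions, ones_k], axis=-1)
        omics_aug = nn.concat([omics_bag, ones_p], axis=-1)
        fused = self.fusion(regions_aug, omics_aug)  # (B, K, P, zdim)
        pathway_emb, w_regions = moe_phase1(fused, self.gate1, region_mask)
        patient, w_pathways, preds = moe_phase2(pathway_emb, self.gate2,
                                                self.pathway_head)
        out = self.head(patient)
        return ForwardOutput(
            output=out, region_weights=w_regions, pathway_weights=w_pathways,
            pathway_embeddings=pathway_emb, patient_embedding=patient,
            pathway_predictions=preds, mus=mus, logvars=logvars,
            modality_keep=keep,
        )

    # -- phase-1 objectives -------------------------------------------------
    def vae_losses(self, cohort: PreparedCohort, idx: np.ndarray, mode: str,
                   rng: np.random.Generator, beta: float) -> nn.Tensor:
        from .omics import vae_loss

        total = None
        for p, vae in enumerate(self.vaes):
            blk = {s: nn.Tensor(cohort.blocks[p][s][idx]) for s in self.source_names}
            mu, logvar = vae.encode(blk)
            zp = vae.reparameterize(mu, logvar, rng) if mode == "train" else mu
            recon = vae.decode(zp)
            loss = vae_loss(recon, blk, mu, logvar, beta=beta)
            total = loss if total is None else total + loss
        return total * (1.0 / len(self.vaes))

    def wsi_recon_loss(self, cohort: PreparedCohort, idx: np.ndarray) -> nn.Tensor:
        """Autoencoding objective for unsupervised WSI pretraining: reconstruct
        merged-patch features from node embeddings."""
        total = None
        for i in idx:
            slide = cohort.slides[i]
            nodes = self.wsi_encoder.node_embeddings(slide)
            rec = self.wsi_decoder(nodes)
            loss = ((rec - nn.Tensor(slide.merged.reps)) ** 2).mean()
            total = loss if total is None else total + loss
        return total * (1.0 / len(idx))

    # -- prediction helpers ---------------------------------------------------
    def predict(self, cohort: PreparedCohort, idx: np.ndarray | None = None,
                missing: set[str] | frozenset[str] = frozenset()) -> np.ndarray:
        """Class probabilities (classification) or risk scores (survival)."""
        if idx is None:
            idx = np.arange(cohort.n_samples)
        fw = self.forward(cohort, idx, mode="eval", missing=missing)
        out = fw.output.numpy()
        if self.task == "classification":
            e = np.exp(out - out.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        return out.ravel()
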