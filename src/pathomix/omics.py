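"""Pathway-partitioned multi-omics variational autoencoders.

Each omics source (e.g. RNA-seq expression, CNV segment means, methylation
beta values, all already mapped to gene level) is partitioned by a gene-set
collection into P pathway blocks.  For every pathway a multi-source VAE
encodes the S blocks into a shared ``zdim`` latent; stacking the P latents
gives the omics bag O^P used by the fusion stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsSource",
    "GeneSetCollection",
    "OmicsBlock",
    "PathwayVAE",
    "OmicsBag",
    "partition_by_pathway",
    "encode_pathway",
    "vae_loss",
    "kl_divergence",
    "build_omics_bag",
]


@dataclass
class OmicsSource:
    """One samples x genes matrix with named columns and row sample ids."""

    name: str
    matrix: np.ndarray
    gene_names: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError(f"source {self.name!r}: matrix must be 2-D")
        if self.matrix.shape[1] != len(self.gene_names):
            raise ValidationError(f"source {self.name!r}: gene_names/column mismatch")
        if not np.isfinite(self.matrix).all():
            raise ValidationError(f"source {self.name!r}: non-finite values")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError(f"source {self.name!r}: duplicate gene names")


@dataclass
class GeneSetCollection:
    """Ordered pathways, each a (name, gene list) pair."""

    pathways: list[tuple[str, list[str]]]

    def __post_init__(self):
        for name, genes in self.pathways:
            if not genes:
                raise ValidationError(f"pathway {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.pathways]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def pathway_of(self) -> dict[str, list[int]]:
        """gene -> list of pathway indices (genes may belong to several)."""
        out: dict[str, list[int]] = {}
        for p, (_, genes) in enumerate(self.pathways):
            for g in genes:
                out.setdefault(g, []).append(p)
        return out


@dataclass
class OmicsBlock:
    source: str
    pathway: str
    matrix: np.ndarray  # (n_samples, n_genes_present)
    gene_names: list[str]


@dataclass
class OmicsBag:
    """P x zdim per-sample pathway embeddings (stacked over samples)."""

    values: np.ndarray  # (n, P, zdim)
    pathway_names: list[str]
    source_mask: np.ndarray | None = None  # (S,) sources present


def partition_by_pathway(sources: list[OmicsSource],
                         sets: GeneSetCollection) -> dict[tuple[str, str], OmicsBlock]:
    """Split every source into per-pathway gene blocks.

    Genes listed in a pathway but absent from a source are dropped from that
    source's block (with a logged warning); a pathway with no genes in any
    source is an error.  Columns are ordered by the pathway's gene list, so
    the result is independent of the on-disk column order.
    """
    blocks: dict[tuple[str, str], OmicsBlock] = {}
    for pname, genes in sets.pathways:
        found_any = False
        for src in sources:
            col = {g: j for j, g in enumerate(src.gene_names)}
            present = [g for g in genes if g in col]
            missing = [g for g in genes if g not in col]
            if missing:
                logger.warning(
                    "pathway %s: %d gene(s) absent from source %s (e.g. %s)",
                    pname, len(missing), src.name, missing[0],
                )
            if present:
                found_any = True
            idx = [col[g] for g in present]
            blocks[(src.name, pname)] = OmicsBlock(
                source=src.name, pathway=pname,
                matrix=src.matrix[:, idx] if idx else np.zeros((src.matrix.shape[0], 0)),
                gene_names=present,
            )
        if not found_any:
            raise ValidationError(f"pathway {pname!r} has no genes in any source")
    return blocks


class PathwayVAE(nn.Module):
    """Multi-source VAE for one pathway.

    Per-source sub-encoders embed each omics block; the central encoder maps
    their concatenation to (mu, log sigma^2); per-source decoders reconstruct
    each block from the latent sample.  An optional block-sparse first layer
    (one block per chromosome) can replace the dense first layer of a source
    to cut parameters on genome-wide methylation input.
    """

    def __init__(self, source_dims: dict[str, int], zdim: int,
                 rng: np.random.Generator, hidden: tuple[int, int] = (128, 64),
                 batch_norm: bool = True, dropout: float = 0.0,
                 chromosome_blocks: dict[str, list[int]] | None = None):
        super().__init__()
        self.source_names = list(source_dims)
        self.zdim = zdim
        h_sub, h_central = hidden
        self.sub_encoders = []
        for name in self.source_names:
            d = source_dims[name]
            blocks = (chromosome_blocks or {}).get(name)
            layers: list[nn.Module] = []
            if blocks:
                per_block_out = [max(1, h_sub // len(blocks))] * len(blocks)
                first = nn.BlockSparseLinear(blocks, per_block_out, rng)
                width = sum(per_block_out)
                layers = [first, nn.ReLU(), nn.Linear(width, h_sub, rng)]
            else:
                layers = [nn.Linear(max(d, 1), h_sub, rng)]
            if batch_norm:
                layers.append(nn.BatchNorm1d(h_sub))
            layers.append(nn.ReLU())
            if dropout > 0:
                layers.append(nn.Dropout(dropout, rng))
            self.sub_encoders.append(nn.Sequential(*layers))
        self.central = nn.mlp([h_sub * len(self.source_names), h_central], rng,
                              batch_norm=batch_norm, final_activation=True)
        self.mu_head = nn.Linear(h_central, zdim, rng)
        self.logvar_head = nn.Linear(h_central, zdim, rng)
        self.dec_hidden = nn.mlp([zdim, h_central], rng, final_activation=True)
        self.decoders = [
            nn.Linear(h_central, max(source_dims[name], 1), rng)
            for name in self.source_names
        ]
        self._source_dims = dict(source_dims)

    def encode(self, blocks: dict[str, nn.Tensor]) -> tuple[nn.Tensor, nn.Tensor]:
        embs = []
        for name, enc in zip(self.source_names, self.sub_encoders):
            x = blocks[name]
            if self._source_dims[name] == 0:
                x = nn.Tensor(np.zeros((x.shape[0], 1)))
            embs.append(enc(x))
        h = self.central(nn.concat(embs, axis=-1))
        return self.mu_head(h), self.logvar_head(h)

    def reparameterize(self, mu: nn.Tensor, logvar: nn.Tensor,
                       rng: np.random.Generator) -> nn.Tensor:
        eps = rng.standard_normal(mu.shape)
        return mu + (logvar * 0.5).exp() * nn.Tensor(eps)

    def decode(self, z: nn.Tensor) -> dict[str, nn.Tensor]:
        h = self.dec_hidden(z)
        return {name: dec(h) for name, dec in zip(self.source_names, self.decoders)}


def encode_pathway(blocks: dict[str, np.ndarray | nn.Tensor], encoder: PathwayVAE,
                   mode: str = "eval",
                   rng: np.random.Generator | None = None) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
    """Encode one pathway's multi-source blocks to (z, mu, logvar).

    ``mode='train'`` returns a reparameterized sample (requires ``rng``);
    ``mode='eval'`` returns the posterior mean, deterministically.
    """
    present = [k for k, v in blocks.items()
               if np.asarray(v.data if isinstance(v, nn.Tensor) else v).size >= 0]
    if not present:
        raise ValidationError("all sources masked for this pathway")
    tensors = {
        k: v if isinstance(v, nn.Tensor) else nn.Tensor(np.atleast_2d(v))
        for k, v in blocks.items()
    }
    mu, logvar = encoder.encode(tensors)
    if mode == "train":
        if rng is None:
            raise ConfigurationError("train-mode encoding requires an rng")
        z = encoder.reparameterize(mu, logvar, rng)
    else:
        z = mu
    return z, mu, logvar


def kl_divergence(mu: nn.Tensor, logvar: nn.Tensor) -> nn.Tensor:
    """Closed-form KL( N(mu, sigma^2) || N(0, 1) ), summed over latent dims,
    averaged over the batch."""
    per_dim = (mu**2 + logvar.exp() - 1.0 - logvar) * 0.5
    return per_dim.sum(axis=-1).mean()


def vae_loss(recon: dict[str, nn.Tensor], target: dict[str, nn.Tensor | np.ndarray],
             mu: nn.Tensor, logvar: nn.Tensor, beta: float = 0.01) -> nn.Tensor:
    """Sum over sources of mean squared reconstruction error (mean over genes
    and batch) plus ``beta`` times the KL term."""
    loss = None
    for name, rec in recon.items():
        tgt = target[name]
        tgt_t = tgt if isinstance(tgt, nn.Tensor) else nn.Tensor(np.atleast_2d(tgt))
        if tgt_t.shape[-1] == 0:
            continue
        term = ((rec - tgt_t) ** 2).mean()
        loss = term if loss is None else loss + term
    kl = kl_divergence(mu, logvar)
    if loss is None:
        return kl * beta
    return loss + kl * beta


def build_omics_bag(sources: list[OmicsSource], sets: GeneSetCollection,
                    encoders: list[PathwayVAE]) -> OmicsBag:
    """Stack eval-mode pathway embeddings into (n, P, zdim), pathway order."""
    if len(encoders) != sets.n_pathways:
        raise ConfigurationError("one encoder per pathway is required")
    blocks = partition_by_pathway(sources, sets)
    for enc in encoders:
        enc.eval()
    per_pathway = []
    for (pname, _), enc in zip(sets.pathways, encoders):
        blk = {src.name: blocks[(src.name, pname)].matrix for src in sources}
        z, _, _ = encode_pathway(blk, enc, mode="eval")
        per_pathway.append(z.numpy())
    values = np.stack(per_pathway, axis=1)
    return OmicsBag(values=values, pathway_names=sets.names)
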