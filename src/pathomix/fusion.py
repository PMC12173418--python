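"""Factorized bilinear fusion and the hierarchical mixture of experts.

The K region embeddings and P pathway embeddings are fused pairwise into a
(K, P, zdim) interaction tensor with factorized bilinear pooling (rank-r sum
pooling followed by signed square root and L2 normalization).  Phase 1 of
the mixture of experts softmax-weights the K regions within each pathway;
phase 2 softmax-weights the P pathway embeddings into one patient embedding.
The recorded gating weights are the interpretability scores (MIS, PES).
Modality dropout zeroes whole modalities at random during training and
rescales the survivors, conferring robustness to genuinely missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError

__all__ = [
    "FusionTensor",
    "GatingRecord",
    "DropoutPolicy",
    "MFBFusion",
    "bilinear_fuse",
    "GatingNetwork",
    "moe_phase1",
    "moe_phase2",
    "apply_modality_dropout",
]

_NEG = 1e9  # logit offset standing in for -inf on masked entries


@dataclass
class FusionTensor:
    values: np.ndarray  # (K, P, zdim) or (B, K, P, zdim)
    region_mask: np.ndarray  # (K,) or (B, K) validity of each region row
    modality_mask: dict = field(default_factory=dict)


@dataclass
class GatingRecord:
    """Per-patient mixture-of-experts weights; read out as MIS and PES."""

    region_weights: np.ndarray  # (K, P), each column sums to 1 over k
    pathway_weights: np.ndarray  # (P,), sums to 1
    pathway_embeddings: np.ndarray  # (P, zdim)
    patient_embedding: np.ndarray  # (zdim,)


@dataclass
class DropoutPolicy:
    rate: float = 0.4
    modalities: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rate < 1.0):
            raise ConfigurationError("dropout rate p must satisfy 0 <= p < 1")


class MFBFusion(nn.Module):
    """Multimodal factorized bilinear pooling for one (region, pathway) pair.

    z = SumPool_r(U x  *  V o), then signed sqrt and L2 normalization.
    ``U`` and ``V`` are (zdim_in, zdim_out * r) projections without bias.
    """

    def __init__(self, zdim: int, rank: int, rng: np.random.Generator,
                 out_dim: int | None = None, in_dim: int | None = None):
        super().__init__()
        if rank < 1:
            raise ConfigurationError("MFB rank r must be >= 1")
        self.rank = rank
        self.zdim = zdim
        self.in_dim = in_dim or zdim
        self.out_dim = out_dim or zdim
        self.u = nn.Linear(self.in_dim, self.out_dim * rank, rng, bias=False)
        self.v = nn.Linear(self.in_dim, self.out_dim * rank, rng, bias=False)

    def forward(self, regions: nn.Tensor, omics: nn.Tensor) -> nn.Tensor:
        """(B, K, z) x (B, P, z) -> (B, K, P, out_dim); also accepts 2-D input."""
        squeeze = regions.ndim == 2
        if squeeze:
            regions = regions.reshape((1,) + regions.shape)
            omics = omics.reshape((1,) + omics.shape)
        b, k, _ = regions.shape
        p = omics.shape[1]
        ux = (regions @ self.u.weight).reshape((b, k, 1, self.out_dim, self.rank))
        vo = (omics @ self.v.weight).reshape((b, 1, p, self.out_dim, self.rank))
        pooled = (ux * vo).sum(axis=-1)  # (B, K, P, out_dim)
        # eps 1e-4 bounds the derivative spike at zero (would be 1e6 at
        # 1e-12), keeping gradient path integrals numerically stable
        signed = pooled * ((pooled.abs() + 1e-4) ** -0.5)  # sign(x) sqrt(|x|)
        norm = ((signed**2).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        out = signed / norm
        return out.reshape((k, p, self.out_dim)) if squeeze else out


def bilinear_fuse(regions, omics, fusion: MFBFusion,
                  region_mask: np.ndarray | None = None) -> FusionTensor:
    """Fuse region and omics bags into the K x P x zdim interaction tensor."""
    reg = regions if isinstance(regions, nn.Tensor) else nn.Tensor(np.asarray(regions, float))
    omi = omics if isinstance(omics, nn.Tensor) else nn.Tensor(np.asarray(omics, float))
    if reg.shape[-1] != omi.shape[-1]:
        raise ValidationError("region and omics embeddings must share zdim")
    was_training = fusion.training
    fusion.eval()
    values = fusion(reg, omi).numpy()
    if was_training:
        fusion.train()
    if region_mask is None:
        region_mask = np.ones(values.shape[-3], dtype=bool)
    return FusionTensor(values=values, region_mask=region_mask)


class GatingNetwork(nn.Module):
    """One-hidden-layer scorer producing a scalar logit per expert input."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.net = nn.Sequential(
            nn.Linear(in_dim, hidden, rng), nn.ReLU(), nn.Linear(hidden, 1, rng)
        )

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        shape = x.shape
        flat = x.reshape((-1, shape[-1]))
        return self.net(flat).reshape(shape[:-1])


def _softmax(logits: nn.Tensor, axis: int) -> nn.Tensor:
    return (logits - logits.logsumexp(axis=axis, keepdims=True)).exp()


def moe_phase1(fused: nn.Tensor | FusionTensor, gate: GatingNetwork,
               region_mask: np.ndarray | None = None) -> tuple[nn.Tensor, nn.Tensor]:
    """Weight regions within each pathway.

    Returns ``(pathway_embeddings, region_weights)`` with shapes
    (..., P, zdim) and (..., K, P); weights are a softmax over K per pathway,
    masked regions receive zero weight.
    """
    if isinstance(fused, FusionTensor):
        region_mask = fused.region_mask if region_mask is None else region_mask
        fused = nn.Tensor(fused.values)
    squeeze = fused.ndim == 3
    if squeeze:
        fused = fused.reshape((1,) + fused.shape)
    b, k, p, z = fused.shape
    if region_mask is None:
        mask = np.ones((b, k), dtype=bool)
    else:
        mask = np.broadcast_to(np.atleast_2d(region_mask).astype(bool), (b, k))
    if not mask.any(axis=1).all():
        raise ValidationError("all regions masked for at least one sample")
    logits = gate(fused)  # (B, K, P)
    offset = np.where(mask, 0.0, -_NEG)[:, :, None]
    weights = _softmax(logits + nn.Tensor(offset), axis=1)  # (B, K, P)
    w_exp = weights.reshape((b, k, p, 1))
    pathway_emb = (w_exp * fused).sum(axis=1)  # (B, P, zdim)
    if squeeze:
        return pathway_emb.reshape((p, z)), weights.reshape((k, p))
    return pathway_emb, weights


def moe_phase2(pathway_embeddings: nn.Tensor, gate: GatingNetwork,
               pathway_head: nn.Module | None = None):
    """Weight pathways into the patient embedding.

    Returns ``(patient_embedding, pathway_weights)`` and, when a
    ``pathway_head`` is given, the per-pathway linear predictions as third
    element.
    """
    x = pathway_embeddings
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape((1,) + x.shape)
    b, p, z = x.shape
    logits = gate(x)  # (B, P)
    weights = _softmax(logits, axis=1)
    patient = (weights.reshape((b, p, 1)) * x).sum(axis=1)  # (B, zdim)
    preds = None
    if pathway_head is not None:
        preds = pathway_head(x.reshape((b * p, z)))
        preds = preds.reshape((b, p, -1) if preds.ndim == 2 else (b, p))
    if squeeze:
        patient = patient.reshape((z,))
        weights = weights.reshape((p,))
        if preds is not None:
            preds = preds.reshape(preds.shape[1:])
    return (patient, weights) if preds is None else (patient, weights, preds)


def apply_modality_dropout(inputs: dict[str, np.ndarray], policy: DropoutPolicy,
                           mode: str = "train",
                           rng: np.random.Generator | None = None,
                           missing: set[str] | frozenset[str] = frozenset(),
                           ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Drop whole modalities per sample with probability ``p``.

    Train mode: each modality is independently zeroed with probability p;
    draws in which every modality of a sample would be dropped are redrawn,
    which makes the marginal keep probability (1-p)/(1-p^M) for M
    modalities, so survivors are rescaled by its inverse (1-p^M)/(1-p) —
    the inverted-dropout contract, preserving the expectation exactly under
    the redraw rule.  Eval mode: identity except that genuinely ``missing``
    modalities are zeroed without rescaling.

    ``inputs`` maps modality name to an array whose first axis is the sample
    axis.  Returns the masked inputs and a {modality: keep-mask} record.
    """
    names = list(inputs)
    if len(names) < 2:
        raise ConfigurationError("modality dropout requires >= 2 modalities")
    n = next(iter(inputs.values())).shape[0]
    for name, arr in inputs.items():
        if arr.shape[0] != n:
            raise ValidationError(f"modality {name!r} has inconsistent sample count")
    if mode == "eval":
        keep = {name: np.full(n, name not in missing) for name in names}
        out = {
            name: (arr if name not in missing else np.zeros_like(arr))
            for name, arr in inputs.items()
        }
        return out, keep
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    p = policy.rate
    keep_mat = rng.random((n, len(names))) >= p
    # never drop every modality of one sample: redraw those rows
    bad = ~keep_mat.any(axis=1)
    while bad.any():
        keep_mat[bad] = rng.random((int(bad.sum()), len(names))) >= p
        bad = ~keep_mat.any(axis=1)
    m = len(names)
    scale = (1.0 - p**m) / (1.0 - p) if p > 0 else 1.0
    out = {}
    keep = {}
    for j, name in enumerate(names):
        k = keep_mat[:, j]
        keep[name] = k
        arr = inputs[name]
        factor = np.where(k, scale, 0.0).reshape((n,) + (1,) * (arr.ndim - 1))
        out[name] = arr * factor
    return out, keep
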