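"""Task losses, the multiphase training loop, splits, and survival metrics.

Classification is trained with categorical cross-entropy; survival with the
Cox negative partial log-likelihood

    L(theta) = - sum_{i: E_i = 1} ( r_i - log sum_{j: T_j >= T_i} exp(r_j) )

with Breslow handling of tied event times (tied patients share the risk
set) and a log-sum-exp-stabilized inner sum.  Training follows a multiphase
strategy: phase 1 pretrains each modality unsupervised (VAE reconstruction +
KL for omics, feature autoencoding for the WSI encoder); phase 2 unfreezes
everything and optimizes the task loss plus a small auxiliary VAE term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .errors import ConfigurationError, ValidationError
from .model import MultimodalNetwork, PreparedCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "TrainConfig",
    "SplitPlan",
    "classification_loss",
    "survival_loss",
    "concordance_index",
    "make_splits",
    "train",
    "TrainHistory",
]


@dataclass
class SurvivalRecord:
    time: float
    event: int

    def __post_init__(self):
        if not self.time > 0:
            raise ValidationError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValidationError("event indicator must be 0 or 1")


@dataclass
class TrainConfig:
    task: str = "classification"
    phase1_epochs: int = 30
    phase2_epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 16
    beta: float = 0.01  # KL weight, linearly warmed up over beta_warmup epochs
    beta_warmup: int = 10
    aux_weight: float = 0.1  # weight of the VAE losses inside the phase-2 loss
    pathway_aux_weight: float = 0.5  # weight of per-pathway prediction losses
    gate_entropy_weight: float = 0.0  # >0 sharpens MoE gates (entropy penalty)
    patience: int = 10
    weight_decay: float = 1e-3
    finetune_all: bool = False  # phase 2: also unfreeze sub-encoders/WSI encoder
    seed: int = 0

    def __post_init__(self):
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ConfigurationError("epoch counts must be >= 0")
        if self.task == "survival" and self.batch_size < 2:
            raise ConfigurationError("survival batches need >= 2 patients")


@dataclass
class SplitPlan:
    """Per-fold (train, val, test) index triples, stratified 60-20-20."""

    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    strata: np.ndarray


def _to_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, float))


def classification_loss(logits, labels) -> nn.Tensor:
    """Mean categorical cross-entropy over the batch."""
    logits = _to_tensor(logits)
    labels = np.asarray(labels, int)
    n, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValidationError("class label out of range")
    log_z = logits.logsumexp(axis=1)
    picked = logits[np.arange(n), labels]
    return (log_z - picked).mean()


def survival_loss(risks, times, events, reduction: str = "sum") -> nn.Tensor:
    """Negative Cox partial log-likelihood (Breslow ties).

    ``reduction='sum'`` is the raw formula; ``'mean'`` divides by the number
    of events (used inside the training loop for step-size stability).
    """
    risks = _to_tensor(risks)
    if risks.ndim == 2:
        risks = risks.reshape((risks.shape[0],))
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = times.shape[0]
    n_events = int(events.sum())
    if n_events == 0:
        raise ValidationError("survival loss undefined on a batch with no events")
    # risk-set mask: R[i, j] = 1 iff T_j >= T_i (ties share the risk set)
    mask = (times[None, :] >= times[:, None]).astype(float)
    big = risks.reshape((1, n)) * nn.Tensor(np.ones((n, 1)))
    masked = big * nn.Tensor(mask) + nn.Tensor((mask - 1.0) * 1e9)
    log_risk_sets = masked.logsumexp(axis=1)  # (n,)
    contrib = (risks - log_risk_sets) * nn.Tensor(events.astype(float))
    total = -contrib.sum()
    if reduction == "mean":
        return total * (1.0 / n_events)
    return total


def concordance_index(risks, times, events) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly.

    A pair (i, j) is comparable when patient i has an event and T_i < T_j;
    it is concordant when risk_i > risk_j, and risk ties count 1/2.
    """
    risks = np.asarray(risks, float).ravel()
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    comparable = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValidationError("no comparable pairs for the concordance index")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def make_splits(strata, seed: int, n_folds: int = 5) -> SplitPlan:
    """Stratified n-fold 60-20-20 train/val/test plan.

    The test sets are the disjoint folds of a stratified K-fold; the
    remaining 80% is split 75/25 (stratified) into train and validation.
    """
    strata = np.asarray(strata)
    values, counts = np.unique(strata, return_counts=True)
    for v, c in zip(values, counts):
        if c < n_folds:
            raise ValidationError(f"stratum {v!r} has only {c} samples (< {n_folds})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = []
    for rest_idx, test_idx in skf.split(np.zeros(len(strata)), strata):
        train_idx, val_idx = train_test_split(
            rest_idx, test_size=0.25, random_state=seed % (2**31),
            stratify=strata[rest_idx],
        )
        folds.append((np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)))
    return SplitPlan(folds=folds, strata=strata)


@dataclass
class TrainHistory:
    phase1: list[dict] = field(default_factory=list)
    phase2: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def _batches(idx: np.ndarray, batch_size: int, rng: np.random.Generator,
             shuffle: bool = True):
    order = rng.permutation(idx) if shuffle else np.asarray(idx)
    for start in range(0, len(order), batch_size):
        yield order[start : start + batch_size]


def _task_loss(model: MultimodalNetwork, cohort: PreparedCohort, out,
               idx: np.ndarray) -> nn.Tensor:
    if model.task == "classification":
        return classification_loss(out.output, cohort.labels[idx])
    return survival_loss(out.output, cohort.times[idx], cohort.events[idx],
                         reduction="mean")


def _pathway_aux_loss(model: MultimodalNetwork, cohort: PreparedCohort, out,
                      idx: np.ndarray) -> nn.Tensor:
    """Supervise the per-pathway linear predictions (averaged over pathways).

    This trains each pathway expert against the outcome directly, which both
    regularizes the shared representation and makes the phase-2 gating
    weights reflect pathway predictive value.
    """
    preds = out.pathway_predictions  # (B, P, C)
    p = preds.shape[1]
    total = None
    for j in range(p):
        pred_j = preds[:, j, :]
        if model.task == "classification":
            term = classification_loss(pred_j, cohort.labels[idx])
        else:
            term = survival_loss(pred_j, cohort.times[idx], cohort.events[idx],
                                 reduction="mean")
        total = term if total is None else total + term
    return total * (1.0 / p)


def train(model: MultimodalNetwork, cohort: PreparedCohort, config: TrainConfig,
          train_idx: np.ndarray, val_idx: np.ndarray | None = None) -> TrainHistory:
    """Multiphase training; returns per-epoch history.

    Phase 1 trains the pathway VAEs and the WSI autoencoder independently;
    phase 2 unfreezes everything and minimizes the task loss plus
    ``aux_weight`` times the VAE losses, with early stopping on the
    validation loss (patience ``config.patience``).
    """
    rng = np.random.default_rng(config.seed)
    train_idx = np.asarray(train_idx, int)
    if model.task == "survival" and cohort.events is not None:
        if cohort.events[train_idx].sum() == 0:
            raise ValidationError("survival training set contains no events")
    history = TrainHistory()

    # ---- phase 1: unsupervised per-modality pretraining -----------------
    vae_params = [p for vae in model.vaes for p in vae.parameters()]
    wsi_params = list(model.wsi_encoder.parameters()) + list(model.wsi_decoder.parameters())
    opt1 = nn.Adam(vae_params + wsi_params, lr=config.lr)
    for epoch in range(config.phase1_epochs):
        beta = config.beta * min(1.0, (epoch + 1) / max(config.beta_warmup, 1))
        model.train()
        ep_losses = []
        for batch in _batches(train_idx, config.batch_size, rng):
            opt1.zero_grad()
            loss = model.vae_losses(cohort, batch, "train", rng, beta)
            loss = loss + model.wsi_recon_loss(cohort, batch)
            loss.backward()
            opt1.step()
            ep_losses.append(loss.item())
        rec = {"epoch": epoch, "train_loss": float(np.mean(ep_losses))}
        if val_idx is not None and len(val_idx):
            model.eval()
            vl = model.vae_losses(cohort, np.asarray(val_idx, int), "eval", rng, beta)
            vl = vl + model.wsi_recon_loss(cohort, np.asarray(val_idx, int))
            rec["val_loss"] = vl.item()
        history.phase1.append(rec)

    # ---- phase 2: joint supervised training ------------------------------
    # the per-source sub-encoders and the WSI encoder keep their unsupervised
    # phase-1 representations unless finetune_all is set; the central
    # encoders, fusion, gates and heads are unfrozen
    if config.finetune_all:
        phase2_params = list(model.parameters())
        aux_weight = config.aux_weight
    else:
        frozen = {id(p) for vae in model.vaes for p in vae.parameters()}
        frozen |= {id(p) for p in model.wsi_encoder.parameters()}
        frozen |= {id(p) for p in model.wsi_decoder.parameters()}
        phase2_params = [p for p in model.parameters() if id(p) not in frozen]
        aux_weight = 0.0  # reconstruction term has no trainable parameters
    # gating networks are exempt from weight decay: shrinking their weights
    # pulls the mixtures toward the uniform saddle and can freeze them there
    gate_ids = {id(p) for p in model.gate1.parameters()}
    gate_ids |= {id(p) for p in model.gate2.parameters()}
    decay_mask = [id(p) not in gate_ids for p in phase2_params]
    opt2 = nn.Adam(phase2_params, lr=config.lr, weight_decay=config.weight_decay,
                   decay_mask=decay_mask)
    best_val = np.inf
    best_state = None
    patience_left = config.patience
    for epoch in range(config.phase2_epochs):
        model.train()
        ep_losses = []
        for batch in _batches(train_idx, config.batch_size, rng):
            if model.task == "survival" and cohort.events[batch].sum() == 0:
                continue  # partial likelihood undefined; skip the batch
            opt2.zero_grad()
            out = model.forward(cohort, batch, mode="train", rng=rng)
            loss = _task_loss(model, cohort, out, batch)
            if config.pathway_aux_weight > 0:
                loss = loss + _pathway_aux_loss(model, cohort, out, batch) \
                    * config.pathway_aux_weight
            if config.gate_entropy_weight > 0:
                eps = 1e-12
                w1, w2 = out.region_weights, out.pathway_weights
                ent = -(w1 * (w1 + eps).log()).sum(axis=1).mean() \
                    - (w2 * (w2 + eps).log()).sum(axis=1).mean()
                loss = loss + ent * config.gate_entropy_weight
            if aux_weight > 0:
                loss = loss + model.vae_losses(cohort, batch, "train", rng,
                                               config.beta) * aux_weight
            loss.backward()
            opt2.step()
            ep_losses.append(loss.item())
        rec = {"epoch": epoch, "train_loss": float(np.mean(ep_losses)) if ep_losses else np.nan}
        if val_idx is not None and len(val_idx):
            vi = np.asarray(val_idx, int)
            model.eval()
            out = model.forward(cohort, vi, mode="eval")
            try:
                vloss = _task_loss(model, cohort, out, vi).item()
            except ValidationError:
                vloss = np.nan
            rec["val_loss"] = vloss
            if np.isfinite(vloss) and vloss < best_val - 1e-9:
                best_val = vloss
                best_state = model.state_dict()
                history.best_epoch = epoch
                patience_left = config.patience
            else:
                patience_left -= 1
        history.phase2.append(rec)
        if val_idx is not None and patience_left <= 0:
            logger.info("early stopping at epoch %d (best %d)", epoch, history.best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history
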