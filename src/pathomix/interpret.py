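"""Multi-level interpretability: gene SHAP values, pathway enrichment, and
the multimodal interaction score.

* Gene level: Shapley-style attributions of the task output to each gene of
  each omics source, computed by integrated gradients averaged over a
  background sample (exact for linear models; satisfies the completeness /
  additivity property up to integration error).
* Pathway level: the phase-2 gating weight ``r_{i,p} = w_{i,p}`` ranks
  pathway contributions per patient (pathway enrichment score, PES); gene
  attributions are normalized by it (``s~ = r * s``) and a two-sample
  Kolmogorov-Smirnov test compares in-pathway versus out-of-pathway
  normalized scores.
* Spatial x molecular level: the phase-1 gating weight is read out verbatim
  as the multimodal interaction score ``MIS_{i,k,p}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, spearmanr
from statsmodels.stats.multitest import multipletests

from . import nn
from .errors import ConfigurationError, ValidationError
from .fusion import GatingRecord, moe_phase1, moe_phase2
from .model import MultimodalNetwork, PreparedCohort
from .omics import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "GeneImportance",
    "PathwayScore",
    "InteractionScore",
    "InterpretationReport",
    "compute_shap",
    "extract_pes",
    "normalize_shap",
    "ks_enrichment",
    "extract_mis",
    "stability_analysis",
    "km_high_low_risk",
]


@dataclass
class GeneImportance:
    """Long table: one row per (patient, gene, source, pathway occurrence)."""

    table: pd.DataFrame  # patient_id, gene, source, pathway, shap[, shap_normalized]
    base_values: np.ndarray  # (n_patients,) expected model output on background
    outputs: np.ndarray  # (n_patients,) model output being explained


@dataclass
class PathwayScore:
    r: np.ndarray  # (n, P) per-patient ranking scores (phase-2 gating weights)
    pathway_names: list[str]
    p_values: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    ks_stats: np.ndarray | None = None

    def cohort_mean(self) -> np.ndarray:
        return self.r.mean(axis=0)


@dataclass
class InteractionScore:
    values: np.ndarray  # (n, K, P) per-patient MIS matrices

    def cohort_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class InterpretationReport:
    gene_table: pd.DataFrame
    pathway_table: pd.DataFrame
    mis: InteractionScore
    metadata: dict = field(default_factory=dict)


# ------------------------------------------------------------------ gating
def extract_pes(gating: list[GatingRecord],
                pathway_names: list[str] | None = None) -> PathwayScore:
    """r_{i,p} = w_{i,p} verbatim; a pure read of the recorded gating."""
    r = np.stack([g.pathway_weights for g in gating])
    names = pathway_names or [f"pathway{p}" for p in range(r.shape[1])]
    return PathwayScore(r=r, pathway_names=list(names))


def extract_mis(gating: list[GatingRecord]) -> InteractionScore:
    """MIS_{i,k,p} = (w_k^p)_i verbatim; a pure read of the recorded gating."""
    return InteractionScore(values=np.stack([g.region_weights for g in gating]))


# -------------------------------------------------------------------- SHAP
def _flat_forward(model: MultimodalNetwork, cohort: PreparedCohort,
                  x_flat: nn.Tensor, slide_idx: int):
    """Forward pass from a flat omics vector (gene_layout order) with the
    patient's WSI side held fixed; returns the ForwardOutput pieces needed."""
    model.eval()
    n = x_flat.shape[0]
    z_list = []
    offset = 0
    for p, vae in enumerate(model.vaes):
        blk = {}
        for s in model.source_names:
            w = cohort.blocks[p][s].shape[1]
            blk[s] = x_flat[:, offset : offset + w]
            offset += w
        mu, _ = vae.encode(blk)
        z_list.append(mu)
    omics_bag = nn.stack(z_list, axis=1)
    region_vals = model.wsi_encoder(cohort.slides[slide_idx]).numpy()
    regions = nn.Tensor(np.repeat(region_vals[None], n, axis=0))
    mask = np.repeat(cohort.slides[slide_idx].region_mask[None], n, axis=0)
    zdim = model.config.zdim
    k, p = regions.shape[1], omics_bag.shape[1]
    regions = model.region_bn(regions.reshape((n * k, zdim))).reshape((n, k, zdim))
    omics_bag = model.omics_bn(omics_bag.reshape((n * p, zdim))).reshape((n, p, zdim))
    regions = nn.concat([regions, nn.Tensor(np.ones((n, k, 1)))], axis=-1)
    omics_bag = nn.concat([omics_bag, nn.Tensor(np.ones((n, p, 1)))], axis=-1)
    fused = model.fusion(regions, omics_bag)
    pathway_emb, _ = moe_phase1(fused, model.gate1, mask)
    patient, _, _ = moe_phase2(pathway_emb, model.gate2, model.pathway_head)
    return model.head(patient), patient


def _scalar_target(out: nn.Tensor, patient: nn.Tensor, task: str,
                   target: str, target_class: int) -> nn.Tensor:
    if target == "latent":
        return patient.mean(axis=-1)
    if task == "classification":
        return out[:, target_class]
    return out.reshape((out.shape[0],))


def _integrated_gradients(f, x: np.ndarray, backgrounds: np.ndarray,
                          steps: int = 25) -> np.ndarray:
    """Integrated gradients of scalar-valued ``f`` at ``x`` against each
    background, averaged over backgrounds (midpoint rule; exact for linear f)."""
    nb, d = backgrounds.shape
    ts = (np.arange(steps) + 0.5) / steps
    diffs = x[None, :] - backgrounds
    points = (backgrounds[:, None, :] + ts[None, :, None] * diffs[:, None, :])
    xt = nn.Tensor(points.reshape(-1, d), requires_grad=True)
    f(xt).sum().backward()
    grads = xt.grad.reshape(nb, steps, d)
    return (diffs * grads.mean(axis=1)).mean(axis=0)


def compute_shap(model: MultimodalNetwork, cohort: PreparedCohort,
                 sample_idx, background_idx, n_background: int = 20,
                 steps: int = 25, target: str = "output",
                 target_class: int | None = None, seed: int = 0,
                 smooth_knn: int = 0) -> GeneImportance:
    """Integrated-gradient Shapley attributions of the task output to genes.

    For each explained patient the attribution of gene g is
    ``(x - b)_g * mean_t  d f / d x_g  at  b + t (x - b)`` averaged over
    ``n_background`` background patients (midpoint rule over ``steps`` path
    points).  Additivity holds up to integration error:
    ``sum_g s_g ~= f(x) - mean_b f(b)``.  ``smooth_knn > 0`` additionally
    averages each patient's attributions over its k nearest neighbours in
    patient-embedding space (attribution smoothing across similar samples).
    """
    if target not in ("output", "latent"):
        raise ConfigurationError("target must be 'output' or 'latent'")
    rng = np.random.default_rng(seed)
    sample_idx = np.asarray(sample_idx, int)
    background_idx = np.asarray(background_idx, int)
    if background_idx.size == 0:
        raise ValidationError("background set must be nonempty")
    if background_idx.size > n_background:
        background_idx = rng.choice(background_idx, size=n_background, replace=False)
    x_all = cohort.flat_omics(np.arange(cohort.n_samples))
    bg = x_all[background_idx]  # (nb, D)
    layout = cohort.gene_layout()
    if target_class is None:
        target_class = 1 if model.n_outputs > 1 else 0

    rows = []
    base_values = np.empty(len(sample_idx))
    outputs = np.empty(len(sample_idx))
    attributions = np.empty((len(sample_idx), x_all.shape[1]))
    embeddings = np.empty((len(sample_idx), model.config.zdim))
    for row, i in enumerate(sample_idx):
        x = x_all[i]

        def f(xt, _i=i):
            out, patient = _flat_forward(model, cohort, xt, _i)
            return _scalar_target(out, patient, model.task, target, target_class)

        attributions[row] = _integrated_gradients(f, x, bg, steps=steps)
        # f(x) and mean_b f(b) for the additivity record
        xb = nn.Tensor(np.vstack([x[None, :], bg]))
        out_b, patient_b = _flat_forward(model, cohort, xb, i)
        fb = _scalar_target(out_b, patient_b, model.task, target, target_class).numpy()
        outputs[row] = fb[0]
        base_values[row] = fb[1:].mean()
        embeddings[row] = patient_b.numpy()[0]
    if smooth_knn > 0 and len(sample_idx) > 1:
        k = min(smooth_knn, len(sample_idx) - 1)
        d = np.linalg.norm(embeddings[:, None] - embeddings[None, :], axis=-1)
        smoothed = np.empty_like(attributions)
        for row in range(len(sample_idx)):
            nbrs = np.argsort(d[row])[: k + 1]  # includes self
            smoothed[row] = attributions[nbrs].mean(axis=0)
        attributions = smoothed
    for row, i in enumerate(sample_idx):
        sid = cohort.sample_ids[i]
        for col, (p, s, g) in enumerate(layout):
            rows.append((sid, g, s, cohort.gene_sets.names[p], attributions[row, col]))
    table = pd.DataFrame(rows, columns=["patient_id", "gene", "source", "pathway", "shap"])
    return GeneImportance(table=table, base_values=base_values, outputs=outputs)


def normalize_shap(gene: GeneImportance, pathway: PathwayScore,
                   sample_ids: list[str]) -> pd.DataFrame:
    """s~_{i,g} = r_{i,p(g)} * s_{i,g}; one value per (gene, pathway) occurrence."""
    name_to_p = {n: j for j, n in enumerate(pathway.pathway_names)}
    id_to_row = {sid: i for i, sid in enumerate(sample_ids)}
    table = gene.table.copy()
    unknown = set(table["pathway"]) - set(name_to_p)
    if unknown:
        raise ValidationError(f"genes with unknown pathway(s): {sorted(unknown)}")
    r_col = np.array([
        pathway.r[id_to_row[sid], name_to_p[pw]]
        for sid, pw in zip(table["patient_id"], table["pathway"])
    ])
    table["shap_normalized"] = r_col * table["shap"].to_numpy()
    return table


# ------------------------------------------------------------- enrichment
def ks_enrichment(normalized_table: pd.DataFrame, sets: GeneSetCollection,
                  score_column: str = "shap_normalized") -> pd.DataFrame:
    """Two-sample KS test of in-pathway vs out-of-pathway gene importances.

    Scores are aggregated per (gene, pathway) occurrence as the mean of
    |normalized score| over patients; each pathway's in-set sample is tested
    against the occurrences of all other pathways (two-sided), and
    Benjamini-Hochberg adjusted p-values are reported alongside raw ones.
    Pathways with fewer than 2 genes on either side are skipped.
    """
    agg = (normalized_table.assign(absval=normalized_table[score_column].abs())
           .groupby(["pathway", "gene"], sort=False)["absval"].mean())
    rows = []
    for pname in sets.names:
        if pname not in agg.index.get_level_values(0):
            logger.warning("pathway %s absent from score table; skipped", pname)
            continue
        inside = agg.loc[pname].to_numpy()
        outside = agg.drop(pname, level=0).to_numpy()
        if inside.size < 2 or outside.size < 2:
            logger.warning("pathway %s skipped: degenerate set sizes", pname)
            continue
        stat, p = ks_2samp(inside, outside, alternative="two-sided")
        rows.append((pname, inside.size, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["pathway", "n_genes", "ks_statistic", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


# -------------------------------------------------------------- stability
def stability_analysis(pathway_scores: list[PathwayScore]) -> dict:
    """Spearman rank correlation of cohort-mean pathway weights across folds."""
    if len(pathway_scores) < 2:
        raise ValidationError("stability analysis needs >= 2 folds")
    means = [ps.cohort_mean() if isinstance(ps, PathwayScore) else np.asarray(ps)
             for ps in pathway_scores]
    k = len(means)
    corr = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rho = spearmanr(means[i], means[j]).statistic
            corr[i, j] = corr[j, i] = rho
    off = corr[np.triu_indices(k, 1)]
    return {"matrix": corr, "mean": float(off.mean()), "sd": float(off.std())}


# ------------------------------------------------------- survival plumbing
def km_high_low_risk(risks, times, events):
    """Median-risk split with Kaplan-Meier fits and a log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    risks = np.asarray(risks, float).ravel()
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    high = risks > np.median(risks)
    km_high, km_low = KaplanMeierFitter(), KaplanMeierFitter()
    km_high.fit(times[high], events[high], label="high risk")
    km_low.fit(times[~high], events[~high], label="low risk")
    lr = logrank_test(times[high], times[~high], events[high], events[~high])
    return {"km_high": km_high, "km_low": km_low, "p_value": float(lr.p_value)}
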