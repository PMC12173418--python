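"""End-to-end pipeline: load a cohort directory, train, predict, interpret.

The declarative run configuration is schema-validated (unknown keys are
rejected) and its hash is recorded in every output so each artifact is
reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .interpret import (
    compute_shap,
    extract_mis,
    extract_pes,
    ks_enrichment,
    normalize_shap,
)
from .model import ModelConfig, MultimodalNetwork, prepare_cohort
from .training import TrainConfig, concordance_index, make_splits, train
from .wsi import KernelParams
from . import io as pio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_model", "load_trained"]


class RunConfig(BaseModel):
    """Declarative configuration of a full run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    data_dir: str
    out_dir: str
    task: str = "classification"
    seed: int = 0
    # WSI encoding
    k_regions: int = 4
    lambda_h: float | None = None  # None -> per-slide median heuristic
    lambda_g: float | None = None
    delta_c: float = 0.5
    delta_h: float = 0.5
    # architecture
    zdim: int = 16
    mfb_rank: int = 4
    gate_hidden: int = 16
    vae_hidden: tuple[int, int] = (32, 16)
    modality_dropout: float = 0.4
    net_dropout: float = 0.0
    # training
    phase1_epochs: int = 20
    phase2_epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 16
    beta: float = 0.01
    aux_weight: float = 0.1
    patience: int = 10
    # interpretation
    shap_patients: int = 20
    allow_missing: list[str] = []

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _stage(name: str, t0: float) -> None:
    logger.info("stage=%s wall=%.2fs", name, time.time() - t0)


def _load_cohort(config: "RunConfig"):
    bags, sources, gene_sets, outcomes, _ = pio.read_cohort_dir(config.data_dir)
    sources = [s for s in sources if s.name not in set(config.allow_missing)]
    kp = KernelParams(lambda_h=config.lambda_h or 1.0, lambda_g=config.lambda_g or 1.0,
                      delta_c=config.delta_c, delta_h=config.delta_h)
    auto = config.lambda_h is None or config.lambda_g is None
    labels = times = events = None
    if "label" in outcomes.columns:
        labels = outcomes["label"].to_numpy()
    else:
        times = outcomes["time"].to_numpy()
        events = outcomes["event"].to_numpy()
    cohort = prepare_cohort(bags, sources, gene_sets, kp, config.k_regions,
                            config.seed, labels=labels, times=times, events=events,
                            auto_bandwidth=auto)
    return cohort


def build_model(config: "RunConfig", cohort) -> MultimodalNetwork:
    n_classes = (int(len(np.unique(cohort.labels)))
                 if cohort.labels is not None else 2)
    return MultimodalNetwork(
        cohort, task=config.task, n_classes=n_classes,
        config=ModelConfig(zdim=config.zdim, mfb_rank=config.mfb_rank,
                           gate_hidden=config.gate_hidden, vae_hidden=config.vae_hidden,
                           modality_dropout=config.modality_dropout,
                           net_dropout=config.net_dropout),
        seed=config.seed,
    )


def load_trained(config: "RunConfig", model_path: str | Path):
    """Rebuild the model for ``config`` and load trained weights."""
    cohort = _load_cohort(config)
    model = build_model(config, cohort)
    with np.load(model_path) as state:
        model.load_state_dict(dict(state))
    model.eval()
    return model, cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute encode -> fuse -> train -> predict -> interpret.

    Returns a summary dict; all tables are written under ``config.out_dir``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "schema_version": 1}
    cohort = _load_cohort(config)
    labels, times, events = cohort.labels, cohort.times, cohort.events
    strata = labels if labels is not None else events
    _stage("encode", t0)

    plan = make_splits(strata, config.seed)
    train_idx, val_idx, test_idx = plan.folds[0]
    model = build_model(config, cohort)
    tc = TrainConfig(task=config.task, phase1_epochs=config.phase1_epochs,
                     phase2_epochs=config.phase2_epochs, lr=config.lr,
                     batch_size=config.batch_size, beta=config.beta,
                     aux_weight=config.aux_weight, patience=config.patience,
                     seed=config.seed)
    history = train(model, cohort, tc, train_idx, val_idx)
    pd.DataFrame(history.phase2).to_csv(out_dir / "train_history.tsv", sep="\t", index=False)
    np.savez(out_dir / "model.npz", **model.state_dict())
    _stage("train", t0)

    missing = frozenset(m for m in config.allow_missing if m == "wsi")
    preds = model.predict(cohort, missing=missing)
    pred_df = pd.DataFrame({"sample_id": cohort.sample_ids})
    summary = dict(meta)
    if config.task == "classification":
        for c in range(preds.shape[1]):
            pred_df[f"prob_class{c}"] = preds[:, c]
        from sklearn.metrics import roc_auc_score

        if len(np.unique(labels)) == 2:
            summary["test_auc"] = float(roc_auc_score(labels[test_idx], preds[test_idx, 1]))
    else:
        pred_df["risk"] = preds
        summary["test_cindex"] = concordance_index(preds[test_idx], times[test_idx],
                                                   events[test_idx])
    pred_df.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
    _stage("predict", t0)

    fw = model.forward(cohort, np.arange(cohort.n_samples), mode="eval")
    gating = fw.gating_records()
    pes = extract_pes(gating, cohort.gene_sets.names)
    mis = extract_mis(gating)
    n_shap = min(config.shap_patients, cohort.n_samples)
    shap_idx = np.sort(np.random.default_rng(config.seed).choice(
        cohort.n_samples, size=n_shap, replace=False))
    gene_imp = compute_shap(model, cohort, shap_idx, train_idx, seed=config.seed)
    pes_sub = extract_pes([gating[i] for i in shap_idx], cohort.gene_sets.names)
    gene_table = normalize_shap(gene_imp, pes_sub,
                                [cohort.sample_ids[i] for i in shap_idx])
    pathway_table = ks_enrichment(gene_table, cohort.gene_sets)
    pathway_table.insert(1, "mean_r", [
        float(pes.cohort_mean()[cohort.gene_sets.names.index(p)])
        for p in pathway_table["pathway"]
    ])
    gene_table.to_csv(out_dir / "gene_importance.tsv", sep="\t", index=False)
    pathway_table.to_csv(out_dir / "pathway_enrichment.tsv", sep="\t", index=False)
    np.save(out_dir / "mis.npy", mis.values)
    (out_dir / "run_meta.json").write_text(json.dumps(
        {**meta, "n_samples": cohort.n_samples, "stages_done": "all"}, indent=2))
    _stage("interpret", t0)
    summary["out_dir"] = str(out_dir)
    return summary
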