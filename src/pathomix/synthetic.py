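"""Desk-scale synthetic cohorts with the statistical structure the model
assumes.

Each patient gets (1) a patch bag whose patches fall into ``n_regions``
spatial clusters with region-specific feature distributions, and (2)
``n_sources`` gene-level omics matrices whose within-pathway correlation
comes from one shared latent factor per (pathway, source pair).  The outcome
is driven by a planted interaction: patients carry a region shift
``alpha_i`` (applied along a fixed feature direction to signal-region
patches) and a pathway factor ``beta_i`` (the latent factor of the signal
pathway), both drawn from N(mu0, sd0^2) with mu0 > 0.  The planted score is
the standardized product

    z_i = (alpha_i * beta_i - mu0^2) / sd(alpha * beta)

and the class label is Bernoulli(sigmoid(effect_size * z_i)); survival times
are exponential with log-hazard ``effect_size * z_i`` (proportional hazards
by construction) under independent exponential censoring tuned to the
requested censoring fraction.  The nonzero factor means give each modality a
main-effect component of the signal, so single-modality inference remains
informative, while the product term is only visible to models that fuse the
two modalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError
from .omics import GeneSetCollection, OmicsSource
from .wsi import PatchBag

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "planted_score_auc",
    "align_region_labels",
]

# factor distribution of the planted region shift and pathway factor
_FACTOR_MEAN = 1.5
_FACTOR_SD = 0.5


@dataclass
class SyntheticConfig:
    n_patients: int = 40
    n_patches: int = 40
    feat_dim: int = 64
    n_regions: int = 4
    n_sources: int = 2
    genes_per_pathway: int = 8
    n_pathways: int = 6
    signal_region: int = 0
    signal_pathway: int = 0
    effect_size: float = 3.0
    censor_rate: float = 0.3
    seed: int = 0
    task: str = "classification"
    # generative nuisance parameters (population structure, not the signal)
    region_separation: float = 3.0
    feature_noise_sd: float = 1.0
    spatial_spread: float = 1.0
    omics_noise_sd: float = 0.5
    signal_patch_scale: float = 2.0

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients, "n_patches": self.n_patches,
            "feat_dim": self.feat_dim, "n_regions": self.n_regions,
            "n_sources": self.n_sources, "genes_per_pathway": self.genes_per_pathway,
            "n_pathways": self.n_pathways,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be a count >= 1 (got {v!r})")
        if not (0 <= self.censor_rate < 1):
            raise ConfigurationError(f"censor_rate must be in [0, 1) (got {self.censor_rate})")
        if not (0 <= self.signal_region < self.n_regions):
            raise ConfigurationError(f"signal_region {self.signal_region} >= n_regions")
        if not (0 <= self.signal_pathway < self.n_pathways):
            raise ConfigurationError(f"signal_pathway {self.signal_pathway} >= n_pathways")
        if self.task not in ("classification", "survival"):
            raise ConfigurationError(f"task must be classification|survival (got {self.task!r})")


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    patch_bags: list[PatchBag]
    omics: list[OmicsSource]
    gene_sets: GeneSetCollection
    labels: np.ndarray | None = None
    times: np.ndarray | None = None
    events: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [bag.slide_id for bag in self.patch_bags]


def _balanced_labels(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Every group occupied, sizes within one of each other, order shuffled."""
    base = np.tile(np.arange(n_groups), n_items // n_groups + 1)[:n_items]
    rng.shuffle(base)
    return base


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort; byte-identical for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    c = config
    mu0, sd0 = _FACTOR_MEAN, _FACTOR_SD
    # cohort-level structure (fixed given the seed)
    region_means = rng.standard_normal((c.n_regions, c.feat_dim))
    region_means *= c.region_separation / np.linalg.norm(region_means, axis=1, keepdims=True)
    region_means *= np.sqrt(c.feat_dim)  # separation per sqrt-dim, scale-free in d
    angles = 2 * np.pi * np.arange(c.n_regions) / c.n_regions
    spatial_centers = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    signal_dir = rng.standard_normal(c.feat_dim)
    signal_dir /= np.linalg.norm(signal_dir)
    loadings = rng.uniform(0.6, 1.0, size=(c.n_sources, c.n_pathways, c.genes_per_pathway))

    alpha = mu0 + sd0 * rng.standard_normal(c.n_patients)
    beta = mu0 + sd0 * rng.standard_normal(c.n_patients)
    sd_prod = np.sqrt(2 * mu0**2 * sd0**2 + sd0**4)
    score = (alpha * beta - mu0**2) / sd_prod

    # patch bags
    bags = []
    patch_truth = []
    for i in range(c.n_patients):
        labels_i = _balanced_labels(c.n_patches, c.n_regions, rng)
        coords = spatial_centers[labels_i] + c.spatial_spread * rng.standard_normal((c.n_patches, 2))
        feats = region_means[labels_i] + c.feature_noise_sd * rng.standard_normal(
            (c.n_patches, c.feat_dim))
        in_signal = labels_i == c.signal_region
        feats[in_signal] += c.signal_patch_scale * alpha[i] * signal_dir
        bags.append(PatchBag(features=feats, coords=coords, slide_id=f"S{i:04d}"))
        patch_truth.append(labels_i)

    # gene sets and omics sources
    pathways = [
        (f"PATHWAY{p}", [f"PATHWAY{p}_GENE{j}" for j in range(c.genes_per_pathway)])
        for p in range(c.n_pathways)
    ]
    gene_sets = GeneSetCollection(pathways=pathways)
    all_genes = [g for _, genes in pathways for g in genes]
    sample_ids = [bag.slide_id for bag in bags]
    factors = rng.standard_normal((c.n_patients, c.n_pathways))
    factors[:, c.signal_pathway] = beta
    sources = []
    for s in range(c.n_sources):
        mat = np.empty((c.n_patients, len(all_genes)))
        col = 0
        for p in range(c.n_pathways):
            block = (factors[:, p : p + 1] * loadings[s, p][None, :]
                     + c.omics_noise_sd * rng.standard_normal(
                         (c.n_patients, c.genes_per_pathway)))
            mat[:, col : col + c.genes_per_pathway] = block
            col += c.genes_per_pathway
        sources.append(OmicsSource(name=f"source{s}", matrix=mat,
                                   gene_names=list(all_genes),
                                   sample_ids=list(sample_ids)))

    truth = {
        "signal_region": c.signal_region, "signal_pathway": c.signal_pathway,
        "alpha": alpha, "beta": beta, "score": score,
        "patch_region_labels": patch_truth, "signal_direction": signal_dir,
    }
    cohort = SyntheticCohort(config=c, patch_bags=bags, omics=sources,
                             gene_sets=gene_sets, truth=truth)
    linpred = c.effect_size * score
    if c.task == "classification":
        cohort.labels = rng.binomial(1, _sigmoid(linpred)).astype(int)
    else:
        hazard = np.exp(linpred)
        t_event = rng.exponential(1.0 / hazard)
        if c.censor_rate > 0:
            def mean_censoring(lam_c):
                return float(np.mean(lam_c / (lam_c + hazard))) - c.censor_rate

            lam_c = brentq(mean_censoring, 1e-8, 1e8)
            t_cens = rng.exponential(1.0 / lam_c, size=c.n_patients)
        else:
            t_cens = np.full(c.n_patients, np.inf)
        cohort.times = np.minimum(t_event, t_cens)
        cohort.events = (t_event <= t_cens).astype(int)
    return cohort


def planted_score_auc(cohort: SyntheticCohort) -> float:
    """AUC of the true generative score for the planted labels (oracle)."""
    from sklearn.metrics import roc_auc_score

    if cohort.labels is None:
        raise ConfigurationError("oracle AUC is defined for classification cohorts")
    return float(roc_auc_score(cohort.labels, cohort.truth["score"]))


def align_region_labels(learned_patch_regions: np.ndarray,
                        planted_patch_regions: np.ndarray,
                        n_learned: int, n_planted: int) -> np.ndarray:
    """Map each learned region id to the planted region holding most of its
    patches (majority vote).  Returns an array of length ``n_learned``."""
    mapping = np.zeros(n_learned, dtype=int)
    for r in range(n_learned):
        members = planted_patch_regions[learned_patch_regions == r]
        if members.size:
            mapping[r] = np.bincount(members, minlength=n_planted).argmax()
    return mapping


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write the cohort in the exact on-disk formats the pipeline reads.

    Emits per-slide patch tables (``patches/<slide>.tsv``), one omics TSV per
    source, a GMT gene-set file, the outcome table, and a JSON manifest
    listing every file plus the generating seed.  Returns the manifest path.
    """
    from . import io as pio

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        patch_dir = directory / "patches"
        patch_dir.mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    patch_files = []
    for bag in cohort.patch_bags:
        path = patch_dir / f"{bag.slide_id}.tsv"
        pio.write_patch_table(bag, path)
        patch_files.append(str(path.relative_to(directory)))
    omics_files = {}
    for src in cohort.omics:
        path = directory / f"omics_{src.name}.tsv"
        pio.write_omics(src, path)
        omics_files[src.name] = path.name
    gmt_path = directory / "gene_sets.gmt"
    pio.write_gmt(cohort.gene_sets, gmt_path)
    outcome_path = directory / "outcomes.tsv"
    if cohort.labels is not None:
        pio.write_labels(cohort.sample_ids, cohort.labels, outcome_path)
    else:
        pio.write_survival(cohort.sample_ids, cohort.times, cohort.events, outcome_path)
    manifest = {
        "schema_version": 1,
        "seed": cohort.config.seed,
        "task": cohort.config.task,
        "n_patients": cohort.config.n_patients,
        "patch_files": patch_files,
        "omics_files": omics_files,
        "gene_sets": gmt_path.name,
        "outcomes": outcome_path.name,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
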