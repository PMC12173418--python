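"""Whole-slide-image encoding: kernel patch merging, K-means regions,
hypergraph construction and an attention hypergraph convolutional encoder.

A slide enters as a *patch bag*: one feature vector (from an upstream patch
feature extractor) plus the spatial center coordinates per patch.  The
pipeline is

1. pairwise similarity ``kappa = kappa_h * kappa_g`` with Gaussian kernels on
   feature and coordinate distances,
2. average-linkage agglomerative merging of patches with ``kappa >= delta_c``,
3. K-means partition of the merged patches into K candidate regions,
4. a hypergraph whose hyperedge for each merged patch collects all
   morphological neighbours (``kappa_h >= delta_h``), encoded by hypergraph
   convolution with per-hyperedge attention, and
5. mean pooling of node embeddings per region into a K x zdim matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans

from . import nn
from .errors import ConfigurationError, ValidationError

__all__ = [
    "PatchBag",
    "KernelParams",
    "MergedPatchSet",
    "HypergraphStructure",
    "RegionEmbeddings",
    "SlideStructure",
    "similarity_kernel",
    "kernel_matrices",
    "median_bandwidths",
    "merge_patches",
    "assign_regions",
    "build_hypergraph",
    "HypergraphEncoder",
    "encode_regions",
    "prepare_slide",
    "canonicalize_regions",
]


@dataclass
class PatchBag:
    """Per-slide set of patch feature vectors and spatial centers.

    Coordinates are patch centers in pixel units at the extraction
    magnification, 0-based, x = column / y = row.
    """

    features: np.ndarray  # (np, d)
    coords: np.ndarray  # (np, 2)
    slide_id: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.features.ndim != 2 or self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("features must be (np, d) and coords (np, 2)")
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValidationError("features and coords must be row-aligned")
        if self.features.shape[0] < 1:
            raise ValidationError("patch bag must contain at least one patch")
        if not (np.isfinite(self.features).all() and np.isfinite(self.coords).all()):
            raise ValidationError(f"non-finite values in patch bag {self.slide_id!r}")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]


@dataclass
class KernelParams:
    """Bandwidths and thresholds of the patch similarity kernels."""

    lambda_h: float = 1.0
    lambda_g: float = 1.0
    delta_c: float = 0.5
    delta_h: float = 0.5

    def __post_init__(self):
        if not (self.lambda_h > 0 and self.lambda_g > 0):
            raise ConfigurationError("lambda_h and lambda_g must be positive")
        for name in ("delta_c", "delta_h"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1]")


@dataclass
class MergedPatchSet:
    reps: np.ndarray  # (m, d) cluster mean features
    centers: np.ndarray  # (m, 2) cluster mean coordinates
    member_counts: np.ndarray  # (m,)
    labels: np.ndarray = field(default=None)  # (np,) original-patch cluster ids

    @property
    def n_merged(self) -> int:
        return self.reps.shape[0]


@dataclass
class HypergraphStructure:
    incidence: np.ndarray  # (m, m) binary, column k = hyperedge seeded at patch k
    region_assignment: np.ndarray  # (m,) K-means region id per merged patch


@dataclass
class RegionEmbeddings:
    values: np.ndarray  # (K, zdim)
    region_mask: np.ndarray  # (K,) True where the region is nonempty


def similarity_kernel(h_a, g_a, h_b, g_b, params: KernelParams) -> float:
    """kappa(a, b) = exp(-lambda_h ||h_a - h_b||^2) * exp(-lambda_g ||g_a - g_b||^2)."""
    h_a, h_b = np.asarray(h_a, float), np.asarray(h_b, float)
    g_a, g_b = np.asarray(g_a, float), np.asarray(g_b, float)
    for arr in (h_a, h_b, g_a, g_b):
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite input to similarity_kernel")
    dh = float(np.sum((h_a - h_b) ** 2))
    dg = float(np.sum((g_a - g_b) ** 2))
    return float(np.exp(-params.lambda_h * dh) * np.exp(-params.lambda_g * dg))


def kernel_matrices(features: np.ndarray, coords: np.ndarray,
                    params: KernelParams) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs morphological (K_h) and spatial (K_g) kernel matrices."""
    dh = cdist(features, features, "sqeuclidean")
    dg = cdist(coords, coords, "sqeuclidean")
    return np.exp(-params.lambda_h * dh), np.exp(-params.lambda_g * dg)


def median_bandwidths(bag: PatchBag) -> tuple[float, float]:
    """Median heuristic: 1 / median(squared pairwise distance), per slide."""
    def one(x):
        d = cdist(x, x, "sqeuclidean")
        off = d[np.triu_indices_from(d, k=1)]
        med = np.median(off) if off.size else 1.0
        return 1.0 / med if med > 0 else 1.0

    return one(bag.features), one(bag.coords)


def merge_patches(bag: PatchBag, params: KernelParams) -> MergedPatchSet:
    """Agglomerative merge of similar patches (average linkage on 1 - kappa).

    Clusters are cut at cophenetic distance 1 - delta_c, i.e. patches with
    combined similarity >= delta_c end up merged; each cluster is replaced by
    the arithmetic mean of its members' features and coordinates.  Cluster
    ids are renumbered by first occurrence so the result is deterministic in
    the input patch order.
    """
    n = bag.n_patches
    if n == 1:
        return MergedPatchSet(
            reps=bag.features.copy(), centers=bag.coords.copy(),
            member_counts=np.array([1]), labels=np.zeros(1, dtype=int),
        )
    kh, kg = kernel_matrices(bag.features, bag.coords, params)
    dist = 1.0 - kh * kg
    np.fill_diagonal(dist, 0.0)
    # sklearn merges strictly below the threshold; nudge up to include equality
    thr = np.nextafter(1.0 - params.delta_c, np.inf)
    agg = AgglomerativeClustering(
        n_clusters=None, metric="precomputed", linkage="average",
        distance_threshold=thr,
    )
    raw = agg.fit_predict(dist)
    # renumber clusters in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        labels[i] = order[lab]
    m = len(order)
    reps = np.vstack([bag.features[labels == k].mean(axis=0) for k in range(m)])
    centers = np.vstack([bag.coords[labels == k].mean(axis=0) for k in range(m)])
    counts = np.bincount(labels, minlength=m)
    return MergedPatchSet(reps=reps, centers=centers, member_counts=counts, labels=labels)


def assign_regions(merged: MergedPatchSet, k_regions: int, seed: int) -> np.ndarray:
    """K-means on standardized merged-patch features; labels in {0..K-1}."""
    m = merged.n_merged
    if m < k_regions:
        raise ValidationError(
            f"only {m} merged patches but K={k_regions} regions requested; lower K"
        )
    x = merged.reps
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    km = KMeans(n_clusters=k_regions, n_init=10, random_state=int(seed) % (2**31))
    return km.fit_predict(xs)


def build_hypergraph(merged: MergedPatchSet, params: KernelParams,
                     region_assignment: np.ndarray | None = None) -> HypergraphStructure:
    """One hyperedge per merged patch: its morphological neighbourhood.

    ``H[j, k] = 1`` iff ``kappa_h(p_k, p_j) >= delta_h``; the spatial kernel
    does not gate membership.  The diagonal is always 1 (self-similarity 1).
    """
    dh = cdist(merged.reps, merged.reps, "sqeuclidean")
    kh = np.exp(-params.lambda_h * dh)
    incidence = (kh >= params.delta_h).astype(np.float64)
    np.fill_diagonal(incidence, 1.0)
    if region_assignment is None:
        region_assignment = np.zeros(merged.n_merged, dtype=int)
    return HypergraphStructure(incidence=incidence,
                               region_assignment=np.asarray(region_assignment, int))


@dataclass
class SlideStructure:
    """Static, precomputed per-slide quantities fed to the encoder."""

    slide_id: str
    merged: MergedPatchSet
    hypergraph: HypergraphStructure
    pool: np.ndarray  # (K, m) row-normalized region pooling matrix
    region_mask: np.ndarray  # (K,) True where region nonempty


def _pool_matrix(assignment: np.ndarray, k_regions: int) -> tuple[np.ndarray, np.ndarray]:
    m = assignment.shape[0]
    pool = np.zeros((k_regions, m))
    mask = np.zeros(k_regions, dtype=bool)
    for r in range(k_regions):
        members = assignment == r
        if members.any():
            pool[r, members] = 1.0 / members.sum()
            mask[r] = True
    return pool, mask


def prepare_slide(bag: PatchBag, params: KernelParams, k_regions: int,
                  seed: int, auto_bandwidth: bool = False) -> SlideStructure:
    """Merge, assign regions, build the hypergraph and pooling matrix."""
    if auto_bandwidth:
        lh, lg = median_bandwidths(bag)
        params = KernelParams(lambda_h=lh, lambda_g=lg,
                              delta_c=params.delta_c, delta_h=params.delta_h)
    merged = merge_patches(bag, params)
    if merged.n_merged < k_regions:
        assignment = np.arange(merged.n_merged) % k_regions
    else:
        assignment = assign_regions(merged, k_regions, seed)
    hg = build_hypergraph(merged, params, assignment)
    pool, mask = _pool_matrix(assignment, k_regions)
    return SlideStructure(slide_id=bag.slide_id, merged=merged, hypergraph=hg,
                          pool=pool, region_mask=mask)


def canonicalize_regions(slides: list["SlideStructure"], k_regions: int,
                         seed: int) -> None:
    """Relabel each slide's K-means regions against K cohort-wide archetypes.

    Per-slide K-means labels are arbitrary, so row k of X^K would refer to a
    different kind of region in every patient.  Region centroids (mean merged
    features per region) from all slides are clustered into K global
    archetypes, and each slide's regions are matched one-to-one to archetypes
    (Hungarian assignment on centroid distance).  After this, region id k
    denotes the same tissue archetype in every patient, which both the
    mixture-of-experts readout and cohort-level interaction scores rely on.
    Operates in place on the slides' assignments, pooling matrices and masks.
    """
    from scipy.optimize import linear_sum_assignment

    centroids = []
    for slide in slides:
        a = slide.hypergraph.region_assignment
        reps = slide.merged.reps
        fallback = reps.mean(axis=0)
        for r in range(k_regions):
            members = reps[a == r]
            centroids.append(members.mean(axis=0) if len(members) else fallback)
    centroids = np.vstack(centroids)
    km = KMeans(n_clusters=k_regions, n_init=10, random_state=int(seed) % (2**31))
    km.fit(centroids)
    centers = km.cluster_centers_
    for si, slide in enumerate(slides):
        local = centroids[si * k_regions : (si + 1) * k_regions]
        cost = cdist(local, centers, "sqeuclidean")
        rows, cols = linear_sum_assignment(cost)
        mapping = np.empty(k_regions, dtype=int)
        mapping[rows] = cols  # local region r -> global archetype mapping[r]
        new_assignment = mapping[slide.hypergraph.region_assignment]
        slide.hypergraph.region_assignment = new_assignment
        pool, mask = _pool_matrix(new_assignment, k_regions)
        slide.pool = pool
        slide.region_mask = mask


class HypergraphConv(nn.Module):
    """One hypergraph convolution with per-hyperedge attention.

    Node scores ``s = X a`` are softmax-normalized within each hyperedge to
    give attention weights; the hyperedge embedding is the attention-weighted
    sum of its (degree-normalized) member nodes, and each node aggregates the
    hyperedges containing it with symmetric degree normalization before the
    linear map Theta:  X' = act(Dv^{-1/2} H (A^T Dv^{-1/2} X) Theta).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: bool = True, identity_init: bool = False):
        super().__init__()
        self.theta = nn.Linear(in_dim, out_dim, rng, bias=not identity_init)
        self.attn = nn.Linear(in_dim, 1, rng, bias=False)
        if identity_init:
            if in_dim != out_dim:
                raise ConfigurationError("identity_init requires in_dim == out_dim")
            self.theta.weight.data = np.eye(in_dim)
            self.attn.weight.data = np.zeros((in_dim, 1))
        self.activation = activation

    def forward(self, x: nn.Tensor, incidence: np.ndarray) -> nn.Tensor:
        h = incidence  # (m, e) with e == m
        dv = h.sum(axis=1)
        dv_inv_sqrt = 1.0 / np.sqrt(np.maximum(dv, 1.0))
        scores = (x @ self.attn.weight).reshape((x.shape[0],))  # (m,)
        # masked softmax of node scores within each hyperedge (columns of H)
        logits = scores.reshape((x.shape[0], 1)) * nn.Tensor(np.ones((1, h.shape[1])))
        logits = logits * nn.Tensor(h) + nn.Tensor((h - 1.0) * 1e9)
        attn = (logits - logits.logsumexp(axis=0, keepdims=True)).exp()  # (m, e)
        xn = x * nn.Tensor(dv_inv_sqrt.reshape(-1, 1))
        edge = attn.transpose((1, 0)) @ xn  # (e, in_dim)
        agg = nn.Tensor(h) @ edge  # (m, in_dim)
        agg = agg * nn.Tensor(dv_inv_sqrt.reshape(-1, 1))
        out = self.theta(agg)
        return out.relu() if self.activation else out


class HypergraphEncoder(nn.Module):
    """Stack of hypergraph convolutions plus region mean-pooling.

    The final layer has no activation so the region embedding space is
    unconstrained in sign.
    """

    def __init__(self, in_dim: int, zdim: int, rng: np.random.Generator,
                 n_layers: int = 2, hidden: int | None = None):
        super().__init__()
        hidden = hidden or zdim
        dims = [in_dim] + [hidden] * (n_layers - 1) + [zdim]
        self.layers = [
            HypergraphConv(dims[i], dims[i + 1], rng, activation=(i < n_layers - 1))
            for i in range(n_layers)
        ]
        self.zdim = zdim

    def node_embeddings(self, slide: SlideStructure) -> nn.Tensor:
        x = nn.Tensor(slide.merged.reps)
        for layer in self.layers:
            x = layer(x, slide.hypergraph.incidence)
        return x

    def forward(self, slide: SlideStructure) -> nn.Tensor:
        """Region embeddings X^K, (K, zdim); empty regions are zero rows."""
        x = self.node_embeddings(slide)
        return nn.Tensor(slide.pool) @ x


def encode_regions(merged: MergedPatchSet, hg: HypergraphStructure,
                   encoder: HypergraphEncoder, k_regions: int | None = None) -> RegionEmbeddings:
    """Run the encoder on a prepared merged set + hypergraph."""
    k = k_regions if k_regions is not None else int(hg.region_assignment.max()) + 1
    pool, mask = _pool_matrix(hg.region_assignment, k)
    slide = SlideStructure(slide_id="", merged=merged, hypergraph=hg,
                           pool=pool, region_mask=mask)
    was_training = encoder.training
    encoder.eval()
    values = encoder(slide).numpy()
    if was_training:
        encoder.train()
    return RegionEmbeddings(values=values, region_mask=mask)
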