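"""Whole-slide encoding: kernel merging, regions, hypergraph, embeddings.

Shows the intermediate objects for one slide: how many merged patches
survive the kernel threshold, the K-means region sizes, the hyperedge
structure, and the final K x zdim region embedding matrix.
"""

import numpy as np

import pathomix as px

cohort = px.generate_cohort(px.SyntheticConfig(n_patients=4, n_patches=40,
                                               feat_dim=16, n_regions=4, seed=2))
bag = cohort.patch_bags[0]
lam_h, lam_g = px.median_bandwidths(bag)
params = px.KernelParams(lambda_h=lam_h, lambda_g=lam_g, delta_c=0.5, delta_h=0.5)

merged = px.merge_patches(bag, params)
print(f"{bag.n_patches} patches -> {merged.n_merged} merged "
      f"(cluster sizes {merged.member_counts.tolist()})")

assignment = px.assign_regions(merged, k_regions=4, seed=0)
print(f"region sizes: {np.bincount(assignment, minlength=4).tolist()}")

hg = px.build_hypergraph(merged, params, assignment)
print(f"hyperedge sizes: {hg.incidence.sum(axis=0).astype(int).tolist()}")

encoder = px.HypergraphEncoder(in_dim=16, zdim=8, rng=np.random.default_rng(0))
emb = px.encode_regions(merged, hg, encoder, k_regions=4)
print(f"region embeddings X^K: shape {emb.values.shape}, "
      f"row norms {np.linalg.norm(emb.values, axis=1).round(2).tolist()}")
# Each row summarizes one tissue region; empty regions would be zero rows
# flagged in emb.region_mask.
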