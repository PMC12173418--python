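"""Bilinear fusion and the two-phase mixture of experts on toy embeddings.

Fuses random region and pathway embeddings into the K x P x zdim tensor and
reduces it with softmax gating, printing the weight distributions.
"""

import numpy as np

import pathomix as px
from pathomix import nn
from pathomix.fusion import GatingNetwork, MFBFusion

rng = np.random.default_rng(0)
K, P, z = 4, 6, 8
regions = rng.standard_normal((K, z))
omics = rng.standard_normal((P, z))

fusion = MFBFusion(zdim=z, rank=4, rng=rng)
tensor = px.bilinear_fuse(regions, omics, fusion)
print(f"fusion tensor Z: shape {tensor.values.shape}")

gate1 = GatingNetwork(z, 8, rng)
gate2 = GatingNetwork(z, 8, rng)
pathway_emb, w_regions = px.moe_phase1(nn.Tensor(tensor.values), gate1)
patient_emb, w_pathways = px.moe_phase2(pathway_emb, gate2)

print("region weights per pathway (columns sum to 1):")
print(np.round(w_regions.numpy(), 3))
print(f"pathway weights (sum {w_pathways.numpy().sum():.6f}):",
      np.round(w_pathways.numpy(), 3))
print(f"patient embedding z^moe: shape {patient_emb.numpy().shape}")
# With an untrained gate the weights are near-uniform; training concentrates
# them on informative (region, pathway) cells — that concentration IS the
# multimodal interaction score.
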