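"""Pathway-partitioned omics encoding with multi-source VAEs.

Splits two omics sources by a gene-set collection, pretrains one VAE per
pathway for a few epochs, and stacks the latents into the omics bag O^P.
"""

import numpy as np

import pathomix as px
from pathomix import nn
from pathomix.omics import vae_loss

cohort = px.generate_cohort(px.SyntheticConfig(n_patients=60, n_patches=4,
                                               feat_dim=4, n_pathways=3,
                                               genes_per_pathway=6, seed=3))
blocks = px.partition_by_pathway(cohort.omics, cohort.gene_sets)
print("blocks:", {f"{s}|{p}": b.matrix.shape for (s, p), b in blocks.items()})

rng = np.random.default_rng(0)
vaes = [px.PathwayVAE({"source0": 6, "source1": 6}, zdim=4, rng=rng,
                      hidden=(16, 8), batch_norm=False) for _ in range(3)]
opt = nn.Adam([p for v in vaes for p in v.parameters()], lr=5e-3)
for epoch in range(30):
    total = 0.0
    for (pname, _), vae in zip(cohort.gene_sets.pathways, vaes):
        blk = {s.name: nn.Tensor(blocks[(s.name, pname)].matrix)
               for s in cohort.omics}
        opt.zero_grad()
        mu, logvar = vae.encode(blk)
        z = vae.reparameterize(mu, logvar, rng)
        loss = vae_loss(vae.decode(z), blk, mu, logvar, beta=0.01)
        loss.backward()
        opt.step()
        total += loss.item()
    if epoch % 10 == 9:
        print(f"epoch {epoch + 1:2d}: summed VAE loss {total:.3f}")

bag = px.build_omics_bag(cohort.omics, cohort.gene_sets, vaes)
print(f"omics bag O^P: shape {bag.values.shape} (patients x pathways x zdim)")
# The falling loss shows each pathway VAE learning its shared latent factor;
# eval-mode encoding (used for the bag) is deterministic.
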