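"""Train the conditional multi-task VAE, encode the cohort, reduce to PCs.

The VAE minimizes 1*reconstruction + 1e-4*KLD + 1e-2*prediction loss with
the decoder and dementia-score head conditioned on standardized age and
sex. The latent means are then reduced by PCA (centering only), mirroring
the "10 PCs per model" design of a transfer-learning imaging GWAS.
"""

import numpy as np

import latentgwas as lg

panel = lg.simulate_genotypes(200, 100, seed=1)
effects = lg.EffectSpec(
    entries=[(0, 1, 0.5, "radius")], age_slope=0.3, sex_offset=0.2, noise_sd=0.1
)
volumes, covariates, dementia = lg.simulate_cohort(
    panel, effects, volume_shape=(32, 32, 32), n_rois=6, seed=2
)

config = lg.CVAEConfig(latent_dim=16, epochs=10, seed=0)
model = lg.train_cvae(volumes, covariates, dementia, config)
first, last = model.history[0], model.history[-1]
print(f"reconstruction MSE: {first['recon']:.4f} -> {last['recon']:.4f} "
      f"(standardized intensity units; must fall if the model learns)")
print(f"dementia prediction MSE: {first['pred']:.4f} -> {last['pred']:.4f}")

latents = lg.encode_volumes(model, volumes)
pcmodel, scores = lg.fit_pca(latents, k=10)
evr = pcmodel.explained_variance_ratio
print(f"latents: {latents.features.shape}; first 3 PC explained-variance "
      f"ratios: {evr[0]:.2f}, {evr[1]:.2f}, {evr[2]:.2f} "
      f"(10 PCs together: {evr.sum():.2f} of latent variance)")

# the slice-averaging hook: any 2D feature function, here a seeded random
# projection standing in for a pretrained 2D encoder
fn = lg.random_projection_features(32, seed=5)
lat2d = lg.slice_average_encode(volumes, fn)
print(f"slice-averaged 2D features: {lat2d.features.shape} "
      "(mean over axial slices of the per-slice feature vector)")
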