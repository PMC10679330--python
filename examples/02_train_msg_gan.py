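"""Train a small multi-scale-gradients GAN on one texture class.

The generator emits an image at every resolution from 4x4 up; the
discriminator scores the whole pyramid, so its gradients reach every
scale.  Training alternates one discriminator and one generator step per
batch under the two-time-scale rule (discriminator learning rate 4x the
generator's).
"""

from msgaug import (GanConfig, SyntheticDatasetConfig, generate_dataset,
                    sample_images, train_gan)

data = generate_dataset(SyntheticDatasetConfig(
    n_classes=3, per_class_count=80, resolution=16, seed=1))
config = GanConfig(latent_dim=64, depth=3, base_channels=32,
                   epochs=10, batch_size=8, seed=0)

gan, log = train_gan(data.restrict_to_class(2), config)
print(log.groupby("epoch")[["d_loss", "g_loss"]].mean().round(3))
print("\nA discriminator loss near 0 with a large generator loss means the "
      "discriminator is winning; values near 2/2 mean it cannot separate "
      "real from fake at all.")

samples = sample_images(gan, n=8, seed=5)
print(f"\nsampled {len(samples)} images at the top resolution "
      f"{samples.resolution}x{samples.resolution}, labelled class "
      f"{samples.labels[0]} ({samples.class_names[samples.labels[0]]})")
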