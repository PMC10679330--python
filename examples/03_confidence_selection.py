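"""Filter synthetic images by the confidence of a baseline classifier.

An image generated for class k is kept only if the classifier trained on
the original (non-augmented) data assigns it probability strictly above
alpha for class k.  This removes label-ambiguous synthetic images before
they can mislead the augmented training run.
"""

import numpy as np

from msgaug import (ClassifierConfig, SelectionConfig, SyntheticDatasetConfig,
                    generate_dataset, score_generated, select,
                    train_classifier)

data = generate_dataset(SyntheticDatasetConfig(
    n_classes=3, per_class_count=100, resolution=16, seed=4))
baseline, _ = train_classifier(data, None, ClassifierConfig(
    n_classes=3, epochs=20, batch_size=32, lr_initial=0.01, momentum=0.9,
    dropout_p=0.0, seed=0))

# stand-in "generated" images: fresh renders of class 1
candidates = generate_dataset(SyntheticDatasetConfig(
    n_classes=3, per_class_count=40, resolution=16, seed=99)).restrict_to_class(1)
probs = score_generated(candidates, baseline, intended_class=1)

for alpha in (0.0, 0.7, 0.85, 0.95):
    result = select(probs, SelectionConfig(alpha=alpha, intended_class=1))
    kept = probs[result.kept_mask]
    print(f"alpha={alpha:4.2f}: kept {result.n_kept:3d}/{len(probs)}"
          + (f", mean confidence of kept = {kept.mean():.3f}" if len(kept) else ""))
print("\nRaising alpha keeps fewer but more confidently classified images; "
      "alpha=0 disables selection entirely.")
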