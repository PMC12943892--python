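"""Train the graph backbone + band-attention classifier on synthetic features.

Generates a labeled feature set with class-dependent band-power patterns
(e.g. beta/gamma elevation for the high-arousal class), trains the full
model for a short schedule, and prints the loss curve and training accuracy.
"""

import numpy as np

from eegfuse import (LabeledFeatureSpec, TrainConfig, generate_labeled_features,
                     predict, train_model)

spec = LabeledFeatureSpec(seed=3, n_subjects=4, trials_per_subject=6,
                          n_classes=3)
features, labels, subjects = generate_labeled_features(spec)
print(f"dataset: {features.shape[0]} trials, shape {features.shape} "
      f"(trials, channels, frames, bands), classes {sorted(set(labels))}")

config = TrainConfig(epochs=15, batch_size=16, seed=0)
model, history = train_model(features, labels, config)

print("epoch loss:", " ".join(f"{l:.3f}" for l in history.loss))
acc = (predict(model, features) == labels).mean()
print(f"training accuracy after {config.epochs} epochs: {acc:.3f}")
print("(the model sees class-dependent band-mean shifts; accuracy near 1.0 "
      "means the attention head and backbone recover that structure)")
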