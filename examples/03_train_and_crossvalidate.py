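"""Train the RMSNN on a synthetic spine library and cross-validate.

Uses a reduced library (120 subimages per class) and fold budget so the
example runs in a couple of minutes; the full protocol (300 per class,
10-fold, scripts/acceptance.py) reports the headline accuracies.
"""

import numpy as np

from spinewave.rmsnn import TrainingConfig, cross_validate, init_model, predict, train
from spinewave.synthetic import CLASS_NAMES, make_spine_library

images, labels = make_spine_library(120, seed=42)
print(f"library: {images.shape[0]} subimages of {images.shape[1]}x{images.shape[2]} px")

model = init_model(n_maps=2, hidden=10, se_shape="disk:4", seed=42)
config = TrainingConfig(eta=0.0015, max_epochs=500, seed=42)
history = train(model, images, labels, config)
print(f"trained {history['epochs']} epochs, "
      f"final mean squared error {history['mean_squared_error'][-1]:.4f}, "
      f"median {history['median_squared_error'][-1]:.4f}")
acc = (predict(model, images) == labels).mean()
print(f"training-set accuracy: {100 * acc:.1f}%")

res = cross_validate(images, labels, TrainingConfig(max_epochs=500, seed=42), folds=3)
print("3-fold confusion matrix (%, rows = actual class):")
for name, row in zip(CLASS_NAMES, np.round(res["confusion_percent"], 1)):
    print(f"  {name:>9s} {row}")
# The diagonal is the per-class accuracy; off-diagonal cells show which
# morphologies get confused (typically stubby vs mushroom, whose head
# sizes overlap).
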