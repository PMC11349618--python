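"""The evaluation statistics on small worked inputs: Dice, ROC/PR with the
DeLong comparison, Pearson with Fisher CI, Bland-Altman, group comparison.
"""

import numpy as np
import pandas as pd

from atrophy2d.stats import (bland_altman, delong_test, dice, group_compare,
                             pearson_with_ci, percent_of, roc_pr_metrics)

pred = np.array([[1, 1, 0], [1, 0, 0]], dtype=bool)
truth = np.array([[1, 1, 1], [0, 0, 0]], dtype=bool)
print(f"Dice(pred, truth) = {dice(pred, truth):.4f}  "
      "(2TP / (2TP + FP + FN) with TP=2, FP=1, FN=1)")

scores = np.array([0.1, 0.4, 0.35, 0.8])
labels = np.array([0, 0, 1, 1])
print(f"AUC = {roc_pr_metrics(scores, labels)['auc']:.2f}  "
      "(3 of 4 positive-negative pairs are concordant)")

rng = np.random.default_rng(0)
y = np.repeat([0, 1], 100)
strong = y + rng.normal(0, 0.6, 200)
weak = y + rng.normal(0, 1.5, 200)
d = delong_test(strong, weak, y)
print(f"DeLong: AUC {d['auc_a']:.3f} vs {d['auc_b']:.3f}, p = {d['p']:.4f} "
      "(paired comparison of two classifiers on the same subjects)")

x = rng.normal(size=100)
noisy = x + rng.normal(0, 1, 100)
p = pearson_with_ci(x, noisy)
print(f"Pearson r = {p['r']:.3f} (95% CI {p['lo']:.3f}-{p['hi']:.3f})")

ba = bland_altman(x, noisy)
print(f"Bland-Altman: bias {ba['bias']:+.3f}, limits of agreement "
      f"[{ba['loa_low']:.2f}, {ba['loa_high']:.2f}]")

table = pd.DataFrame({"dx": np.repeat(["CU", "DAT"], 100),
                      "age": np.concatenate([rng.normal(68, 11, 100),
                                             rng.normal(70, 10, 100)])})
g = group_compare(table, "age", "dx")
print(f"group comparison of age: {g['test']}, p = {g['p']:.3f}")
print(f"worked demographics: 542 of 924 female = {percent_of(542, 924)}%")
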