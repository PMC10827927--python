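"""Compare two classifiers the way the evaluation protocol does.

Wilcoxon signed-rank on paired per-fold accuracies (training-side
comparison) and the DeLong test on paired per-item scores from a common
test set (test-side comparison of correlated AUCs).
"""

import numpy as np

from ertnet import delong_test, wilcoxon_signed_rank

rng = np.random.default_rng(0)

# paired 10-fold accuracies of two models; model A is ~2 points better
acc_a = 74.0 + rng.normal(0, 2.0, 10)
acc_b = 72.0 + rng.normal(0, 2.0, 10)
w, p = wilcoxon_signed_rank(acc_a, acc_b)
print(f"Wilcoxon signed-rank on 10 paired folds: W = {w:.1f}, p = {p:.4f}")
print("  (p < 0.05 -> the per-fold accuracy difference is systematic)")

# the same 300 test items scored by both models; A is less noisy
y = rng.integers(0, 2, 300)
scores_a = y + rng.normal(0, 0.8, 300)
scores_b = y + rng.normal(0, 1.4, 300)
auc1, auc2, z, p = delong_test(scores_a, scores_b, y)
print(f"DeLong: AUC_A = {auc1:.3f}, AUC_B = {auc2:.3f}, "
      f"z = {z:.2f}, p = {p:.4f}")
print("  (correlated-AUC test: both models scored the same items)")
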