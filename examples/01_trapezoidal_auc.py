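"""Trapezoidal AUC of a small two-sample score set.

Builds the classic 5-TP / 6-TN configuration in which the lowest-scoring
case sits below four controls, computes its AUC as an exact rational, and
prints the ROC staircase.
"""

from exactroc import ROCSample, roc_points, trapezoidal_auc

sample = ROCSample(tp_scores=[2.5, 8, 9, 10, 11],
                   tn_scores=[1, 2, 3, 4, 5, 6])
auc = trapezoidal_auc(sample)

print(f"n = {sample.n} cases, m = {sample.m} controls")
print(f"AUC = {auc.value} = {float(auc):.4f} (deficit {auc.deficit} of "
      f"{sample.n * sample.m} unit rectangles)")
print("ROC staircase (FPR, TPR):")
for fpr, tpr in roc_points(sample):
    print(f"  ({float(fpr):.3f}, {float(tpr):.3f})")

# The AUC equals the fraction of (case, control) pairs ranked correctly:
# 26 of 30 here, so the curve loses 4 rectangles of area 1/30 each.
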