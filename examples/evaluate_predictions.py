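"""Metric arithmetic on published benchmark confusion counts.

Feeds the confusion counts reported for nine lncRNA-identification tools
on a human test set through the standard metric formulas (lncRNA = the
positive class) and prints the derived percentages. The first row's
accuracy 94.53 / F1 95.38 are the headline numbers of the 1D-CNN
classifier this package reimplements.
"""

from xlnc1d.evaluation import ConfusionCounts, metrics_rounded

ROWS = [
    ("Xlnc1DCNN", 20895, 1204, 14087, 821),
    ("CPC2", 21023, 6457, 8834, 693),
    ("CNIT", 21307, 3580, 11711, 409),
    ("PLEK", 20704, 6665, 8626, 1012),
    ("CPAT", 20646, 2597, 12694, 1070),
    ("FEELnc", 20023, 1182, 14109, 1693),
    ("RNAsamba", 20998, 1795, 13496, 718),
    ("lncRNA_Mdeep", 20813, 1799, 13492, 903),
    ("LncADeep", 20232, 1113, 14178, 1484),
]

header = f"{'tool':<14}{'acc':>8}{'sens':>8}{'spec':>8}{'prec':>8}{'F1':>8}"
print(header)
for tool, tp, fp, tn, fn in ROWS:
    m = metrics_rounded(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    print(f"{tool:<14}{m['accuracy']:>8.2f}{m['sensitivity']:>8.2f}"
          f"{m['specificity']:>8.2f}{m['precision']:>8.2f}{m['f1']:>8.2f}")
# sensitivity = recall on lncRNAs, specificity = recall on mRNAs,
# precision = fraction of lncRNA calls that are correct,
# F1 = harmonic mean of precision and sensitivity.
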