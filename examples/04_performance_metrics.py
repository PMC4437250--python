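"""The five performance measures from a confusion table.

Builds a confusion table typical of an imbalanced cohort (125 cases vs
5 controls), derives Sn, Sp, Acc, balanced accuracy and MCC, and shows
why balanced accuracy and MCC matter: overall accuracy looks excellent
even when a fifth of the minority class is misclassified.
"""

from fscop import ConfusionTable, avc_from_rates, metrics

ct = ConfusionTable(tp=124, fn=1, tn=4, fp=1)
m = metrics(ct)

print(f"confusion: TP={ct.tp} FN={ct.fn} TN={ct.tn} FP={ct.fp}")
print(f"Sn  = {m.sn:.3f}   (TP / (TP+FN))")
print(f"Sp  = {m.sp:.3f}   (TN / (TN+FP))")
print(f"Acc = {m.acc:.3f}   ((TP+TN) / total)")
print(f"Avc = {m.avc:.3f}   ((Sn+Sp) / 2)")
print(f"MCC = {m.mcc:.3f}")
print()
print(f"avc_from_rates(0.992, 0.800) = {avc_from_rates(0.992, 0.800):.3f}")
# Acc 0.985 hides that 1 of the 5 negatives is misclassified; balanced
# accuracy (0.896) and MCC (0.792) expose the imbalance.
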