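"""Sectionwise metric arithmetic from error counts.

A screening model that reviews 1962 tissue sections (1119 with tumor, 843
without) and gets 30 false positives and 41 false negatives yields the
accuracy/sensitivity/specificity and recall-weighted F-beta reported below.
"""

from nestseg.evaluation import confusion_counts, f_beta, metrics_from_counts

truth = ["Tumor"] * 1119 + ["Normal"] * 843
predicted = (["Tumor"] * 1078 + ["Normal"] * 41      # tumor sections: 41 missed
             + ["Normal"] * 813 + ["Tumor"] * 30)    # normal sections: 30 false alarms

counts = confusion_counts(predicted, truth)
metrics = metrics_from_counts(counts)
fb = f_beta(metrics["precision"], metrics["sensitivity"], beta=1.5)

print(f"confusion: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
print(f"accuracy    {metrics['accuracy']:.3f}")
print(f"sensitivity {metrics['sensitivity']:.3f}   (fraction of tumor sections caught)")
print(f"specificity {metrics['specificity']:.3f}   (fraction of clean sections passed)")
print(f"F_1.5       {fb:.3f}   (recall-weighted precision/recall trade-off)")
print(f"error rate  {100 * (counts.fp + counts.fn) / counts.total:.1f}%")
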