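"""Detection-stage metrics from confusion counts.

Precision P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R),
here on the raw head+trunk counts of a horizontal high camera angle.
"""

from scqmon import ConfusionCounts, f1, percent, precision, recall

c = ConfusionCounts(TP=262, FP=51, FN=45)
print(f"precision = {precision(c):.4f} ({percent(precision(c))}%)")
print(f"recall    = {recall(c):.4f} ({percent(recall(c))}%)")
print(f"F1        = {f1(c):.4f} ({percent(f1(c))}%)")
# Whole-percent values use round-half-up, the convention of printed
# summary tables.
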