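"""Recompute per-class metrics from the published confusion matrices.

The original 261-patient study printed one aggregated 3x3 confusion
matrix per model (rows = predicted, columns = pathology).  Applying the
per-class metric reductions reproduces the printed performance cells:
the ALL-P model reaches accuracy 0.80 with ccRCC sensitivity/specificity
0.85/0.83, pRCC 0.60/0.91, cRCC 0.66/0.91.
"""

from rcc_radiomics import per_class_metrics, reference_confusion_matrices, round_half_up

for name, cm in reference_confusion_matrices().items():
    mt = per_class_metrics(cm)
    acc = round_half_up(mt["accuracy"].iloc[0])
    print(f"\n{name} (n={int(cm.to_numpy().sum())}, accuracy {acc:.2f})")
    for cls in ("ccRCC", "pRCC", "cRCC"):
        print(
            f"  {cls:6s} sens {round_half_up(mt.loc[cls, 'sensitivity']):.2f}"
            f"  spec {round_half_up(mt.loc[cls, 'specificity']):.2f}"
            f"  prec {round_half_up(mt.loc[cls, 'precision']):.2f}"
            f"  f1 {round_half_up(mt.loc[cls, 'f1']):.2f}"
        )
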