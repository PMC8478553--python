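"""Published reference results for the original 261-patient RCC cohort.

The patient images behind the original study are not deposited, but its
aggregated test-set confusion matrices are printed and serve as fixed
inputs here: applying :func:`rcc_radiomics.metrics.per_class_metrics` to
them reproduces the published per-class metric cells (e.g. ALL-P
accuracy 0.80, ccRCC sensitivity 0.85).

Orientation: rows = predicted class, columns = pathology class, order
(ccRCC, pRCC, cRCC).  Column totals give 207/25/29 = 261 subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASS_ORDER = ("ccRCC", "pRCC", "cRCC")

_MATRICES = {
    "NCP": [[129, 13, 9], [38, 6, 3], [40, 6, 17]],
    "CMP": [[165, 4, 3], [17, 10, 9], [25, 11, 17]],
    "NP": [[159, 11, 10], [34, 4, 6], [14, 10, 13]],
    "EP": [[146, 9, 8], [31, 8, 10], [30, 8, 11]],
    "ALL-P": [[175, 5, 4], [16, 15, 6], [16, 5, 19]],
    "Traditional": [[201, 18, 20], [3, 3, 3], [3, 4, 6]],
}


def reference_confusion_matrices() -> dict[str, pd.DataFrame]:
    """The published aggregated confusion matrices, one per model."""
    return {
        name: pd.DataFrame(
            np.asarray(m, dtype=int), index=list(CLASS_ORDER), columns=list(CLASS_ORDER)
        )
        for name, m in _MATRICES.items()
    }
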