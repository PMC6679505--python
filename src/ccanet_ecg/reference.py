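"""Bundled reference confusion matrices.

Aggregated k-fold confusion matrices reported for the MIT-BIH (15-class,
10-fold, 3350 beats) and INCART (7-class, 5-fold, 1720 beats) evaluation
protocols, shipped as plain CSV so the metric engine can be validated against
known counts and so ``ccanet metrics`` has ready-made inputs.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from ccanet_ecg.evaluate import ConfusionMatrix

#: benchmark key -> bundled CSV file
BENCHMARKS = {
    "mitdb-dl-ii-v5": "mitdb_dl_ii_v5.csv",
    "incart-dl-ii-v1": "incart_dl_ii_v1.csv",
    "incart-dl-v1-v5": "incart_dl_v1_v5.csv",
    "incart-dl-ii-v5": "incart_dl_ii_v5.csv",
    "incart-tl-ii-v1-v5": "incart_tl_ii_v1_v5.csv",
}


def load_reference_confusion(key: str) -> ConfusionMatrix:
    """Load one bundled benchmark confusion matrix by key (see BENCHMARKS)."""
    if key not in BENCHMARKS:
        raise KeyError(
            f"unknown benchmark {key!r}; available: {sorted(BENCHMARKS)}")
    path = resources.files("ccanet_ecg").joinpath("data", BENCHMARKS[key])
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    labels = rows[0][1:]
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]],
                      dtype=np.int64)
    return ConfusionMatrix(counts, labels)
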