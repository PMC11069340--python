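"""Two-condition expression screen: CPM normalization and log2 fold change.

Screening criterion (1) — induction by the substrate — is a
threshold on the log2 fold change of treated versus control mean CPM,
not a full differential-expression model: the screen needs a ranking,
and dispersion modelling is deliberately out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CountMatrix
from .errors import FormatError

DEFAULT_PSEUDOCOUNT = 1.0  # CPM units
DEFAULT_LOG2FC_THRESHOLD = 1.0


def cpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column rescaled to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise FormatError(f"zero total count in sample(s) {list(zero.index)}")
    return cm.counts * (1e6 / totals)


def log2_fold_change(
    cpm: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene log2((mean treated CPM + p) / (mean control CPM + p)).

    Means are arithmetic means of CPM over replicates.  Returns a
    fold-change table with columns ``mean_cpm_control``,
    ``mean_cpm_treated``, ``log2fc``, ``upregulated``.
    """
    if pseudocount <= 0:
        raise FormatError("pseudocount must be positive")
    samples = {
        cond: [s for s in cpm.columns if design.loc[s, "condition"] == cond]
        for cond in ("treated", "control")
    }
    for cond, ss in samples.items():
        if not ss:
            raise FormatError(f"no sample with condition {cond!r}")
    mean_t = cpm[samples["treated"]].mean(axis=1)
    mean_c = cpm[samples["control"]].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    return pd.DataFrame(
        {
            "mean_cpm_control": mean_c,
            "mean_cpm_treated": mean_t,
            "log2fc": log2fc,
            "upregulated": log2fc >= log2fc_threshold,
        }
    )


def call_upregulated(table: pd.DataFrame, log2fc_threshold: float) -> set[str]:
    """Gene ids whose log2 fold change meets the threshold."""
    if not np.isfinite(log2fc_threshold):
        raise FormatError("log2fc threshold must be finite")
    return set(table.index[table["log2fc"] >= log2fc_threshold])


def fold_change_table(
    cm: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Convenience: CPM-normalize and compute the fold-change table."""
    return log2_fold_change(
        cpm_normalize(cm), cm.design, pseudocount=pseudocount, log2fc_threshold=log2fc_threshold
    )
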