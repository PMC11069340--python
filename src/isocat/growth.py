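"""Dose-dependent growth inhibition from plate-reader curves.

Each replicate curve is reduced to its trapezoidal AUC (OD600 x h).
The inhibition index of a treated replicate is 1 - AUC / mean(control
AUCs of the same strain), so 0 means control-like growth and 1 means no
growth; the raw AUC ratio is available as an alternative convention.
Dose-versus-control comparisons use Welch's t-test with
Benjamini-Hochberg FDR adjustment across all comparisons in a run.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError

INDEX_VARIANTS = ("one_minus_ratio", "ratio")


def auc_trapezoid(times: Sequence[float], od: Sequence[float]) -> float:
    """Composite trapezoidal AUC on the given grid; no extrapolation."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape:
        raise FormatError("times and od must have the same length")
    if t.size < 2:
        raise FormatError("need at least two time points for an AUC")
    if not (np.diff(t) > 0).all():
        raise FormatError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def inhibition_index(
    auc_treated: float, control_aucs: Sequence[float], variant: str = "one_minus_ratio"
) -> float:
    """Growth inhibition relative to the same strain's 0-dose controls."""
    if variant not in INDEX_VARIANTS:
        raise FormatError(f"unknown index variant {variant!r}")
    ref = float(np.mean(control_aucs))
    if ref <= 0:
        raise FormatError("mean control AUC must be positive")
    ratio = auc_treated / ref
    return ratio if variant == "ratio" else 1.0 - ratio


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise FormatError("need at least two values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate: no within-group variability at all
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        warnings.warn("both groups have zero variance with different means; p=0 sentinel")
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise FormatError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def growth_results(
    growth: pd.DataFrame, index_variant: str = "one_minus_ratio"
) -> pd.DataFrame:
    """Per-replicate AUC and inhibition index from a long growth table.

    Expects columns strain_id, dose_uM, replicate, time_h, od600; every
    strain must include dose 0 (the normalizer).
    """
    rows = []
    for (strain, dose, rep), grp in growth.groupby(
        ["strain_id", "dose_uM", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        rows.append(
            {
                "strain_id": strain,
                "dose_uM": dose,
                "replicate": rep,
                "auc": auc_trapezoid(grp["time_h"].to_numpy(), grp["od600"].to_numpy()),
            }
        )
    res = pd.DataFrame(rows)
    indices = []
    for strain, grp in res.groupby("strain_id", sort=False):
        controls = grp.loc[grp["dose_uM"] == 0, "auc"]
        if controls.empty:
            raise FormatError(f"strain {strain}: no 0-dose control curves")
        for auc in grp["auc"]:
            indices.append(inhibition_index(auc, controls, variant=index_variant))
    res["inhibition_index"] = indices
    return res


def growth_tests(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Welch dose-vs-control tests per strain, BH-adjusted across the run."""
    rows = []
    for strain, grp in results.groupby("strain_id", sort=True):
        control = grp.loc[grp["dose_uM"] == 0, "inhibition_index"].to_numpy()
        for dose in sorted(grp["dose_uM"].unique()):
            if dose == 0:
                continue
            treated = grp.loc[grp["dose_uM"] == dose, "inhibition_index"].to_numpy()
            t, df, p = welch_t_test(treated, control)
            rows.append(
                {"strain_id": strain, "dose_uM": dose, "t": t, "df": df, "p": p}
            )
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["p_adj"] = bh_adjust(tests["p"])
        tests["significant"] = tests["p_adj"] < alpha
    return tests


def analyze_growth(
    growth: pd.DataFrame, index_variant: str = "one_minus_ratio", alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full growth-assay analysis: (per-replicate results, pairwise tests)."""
    results = growth_results(growth, index_variant=index_variant)
    return results, growth_tests(results, alpha=alpha)
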