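"""Fold-change plus Student's t-test differential-expression filtering.

The screen used throughout the pipeline is the classic two-gate microarray
filter: a feature is differentially expressed when its linear-scale fold
change exceeds a class-specific threshold (default 2.0 for miRNA, 1.5 for
lncRNA/mRNA) AND its two-sided pooled-variance Student's t-test p-value is
below 0.05.  Fold change is reported as the >= 1 ratio of group means with
an up/down direction label, so large fold changes are printed for both
directions.  Raw p-values are the gate; a Benjamini-Hochberg FDR column is
emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

DEFAULT_FC_THRESHOLDS = {"miRNA": 2.0, "lncRNA": 1.5, "mRNA": 1.5}
DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression statistics and filter verdict."""

    feature_id: str
    feature_class: str
    mean_case: float
    mean_control: float
    fold_change: float
    regulation: str  # up | down | flat
    p_value: float
    passes: bool
    q_value: Optional[float] = None  # BH-FDR, informational only


def student_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    Degenerate inputs follow a documented convention: zero pooled variance
    with equal means gives p = 1 (no evidence), with unequal means p = 0
    (infinite t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t-test needs >= 2 observations per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def fold_change(mean_case: float, mean_control: float) -> tuple[float, str]:
    """(>=1 fold-change ratio, direction label) from linear-scale means.

    A zero mean against a positive mean yields ``inf`` with the correct
    direction; both-zero is undefined and raises.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValidationError("group means must be >= 0 on the linear scale")
    if mean_case == 0 and mean_control == 0:
        raise ValidationError("fold change undefined: both group means are zero")
    if mean_case == mean_control:
        return 1.0, "flat"
    regulation = "up" if mean_case > mean_control else "down"
    hi, lo = max(mean_case, mean_control), min(mean_case, mean_control)
    return (math.inf if lo == 0 else hi / lo), regulation


def select_de(
    matrix: ExpressionMatrix,
    fc_threshold: Optional[float] = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    equal_var: bool = True,
) -> list[DERecord]:
    """Apply the fold-change + t-test filter to every feature.

    Intensities are converted to the linear scale first when the matrix is
    log2.  ``fc_threshold`` defaults per feature class (2.0 for miRNA,
    1.5 for lncRNA/mRNA).
    """
    if fc_threshold is None:
        fc_threshold = DEFAULT_FC_THRESHOLDS[matrix.feature_class]
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValidationError("thresholds must be > 0")
    linear = matrix.to_linear()
    case = linear.values[linear.group_samples("case")].to_numpy()
    ctrl = linear.values[linear.group_samples("control")].to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValidationError("fewer than 2 samples in a group")

    records: list[DERecord] = []
    pvals = np.empty(linear.n_features)
    for i, fid in enumerate(linear.feature_ids):
        pvals[i] = student_t_test(case[i], ctrl[i], equal_var=equal_var)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for i, fid in enumerate(linear.feature_ids):
        mc, mn = float(case[i].mean()), float(ctrl[i].mean())
        fc, reg = fold_change(mc, mn)
        records.append(
            DERecord(
                feature_id=fid,
                feature_class=linear.feature_class,
                mean_case=mc,
                mean_control=mn,
                fold_change=fc,
                regulation=reg,
                p_value=float(pvals[i]),
                passes=bool(fc > fc_threshold and pvals[i] < p_threshold),
                q_value=float(qvals[i]),
            )
        )
    return records


def passing_ids(records: Sequence[DERecord]) -> list[str]:
    return [r.feature_id for r in records if r.passes]


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """Report table shaped like a classic microarray DE listing."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "feature_class": [r.feature_class for r in records],
            "p_value": [r.p_value for r in records],
            "fold_change": [r.fold_change for r in records],
            "regulation": [r.regulation for r in records],
            "q_value": [r.q_value for r in records],
            "passes": [r.passes for r in records],
        }
    )
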