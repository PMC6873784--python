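"""Co-expression competing triplet construction.

The ceRNA hypothesis is operationalized in three steps:

1. among differentially expressed features, keep lncRNA-mRNA pairs whose
   expression profiles satisfy Pearson r > ``pcc_threshold`` (default 0.99)
   with p < ``p_threshold`` (default 0.05);
2. for each retained pair, every miRNA that is a predicted binder of BOTH
   members and is negatively co-expressed with both (r < ``neg_threshold``,
   default 0, with p < ``p_threshold``) completes one
   lncRNA-miRNA-mRNA co-expression competing triplet;
3. each retained pair also gets a shared-miRNA hypergeometric score (the
   "ceRNA score" stand-in; the upper-tail probability that two target sets
   of the observed sizes share at least the observed number of miRNAs).

Correlations are computed across all samples, case and control pooled, on
the log2 scale by default.  Constant features cannot be correlated and are
dropped with a warning before testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    InteractionPair,
    ValidationError,
    targets_by_mirna,
)

logger = logging.getLogger(__name__)

DEFAULT_PCC_THRESHOLD = 0.99
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_NEG_THRESHOLD = 0.0


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient with its two-sided p-value and sample count."""

    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CeRNATriplet:
    """One lncRNA-miRNA-mRNA triplet with its full correlation evidence."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_mrna: CorrelationResult
    mir_lnc: CorrelationResult
    mir_mrna: CorrelationResult
    cerna_score: Optional[float] = None  # shared-miRNA hypergeometric p

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform t = r*sqrt((n-2)/(1-r^2)), df=n-2."""
    r = np.asarray(r, dtype=float)
    p = np.zeros_like(r)
    sat = np.isclose(np.abs(r), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p[~sat] = 2.0 * stats.t.sf(np.abs(t[~sat]), df=n - 2)
    return p


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Textbook Pearson correlation with the t-transform p-value.

    Perfect correlation (|r| = 1) yields p = 0 by convention; a constant
    vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"Pearson correlation needs n >= 3, got n = {n}")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0.0:
            raise ValidationError(f"vector {name} is constant: r undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    p = float(_corr_p(np.array([r]), n)[0])
    return CorrelationResult(r=r, p_value=p, n=n)


def _log2_values(matrix: ExpressionMatrix, use_log2: bool) -> pd.DataFrame:
    m = matrix.to_log2() if use_log2 else matrix.to_linear()
    return m.values


def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
    arr = df.to_numpy()
    const = np.ptp(arr, axis=1) == 0.0
    if const.any():
        dropped = list(df.index[const])
        logger.warning(
            "dropping %d constant %s feature(s) before correlation: %s",
            len(dropped), what, dropped,
        )
        df = df.loc[~const]
    return df


def _check_aligned(a: ExpressionMatrix, b: ExpressionMatrix) -> None:
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValidationError(
            "matrices are not sample-aligned: "
            f"{a.sample_ids} vs {b.sample_ids}"
        )


def _cross_corr(x: pd.DataFrame, y: pd.DataFrame) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between two aligned frames."""
    xa = x.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    xa = (xa - xa.mean(axis=1, keepdims=True)) / xa.std(axis=1, keepdims=True)
    ya = (ya - ya.mean(axis=1, keepdims=True)) / ya.std(axis=1, keepdims=True)
    r = xa @ ya.T / xa.shape[1]
    return np.clip(r, -1.0, 1.0)


def select_lnc_mrna_pairs(
    lnc_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    de_lnc: Optional[Iterable[str]] = None,
    de_mrna: Optional[Iterable[str]] = None,
    pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_log2: bool = True,
) -> list[tuple[str, str, CorrelationResult]]:
    """All DE-lncRNA x DE-mRNA pairs with r > pcc_threshold and p < p_threshold.

    Output is sorted by descending r, ties broken lexicographically by ids.
    When ``de_lnc``/``de_mrna`` are omitted, every feature is tested.
    """
    _check_aligned(lnc_matrix, mrna_matrix)
    lv = _log2_values(lnc_matrix, use_log2)
    mv = _log2_values(mrna_matrix, use_log2)
    if de_lnc is not None:
        lv = lv.loc[[f for f in de_lnc if f in lv.index]]
    if de_mrna is not None:
        mv = mv.loc[[f for f in de_mrna if f in mv.index]]
    lv = _drop_constant(lv, "lncRNA")
    mv = _drop_constant(mv, "mRNA")
    if lv.empty or mv.empty:
        return []
    n = lv.shape[1]
    r = _cross_corr(lv, mv)
    p = _corr_p(r, n)
    keep = (r > pcc_threshold) & (p < p_threshold)
    out = []
    for i, j in zip(*np.where(keep)):
        out.append(
            (
                str(lv.index[i]),
                str(mv.index[j]),
                CorrelationResult(float(r[i, j]), float(p[i, j]), n),
            )
        )
    out.sort(key=lambda t: (-t[2].r, t[0], t[1]))
    return out


def build_triplets(
    pairs: Sequence[tuple[str, str, CorrelationResult]],
    interactions: Iterable[InteractionPair],
    mirna_matrix: ExpressionMatrix,
    lnc_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    neg_threshold: float = DEFAULT_NEG_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_log2: bool = True,
    de_mirna: Optional[Iterable[str]] = None,
    attach_scores: bool = True,
) -> list[CeRNATriplet]:
    """Complete retained lncRNA-mRNA pairs into co-expression competing triplets.

    A miRNA joins a pair only if (a) the interaction set predicts it to bind
    both members, and (b) it is negatively co-expressed with both
    (r < neg_threshold with p < p_threshold).  miRNA ids in the interaction
    set but absent from the expression matrix are skipped with a warning.
    ``de_mirna``, when given, restricts candidate miRNAs to that set.
    """
    _check_aligned(lnc_matrix, mrna_matrix)
    _check_aligned(lnc_matrix, mirna_matrix)
    interactions = list(interactions)
    lnc_targets = targets_by_mirna(interactions, "lncRNA")
    mrna_targets = targets_by_mirna(interactions, "mRNA")

    mirna_ids = sorted(set(lnc_targets) | set(mrna_targets))
    missing = [m for m in mirna_ids if m not in mirna_matrix.values.index]
    if missing:
        logger.warning(
            "skipping %d miRNA id(s) in interactions but absent from the "
            "miRNA matrix: %s", len(missing), missing,
        )
    allowed = set(mirna_ids) - set(missing)
    if de_mirna is not None:
        allowed &= set(de_mirna)

    mirv = _drop_constant(
        _log2_values(mirna_matrix, use_log2).loc[sorted(allowed)], "miRNA"
    )
    lv = _log2_values(lnc_matrix, use_log2)
    mv = _log2_values(mrna_matrix, use_log2)
    if mirv.empty or not pairs:
        return []
    n = mirv.shape[1]

    lnc_ids = sorted({p[0] for p in pairs} & set(lv.index))
    mrna_ids = sorted({p[1] for p in pairs} & set(mv.index))
    lv = _drop_constant(lv.loc[lnc_ids], "lncRNA")
    mv = _drop_constant(mv.loc[mrna_ids], "mRNA")
    if lv.empty or mv.empty:
        return []
    r_ml = _cross_corr(mirv, lv)
    r_mm = _cross_corr(mirv, mv)
    p_ml = _corr_p(r_ml, n)
    p_mm = _corr_p(r_mm, n)
    mir_index = {m: i for i, m in enumerate(mirv.index)}
    lnc_index = {f: i for i, f in enumerate(lv.index)}
    mrna_index = {f: i for i, f in enumerate(mv.index)}

    universe = int(mirna_matrix.n_features)
    triplets: list[CeRNATriplet] = []
    for lnc, mrna, corr in pairs:
        if lnc not in lnc_index or mrna not in mrna_index:
            continue
        li, gi = lnc_index[lnc], mrna_index[mrna]
        shared = sorted(
            m
            for m in allowed
            if lnc in lnc_targets.get(m, ()) and mrna in mrna_targets.get(m, ())
        )
        score = None
        if attach_scores:
            lnc_binders = {m for m in allowed if lnc in lnc_targets.get(m, ())}
            mrna_binders = {m for m in allowed if mrna in mrna_targets.get(m, ())}
            _, score = score_cerna(lnc_binders, mrna_binders, universe)
        for m in shared:
            mi = mir_index[m]
            ok_l = r_ml[mi, li] < neg_threshold and p_ml[mi, li] < p_threshold
            ok_m = r_mm[mi, gi] < neg_threshold and p_mm[mi, gi] < p_threshold
            if ok_l and ok_m:
                triplets.append(
                    CeRNATriplet(
                        lncrna_id=lnc,
                        mirna_id=m,
                        mrna_id=mrna,
                        lnc_mrna=corr,
                        mir_lnc=CorrelationResult(
                            float(r_ml[mi, li]), float(p_ml[mi, li]), n
                        ),
                        mir_mrna=CorrelationResult(
                            float(r_mm[mi, gi]), float(p_mm[mi, gi]), n
                        ),
                        cerna_score=score,
                    )
                )
    triplets.sort(key=lambda t: t.ids)
    return triplets


def score_cerna(
    lnc_targets: set[str], mrna_targets: set[str], universe: int
) -> tuple[int, float]:
    """Shared-miRNA count and hypergeometric upper-tail probability.

    The probability that two random miRNA sets of the given sizes drawn
    from ``universe`` miRNAs share at least the observed number of members.
    """
    if len(lnc_targets) > universe or len(mrna_targets) > universe:
        raise ValidationError("target set size exceeds the miRNA universe")
    shared = len(lnc_targets & mrna_targets)
    p = float(
        stats.hypergeom.sf(
            shared - 1, universe, len(lnc_targets), len(mrna_targets)
        )
    )
    return shared, min(1.0, max(0.0, p))


def triplet_table(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    """Tab-delimited-ready table with all six correlation statistics."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "lnc_mrna_r": t.lnc_mrna.r,
                "lnc_mrna_p": t.lnc_mrna.p_value,
                "mir_lnc_r": t.mir_lnc.r,
                "mir_lnc_p": t.mir_lnc.p_value,
                "mir_mrna_r": t.mir_mrna.r,
                "mir_mrna_p": t.mir_mrna.p_value,
                "cerna_score_hypergeom_p": t.cerna_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mirna_id", "mrna_id",
            "lnc_mrna_r", "lnc_mrna_p", "mir_lnc_r", "mir_lnc_p",
            "mir_mrna_r", "mir_mrna_p", "cerna_score_hypergeom_p",
        ],
    )
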