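"""Bidirectional hierarchical clustering and hypergeometric enrichment.

``bicluster`` runs agglomerative clustering independently on the rows and
columns of an expression (or correlation) matrix — the classic two-way
heat-map module view of lncRNA-mRNA co-expression.  The default distance
is 1 - Pearson with average linkage, which groups features by profile
shape rather than absolute intensity; Euclidean/complete (the usual
heatmap defaults) are available by flag.

``enrich`` is a generic gene-set over-representation engine: for each
user-supplied annotation set it computes the hypergeometric upper-tail
probability of the observed overlap with a query set, Benjamini-Hochberg
corrected across sets.  Database content (GO/KEGG) is out of scope; sets
arrive as GMT-style files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

logger = logging.getLogger(__name__)

_METRICS = {"correlation", "euclidean"}
_LINKAGES = {"average", "complete", "single", "ward"}


@dataclass
class ModuleAssignment:
    """Module labels for one clustering axis."""

    axis: str  # feature_rows | feature_cols
    labels: dict[str, int]  # id -> module index, contiguous from 1
    n_modules: int
    linkage: str
    distance: str
    cut: float  # k (maxclust) or h (height), per cut_mode
    cut_mode: str  # "k" | "h"

    def members(self, module: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == module)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation statistics for one annotation set."""

    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


def _cluster_axis(
    df: pd.DataFrame,
    axis: str,
    linkage: str,
    distance: str,
    k: Optional[int],
    h: Optional[float],
) -> ModuleAssignment:
    ids = list(df.index)
    if len(ids) < 2:
        raise ValidationError(f"{axis}: need >= 2 items to cluster")
    if k is not None and k > len(ids):
        raise ValidationError(
            f"{axis}: k = {k} exceeds the number of leaves ({len(ids)})"
        )
    d = pdist(df.to_numpy(dtype=float), metric=distance)
    # zero-distance duplicates merge first; tiny negatives from float error
    d = np.clip(d, 0.0, None)
    Z = hierarchy.linkage(d, method=linkage)
    if k is not None:
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cut, cut_mode = float(k), "k"
    else:
        raw = hierarchy.fcluster(Z, t=h, criterion="distance")
        cut, cut_mode = float(h), "h"
    # relabel to first-appearance order so indices are contiguous from 1
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for fid, lab in zip(ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[fid] = remap[lab]
    return ModuleAssignment(
        axis=axis,
        labels=labels,
        n_modules=len(remap),
        linkage=linkage,
        distance=distance,
        cut=cut,
        cut_mode=cut_mode,
    )


def bicluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    distance: str = "correlation",
    k: Optional[int] = 2,
    h: Optional[float] = None,
) -> tuple[ModuleAssignment, ModuleAssignment]:
    """Two-way agglomerative clustering of a feature x sample matrix.

    Rows and columns are clustered independently; constant rows (undefined
    correlation distance) are dropped with a warning.  Exactly one of
    ``k`` (module count) or ``h`` (cut height) applies; ``h`` wins when
    both are given.
    """
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {sorted(_LINKAGES)}")
    if distance not in _METRICS:
        raise ValidationError(f"distance must be one of {sorted(_METRICS)}")
    if h is not None:
        k = None
    if k is None and h is None:
        raise ValidationError("one of k or h must be given")
    df = matrix.astype(float)
    if distance == "correlation":
        const_rows = df.std(axis=1).to_numpy() == 0.0
        if const_rows.any():
            logger.warning(
                "dropping %d constant row(s) before clustering: %s",
                int(const_rows.sum()), list(df.index[const_rows]),
            )
            df = df.loc[~const_rows]
        const_cols = df.std(axis=0).to_numpy() == 0.0
        if const_cols.any():
            logger.warning(
                "dropping %d constant column(s) before clustering: %s",
                int(const_cols.sum()), list(df.columns[const_cols]),
            )
            df = df.loc[:, ~const_cols]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValidationError(
            "matrix is degenerate after dropping constant rows/columns: "
            f"shape {df.shape}, need >= 2 x 2"
        )
    rows = _cluster_axis(df, "feature_rows", linkage, distance, k, h)
    cols = _cluster_axis(df.T, "feature_cols", linkage, distance, k, h)
    return rows, cols


def enrich(
    query: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    Each set is intersected with the universe before testing; p-values are
    BH-corrected across all sets tested; output is sorted by ascending p
    (ties by set id).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query)
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query ids outside the universe: {sorted(outside)[:5]}"
        )
    names = sorted(annotation_sets)
    if not names:
        return []
    raw: list[tuple[str, int, int]] = []
    for name in names:
        members = set(annotation_sets[name]) & universe
        raw.append((name, len(members), len(members & query)))
    M, n_query = len(universe), len(query)
    pvals = np.array(
        [
            float(stats.hypergeom.sf(overlap - 1, M, set_size, n_query))
            for (_, set_size, overlap) in raw
        ]
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_id=name,
            overlap=overlap,
            set_size=set_size,
            query_size=n_query,
            universe_size=M,
            p_value=float(p),
            q_value=float(q),
        )
        for (name, set_size, overlap), p, q in zip(raw, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def plot_heatmap(
    matrix: pd.DataFrame,
    rows: Optional[ModuleAssignment] = None,
    cols: Optional[ModuleAssignment] = None,
    path: Optional[str] = None,
):
    """Basic module heat map (features reordered by module label)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix
    if rows is not None:
        order = sorted(
            (i for i in df.index if i in rows.labels),
            key=lambda i: (rows.labels[i], i),
        )
        df = df.loc[order]
    if cols is not None:
        order = sorted(
            (c for c in df.columns if c in cols.labels),
            key=lambda c: (cols.labels[c], c),
        )
        df = df[order]
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(df.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(df.shape[1]), labels=df.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(df.shape[0]), labels=df.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
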