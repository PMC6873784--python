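"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` is a features x samples intensity table carrying
its feature class (lncRNA, miRNA or mRNA), per-sample case/control labels and
a flag recording whether values are on the log2 scale.  An
:class:`InteractionPair` is one candidate miRNA->target relation, either
imported from an external predictor table or produced by the built-in
seed-match scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("lncRNA", "miRNA", "mRNA")
TARGET_CLASSES = ("lncRNA", "mRNA")
GROUPS = ("case", "control")


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Features x samples intensity matrix for one feature class.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    feature_class
        One of ``lncRNA``, ``miRNA``, ``mRNA``; uniform for the matrix.
    groups
        Series mapping every sample id to ``case`` or ``control``.
    is_log2
        Whether ``values`` are log2 intensities (otherwise linear scale,
        non-negative).
    """

    values: pd.DataFrame
    feature_class: str
    groups: pd.Series
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"group labels must be in {GROUPS}, got {bad}"
            )
        for g in GROUPS:
            if int((self.groups == g).sum()) < 2:
                raise ValidationError(f"fewer than 2 samples in group {g!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("expression matrix contains missing values")
        if not self.is_log2 and (arr < 0).any():
            raise ValidationError("linear-scale intensities must be >= 0")
        self.values = self.values.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    # -- scale conversion ------------------------------------------------
    def to_linear(self) -> "ExpressionMatrix":
        if not self.is_log2:
            return self
        return replace(self, values=2.0 ** self.values, is_log2=False)

    def to_log2(self) -> "ExpressionMatrix":
        if self.is_log2:
            return self
        if (self.values.to_numpy() <= 0).any():
            raise ValidationError(
                "cannot take log2 of non-positive intensities"
            )
        return replace(self, values=np.log2(self.values), is_log2=True)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        unknown = [f for f in ids if f not in self.values.index]
        if unknown:
            raise ValidationError(f"unknown feature ids: {unknown}")
        return replace(self, values=self.values.loc[ids])


@dataclass(frozen=True, order=True)
class InteractionPair:
    """One candidate miRNA -> target (lncRNA or mRNA) relation."""

    mirna_id: str
    target_id: str
    target_class: str
    source: str = "imported"
    score: Optional[float] = None
    mfe: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(
                f"target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )
        if self.mfe is not None and self.mfe > 0:
            raise ValidationError(
                f"mfe must be <= 0 kcal/mol, got {self.mfe}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


def targets_by_mirna(
    pairs: Iterable[InteractionPair], target_class: Optional[str] = None
) -> dict[str, set[str]]:
    """Map miRNA id -> set of its target ids (optionally one class only)."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        if target_class is not None and p.target_class != target_class:
            continue
        out.setdefault(p.mirna_id, set()).add(p.target_id)
    return out


def mirnas_by_target(pairs: Iterable[InteractionPair]) -> dict[str, set[str]]:
    """Map target id -> set of miRNAs predicted to bind it."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        out.setdefault(p.target_id, set()).add(p.mirna_id)
    return out
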