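"""Readers and writers for every external representation the pipeline touches.

Tab-delimited expression/interaction/result tables (GEO series-matrix style:
tab separator, mandatory header row, "." decimal point), FASTA sequences,
and Cytoscape-readable SIF / GraphML network files.  Loading is strict: a
malformed cell is an error with a line number, never a silent coercion.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    GROUPS,
    TARGET_CLASSES,
    ExpressionMatrix,
    InteractionPair,
    ValidationError,
)

PathLike = Union[str, os.PathLike]

SIF_RELATIONS = ("lnc_mir", "mir_mrna", "lnc_mrna")


class ParseError(ValueError):
    """A file violates its format contract; message carries the line number."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_group_table(path: PathLike) -> pd.Series:
    """Read a two-column sample_id<TAB>group table (header mandatory)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: group table needs 2 columns, got {df.shape[1]}")
    ids, grp = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        line = int(ids.index[ids.duplicated()][0]) + 2
        raise ParseError(f"{path}: duplicate sample id on line {line}")
    bad = ~grp.isin(GROUPS)
    if bad.any():
        line = int(grp.index[bad][0]) + 2
        raise ParseError(
            f"{path}: line {line}: group must be one of {GROUPS}, "
            f"got {grp[bad].iloc[0]!r}"
        )
    return pd.Series(grp.values, index=ids.values, name="group")


def read_expression(
    path: PathLike,
    class_label: str,
    group_table_path: Optional[PathLike] = None,
    groups: Optional[pd.Series] = None,
    is_log2: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table (first column = feature id).

    Either ``group_table_path`` or an in-memory ``groups`` series must be
    given.  Validation is strict: duplicate feature ids, non-numeric cells
    and samples without a group label raise :class:`ParseError` naming the
    offending line.
    """
    if (group_table_path is None) == (groups is None):
        raise ValidationError("exactly one of group_table_path/groups required")
    if groups is None:
        groups = read_group_table(group_table_path)

    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature id plus >=1 sample column")
    feature_ids = raw.iloc[:, 0]
    dup = feature_ids.duplicated()
    if dup.any():
        line = int(feature_ids.index[dup][0]) + 2  # header is line 1
        raise ParseError(
            f"{path}: duplicate feature id {feature_ids[dup].iloc[0]!r} "
            f"on line {line}"
        )
    body = raw.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce")
    nan_mask = values.isna() & body.notna()
    missing_mask = body.isna()
    for mask, what in ((nan_mask, "non-numeric"), (missing_mask, "missing")):
        if mask.to_numpy().any():
            row = int(np.where(mask.any(axis=1))[0][0])
            col = mask.columns[mask.iloc[row].to_numpy()][0]
            raise ParseError(
                f"{path}: {what} cell in column {col!r} on line {row + 2}"
            )
    values.index = pd.Index(feature_ids.values, name=raw.columns[0])

    unlabeled = [s for s in values.columns if s not in groups.index]
    if unlabeled:
        raise ParseError(f"{path}: sample(s) without group label: {unlabeled}")
    unknown = [s for s in groups.index if s not in values.columns]
    if unknown:
        raise ParseError(
            f"group table lists sample(s) absent from {path}: {unknown}"
        )
    return ExpressionMatrix(
        values=values,
        feature_class=class_label,
        groups=groups,
        is_log2=is_log2,
    )


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_group_table(groups: pd.Series, path: PathLike) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

INTERACTION_COLUMNS = ("mirna_id", "target_id", "target_class", "source", "score", "mfe")


def read_interactions(path: PathLike) -> list[InteractionPair]:
    """Read a tab-delimited interaction table.

    Required columns: mirna_id, target_id, target_class; optional: source,
    score, mfe.  An unknown target_class token is an error listing the
    allowed values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("mirna_id", "target_id", "target_class")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out: list[InteractionPair] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        if row["target_class"] not in TARGET_CLASSES:
            raise ParseError(
                f"{path}: line {line}: target_class {row['target_class']!r} "
                f"not in allowed tokens {TARGET_CLASSES}"
            )
        try:
            score = _opt_float(row.get("score"))
            mfe = _opt_float(row.get("mfe"))
            pair = InteractionPair(
                mirna_id=row["mirna_id"],
                target_id=row["target_id"],
                target_class=row["target_class"],
                source=row.get("source") if pd.notna(row.get("source")) else "imported",
                score=score,
                mfe=mfe,
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
        out.append(pair)
    return out


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x):
        return None
    return float(x)


def write_interactions(pairs: Iterable[InteractionPair], path: PathLike) -> None:
    rows = [
        {
            "mirna_id": p.mirna_id,
            "target_id": p.target_id,
            "target_class": p.target_class,
            "source": p.source,
            "score": p.score,
            "mfe": p.mfe,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, upper-cased and stored as DNA (U -> T)."""

    id: str
    seq: str
    was_rna: bool = False


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA; ids are headers up to first whitespace, U normalized to T."""
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: malformed FASTA header (empty id)")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        was_rna = "U" in seq
        records.append(SequenceRecord(rec.id, seq.replace("U", "T"), was_rna))
    return records


# ---------------------------------------------------------------------------
# networks: SIF and GraphML
# ---------------------------------------------------------------------------

def write_network(network, path: PathLike, dialect: str = "SIF") -> None:
    """Write a tripartite network as Cytoscape-readable SIF or GraphML.

    SIF: one ``source<TAB>relation<TAB>target`` line per edge; isolated
    nodes become single-column lines.  GraphML carries node attribute
    ``class`` and edge attribute ``relation``.
    """
    g = network.graph
    dialect = dialect.upper()
    if dialect == "SIF":
        lines = []
        for u, v, data in sorted(g.edges(data=True)):
            lines.append(f"{u}\t{data['relation']}\t{v}")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                lines.append(str(n))
        Path(path).write_text("".join(line + "\n" for line in lines))
    elif dialect == "GRAPHML":
        nx.write_graphml(g, str(path), named_key_ids=True)
    else:
        raise ValidationError(f"unknown network dialect {dialect!r} (SIF, GraphML)")


def read_network(
    path: PathLike,
    dialect: str = "SIF",
    classes: Optional[dict[str, str]] = None,
):
    """Read a network written by :func:`write_network`.

    SIF does not carry node classes, so isolated (single-column) nodes need
    a ``classes`` registry mapping node id -> feature class; edge endpoints
    have their class inferred from the relation token.  GraphML is lossless.
    """
    from .topology import TripartiteNetwork  # local import: avoid cycle

    dialect = dialect.upper()
    net = TripartiteNetwork()
    if dialect == "SIF":
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                node = parts[0]
                if classes is None or node not in classes:
                    raise ParseError(
                        f"{path}: line {lineno}: isolated SIF node {node!r} "
                        "needs a `classes` registry entry (SIF carries no "
                        "feature class)"
                    )
                net.add_node(node, classes[node])
                continue
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            u, rel, v = parts
            if rel not in SIF_RELATIONS:
                raise ParseError(
                    f"{path}: line {lineno}: unknown relation {rel!r} "
                    f"(allowed: {SIF_RELATIONS})"
                )
            cls_u, cls_v = _classes_for_relation(rel)
            net.add_node(u, cls_u)
            net.add_node(v, cls_v)
            net.add_edge(u, v)
        return net
    if dialect == "GRAPHML":
        g = nx.read_graphml(str(path))
        for n, data in g.nodes(data=True):
            net.add_node(str(n), data["class"])
        for u, v in g.edges():
            net.add_edge(str(u), str(v))
        return net
    raise ValidationError(f"unknown network dialect {dialect!r} (SIF, GraphML)")


def _classes_for_relation(rel: str) -> tuple[str, str]:
    return {
        "lnc_mir": ("lncRNA", "miRNA"),
        "mir_mrna": ("miRNA", "mRNA"),
        "lnc_mrna": ("lncRNA", "mRNA"),
    }[rel]


# ---------------------------------------------------------------------------
# GMT annotation sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> dict[str, set[str]]:
    """Read GMT-style annotation sets: name<TAB>description<TAB>id...."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}: line {lineno}: GMT rows need name, description "
                "and at least one member"
            )
        name = parts[0]
        if name in sets:
            raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: PathLike) -> None:
    lines = [
        "\t".join([name, name] + sorted(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))
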