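"""Candidate miRNA->target pairs: built-in seed matching plus import/merge.

External predictors (RNAhybrid, miRanda, TargetScan) are consumed as
interaction tables through :mod:`cernet.io`; the only built-in predictor is
canonical seed matching.  A site is an occurrence on the target transcript
(5'->3') of the reverse complement of the miRNA seed (positions 2-7,
1-based), classified by the standard flanking rules:

* position 8 of the miRNA also pairs  -> ``7mer-m8``;
* an A faces miRNA position 1 on the target -> ``7mer-A1``;
* both -> ``8mer``; neither -> ``6mer``.

Coordinates are 0-based half-open on the target.  Only the transcript
strand is scanned (targets are transcripts, not genomic loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from .containers import InteractionPair, ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MATCH_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
# minimum reportable class -> accepted site types
_MIN_CLASS = {
    "6mer": set(MATCH_TYPES),
    "7mer": {"7mer-A1", "7mer-m8", "8mer"},
    "8mer": {"8mer"},
}


@dataclass(frozen=True)
class SeedMatchSite:
    """One seed-match site on a target transcript (0-based half-open)."""

    mirna_id: str
    target_id: str
    start: int
    site_length: int
    match_type: str

    @property
    def end(self) -> int:
        return self.start + self.site_length


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValidationError(f"{what} sequence is empty")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValidationError(
            f"{what} sequence contains non-ACGT/U symbols: {sorted(bad)}"
        )
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_match_scan(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
    min_class: str = "7mer",
) -> list[SeedMatchSite]:
    """Report every seed-match site of ``mirna_seq`` on ``target_seq``.

    Overlapping sites are all reported; the scan covers the whole target.
    ``min_class`` (6mer/7mer/8mer, default 7mer) sets the weakest site type
    reported.
    """
    if min_class not in _MIN_CLASS:
        raise ValidationError(
            f"min_class must be one of {sorted(_MIN_CLASS)}, got {min_class!r}"
        )
    mirna = _normalize(mirna_seq, "miRNA")
    target = _normalize(target_seq, "target")
    if len(mirna) < 8:
        raise ValidationError(
            f"miRNA must be >= 8 nt for seed matching, got {len(mirna)}"
        )
    core = revcomp(mirna[1:7])          # seed positions 2-7 -> 6-nt match
    m8_base = revcomp(mirna[7])         # target base pairing miRNA position 8
    accepted = _MIN_CLASS[min_class]

    sites: list[SeedMatchSite] = []
    for i in range(len(target) - 6 + 1):
        if target[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and target[i - 1] == m8_base
        has_a1 = i + 6 < len(target) and target[i + 6] == "A"
        if has_m8 and has_a1:
            mt, start, length = "8mer", i - 1, 8
        elif has_m8:
            mt, start, length = "7mer-m8", i - 1, 7
        elif has_a1:
            mt, start, length = "7mer-A1", i, 7
        else:
            mt, start, length = "6mer", i, 6
        if mt in accepted:
            sites.append(SeedMatchSite(mirna_id, target_id, start, length, mt))
    return sites


def scan_many(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    min_class: str = "7mer",
) -> list[SeedMatchSite]:
    """Scan every (miRNA, target) combination; deterministic order."""
    sites: list[SeedMatchSite] = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            sites.extend(
                seed_match_scan(mirnas[mid], targets[tid], mid, tid, min_class)
            )
    return sites


def pairs_from_sites(
    sites: Iterable[SeedMatchSite],
    target_class: Union[str, Mapping[str, str]],
    source: str = "seed_match",
) -> list[InteractionPair]:
    """Collapse sites to one pair per (miRNA, target); score = site count.

    ``target_class`` is either one class for all targets or a mapping
    target id -> class.  Output order is lexicographic by miRNA then
    target.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in sites:
        counts[(s.mirna_id, s.target_id)] = counts.get((s.mirna_id, s.target_id), 0) + 1
    pairs = []
    for (mid, tid) in sorted(counts):
        cls = target_class if isinstance(target_class, str) else target_class[tid]
        pairs.append(
            InteractionPair(mid, tid, cls, source=source, score=float(counts[(mid, tid)]))
        )
    return pairs


def merge_interactions(
    imported: Iterable[InteractionPair],
    computed: Iterable[InteractionPair],
    dedupe: bool = True,
) -> list[InteractionPair]:
    """Set union on (miRNA, target) keeping the best (largest) score.

    A target id appearing with two different classes is a hard error.
    Output is deterministic: lexicographic by miRNA then target.
    """
    classes: dict[str, str] = {}
    best: dict[tuple[str, str], InteractionPair] = {}
    for p in list(imported) + list(computed):
        prev_cls = classes.get(p.target_id)
        if prev_cls is not None and prev_cls != p.target_class:
            raise ValidationError(
                f"conflicting target_class for {p.target_id!r}: "
                f"{prev_cls!r} vs {p.target_class!r}"
            )
        classes[p.target_id] = p.target_class
        cur = best.get(p.key)
        if cur is None or not dedupe:
            best[p.key] = p
        else:
            a, b = cur.score, p.score
            if a is None or (b is not None and b > a):
                best[p.key] = p
    return [best[k] for k in sorted(best)]
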