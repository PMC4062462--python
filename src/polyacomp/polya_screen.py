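"""Poly(A)-tail screening of transcript/read sequences.

A sequence qualifies as polyadenylated when it carries a tail of at
least ``min_tail`` (default 12) continuous A's at its 3' end. The tail
is taken as the MAXIMAL trailing A-run, so the anchor never ends in A:
trimming maximally prevents genome-templated A's at the junction from
being double counted as tail. The fixed-length sequence immediately
upstream of the tail (the anchor: 100 bases for full mRNA, 80 for
fragmented reads) is the unit of genome placement and deduplication.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

_U_TO_T = str.maketrans("Uu", "Tt")
_ACGT = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA U's to DNA T's."""
    return seq.translate(_U_TO_T).upper()


def detect_tail(seq: str, min_tail: int = 12) -> Optional[int]:
    """Length of the maximal trailing A-run, or None if below ``min_tail``.

    The input may be RNA (U) or DNA (T); case-insensitive.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = normalize(seq)
    i = len(s)
    while i > 0 and s[i - 1] == "A":
        i -= 1
    run = len(s) - i
    return run if run >= min_tail else None


@dataclass(frozen=True)
class AnchoredTranscript:
    """A transcript proven polyadenylated, reduced to tail length + anchor."""

    source_id: str
    anchor: str
    tail_len: int

    def __post_init__(self):
        if self.tail_len < 1:
            raise ValueError("tail_len must be positive")


def extract_anchor(
    seq: str, tail_len: int, anchor_len: int = 100, source_id: str = ""
) -> Optional[AnchoredTranscript]:
    """The ``anchor_len`` bases immediately preceding the trailing A-run.

    Returns None when fewer than ``anchor_len`` bases precede the run or
    when the anchor contains a non-ACGT letter (an ambiguous anchor can
    never be placed by zero-mismatch matching).
    """
    s = normalize(seq)
    upstream = s[: len(s) - tail_len]
    if len(upstream) < anchor_len:
        return None
    anchor = upstream[-anchor_len:]
    if not _ACGT.issuperset(anchor):
        return None
    return AnchoredTranscript(source_id=source_id, anchor=anchor, tail_len=tail_len)


def dedupe_by_anchor(
    items: Iterable[AnchoredTranscript],
) -> tuple[list[AnchoredTranscript], int]:
    """Keep the first occurrence of each distinct anchor string.

    Returns (unique items in first-occurrence order, duplicate count).
    All anchors must share one length.
    """
    items = list(items)
    lengths = {len(it.anchor) for it in items}
    if len(lengths) > 1:
        raise ValueError(f"mixed anchor lengths: {sorted(lengths)}")
    seen: dict[str, AnchoredTranscript] = {}
    for it in items:
        if it.anchor not in seen:
            seen[it.anchor] = it
    unique = list(seen.values())
    return unique, len(items) - len(unique)


@dataclass
class ScreenReport:
    """Per-category counts from one screening pass."""

    n_input: int = 0
    n_id_excluded: int = 0
    n_no_tail: int = 0
    n_tailed: int = 0
    n_too_short: int = 0
    n_ambiguous_anchor: int = 0
    n_anchored: int = 0
    n_duplicates: int = 0
    n_unique: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def screen_transcripts(
    records: Iterable[tuple[str, str]],
    min_tail: int = 12,
    anchor_len: int = 100,
    id_exclude: Optional[str] = None,
) -> tuple[list[AnchoredTranscript], ScreenReport]:
    """Full screening pass: tail detection, anchor extraction, dedup.

    ``id_exclude`` is an optional regex; records whose id matches are
    dropped before screening (e.g. to remove computation-predicted mRNA
    accessions by pattern).
    """
    pattern = re.compile(id_exclude) if id_exclude else None
    report = ScreenReport()
    anchored: list[AnchoredTranscript] = []
    for rid, seq in records:
        report.n_input += 1
        if pattern is not None and pattern.search(rid):
            report.n_id_excluded += 1
            continue
        if not seq:
            report.n_no_tail += 1
            continue
        tail = detect_tail(seq, min_tail=min_tail)
        if tail is None:
            report.n_no_tail += 1
            continue
        report.n_tailed += 1
        item = extract_anchor(seq, tail, anchor_len=anchor_len, source_id=rid)
        if item is None:
            # distinguish the two rejection categories for the report
            s = normalize(seq)
            if len(s) - tail < anchor_len:
                report.n_too_short += 1
            else:
                report.n_ambiguous_anchor += 1
            continue
        report.n_anchored += 1
        anchored.append(item)
    unique, ndup = dedupe_by_anchor(anchored)
    report.n_duplicates = ndup
    report.n_unique = len(unique)
    return unique, report
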