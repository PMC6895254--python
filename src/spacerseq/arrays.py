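"""In vivo expanded-array analysis: junction anchors, hypothetical spacers,
and repeat-spacer junction calls.

Each 250-bp amplicon read of an expanded array is decoded in four steps:
locate the leader-repeat junction and the start of the second repeat copy
(anchor matches within a mismatch tolerance); enumerate hypothetical new
spacers of every length in the configured range (default 27-33 bp, seven
candidates) ending at the second repeat; keep the longest candidate that
aligns with zero mismatches to the reference set (genome + plasmid) as the
true spacer; and report the repeat-spacer junction as the length of the
first (newly duplicated) repeat copy, in the mutant repeat's own 1-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .align import scan
from .sequences import revcomp, validate_dna

DEFAULT_ANCHOR_LEN = 20


@dataclass(frozen=True)
class ArrayCall:
    """Per-read junction call."""

    read_id: str
    lr_offset: Optional[int] = None  # 0-based read offset where repeat copy 1 starts
    second_repeat_offset: Optional[int] = None  # 0-based read offset of repeat copy 2
    spacer_len: Optional[int] = None
    rs_position: Optional[int] = None  # 1-based mutant-repeat coordinate
    category: str = "uncallable"  # "WT-site" | "shifted-site" | "other" | "uncallable"
    reason: str = ""

    @property
    def callable(self) -> bool:
        return self.rs_position is not None


def find_anchors(read: str, leader_suffix: str, repeat_seq: str,
                 max_mismatches: int = 2,
                 anchor_len: int = DEFAULT_ANCHOR_LEN
                 ) -> Tuple[Optional[int], Optional[int], str]:
    """Locate the LR junction and the second repeat copy in a read.

    Returns ``(lr_offset, second_repeat_offset, reason)``: 0-based offsets
    of the first base of the first repeat copy and of the second repeat
    copy, with a non-empty *reason* when either anchor is missing. Both
    anchors are leftmost best-stratum matches; the second-repeat search
    starts after the first repeat.
    """
    leader_anchor = leader_suffix[-anchor_len:]
    repeat_anchor = repeat_seq[:anchor_len]
    offsets, mm = scan(read, leader_anchor, max_mismatches)
    if mm is None:
        return None, None, "no-leader"
    lr_offset = offsets[0] + len(leader_anchor)
    floor = lr_offset + len(repeat_seq)
    if floor + len(repeat_anchor) > len(read):
        return lr_offset, None, "no-second-repeat"
    offsets, mm = scan(read[floor:], repeat_anchor, max_mismatches)
    if mm is None:
        return lr_offset, None, "no-second-repeat"
    return lr_offset, floor + offsets[0], ""


def enumerate_hypothetical_spacers(read: str, second_repeat_offset: int,
                                   min_spacer: int = 27, max_spacer: int = 33
                                   ) -> List[Tuple[int, str]]:
    """One candidate per length L in the range: the L bases of the read
    ending at the second repeat's start. Candidates whose window underflows
    the read start are dropped (shorter list)."""
    if not 0 <= second_repeat_offset <= len(read):
        raise ValueError("second repeat offset outside read")
    out = []
    for length in range(min_spacer, max_spacer + 1):
        start = second_repeat_offset - length
        if start < 0:
            continue
        out.append((length, read[start: second_repeat_offset]))
    return out


def select_true_spacer(candidates: Sequence[Tuple[int, str]],
                       references: Sequence[Tuple[str, str]]) -> Optional[int]:
    """Length of the longest candidate with a zero-mismatch hit (either
    strand) anywhere in the reference set, or ``None``."""
    for length, seq in sorted(candidates, key=lambda c: -c[0]):
        rc = revcomp(seq)
        for _, ref in references:
            if seq in ref or rc in ref:
                return length
    return None


def call_read(read_id: str, read: str, leader_suffix: str, repeat_seq: str,
              references: Sequence[Tuple[str, str]], wt_site: int = 36,
              min_spacer: int = 27, max_spacer: int = 33,
              max_mismatches: int = 2, shift_threshold: int = 3,
              anchor_len: int = DEFAULT_ANCHOR_LEN) -> ArrayCall:
    """Full per-read pipeline: anchors -> candidates -> spacer -> junction.

    The junction (RS position) is ``second repeat offset - spacer length -
    LR offset``: the length of the duplicated repeat copy, in the mutant
    repeat's own coordinates. Categories: "WT-site" (== *wt_site*),
    "shifted-site" (within *shift_threshold*), "other" (farther, including
    spacer-internal attacks), "uncallable".
    """
    lr, second, reason = find_anchors(read, leader_suffix, repeat_seq,
                                      max_mismatches, anchor_len)
    if reason:
        return ArrayCall(read_id, lr, second, reason=reason)
    # reads without a new spacer: the two repeat anchors sit closer than any
    # plausible spacer (3-nt slack covers repair at the copy's 3' end)
    if second - lr - len(repeat_seq) < min_spacer - shift_threshold:
        return ArrayCall(read_id, lr, second, reason="unexpanded")
    candidates = enumerate_hypothetical_spacers(read, second, min_spacer, max_spacer)
    if not candidates:
        return ArrayCall(read_id, lr, second, reason="no-candidates")
    spacer_len = select_true_spacer(candidates, references)
    if spacer_len is None:
        return ArrayCall(read_id, lr, second, reason="no-perfect-spacer")
    rs = second - spacer_len - lr
    if rs <= 0:
        return ArrayCall(read_id, lr, second, spacer_len, None,
                         category="other", reason="negative-repeat-length")
    if rs == wt_site:
        category = "WT-site"
    elif abs(rs - wt_site) <= shift_threshold:
        category = "shifted-site"
    else:
        category = "other"
    return ArrayCall(read_id, lr, second, spacer_len, rs, category)


def call_reads(reads: Iterable[Tuple[str, str]], leader_suffix: str,
               repeat_seq: str, references: Sequence[Tuple[str, str]],
               **kwargs) -> List[ArrayCall]:
    return [call_read(rid, seq, leader_suffix, repeat_seq, references, **kwargs)
            for rid, seq in reads]


def summarize(calls: Sequence[ArrayCall]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position percent table (over callable reads) and category table.

    Percents sum to 100 over callable reads; callable + uncallable equals
    the input count.
    """
    callable_calls = [c for c in calls if c.callable]
    n_callable = len(callable_calls)
    pos_counts: Dict[int, int] = {}
    for c in callable_calls:
        pos_counts[c.rs_position] = pos_counts.get(c.rs_position, 0) + 1
    positions = pd.DataFrame(
        [dict(rs_position=p, reads=n, percent=100.0 * n / n_callable)
         for p, n in sorted(pos_counts.items())],
        columns=["rs_position", "reads", "percent"])
    cat_counts: Dict[str, int] = {}
    for c in calls:
        cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
    categories = pd.DataFrame(
        [dict(category=k, reads=v, percent=100.0 * v / len(calls))
         for k, v in sorted(cat_counts.items())],
        columns=["category", "reads", "percent"])
    return positions, categories


def calls_to_frame(calls: Sequence[ArrayCall]) -> pd.DataFrame:
    return pd.DataFrame([dict(read_id=c.read_id, lr_offset=c.lr_offset,
                              second_repeat_offset=c.second_repeat_offset,
                              spacer_len=c.spacer_len, rs_position=c.rs_position,
                              category=c.category, reason=c.reason)
                         for c in calls])


def modal_rs_position(calls: Sequence[ArrayCall]) -> Optional[int]:
    """Most frequent called junction position (ties -> smaller position)."""
    counts: Dict[int, int] = {}
    for c in calls:
        if c.callable:
            counts[c.rs_position] = counts.get(c.rs_position, 0) + 1
    if not counts:
        return None
    return min(counts, key=lambda p: (-counts[p], p))
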