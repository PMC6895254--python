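"""Self-contained k-mismatch alignment of short fragments to small references.

References here are a few kilobases at most (plasmids, linear targets, a
genome surrogate), so alignment is an exhaustive Hamming scan over every
offset on both strands, reporting only the best stratum (all hits at the
minimum achieved mismatch count, as short-read aligners do). Exact hits are
found first with C-speed substring search; the vectorised scan only runs
when no exact hit exists and mismatches are allowed.

Offsets are 0-based plus-strand coordinates of the leftmost matched base;
a "-" strand hit means the reverse complement of the query matches the plus
strand there, so ``align(q)`` on "+" mirrors ``align(revcomp(q))`` on "-"
with identical offsets. ``N`` matches nothing on either side. Circular
references are handled by doubling the sequence and reducing offsets
modulo the reference length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .sequences import encode, revcomp, validate_dna


@dataclass(frozen=True)
class AlignmentHit:
    reference_id: str
    offset: int  # 0-based, plus strand, leftmost matched base
    strand: str  # "+" | "-"
    mismatches: int


def _exact_offsets(haystack: str, needle: str, n_starts: int) -> List[int]:
    """All exact occurrences of *needle* with start < *n_starts*."""
    out = []
    idx = haystack.find(needle)
    while 0 <= idx < n_starts:
        out.append(idx)
        idx = haystack.find(needle, idx + 1)
    return out


def _mismatch_scan(haystack: str, needle: str, n_starts: int) -> np.ndarray:
    """Mismatch count of *needle* at every start offset < *n_starts*."""
    ref = encode(haystack.replace("N", "@"))
    q = encode(needle.replace("N", "#"))  # query N never matches, even ref N
    windows = np.lib.stride_tricks.sliding_window_view(ref, len(q))[:n_starts]
    return (windows != q).sum(axis=1)


def scan(haystack: str, needle: str, max_mismatches: int,
         n_starts: Optional[int] = None) -> Tuple[List[int], Optional[int]]:
    """Best-stratum occurrence scan on a single strand.

    Returns ``(offsets, mismatches)`` where *offsets* are all 0-based start
    offsets achieving the minimum mismatch count <= *max_mismatches*
    (empty list and ``None`` when there is none).
    """
    if n_starts is None:
        n_starts = len(haystack) - len(needle) + 1
    if n_starts <= 0 or len(needle) == 0:
        return [], None
    exact = _exact_offsets(haystack, needle, n_starts)
    if exact:
        return exact, 0
    if max_mismatches == 0:
        return [], None
    mm = _mismatch_scan(haystack, needle, n_starts)
    best = int(mm.min())
    if best > max_mismatches:
        return [], None
    return np.flatnonzero(mm == best).tolist(), best


def align(query: str, reference: str, max_mismatches: int = 2,
          circular: bool = False, reference_id: str = "ref") -> List[AlignmentHit]:
    """All best-stratum hits of *query* on both strands of *reference*.

    Returns the hits at the minimum achieved mismatch count <=
    *max_mismatches* across both strands, sorted by (offset, strand);
    empty list when nothing aligns within tolerance.
    """
    query = validate_dna(query)
    reference = validate_dna(reference)
    if not 1 <= len(query) <= len(reference):
        raise ValueError(
            f"query length {len(query)} outside [1, {len(reference)}]")
    ref_len = len(reference)
    if circular:
        haystack = reference + reference[: len(query) - 1]
        n_starts = ref_len
    else:
        haystack = reference
        n_starts = ref_len - len(query) + 1

    candidates: List[Tuple[int, str, int]] = []
    best_overall: Optional[int] = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        offsets, mm = scan(haystack, q, max_mismatches, n_starts)
        if mm is None:
            continue
        candidates.extend((off, strand, mm) for off in offsets)
        best_overall = mm if best_overall is None else min(best_overall, mm)
    if best_overall is None:
        return []
    hits = [AlignmentHit(reference_id, off % ref_len, strand, mm)
            for off, strand, mm in candidates if mm == best_overall]
    # circular doubling cannot duplicate (offset, strand) since starts < ref_len
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits
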