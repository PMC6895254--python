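"""Non-CRISPR integration sites: base preference and flanking context.

Off-target events are the integrations that land outside the annotated
CRISPR array. Two summaries characterise them: the base composition at the
attacked position (read on the attacked strand, so a "-" event at a
plus-strand C counts as G) and a position x base context matrix over a
window around the site, oriented on the attacked strand so the resulting
logo is junction-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequences import DNA_ALPHABET, revcomp


def partition_sites(events: Sequence[dict], array_interval: Optional[Tuple[int, int]],
                    reference_length: int, margin: int = 0
                    ) -> Tuple[List[dict], List[dict]]:
    """Split events into (on-CRISPR, off-target) by the annotated array.

    *array_interval* is a 1-based inclusive (start, end) on the reference,
    or ``None`` for references without an array (everything off-target).
    """
    if array_interval is None:
        return [], list(events)
    start, end = array_interval
    if not (1 <= start <= end <= reference_length):
        raise ValueError(
            f"array interval {start}..{end} outside reference of length "
            f"{reference_length}")
    lo, hi = start - margin, end + margin
    on = [ev for ev in events if lo <= int(ev["site"]) <= hi]
    off = [ev for ev in events if not lo <= int(ev["site"]) <= hi]
    return on, off


def _attacked_base(reference: str, site: int, strand: str) -> str:
    base = reference[site - 1]
    return base if strand == "+" else revcomp(base)


def base_composition(events: Sequence[dict], reference: str) -> Dict[str, float]:
    """Fraction of events whose attacked-strand base is G, A, C or T."""
    if not events:
        raise ValueError("base composition of an empty event set")
    counts = {b: 0 for b in DNA_ALPHABET}
    for ev in events:
        base = _attacked_base(reference, int(ev["site"]), ev["strand"])
        if base in counts:
            counts[base] += 1
    total = sum(counts.values())
    return {b: c / total for b, c in counts.items()}


@dataclass
class ContextMatrix:
    """Base counts at positions -U..+D around integration sites (position 0
    is the attacked base, read on the attacked strand)."""

    counts: pd.DataFrame  # index: relative position, columns: A C G T
    n_sites: int
    n_truncated: int

    def frequencies(self) -> pd.DataFrame:
        """Per-position base frequencies (logo-ready: rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def information_content(self) -> pd.Series:
        """Per-position information content in bits (2 - entropy)."""
        freq = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -(freq * np.log2(freq.where(freq > 0))).sum(axis=1)
        return 2.0 - ent.fillna(2.0)


def context_matrix(events: Sequence[dict], reference: str,
                   upstream: int = 10, downstream: int = 10,
                   circular: bool = False) -> ContextMatrix:
    """Tally reference bases from -upstream..+downstream around each event,
    on the attacked strand (reverse-complemented for "-" events).

    Sites whose window runs off a linear reference are truncated and
    tallied; circular references wrap instead.
    """
    positions = list(range(-upstream, downstream + 1))
    mat = pd.DataFrame(0, index=positions, columns=list(DNA_ALPHABET))
    n = len(reference)
    truncated = 0
    for ev in events:
        site, strand = int(ev["site"]), ev["strand"]
        window_hit_edge = False
        for rel in positions:
            # plus-strand coordinate of the base at attacked-strand offset rel
            plus_pos = site + rel if strand == "+" else site - rel
            if circular:
                plus_pos = (plus_pos - 1) % n + 1
            elif not 1 <= plus_pos <= n:
                window_hit_edge = True
                continue
            base = _attacked_base(reference, plus_pos, strand)
            if base in mat.columns:
                mat.loc[rel, base] += 1
        truncated += window_hit_edge
    return ContextMatrix(mat, n_sites=len(events), n_truncated=truncated)
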