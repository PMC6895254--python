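"""In vitro read analysis: pre-spacer location, junction calling, profiles.

For each read the complete pre-spacer sequence is located (leftmost
best-stratum occurrence within a mismatch tolerance), up to 50 bp of
sequence immediately downstream of its end is extracted, and the fragment
is aligned to the reference. The integration site is the plus-strand
coordinate of the fragment's first aligned base: the nucleotide whose 5'
phosphate was attacked. Reads are tallied at every stage so that
``mapped + discarded == input``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .align import AlignmentHit, align, scan
from .locus import IntegrationEvent, PreSpacer
from .io import write_bedgraph

DISCARD_KEYS = ("no_prespacer", "short_fragment", "unaligned", "multimapped")


def find_prespacer(read: str, prespacer_strand: str,
                   max_mismatches: int = 2) -> Optional[int]:
    """Offset immediately after the leftmost best-stratum occurrence of the
    pre-spacer strand in *read*, or ``None`` when absent within tolerance."""
    if len(prespacer_strand) > len(read):
        return None
    offsets, mm = scan(read, prespacer_strand, max_mismatches)
    if mm is None:
        return None
    return offsets[0] + len(prespacer_strand)


def extract_downstream(read: str, offset: int, window: int = 50) -> str:
    """Up to *window* bases immediately downstream of *offset* (shorter when
    the read ends first; empty means the read is discarded upstream)."""
    if offset > len(read):
        raise ValueError("offset beyond read end")
    return read[offset: offset + window]


def call_site(hit: AlignmentHit, fragment_len: int) -> Tuple[int, str]:
    """Integration site from a unique alignment hit.

    Plus-strand hits: the fragment's first base is the attacked nucleotide,
    site = offset + 1 (1-based). Minus-strand hits: the fragment's first
    base pairs with the rightmost plus-strand position of the match,
    site = offset + fragment length.
    """
    if hit.strand == "+":
        return hit.offset + 1, "+"
    return hit.offset + fragment_len, "-"


@dataclass
class SiteProfile:
    """Per (position, strand) read counts and percent of mapped reads."""

    counts: Dict[Tuple[int, str], int]
    discards: Dict[str, int]
    normalization: str = "raw"  # "raw" | "per-strand"

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    @property
    def strand_totals(self) -> Dict[str, int]:
        totals = {"+": 0, "-": 0}
        for (_, strand), c in self.counts.items():
            totals[strand] += c
        return totals

    @property
    def percents(self) -> Dict[Tuple[int, str], float]:
        """Percent of total per bin; sums to 100 over all bins.

        "raw": count / total mapped. "per-strand": each strand is first
        scaled to its own depth (the two strand-specific amplicon libraries
        are sequenced independently), then both contribute
        percent-of-combined-total with equal strand weight.
        """
        if not self.counts:
            return {}
        if self.normalization == "raw":
            total = self.total_mapped
            return {k: 100.0 * c / total for k, c in self.counts.items()}
        totals = self.strand_totals
        scaled = {k: c / totals[k[1]] for k, c in self.counts.items()}
        denom = sum(scaled.values())
        return {k: 100.0 * v / denom for k, v in scaled.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percents
        rows = [dict(position=pos, strand=strand, count=c,
                     percent=pct[(pos, strand)])
                for (pos, strand), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["position", "strand", "count", "percent"])

    def discard_frame(self) -> pd.DataFrame:
        rows = [dict(reason=k, reads=v) for k, v in self.discards.items()]
        rows.append(dict(reason="mapped", reads=self.total_mapped))
        return pd.DataFrame(rows)

    def write_bedgraph(self, prefix, chrom: str) -> None:
        """One bedGraph per strand (percent values, 0-based half-open)."""
        pct = self.percents
        for strand, tag in (("+", "plus"), ("-", "minus")):
            values = {pos: v for (pos, s), v in pct.items() if s == strand}
            write_bedgraph(f"{prefix}.{tag}.bedgraph", chrom, values,
                           track_name=f"integration_{tag}")


def map_reads(reads: Iterable[Tuple[str, str]], reference: str,
              prespacer: PreSpacer, window: int = 50, max_mismatches: int = 2,
              circular: bool = False, min_fragment: int = 15,
              reference_id: str = "ref") -> Tuple[List[dict], Dict[str, int]]:
    """Run the full per-read pipeline over ``(read_id, sequence)`` pairs.

    Both pre-spacer strands are tried (the libraries mix top- and
    bottom-strand joints); ties go to the lower mismatch count, then to the
    top strand. Returns called events plus discard tallies; the tallies and
    the event count always add up to the input count.
    """
    tallies = {k: 0 for k in DISCARD_KEYS}
    events: List[dict] = []
    for read_id, seq in reads:
        best_off: Optional[int] = None
        for strand_seq in (prespacer.top_strand, prespacer.bottom_strand):
            if len(strand_seq) > len(seq):
                continue
            offsets, mm = scan(seq, strand_seq, max_mismatches)
            if mm is None:
                continue
            if best_off is None or mm < best_mm:
                best_off, best_mm = offsets[0] + len(strand_seq), mm
        if best_off is None:
            tallies["no_prespacer"] += 1
            continue
        fragment = extract_downstream(seq, best_off, window)
        if len(fragment) < min_fragment:
            tallies["short_fragment"] += 1
            continue
        hits = align(fragment, reference, max_mismatches=max_mismatches,
                     circular=circular, reference_id=reference_id)
        if not hits:
            tallies["unaligned"] += 1
            continue
        if len(hits) > 1:
            tallies["multimapped"] += 1
            continue
        site, strand = call_site(hits[0], len(fragment))
        if circular:  # minus-strand hits spanning the origin wrap past the end
            site = (site - 1) % len(reference) + 1
        events.append(dict(read_id=read_id, target=reference_id, site=site,
                           strand=strand, mismatches=hits[0].mismatches))
    return events, tallies


def build_profile(events: Sequence[dict], discards: Optional[Dict[str, int]] = None,
                  normalization: str = "raw") -> SiteProfile:
    """Aggregate called events into a strand-specific site profile."""
    if normalization not in ("raw", "per-strand"):
        raise ValueError("normalization must be 'raw' or 'per-strand'")
    counts: Dict[Tuple[int, str], int] = {}
    for ev in events:
        key = (int(ev["site"]), ev["strand"])
        counts[key] = counts.get(key, 0) + 1
    profile = SiteProfile(counts, dict(discards or {}), normalization)
    if profile.total_mapped == 0:
        import warnings
        warnings.warn("profile built from zero mapped reads", stacklevel=2)
    return profile


def events_to_integration_events(events: Sequence[dict]) -> List[IntegrationEvent]:
    """Adapt mapper output dicts to :class:`IntegrationEvent` objects."""
    out = []
    for ev in events:
        strand = ev["strand"]
        out.append(IntegrationEvent(
            target_id=ev.get("target", "ref"), strand=strand,
            site=int(ev["site"]),
            joined_end="leader-side" if strand == "+" else "spacer-side",
            event_class="half-LR" if strand == "+" else "half-RS"))
    return out
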