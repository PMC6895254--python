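"""Synthetic sequencing libraries with the structure of the three assays.

Three library types are emulated, each carrying per-read ground truth so
the downstream mapper/caller can be tested by round trip:

* **plasmid**: random-primed libraries from plasmid integration reactions;
  each read is the complete pre-spacer strand followed by plasmid context
  starting at the integration site (100-bp reads).
* **linear**: strand-specific junction amplicons from a minimal linear
  CRISPR target; each read is the joined product strand (pre-spacer end
  plus target sequence from the site to the strand's 3' end).
* **in-vivo-array**: 250-bp amplicons of expanded CRISPR arrays after
  full-site integration and repair: leader, duplicated repeat copy (length
  set by the second-site rule), new spacer (27-33 bp), second repeat, old
  spacer.

Sequencing error is a per-base substitution process applied separately
(``add_errors``); all randomness flows from explicit seeds and identical
seeds give byte-identical batches. Quality strings are constant ('I'):
the analysis never uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import FastqRecord, write_fastq, write_tsv
from .locus import CrisprLocus, PreSpacer, predict_second_site
from .references import LocusAnnotation
from .sequences import DNA_ALPHABET, revcomp

#: Off-target base preference of the integrase at non-CRISPR sites
#: (percent of events at G, A, C, T), as quantified on the plasmid
#: carrying a CRISPR array.
DEFAULT_BASE_WEIGHTS: Dict[str, float] = {"G": 56.5, "A": 22.1, "C": 13.7, "T": 7.7}


@dataclass(frozen=True)
class SiteDistribution:
    """Sampling weights for event placement (normalised before use)."""

    lr: float = 0.5
    rs: float = 0.5
    off_target: float = 0.0
    base_weights: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_BASE_WEIGHTS.items())

    def __post_init__(self) -> None:
        if min(self.lr, self.rs, self.off_target) < 0:
            raise ValueError("weights must be non-negative")
        if self.lr + self.rs + self.off_target <= 0:
            raise ValueError("at least one weight must be positive")

    @property
    def event_probs(self) -> np.ndarray:
        w = np.array([self.lr, self.rs, self.off_target], dtype=float)
        return w / w.sum()

    @property
    def base_probs(self) -> Tuple[List[str], np.ndarray]:
        bases = [b for b, _ in self.base_weights]
        w = np.array([v for _, v in self.base_weights], dtype=float)
        if w.sum() <= 0:
            raise ValueError("base weights must sum to a positive value")
        return bases, w / w.sum()


@dataclass
class ReadBatch:
    """Simulated reads plus their hidden ground truth."""

    records: List[FastqRecord]
    library_type: str
    seed: int
    error_rate: float = 0.0
    truth: List[dict] = field(default_factory=list)
    skipped: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def truth_frame(self) -> pd.DataFrame:
        cols = ["read_id", "target", "strand", "site", "event_class"]
        frame = pd.DataFrame(self.truth)
        if frame.empty:
            return pd.DataFrame(columns=cols)
        ordered = cols + [c for c in frame.columns if c not in cols]
        return frame[ordered]

    def write_fastq(self, path) -> None:
        write_fastq(path, self.records)

    def write_truth(self, path) -> None:
        write_tsv(path, self.truth_frame(),
                  comment="per-read ground truth; site is a 1-based plus-strand "
                          "coordinate (array libraries: repeat coordinate)")


def _context_plus(seq: str, site: int, length: int, circular: bool) -> str:
    """Plus-strand context starting at 1-based *site* (wrapping if circular)."""
    start = site - 1
    if circular:
        doubled = seq + seq
        return doubled[start: start + length]
    return seq[start: start + length]


def _context_minus(seq: str, site: int, length: int, circular: bool) -> str:
    """Minus-strand context whose first base pairs with plus position *site*."""
    if circular:
        n = len(seq)
        doubled = seq + seq
        return revcomp(doubled[site - length + n: site + n])
    return revcomp(seq[max(site - length, 0): site])


def simulate_plasmid_library(plasmid_id: str, plasmid_seq: str,
                             dist: SiteDistribution, prespacer: PreSpacer,
                             n: int, read_len: int = 100, seed: int = 0,
                             annotation: Optional[LocusAnnotation] = None,
                             circular: bool = True) -> ReadBatch:
    """Random-primed plasmid library: pre-spacer followed by plasmid context.

    On-target events land at the annotated LR site (plus strand) or RS site
    (minus strand); off-target sites are drawn by the configured base
    preference on a uniformly chosen strand, from non-CRISPR positions
    (outside the annotated array) when an annotation is given.
    """
    batch = ReadBatch([], "plasmid", seed)
    if n <= 0:
        return batch
    if len(plasmid_seq) < read_len:
        raise ValueError("plasmid shorter than the read length")
    if annotation is None and (dist.lr > 0 or dist.rs > 0):
        raise ValueError("on-target weights require a locus annotation")

    rng = np.random.default_rng(seed)
    bases, base_p = dist.base_probs
    # per-(strand, base) position pools for off-target sampling
    excluded = (set(range(annotation.array_start, annotation.array_end + 1))
                if annotation else set())
    pools: Dict[Tuple[str, str], np.ndarray] = {}
    comp = dict(zip("ACGT", "TGCA"))
    for b in bases:
        plus = [i + 1 for i, c in enumerate(plasmid_seq)
                if c == b and i + 1 not in excluded]
        minus = [i + 1 for i, c in enumerate(plasmid_seq)
                 if comp.get(c) == b and i + 1 not in excluded]
        pools[("+", b)] = np.array(plus, dtype=int)
        pools[("-", b)] = np.array(minus, dtype=int)

    kinds = rng.choice(3, size=n, p=dist.event_probs)
    for i, kind in enumerate(kinds):
        if kind == 0:  # LR half-site, top strand
            strand, site, klass = "+", annotation.lr_site, "half-LR"
        elif kind == 1:  # RS half-site, bottom strand
            strand, site, klass = "-", annotation.rs_site, "half-RS"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            base = bases[rng.choice(len(bases), p=base_p)]
            pool = pools[(strand, base)]
            if len(pool) == 0:
                raise ValueError(f"no {base} positions available on strand {strand}")
            site, klass = int(pool[rng.integers(len(pool))]), "off-target"
        ps = prespacer.top_strand if strand == "+" else prespacer.bottom_strand
        ctx_len = read_len - len(ps)
        ctx = (_context_plus(plasmid_seq, site, ctx_len, circular) if strand == "+"
               else _context_minus(plasmid_seq, site, ctx_len, circular))
        seq = (ps + ctx)[:read_len]
        rid = f"plasmid_{i}"
        batch.records.append((rid, seq, "I" * len(seq)))
        batch.truth.append(dict(read_id=rid, target=plasmid_id, strand=strand,
                                site=site, event_class=klass))
    return batch


def simulate_linear_library(target: CrisprLocus, dist: SiteDistribution,
                            prespacer: PreSpacer, n: int, seed: int = 0,
                            strand: str = "both",
                            read_len: Optional[int] = None,
                            target_id: str = "linear_target") -> ReadBatch:
    """Strand-specific junction amplicons from a linear CRISPR target.

    Each read is the covalently joined product strand: pre-spacer strand
    followed by target sequence from the attacked site to that strand's 3'
    end. Events whose strand does not match a single-strand library are
    skipped and tallied.
    """
    if strand not in ("top", "bottom", "both"):
        raise ValueError("strand must be 'top', 'bottom' or 'both'")
    if dist.off_target > 0:
        raise ValueError("linear junction libraries model on-target events only")
    batch = ReadBatch([], f"linear-{strand}", seed)
    if n <= 0:
        return batch
    rng = np.random.default_rng(seed)
    plus = target.top_strand
    lr_site = target.repeat_start()
    rs_site = lr_site + len(target.repeat) - 1
    probs = np.array([dist.lr, dist.rs], dtype=float)
    probs = probs / probs.sum()
    kinds = rng.choice(2, size=n, p=probs)
    skipped = 0
    for i, kind in enumerate(kinds):
        ev_strand = "+" if kind == 0 else "-"
        if strand == "top" and ev_strand != "+" or strand == "bottom" and ev_strand != "-":
            skipped += 1
            continue
        if ev_strand == "+":
            site, klass = lr_site, "half-LR"
            seq = prespacer.top_strand + plus[site - 1:]
        else:
            site, klass = rs_site, "half-RS"
            seq = prespacer.bottom_strand + revcomp(plus[:site])
        if read_len is not None:
            seq = seq[:read_len]
        rid = f"linear_{i}"
        batch.records.append((rid, seq, "I" * len(seq)))
        batch.truth.append(dict(read_id=rid, target=target_id, strand=ev_strand,
                                site=site, event_class=klass))
    if skipped:
        batch.skipped["strand_mismatch"] = skipped
    return batch


def draw_spacer_pool(genome_seq: str, n_spacers: int, seed: int = 0,
                     lengths: Sequence[int] = tuple(range(27, 34)),
                     forbidden_flank: Optional[str] = None) -> List[str]:
    """Sample protospacers (plus strand) from a reference genome.

    When *forbidden_flank* is given, loci whose genome base immediately 5'
    of the protospacer equals it are redrawn: at such loci the
    longest-perfect-match junction rule is intrinsically ambiguous (the
    repeat-extended candidate also aligns), so no unique ground truth
    exists for a round trip.
    """
    rng = np.random.default_rng(seed)
    pool: List[str] = []
    lengths = list(lengths)
    while len(pool) < n_spacers:
        length = int(lengths[rng.integers(len(lengths))])
        start = int(rng.integers(1, len(genome_seq) - length))
        if forbidden_flank and genome_seq[start - 1] == forbidden_flank:
            continue
        spacer = genome_seq[start: start + length]
        if "N" in spacer:
            continue
        pool.append(spacer)
    return pool


def simulate_expanded_arrays(locus: CrisprLocus, spacer_pool: Sequence[str],
                             n: int, seed: int = 0, read_len: int = 250,
                             leader_in_read: int = 30,
                             second_site_rule: Optional[Callable[[str], int]] = None,
                             anchor_len: int = 20,
                             target_id: str = "expanded_array") -> ReadBatch:
    """Amplicon reads from CRISPR arrays expanded by full-site integration.

    Each read is ``leader tail + duplicated repeat copy + new spacer +
    second (full) repeat + old spacer ...`` truncated to *read_len*. The
    duplicated copy runs from the LR junction to the second integration
    site predicted by *second_site_rule* (default: the molecular-ruler
    prediction), so downstream-indel mutants gain or lose bases at the
    copy's 3' end exactly as repair does in vivo. Spacers whose junction
    anchors would not fit in the read window are rejected and tallied.
    """
    rule = second_site_rule or predict_second_site
    batch = ReadBatch([], "in-vivo-array", seed)
    if n <= 0 or not spacer_pool:
        return batch
    rng = np.random.default_rng(seed)
    plus = locus.top_strand
    repeat_start0 = locus.repeat_start() - 1
    downstream = plus[repeat_start0:]  # first repeat, old spacer, further units
    site2 = int(rule(locus.repeat))
    if site2 > len(downstream):
        raise ValueError("second site beyond the end of the array")
    dup = downstream[:site2]
    leader_tail = locus.leader_seq[-leader_in_read:]
    rejected = 0
    for i in range(n):
        spacer = spacer_pool[int(rng.integers(len(spacer_pool)))]
        needed = len(leader_tail) + len(dup) + len(spacer) + anchor_len
        if needed > read_len:
            rejected += 1
            continue
        seq = (leader_tail + dup + spacer + downstream)[:read_len]
        rid = f"array_{i}"
        batch.records.append((rid, seq, "I" * len(seq)))
        batch.truth.append(dict(read_id=rid, target=target_id, strand="+",
                                site=site2, event_class="full",
                                spacer_len=len(spacer),
                                lr_offset=len(leader_tail)))
    if rejected:
        batch.skipped["spacer_window_overflow"] = rejected
    return batch


def add_errors(batch: ReadBatch, rate: float, seed: int = 0) -> ReadBatch:
    """Apply per-base substitution errors (uniform over the 3 alternatives).

    Deterministic given *seed*; ground truth is carried over unchanged.
    """
    if not 0 <= rate < 1 and rate != 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0:
        return ReadBatch(list(batch.records), batch.library_type, batch.seed,
                         0.0, list(batch.truth), dict(batch.skipped))
    rng = np.random.default_rng(seed)
    alt = {b: DNA_ALPHABET.replace(b, "") for b in DNA_ALPHABET}
    records: List[FastqRecord] = []
    for rid, seq, qual in batch.records:
        hit = np.flatnonzero(rng.random(len(seq)) < rate)
        if len(hit):
            chars = list(seq)
            for pos in hit:
                choices = alt.get(chars[pos], DNA_ALPHABET)
                chars[pos] = choices[int(rng.integers(len(choices)))]
            seq = "".join(chars)
        records.append((rid, seq, qual))
    return ReadBatch(records, batch.library_type, batch.seed, rate,
                     list(batch.truth), dict(batch.skipped))
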