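"""Model of a type II-A CRISPR locus and the two-step integration reaction.

Spacer acquisition by the Cas1-Cas2 integrase proceeds through two ordered
transesterification attacks on the leader-proximal repeat: the first by a
pre-spacer 3'-OH on the top strand at the leader-repeat (LR) junction
(repeat position 1), the second by the opposite 3'-OH on the bottom strand
at the repeat-spacer (RS) junction. The second site is not read from the
repeat border itself but measured by a molecular ruler: a short repeat
element (5'-CTGTA-3' at positions 28-32 in the wild-type repeat) directs
the attack a fixed 8 bp downstream of the element's 5' border, so that
length changes upstream of the element shift the second site by the same
amount while length changes downstream leave it untouched.

Coordinates
-----------
Repeat positions are 1-based on the top strand, position 1 at the
leader-proximal border; leader positions are negative (-1 adjacent to the
repeat); positions greater than the repeat length run into the downstream
spacer. Bottom-strand attack sites are reported as the plus-strand
coordinate of the paired base, so the wild-type RS site is 36. Internal
string slicing is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .sequences import revcomp, validate_dna


class CoordinateError(ValueError):
    """A mutation or lookup addressed a position outside the repeat."""


class RulerDisruptedError(ValueError):
    """The ruler element is absent, so no second site can be predicted."""


class BlockedEndError(ValueError):
    """An integration event required a 3' end that is dideoxy-terminated."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RulerElement:
    """The repeat element that sets the distance of the second attack.

    ``wt_start + offset`` equals the wild-type second integration site
    (position 36 for the 36-bp repeat with the element at 28-32).
    """

    motif: str = "CTGTA"
    wt_start: int = 28
    offset: int = 8
    search_floor: int = 20  # ignore motif copies upstream of this position

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", validate_dna(self.motif, allow_n=False))
        if self.offset < 0 or self.wt_start < 1:
            raise ValueError("ruler start and offset must be positive")

    @property
    def wt_second_site(self) -> int:
        return self.wt_start + self.offset


@dataclass(frozen=True)
class RepeatMutation:
    """A substitution, insertion or deletion in 1-based repeat coordinates.

    * substitution: ``bases`` replaces the same number of bases starting at
      ``start`` (point substitution when a single base).
    * insertion: ``bases`` is inserted *before* the wild-type base at
      ``start``; wild-type positions >= start shift downstream by
      ``len(bases)``.
    * deletion: positions ``start..end`` (inclusive) are removed.
    """

    kind: str  # "substitution" | "insertion" | "deletion"
    start: int
    bases: str = ""
    end: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        object.__setattr__(self, "bases", validate_dna(self.bases, allow_n=False))
        if self.kind == "deletion" and self.end == 0:
            object.__setattr__(self, "end", self.start)

    # Convenience constructors matching how mutants are written in the field
    @classmethod
    def insertion(cls, start: int, bases: str) -> "RepeatMutation":
        return cls("insertion", start, bases=bases)

    @classmethod
    def deletion(cls, start: int, end: Optional[int] = None) -> "RepeatMutation":
        return cls("deletion", start, end=end if end is not None else start)

    @classmethod
    def substitution(cls, start: int, bases: str) -> "RepeatMutation":
        return cls("substitution", start, bases=bases)


@dataclass(frozen=True)
class PreSpacer:
    """A processed pre-spacer duplex poised for integration.

    The default substrate geometry is a 30-bp duplex core with 5-nt 3'
    overhangs on each strand (35-nt strands). ``top_3p``/``bottom_3p``
    record the chemistry of each strand's 3' terminus: "OH" ends can carry
    out the nucleophilic attack, dideoxy ("dd") ends never join.
    """

    top_strand: str
    bottom_strand: str
    top_3p: str = "OH"
    bottom_3p: str = "OH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "top_strand", validate_dna(self.top_strand))
        object.__setattr__(self, "bottom_strand", validate_dna(self.bottom_strand))
        for chem in (self.top_3p, self.bottom_3p):
            if chem not in ("OH", "dd"):
                raise ValueError(f"end chemistry must be 'OH' or 'dd', got {chem!r}")

    def with_chemistry(self, top_3p: str = "OH", bottom_3p: str = "OH") -> "PreSpacer":
        return replace(self, top_3p=top_3p, bottom_3p=bottom_3p)

    @classmethod
    def from_core(cls, core: str, top_overhang: str, bottom_overhang: str,
                  top_3p: str = "OH", bottom_3p: str = "OH") -> "PreSpacer":
        """Build from a duplex core plus per-strand 3' overhangs."""
        core = validate_dna(core)
        return cls(core + validate_dna(top_overhang),
                   revcomp(core) + validate_dna(bottom_overhang),
                   top_3p=top_3p, bottom_3p=bottom_3p)


@dataclass(frozen=True)
class IntegrationEvent:
    """One transesterification attack on a target molecule.

    ``site`` is the plus-strand 1-based coordinate of the base whose 5'
    phosphate is attacked (for "-" strand events, the plus-strand
    coordinate of the paired base). ``joined_end`` records which pre-spacer
    3' end performs the attack: the top strand joins at LR-type (plus
    strand) sites, the bottom strand at RS-type (minus strand) sites.
    """

    target_id: str
    strand: str  # "+" (top) | "-" (bottom)
    site: int
    joined_end: str = "leader-side"  # "leader-side" (top 3') | "spacer-side" (bottom 3')
    event_class: str = "half-LR"  # "half-LR" | "half-RS" | "full" | "off-target"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class CrisprLocus:
    """A CRISPR locus: leader followed by (repeat, spacer) units.

    ``topology`` is one of ``plasmid-circular``, ``linear``,
    ``spacer-hairpin`` or ``leader-hairpin``; the hairpin topologies model
    single-molecule targets in which the two strands are covalently
    connected by a loop at the spacer or leader end. ``hairpin_loop`` is a
    placeholder loop sequence used for product-size computation.
    """

    leader_seq: str
    units: Tuple[Tuple[str, str], ...]
    topology: str = "linear"
    hairpin_loop: str = "TTTT"

    def __post_init__(self) -> None:
        if self.topology not in ("plasmid-circular", "linear",
                                 "spacer-hairpin", "leader-hairpin"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "leader_seq", validate_dna(self.leader_seq))
        units = tuple((validate_dna(r), validate_dna(s)) for r, s in self.units)
        if not units:
            raise ValueError("locus needs at least one repeat-spacer unit")
        object.__setattr__(self, "units", units)

    @property
    def repeat(self) -> str:
        """Leader-proximal (first) repeat."""
        return self.units[0][0]

    @property
    def top_strand(self) -> str:
        return self.leader_seq + "".join(r + s for r, s in self.units)

    def repeat_start(self, unit: int = 0) -> int:
        """Plus-strand 1-based coordinate of position 1 of *unit*'s repeat."""
        offset = len(self.leader_seq)
        for r, s in self.units[:unit]:
            offset += len(r) + len(s)
        return offset + 1

    def to_plus_coord(self, repeat_pos: int, unit: int = 0) -> int:
        """Convert a 1-based repeat coordinate (leader negative) to a
        plus-strand coordinate."""
        start = self.repeat_start(unit)
        if repeat_pos == 0:
            raise CoordinateError("repeat coordinates have no position 0")
        return start + repeat_pos - 1 if repeat_pos > 0 else start + repeat_pos

    def to_repeat_coord(self, plus_pos: int, unit: int = 0) -> int:
        start = self.repeat_start(unit)
        delta = plus_pos - start
        return delta + 1 if delta >= 0 else delta


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

CoordMap = Dict[int, Optional[int]]


def apply_mutation(repeat_seq: str, mutation: RepeatMutation) -> Tuple[str, CoordMap]:
    """Apply *mutation* to *repeat_seq*, returning the mutant sequence and a
    monotone map from wild-type 1-based positions to mutant positions
    (``None`` for deleted positions)."""
    repeat_seq = validate_dna(repeat_seq)
    n = len(repeat_seq)
    m = mutation
    if m.kind == "substitution":
        end = m.start + len(m.bases) - 1
        if m.bases and not (1 <= m.start and end <= n):
            raise CoordinateError(
                f"substitution {m.start}..{end} outside repeat of length {n}")
        mutant = repeat_seq[: m.start - 1] + m.bases + repeat_seq[m.start - 1 + len(m.bases):] \
            if m.bases else repeat_seq
        coord_map: CoordMap = {i: i for i in range(1, n + 1)}
        return mutant, coord_map
    if m.kind == "insertion":
        if not m.bases:
            raise ValueError("insertion requires bases")
        if not (1 <= m.start <= n + 1):
            raise CoordinateError(f"insertion at {m.start} outside repeat of length {n}")
        k = len(m.bases)
        mutant = repeat_seq[: m.start - 1] + m.bases + repeat_seq[m.start - 1:]
        coord_map = {i: (i if i < m.start else i + k) for i in range(1, n + 1)}
        return mutant, coord_map
    # deletion
    if not (1 <= m.start <= m.end <= n):
        raise CoordinateError(f"deletion {m.start}..{m.end} outside repeat of length {n}")
    k = m.end - m.start + 1
    mutant = repeat_seq[: m.start - 1] + repeat_seq[m.end:]
    coord_map = {}
    for i in range(1, n + 1):
        if i < m.start:
            coord_map[i] = i
        elif i <= m.end:
            coord_map[i] = None
        else:
            coord_map[i] = i - k
    return mutant, coord_map


def invert_coord_map(coord_map: CoordMap) -> CoordMap:
    """Mutant-position -> wild-type-position map (inserted bases absent)."""
    return {v: k for k, v in coord_map.items() if v is not None}


def locate_ruler(repeat_seq: str, ruler: RulerElement = RulerElement()) -> Optional[int]:
    """1-based start of the leftmost exact ruler-motif occurrence at or
    downstream of the search floor, or ``None`` when the element is absent.

    The floor (default position 20) guards against spurious upstream motif
    copies; ruler elements sit just upstream of the RS junction.
    """
    repeat_seq = validate_dna(repeat_seq)
    idx = repeat_seq.find(ruler.motif, ruler.search_floor - 1)
    return idx + 1 if idx >= 0 else None


def predict_second_site(repeat_seq: str, ruler: RulerElement = RulerElement()) -> int:
    """Second (RS) integration site in the repeat's own 1-based frame.

    The attack lands ``ruler.offset`` bp downstream of the element's 5'
    border; for mutants the position is reported in mutant coordinates and
    may run past the repeat end into the downstream spacer.
    """
    start = locate_ruler(repeat_seq, ruler)
    if start is None:
        raise RulerDisruptedError(
            f"ruler motif {ruler.motif} not found at or after position "
            f"{ruler.search_floor}")
    return start + ruler.offset


def predict_first_site(locus: CrisprLocus) -> int:
    """First (LR) integration site: position 1 of the leader-proximal
    repeat, top strand. Invariant under repeat mutations."""
    return 1


@dataclass(frozen=True)
class IntegrationProduct:
    """A covalently joined strand produced by one attack."""

    event: IntegrationEvent
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def simulate_products(locus: CrisprLocus, prespacer: PreSpacer,
                      events: Iterable[IntegrationEvent]) -> List[IntegrationProduct]:
    """Joined strand sequences after each attack, for gel-size prediction.

    A "+" (LR-type) event joins the pre-spacer top strand to the target
    plus strand from the attacked base to its 3' end; a "-" (RS-type) event
    joins the bottom strand to the target minus strand analogously. Hairpin
    topologies continue through the loop into the connected strand;
    circular targets are linearised at the nick (one full pass).
    Chemistry is binary: a dideoxy 3' end never joins.
    """
    plus = locus.top_strand
    n = len(plus)
    products: List[IntegrationProduct] = []
    for ev in events:
        if ev.strand == "+":
            if prespacer.top_3p != "OH":
                raise BlockedEndError(
                    "top-strand (LR) attack requires a 3'-OH on the pre-spacer "
                    "top strand")
            if not (1 <= ev.site <= n):
                raise CoordinateError(f"site {ev.site} outside target of length {n}")
            tail = plus[ev.site - 1:]
            if locus.topology == "spacer-hairpin":
                tail = tail + locus.hairpin_loop + revcomp(plus)
            elif locus.topology == "plasmid-circular":
                tail = tail + plus[: ev.site - 1]
            products.append(IntegrationProduct(ev, prespacer.top_strand + tail))
        else:
            if prespacer.bottom_3p != "OH":
                raise BlockedEndError(
                    "bottom-strand (RS) attack requires a 3'-OH on the "
                    "pre-spacer bottom strand")
            if not (1 <= ev.site <= n):
                raise CoordinateError(f"site {ev.site} outside target of length {n}")
            tail = revcomp(plus[: ev.site])
            if locus.topology == "leader-hairpin":
                tail = tail + locus.hairpin_loop + plus
            elif locus.topology == "plasmid-circular":
                tail = tail + revcomp(plus[ev.site:])
            products.append(IntegrationProduct(ev, prespacer.bottom_strand + tail))
    return products


# Mutant panels studied by in vitro and in vivo mutagenesis of the repeat:
# single C insertions tiled across the repeat, single/multi-nt indels around
# the RS border, and the in vivo insertion/deletion set.
NAMED_MUTATIONS: Dict[str, RepeatMutation] = {
    "WT": RepeatMutation.substitution(1, ""),
    "InsC5": RepeatMutation.insertion(5, "C"),
    "InsC9": RepeatMutation.insertion(9, "C"),
    "InsC14": RepeatMutation.insertion(14, "C"),
    "InsC19": RepeatMutation.insertion(19, "C"),
    "InsC24": RepeatMutation.insertion(24, "C"),
    "InsC28": RepeatMutation.insertion(28, "C"),
    "InsC33": RepeatMutation.insertion(33, "C"),
    "InsC36": RepeatMutation.insertion(36, "C"),
    "Del14": RepeatMutation.deletion(14),
    "DelA23": RepeatMutation.deletion(23),
    "Ins36": RepeatMutation.insertion(36, "C"),
    "Ins36-37": RepeatMutation.insertion(36, "CC"),
    "Ins36-38": RepeatMutation.insertion(36, "CCC"),
    "Del35": RepeatMutation.deletion(35),
    "Del34-35": RepeatMutation.deletion(34, 35),
    "Del33-35": RepeatMutation.deletion(33, 35),
    "InsCG33-34": RepeatMutation.insertion(33, "CG"),
    "DelC33": RepeatMutation.deletion(33),
    "DelCA33-34": RepeatMutation.deletion(33, 34),
}
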