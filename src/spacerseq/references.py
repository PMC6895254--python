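"""Reference sequences and synthetic stand-in constructs.

Only the 36-bp consensus repeat of the *S. thermophilus* CRISPR1 locus is a
real biological sequence; it carries every feature the integration model
relies on: guanine at position 1 (LR attack, top strand), guanine at
position 36 on the bottom strand (RS attack), and the 5'-CTGTA-3' ruler
element at positions 28-32. The leader, spacers, pre-spacer core, plasmid
backbones and the host-genome surrogate are synthetic, deterministically
generated stand-ins (the study's plasmid/oligo sequences live in
unpublished supplementary material); they are seeded so every build of the
references is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

from .locus import CrisprLocus, PreSpacer
from .sequences import random_dna

#: Consensus repeat of the S. thermophilus CRISPR1 array (36 bp).
WT_REPEAT = "GTTTTTGTACTCTCAAGATTTAAGTAACTGTACAAC"

_LEADER_SEED = 20190301
_BACKBONE_SEED = 20190302
_GENOME_SEED = 20190303
_SPACER_SEED = 20190304

LEADER_LENGTH = 157


@lru_cache(maxsize=None)
def default_leader(length: int = LEADER_LENGTH) -> str:
    """Synthetic 157-bp leader stand-in (seeded, stable)."""
    rng = np.random.default_rng(_LEADER_SEED)
    return random_dna(rng, length)


@lru_cache(maxsize=None)
def default_spacers(n: int = 2, length: int = 30) -> Tuple[str, ...]:
    """Synthetic resident-array spacers."""
    rng = np.random.default_rng(_SPACER_SEED)
    return tuple(random_dna(rng, length) for _ in range(n))


@lru_cache(maxsize=None)
def default_prespacer() -> PreSpacer:
    """Synthetic stand-in for the phage-derived pre-spacer substrate:
    a 30-bp duplex core with 5-nt 3' overhangs on both strands."""
    rng = np.random.default_rng(20190305)
    core = random_dna(rng, 30)
    return PreSpacer.from_core(core, random_dna(rng, 5), random_dna(rng, 5))


@dataclass(frozen=True)
class LocusAnnotation:
    """Where the CRISPR array sits on a reference molecule.

    Coordinates are 1-based inclusive plus-strand positions.
    ``array_start`` is repeat position 1 of the leader-proximal repeat;
    ``lr_site``/``rs_site`` are the wild-type attack sites.
    """

    array_start: int
    array_end: int
    repeat_len: int
    leader_len: int

    @property
    def lr_site(self) -> int:
        return self.array_start

    @property
    def rs_site(self) -> int:
        return self.array_start + self.repeat_len - 1


def build_plasmid_locus(repeat: str = WT_REPEAT, n_units: int = 2,
                        leader: Optional[str] = None) -> CrisprLocus:
    """Plasmid-style locus: full-length leader + *n_units* repeat-spacer
    units (the first repeat may be a mutant)."""
    leader = leader if leader is not None else default_leader()
    spacers = default_spacers(n_units)
    units = tuple((repeat if i == 0 else WT_REPEAT, spacers[i])
                  for i in range(n_units))
    return CrisprLocus(leader, units, topology="plasmid-circular")


def build_minimal_linear_target(repeat: str = WT_REPEAT,
                                topology: str = "linear") -> CrisprLocus:
    """Minimal target used for in vitro integration: 10 bp of leader, a
    single repeat, and a single 20-bp spacer (66 nt for the WT repeat)."""
    rng = np.random.default_rng(20190306)
    spacer20 = random_dna(rng, 20)
    return CrisprLocus(default_leader()[-10:], ((repeat, spacer20),),
                       topology=topology)


def build_pcrispr(repeat: str = WT_REPEAT, backbone_len: int = 2500,
                  n_units: int = 2) -> Tuple[str, str, LocusAnnotation]:
    """Synthetic pCRISPR: random backbone followed by leader + array.

    Returns ``(name, plus_strand_sequence, annotation)``; the molecule is
    circular.
    """
    rng = np.random.default_rng(_BACKBONE_SEED)
    backbone = random_dna(rng, backbone_len)
    locus = build_plasmid_locus(repeat=repeat, n_units=n_units)
    seq = backbone + locus.top_strand
    array_start = backbone_len + len(locus.leader_seq) + 1
    ann = LocusAnnotation(array_start=array_start, array_end=len(seq),
                          repeat_len=len(repeat),
                          leader_len=len(locus.leader_seq))
    return "pCRISPR_synthetic", seq, ann


def build_pcontrol(length: int = 2800) -> Tuple[str, str]:
    """Synthetic pControl: a circular plasmid with no CRISPR array."""
    rng = np.random.default_rng(_BACKBONE_SEED + 1)
    return "pControl_synthetic", random_dna(rng, length)


def build_genome_surrogate(length: int = 20000,
                           seed: int = _GENOME_SEED) -> Tuple[str, str]:
    """Synthetic host-genome surrogate from which protospacers are drawn."""
    rng = np.random.default_rng(seed)
    return "genome_synthetic", random_dna(rng, length)
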