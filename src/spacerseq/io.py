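"""File-format plumbing: FASTA/FASTQ, TSV, bedGraph, and run configs.

FASTQ is written by a plain 4-line writer so that identical inputs produce
byte-identical files (a reproducibility invariant of the whole package);
FASTA goes through Biopython. bedGraph intervals are 0-based half-open
(genome-browser convention) while tabular reports use 1-based coordinates;
both say so in their headers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FastqRecord = Tuple[str, str, str]  # (id, sequence, quality)


class FormatError(ValueError):
    """Malformed record in an input file."""


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA as ``[(id, sequence), ...]``; duplicate IDs are an error."""
    records: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


def read_fastq(path) -> List[FastqRecord]:
    """Read 4-line FASTQ records, reporting the line number on malformed
    input."""
    records: List[FastqRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line {len(lines) + 1})")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i: i + 4]
        if not header.startswith("@"):
            raise FormatError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: line {i + 4}: quality length != sequence length")
        records.append((header[1:].split()[0], seq, qual))
    return records


def write_fastq(path, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_tsv(path, frame: pd.DataFrame, comment: str = "") -> None:
    """Write a DataFrame as TSV, with optional '#'-prefixed header comment."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bedgraph(path, chrom: str,
                   values: Dict[int, float], track_name: str = "coverage") -> None:
    """Write per-position values as bedGraph (0-based half-open intervals).

    *values* maps 1-based positions to values; adjacent equal values are
    merged into one interval.
    """
    items = sorted(values.items())
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        i = 0
        while i < len(items):
            pos, val = items[i]
            end = pos
            j = i + 1
            while j < len(items) and items[j][0] == end + 1 and items[j][1] == val:
                end = items[j][0]
                j += 1
            fh.write(f"{chrom}\t{pos - 1}\t{end}\t{val:g}\n")
            i = j


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one subcommand run; written next to outputs
    so identical configs reproduce identical results."""

    subcommand: str
    seed: int = 0
    params: dict = dataclasses.field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def load_locus_config(path) -> dict:
    """Key-value locus annotation config (YAML): leader/repeat/spacer
    sequences, ruler motif/offset, topology."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: locus config must be a mapping")
    return cfg
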