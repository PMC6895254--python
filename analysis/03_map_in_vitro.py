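#!/usr/bin/env python
"""Map the in vitro libraries back to their targets and profile the sites.

Reads the FASTQ files written by 02_simulate_libraries.py, locates the
pre-spacer in each read, aligns the downstream fragment, and tabulates
integration sites per strand. Writes per-site profiles (TSV + bedGraph)
and discard tallies under results/mapping/, and an event table consumed by
04_offtarget_context.py.
"""

from pathlib import Path

import pandas as pd

from spacerseq import build_profile, map_reads
from spacerseq.io import read_fastq, write_tsv
from spacerseq.references import (build_minimal_linear_target, build_pcrispr,
                                  default_prespacer)

LIB = Path(__file__).resolve().parent.parent / "results" / "libraries"
OUT = Path(__file__).resolve().parent.parent / "results" / "mapping"


def run(label, reads_path, reference, reference_id, circular):
    reads = [(rid, seq) for rid, seq, _ in read_fastq(reads_path)]
    events, tallies = map_reads(reads, reference, default_prespacer(),
                                circular=circular, reference_id=reference_id)
    profile = build_profile(events, tallies)
    profile.to_frame().to_csv(OUT / f"{label}.profile.tsv", sep="\t", index=False)
    profile.discard_frame().to_csv(OUT / f"{label}.discards.tsv", sep="\t",
                                   index=False)
    profile.write_bedgraph(OUT / label, chrom=reference_id)
    print(f"{label}: {len(events)} mapped, {sum(tallies.values())} discarded "
          f"({tallies})")
    return events


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    name, seq, _ = build_pcrispr()
    events = run("plasmid", LIB / "plasmid.fastq", seq, name, circular=True)
    pd.DataFrame(events).to_csv(OUT / "plasmid.events.tsv", sep="\t", index=False)

    target = build_minimal_linear_target()
    run("linear", LIB / "linear.fastq", target.top_strand, "linear_target",
        circular=False)


if __name__ == "__main__":
    main()
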