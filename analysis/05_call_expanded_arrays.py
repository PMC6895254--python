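#!/usr/bin/env python
"""Decode expanded-array reads and locate the repeat-spacer junction.

Runs the anchor/candidate/selection caller over the array library from
02_simulate_libraries.py, summarises junction positions and read
categories, and checks the calls against the simulator's ground truth.
Writes tables under results/arrays/.
"""

from pathlib import Path

import pandas as pd

from spacerseq import (build_plasmid_locus, call_reads, calls_to_frame,
                       modal_rs_position, summarize)
from spacerseq.io import read_fastq
from spacerseq.references import WT_REPEAT, build_genome_surrogate

LIB = Path(__file__).resolve().parent.parent / "results" / "libraries"
OUT = Path(__file__).resolve().parent.parent / "results" / "arrays"
SEED = 20240901  # matches 02_simulate_libraries.py


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus = build_plasmid_locus()
    genome = build_genome_surrogate(seed=SEED + 2)
    reads = [(rid, seq) for rid, seq, _ in read_fastq(LIB / "array.fastq")]

    calls = call_reads(reads, locus.leader_seq, WT_REPEAT, [genome])
    calls_to_frame(calls).to_csv(OUT / "calls.tsv", sep="\t", index=False)
    positions, categories = summarize(calls)
    positions.to_csv(OUT / "positions.tsv", sep="\t", index=False)
    categories.to_csv(OUT / "categories.tsv", sep="\t", index=False)

    truth = pd.read_csv(LIB / "array.truth.tsv", sep="\t", comment="#") \
        .set_index("read_id")["site"].to_dict()
    callable_calls = [c for c in calls if c.callable]
    correct = sum(c.rs_position == truth[c.read_id] for c in callable_calls)
    print(positions.to_string(index=False))
    print(categories.to_string(index=False))
    print(f"modal junction position: {modal_rs_position(calls)}")
    print(f"callable: {len(callable_calls)}/{len(calls)}, "
          f"correct vs ground truth: {correct}/{len(callable_calls)}")


if __name__ == "__main__":
    main()
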