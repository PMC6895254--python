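#!/usr/bin/env python
"""Simulate the three synthetic sequencing libraries used downstream.

Writes FASTQ reads plus ground-truth tables under results/libraries/:
  - plasmid: 100-bp reads from integration into the circular plasmid target
    (on-target LR/RS plus off-target events with the measured base weights)
  - linear:  junction-amplicon reads from the minimal linear target
  - array:   250-bp reads over expanded arrays at the wild-type locus
Seeds are fixed so all downstream scripts see identical inputs.
"""

from pathlib import Path

from spacerseq import (SiteDistribution, build_plasmid_locus, draw_spacer_pool,
                       predict_second_site, simulate_expanded_arrays,
                       simulate_linear_library, simulate_plasmid_library)
from spacerseq.references import (WT_REPEAT, build_genome_surrogate,
                                  build_minimal_linear_target, build_pcrispr,
                                  default_prespacer)

OUT = Path(__file__).resolve().parent.parent / "results" / "libraries"
N_READS = 2000
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prespacer = default_prespacer()

    name, seq, ann = build_pcrispr()
    plasmid = simulate_plasmid_library(
        name, seq, SiteDistribution(lr=0.4, rs=0.4, off_target=0.2),
        prespacer, N_READS, seed=SEED, annotation=ann)
    plasmid.write_fastq(OUT / "plasmid.fastq")
    plasmid.write_truth(OUT / "plasmid.truth.tsv")

    target = build_minimal_linear_target()
    linear = simulate_linear_library(target, SiteDistribution(lr=0.5, rs=0.5),
                                     prespacer, N_READS, seed=SEED + 1)
    linear.write_fastq(OUT / "linear.fastq")
    linear.write_truth(OUT / "linear.truth.tsv")

    locus = build_plasmid_locus()
    genome = build_genome_surrogate(seed=SEED + 2)
    site2 = predict_second_site(WT_REPEAT)
    dup_last = locus.top_strand[locus.repeat_start() - 1 + site2 - 1]
    pool = draw_spacer_pool(genome[1], 200, seed=SEED + 3,
                            forbidden_flank=dup_last)
    arrays = simulate_expanded_arrays(locus, pool, N_READS, seed=SEED + 4)
    arrays.write_fastq(OUT / "array.fastq")
    arrays.write_truth(OUT / "array.truth.tsv")

    for label, batch in [("plasmid", plasmid), ("linear", linear),
                         ("array", arrays)]:
        print(f"{label}: {len(batch)} reads, skipped {sum(batch.skipped.values())}")


if __name__ == "__main__":
    main()
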