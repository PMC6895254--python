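#!/usr/bin/env python
"""Characterise off-target integration sites on the plasmid target.

Partitions the mapped events from 03_map_in_vitro.py into on-array and
off-target sets, reports the attacked-base composition of the off-target
set, builds the +/-10 nt sequence-context matrix, and draws an
information-content profile. Writes tables and a PNG under
results/offtarget/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from spacerseq import base_composition, context_matrix, partition_sites
from spacerseq.references import build_pcrispr

MAPPING = Path(__file__).resolve().parent.parent / "results" / "mapping"
OUT = Path(__file__).resolve().parent.parent / "results" / "offtarget"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    name, seq, ann = build_pcrispr()
    events = pd.read_csv(MAPPING / "plasmid.events.tsv", sep="\t") \
        .to_dict("records")

    on, off = partition_sites(events, (ann.array_start, ann.array_end),
                              len(seq))
    print(f"{len(on)} on-array events, {len(off)} off-target events")

    comp = base_composition(off, seq)
    pd.DataFrame([dict(base=b, percent=100 * f) for b, f in comp.items()]) \
        .to_csv(OUT / "base_composition.tsv", sep="\t", index=False)
    print({b: f"{100 * f:.1f}%" for b, f in comp.items()})

    mat = context_matrix(off, seq, upstream=10, downstream=10, circular=True)
    mat.frequencies().to_csv(OUT / "context_frequencies.tsv", sep="\t")
    ic = mat.information_content()

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(ic.index, ic.values, color="steelblue")
    ax.set_xlabel("position relative to attacked base")
    ax.set_ylabel("information content (bits)")
    ax.set_title(f"off-target site context, n={mat.n_sites}")
    fig.tight_layout()
    fig.savefig(OUT / "context_information.png", dpi=120)
    print(f"central-position information: {ic.loc[0]:.3f} bits")


if __name__ == "__main__":
    main()
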