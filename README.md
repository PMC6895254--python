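# spacerseq

Modelling and read-level analysis of CRISPR spacer integration by the
Cas1–Cas2 integrase: a molecular-ruler model of the two
transesterification sites, synthetic sequencing libraries for three assay
designs, a self-contained k-mismatch aligner, an integration-site mapper,
off-target site characterisation, and a decoder for in vivo expanded
arrays.

## The problem

Cas1–Cas2 inserts a new spacer at the leader end of a CRISPR array in two
steps: the pre-spacer's top-strand 3′-OH attacks the plus strand at the
leader–repeat junction (repeat position 1), then the bottom-strand 3′-OH
attacks the minus strand at the repeat–spacer junction. In the 36-bp
wild-type repeat the second site is position 36 — but it is not measured
from the first site. A sequence element (5′-CTGTA-3′, wild-type positions
28–32) acts as a **molecular ruler**: the second site sits a fixed
`offset = 8` downstream of the element start,

```
second_site = element_start + offset        (1-based repeat coordinates)
```

so insertions/deletions upstream of the element shift the site with the
length change, while changes between the element and the junction, or
downstream of it, leave the site at 36. `spacerseq` implements this model,
simulates the sequencing readouts used to test it, and implements the
decoding procedures that recover integration sites from reads.

## Worked example

Predict the second integration site for a repeat carrying a C insertion
before position 24:

```bash
$ spacerseq predict-ruler -m InsC24
mutant  repeat_length  ruler_start  second_site
InsC24             37           29           37
```

The insertion pushes the ruler element from 28 to 29, and the predicted
site from 36 to 37 (mutant coordinates). A deletion of position 14 moves
it the other way:

```bash
$ spacerseq predict-ruler -m del:14
mutant  repeat_length  ruler_start  second_site
del:14             35           27           35
```

The same model is available from Python:

```python
from spacerseq import NAMED_MUTATIONS, apply_mutation, predict_second_site
from spacerseq.references import WT_REPEAT

mutant, coord_map = apply_mutation(WT_REPEAT, NAMED_MUTATIONS["InsC24"])
predict_second_site(mutant)   # -> 37
```

## Layout

- `src/spacerseq/` — the library: `locus` (ruler model, mutations,
  integration products), `simulate` (synthetic libraries + error model),
  `align` (best-stratum k-mismatch aligner), `mapping` (in vitro
  integration-site mapper and profiles), `offtarget` (site partitioning,
  base composition, context matrices), `arrays` (expanded-array junction
  caller), `io` (FASTA/FASTQ/TSV/bedGraph/config), `cli`.
- `analysis/` — numbered drivers reproducing the study figures as tables
  under `results/`: ruler predictions for the full mutant panel, library
  simulation, in vitro mapping, off-target context, expanded-array calls.
  Run them in order: `python analysis/01_predict_ruler_shifts.py`, etc.
- `tests/` — unit, property-based, and end-to-end tests, including
  randomized equivalence of the aligner against a brute-force oracle and
  simulator→decoder round trips with and without sequencing errors.
- `docs/methods.md` — model, assumptions, parameters, and limitations.

## Command-line interface

`spacerseq` exposes five subcommands: `predict-ruler`, `simulate`
(plasmid / linear / array libraries), `map` (in vitro reads → site
profiles), `offtarget` (composition + context matrices), and `call-array`
(expanded-array junction calls). Each writes its outputs plus a
`*.config.yaml` recording all parameters and seeds. See
`spacerseq <cmd> --help`.

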