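# Methods

This note records the model, the simulator design, the decoding
procedures, and the numerical choices behind `spacerseq`. Defaults quoted
here are the package defaults; all are overridable through function
arguments or CLI flags.

## 1. Locus model and the molecular ruler

A CRISPR locus is modelled as `leader + (repeat, spacer) x n_units` on the
top (plus) strand. The wild-type repeat is 36 bp. Spacer integration is a
two-step transesterification by the Cas1–Cas2 integrase:

1. **First site (LR junction).** The 3′-OH of the top strand of the
   incoming pre-spacer attacks the plus strand at repeat position 1
   (the leader–repeat boundary).
2. **Second site (RS junction).** The 3′-OH of the bottom strand attacks
   the minus strand opposite repeat position 36 (the repeat–spacer
   boundary) in the wild type.

The second site is not measured from the first. It is specified by a
**molecular ruler**: a 5′-CTGTA-3′ element whose leftmost occurrence at or
after position 20 of the repeat anchors the cut `offset = 8` positions
downstream of the element start (wild type: element at 28, site at
28 + 8 = 36). Consequences encoded by `predict_second_site`:

- Insertions or deletions strictly upstream of the element shift the
  element and the site together: a 1-bp insertion at position 24 moves the
  site to 37 (mutant coordinates); a 1-bp deletion moves it to 35.
- Changes at or downstream of position 33 (between element and cut, or
  past the cut) leave the site at 36 as long as the element is intact.
- If no intact element exists at or after the search floor,
  `RulerDisruptedError` is raised; no site is predicted.

Coordinates are 1-based throughout. `apply_mutation` returns both the
mutant sequence and an explicit wild-type→mutant coordinate map so that
predictions can be expressed in either frame; all reported mutant-panel
positions are in **mutant coordinates**.

The search floor (default 20) exists because the wild-type repeat contains
a TGTA at position 6; without a floor, a fortuitous upstream C created by
a mutation could produce a spurious earlier element. The floor encodes the
assumption that the functional element is the one in the 3′ half of the
repeat.

## 2. Pre-spacer and integration products

The pre-spacer substrate is a 30-bp duplex with 5-nt 3′ overhangs (35-nt
strands). Each 3′ end carries a chemistry flag, `OH` (attack-competent) or
`dd` (dideoxy-blocked). Half-site products use whichever end is
competent; a `dd/dd` substrate yields no products (`BlockedEndError`).
`simulate_products` emits joined single strands for each event, handling
four topologies: linear, circular plasmid (product linearised at the
nick), and the two hairpin-capped substrates (the product strand continues
through the loop into the complementary strand).

## 3. Synthetic libraries (the study conditions)

Three generators produce FASTQ-style reads with per-read ground truth.
All randomness comes from `numpy.random.default_rng(seed)`; a given seed
yields byte-identical output.

**Plasmid library** (default 100-bp reads). Each read is the integrated
pre-spacer strand followed by target sequence downstream of the
integration site on the attacked strand. Events are drawn from a
`SiteDistribution` over {LR, RS, off-target}. Off-target sites are sampled
uniformly among positions carrying a base drawn from the measured
attacked-base weights — G 56.5 %, A 22.1 %, C 13.7 %, T 7.7 % — with the
annotated array interval excluded, and strand chosen uniformly. The
plasmid is circular; reads may span the origin.

**Linear-target library.** Joined-product strands from the 66-bp minimal
linear target (10-nt leader + repeat + 20-nt spacer). LR events read out
on the top strand, RS events on the bottom strand; reads on the
non-selected strand are tallied as skipped rather than emitted.

**Expanded-array library** (default 250-bp reads). Reads of in vivo
expanded arrays: a leader tail (30 nt), the duplicated repeat copy — whose
length equals the second integration site in mutant coordinates — the new
spacer (27–33 bp drawn from a genome-derived pool), then the full repeat
and the old first spacer. Reads that cannot hold this layout are rejected
and tallied (`spacer_window_overflow`).

*Spacer-pool identifiability.* The decoder picks the longest
perfect-match candidate (section 5). If the genomic base 5′ of a sampled
protospacer happens to equal the last base of the duplicated repeat copy,
the (length + 1) candidate also matches perfectly and the longest-match
rule would systematically overcall by one (~25 % of random pool draws).
`draw_spacer_pool(forbidden_flank=...)` excludes such protospacers, making
ground truth well-defined. This is a property of the simulation design,
not a tuning of the caller.

**Error model.** `add_errors` applies uniform i.i.d. substitutions at the
given per-base rate (each errored base replaced by one of the three
alternatives uniformly). No indel or quality model is included; the
decoders are mismatch-tolerant but not gap-tolerant, matching the
substitution-dominated error profile of short-read amplicon sequencing.

## 4. Aligner

The k-mismatch aligner is written in-house because its exact semantics
are the point: it returns the complete best stratum — all placements, on
both strands, at the minimum Hamming distance ≤ `max_mismatches` (default
2). `N` matches nothing. Circular references are handled by doubling the
sequence and reducing offsets modulo the length. Implementation: exact
matches via `str.find` (the fast path for error-free data), mismatch
scans via a `numpy` sliding-window comparison. It is validated against a
pure-Python brute-force oracle by randomized equivalence tests.

## 5. Decoders

**In vitro mapper** (`map_reads`). Locate the pre-spacer strand in the
read (either strand; ≤2 mismatches; lower-mismatch strand wins), take up
to `window = 50` nt downstream, align it to the target, and call the site:
for a plus-strand hit the site is the 1-based position of the first
fragment base; for a minus-strand hit it is the plus-strand position
paired with the fragment start (offset + fragment length, reduced modulo
the length on circular targets). Reads are discarded — and tallied — as
`no_prespacer`, `short_fragment` (< 15 nt), `unaligned`, or `multimapped`
(ambiguous best stratum). Profiles report percent of mapped reads, either
raw or per-strand depth-normalised; bedGraph output uses the 0-based
half-open convention.

**Expanded-array caller** (`call_reads`). Anchor 1: the last 20 nt of the
leader (≤2 mismatches). Anchor 2: the repeat searched at or after
anchor 1 + repeat length, i.e. the *second* (original) repeat copy, since
the duplicated copy directly follows the leader. The 7 hypothetical
spacers are the 27–33-nt windows ending at anchor 2; the true spacer is
the **longest** candidate with a zero-mismatch match in the reference
genome (either strand). The repeat–spacer junction position is then
`anchor2 − spacer_length − anchor1`, the length of the duplicated copy,
in mutant repeat coordinates. Reads are categorised as `WT-site`
(position 36), `shifted-site`, `other`, or `uncallable` (missing anchors,
or an inter-anchor window smaller than `min_spacer − 3`, flagged
`unexpanded`; the 3-nt slack keeps shifted-site mutants with short
spacers callable).

## 6. Problem sizes and runtime

Defaults used in the analysis scripts: 2 000 reads per library. The
acceptance checks use 10 000 reads per library type and complete in well
under a minute per library on one CPU; the full test suite runs in ~30 s.
The headline-results script (`scripts/acceptance.py`) simulates 1 000
error-free expanded-array reads for the pipeline-level target.

## 7. Limitations

- Substitution-only error model; no indels, no quality scores, no PCR or
  coverage biases.
- Off-target placement depends only on the attacked base, not on wider
  sequence context; the context matrix of simulated data is therefore
  informative only at position 0.
- The ruler model is sequence-based; it does not model protein contacts,
  so mutations that preserve the CTGTA element are always predicted to
  use the canonical offset.
- The aligner is Hamming-only (no gaps), by design.
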