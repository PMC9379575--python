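# Methods

`vntrcall` detects two classes of variation in coding VNTRs (variable
number tandem repeats, motif length ≥ 6 bp) from short reads: diploid
motif-count genotypes for *short* loci (total length ≤ 140 bp) and
small intra-repeat insertions/deletions for *long* loci (≥ 300 bp).
This note records the model, the parameters that matter, the numerical
and design choices made where the design was genuinely open, and what
the synthetic evaluation does and does not demonstrate.

## The multi-motif profile HMM

A reference VNTR is first decomposed into motif *occurrences* by the
Viterbi path of a single-motif profile HMM built on the consensus
motif; occurrences with identical sequences share an integer label
`1..u` assigned in order of first appearance. Each of the `u` distinct
motifs, and each 150 bp flanking sequence, becomes a standard profile
HMM unit (Match/Insert/Delete states per column). The units are joined
into one model: Start fans out to the prefix-flank unit (probability
1/2) and to the motif units (1/(2u) each, split between the unit start
and its individual match columns so that reads beginning anywhere in
the region remain representable); every Motif-End state connects to
every Motif-Start, to the suffix flank, and to End; flank units have no
back-transition. The number of states is proportional to the summed
length of the distinct motifs plus the two flanks.

Transition and emission probabilities encode the strong conservation of
coding repeats:

| parameter | default | meaning |
|---|---|---|
| `match_to_match` | 0.9975 | Match → next Match |
| `ref_emission` | 0.996 | Match emits its reference base |
| `alt_event` | 0.00125 | each alternative transition (gap open, read-end exit) |
| `gap_extend` | 0.15 | Insert → Insert and Delete → Delete |

Non-reference emissions split the residual `(1 − 0.996)/3` equally over
the three other bases, so every emission row normalises exactly; the
nominal per-base values for the alternatives are retained. The Match
alternative mass towards deletions is split evenly between Delete entry
and a direct Match → End exit, so a read that ends mid-motif pays one
bounded exit penalty instead of a delete-chain traversal; without this
the parse of every read not ending on a motif boundary would be charged
as a long deletion.

Gaps are **affine**: opening an indel is rare (`alt_event`), but
extending one costs `gap_extend` per base. With a purely per-base gap
probability of 0.00125, a deletion of `s` bases costs ≈ 6.7·`s` nats,
which for `s` ≳ 15 exceeds the cost of simply mis-aligning a short read
tail — the parser would then systematically *absorb* large indels near
read ends and the caller would lose exactly the variants the method
exists for. The geometric extension (0.15 per base ≈ 1.9 nats) keeps
multi-base indel paths competitive while single-base errors remain as
improbable as before. Indel length distributions in tandem repeats are
heavily skewed to 1 bp with a long tail, which a geometric run-length
model captures qualitatively.

## Decoding: full and banded Viterbi

Both decoders run column by column over the read. Silent states
(Delete, unit boundaries, Start/End) are relaxed within a column along
one canonical edge order that realises a topological ordering: each
Motif-End first receives its emission-fed value, then the Motif-End →
Motif-Start back-transitions are relaxed once, then the delete chains,
then a second Motif-End update from its own delete chain that does not
re-enter other units. This permits one cross-unit hop (and at most one
whole-motif deletion per unit) per column and excludes degenerate
zero-emission cycles. Ties in the running maximum break towards the
earlier edge in the canonical order, making backtracking deterministic.

The full decoder fills the complete `n × (m+1)` table and is the
correctness oracle. The banded decoder relaxes the same edge sequence
but stores a cell only when its running score reaches a threshold τ;
reads whose final End-state score does not clear τ are reported as
`no_alignment`. Because both decoders relax the identical ordered edge
sequence, the banded score equals the full score whenever the optimum
itself exceeds τ (verified to 1e-9 on hundreds of random instances).

τ is derived from an explicit per-read budget: the score of an
idealised error-free parse of an `m` bp read — per-symbol match score
`m·(ln 0.9975 + ln 0.996)` *plus* the structural costs every real parse
pays (worst-case model entry, one Motif-End → Motif-Start transition per
motif copy spanned, inter-unit links, and the read-end exit) — minus
`δ` times the worst per-indel-transition penalty. `δ` defaults to half
the consensus motif length, which guarantees that reads carrying any
injectable indel (size < motif/2) are never pruned. Without the
structural terms the nominal threshold would prune perfectly clean
reads on short-motif loci, where a 150 bp read must pay dozens of
back-transition costs.

The explored fraction (stored cells over `n × (m+1)`) is tracked per
read. Note that with `δ = w/2` the indel budget covers every phase
shift within a motif, so the motif-unit block of the table is explored
nearly completely; the overall fraction is therefore governed by the
ratio of motif states to (mostly pruned) flank states and grows with
`u·w`. On loci with a single short motif the fraction is small; on the
multi-motif loci used in the evaluation (u ≥ 3) it is substantially
larger than the average over a realistic locus panel dominated by
single- and few-motif repeats.

## Reference label-order guidance

A mutation can convert one motif into (a copy of) another distinct
motif, making it invisible to the HMM. Each read's label string —
complete motif segments plus boundary fragments covering at least half
their motif — is aligned to the reference label order by a gap-free
local alignment over the label alphabet (+1 match, −1 mismatch, at most
one mismatch, ties broken towards the larger overlap; remaining ties
are reported ambiguous, not guessed). Reads emitting ≥ 10 bp of flank
sequence are pinned to the offset their anchor dictates. At aligned
positions the reference label replaces the parse label and, where they
disagree (or for boundary fragments), the substring is re-parsed
against the reference label's own single-motif HMM — with mid-motif
entry allowed for leading fragments — so the underlying substitution or
indel resurfaces. Re-parses showing more than `max_motif_mismatches`
(default 4) substitutions mark the segment hyper-variable; such
segments are excluded from indel evidence entirely, as mutation calls
inside hyper-variable motifs are unreliable.

## Mutation test

At a motif state covered by `d` informative reads with `i` observed
indel transitions, the statistic

    stat = −2 ln [ Binom(d, i, ε) / Binom(d, i, 1/(2u)) ]

compares the sequencing-error explanation (ε = 0.01 per-nucleotide
erroneous indel rate) against a heterozygous mutation in one of the
`u` reference occurrences of the motif; the binomial coefficients
cancel. `stat` is referred to the upper tail of χ² with one degree of
freedom (a simple-vs-simple ratio); the p-value is 1 whenever the null
fits at least as well, and calls additionally require `i ≥ 5`
supporting reads and nominal `p < 0.001`, one-sided (`i/d > ε`). No
multiplicity correction is applied, matching the nominal-p reporting
convention.

Evidence accounting, bottom-up:

* runs of adjacent Insert emissions / Delete columns within one read
  are merged into single multi-bp events during path segmentation;
* across reads, events of the same label, type and size within two
  columns are pooled (read frames jitter placement); single-base events
  pool only within one column, and the null rate ε is scaled by the
  number of pooled columns for single-base evidence, since i.i.d.
  error indels accumulate per column — without this the pooled test is
  anti-conservative;
* the same multi-bp (≥ 3 bp) event attributed to different similar
  motifs, and nearby fragments of one long insertion, are pooled under
  the best-supported label;
* an insertion between the flank and the bordering motif copy counts
  as an event at that copy's edge column;
* `d` counts *informative* copy traversals: segments spanning all of
  the event's columns with at least one event-length (12 bp for
  single-base events) of read context on each side — a read that could
  not have expressed the event is not evidence about it — and is capped
  by the physical read depth summed over the motif's occurrences, since
  any surplus in observed counts is label misattribution;
* single-base indel transitions closer than 12 bp to a read end are
  ignored (boundary re-synchronisation artifacts), mirroring standard
  read-edge masking in small-variant calling;
* on multi-motif loci, boundary fragments shorter than half their motif
  contribute evidence only from reads whose label string aligned — a
  short fragment cannot identify its motif on its own, and tie-broken
  labels would systematically inflate the coverage of low-index labels.

## Motif-count genotyping

Only reads anchored ≥ 10 bp in both flanks carry a complete motif
count (the number of Motif-End traversals of the parse). The diploid
pair (c₁ ≤ c₂) maximises a mixture likelihood over the count histogram
in which each read draws its allele with probability proportional to
that allele's *spanning window* (150 − allele length − two anchors) —
longer alleles are systematically under-sampled among spanning reads,
and an equal mixture would bias genotypes towards the shorter allele —
and then reports the allele's count up to a symmetric ±1 slippage error
(rate 0.01, floor 1e-4 for larger deviations). A uniform prior over
pairs is used; fewer than 3 spanning reads yields a no-call.

## Synthetic data

The generator emulates the structure of coding VNTRs:

* motif length log-uniform on 6–100 bp (catalogued repeat motifs are
  heavily skewed short); long-class total length uniform on 300–600 bp,
  short-class on 36–96 bp (short coding VNTRs cluster near 54 bp, and
  both alleles of a copy-number heterozygote must remain spannable by a
  150 bp read);
* the number of distinct motifs scales with copy number — one distinct
  variant per 1.5–3 copies, generated by 1–3 random substitutions of
  the consensus — reflecting substitution-scarred coding repeats; a
  locus with dozens of identical copies is both unrealistic for coding
  sequence and statistically undetectable under the 1/(2u) alternative;
* unique random 150 bp flanks; a MUC1-like preset uses 60 bp motifs at
  GC fraction 0.7 and exactly 25 copies;
* heterozygous mutations: an indel of size uniform on 1..⌈w/2⌉−1
  (strictly below half the motif length) at a uniform position for long
  loci, or a whole-copy gain/loss for short loci;
* single-end 150 bp reads at 30× total (15× per haplotype), uniform
  start positions, random strand, i.i.d. substitution errors at 0.001
  and single-base indel errors at 0.0001 (an internal sampler standing
  in for an external read simulator, with configurable rates), constant
  Q30 qualities. All randomness flows through one seeded generator;
  outputs are byte-identical under a fixed seed.

What this does **not** emulate: GC-dependent coverage dropout (real
MUC1 coverage is depressed), paired-end structure, quality-correlated
and context-dependent (homopolymer) errors, mapping-based read
recruitment from a whole genome, and reference motif compositions more
complex than substitution scars (e.g. rotated or length-variant
motifs). Passing results therefore demonstrate the correctness and
calibration of the parsing and testing machinery under idealised
sampling, not performance on real sequencing data.

## Evaluation scale

The built-in evaluation harnesses use desk-scale problem sizes: 30
loci × 10 replicates for long-locus indel detection, one MUC1-like
locus × 10 replicates, 20 multi-motif loci / ≥ 500 reads for the
search-space measurement, and 500 mutation-free loci for the type-I
error check. These sizes give binomial standard errors of about 0.5–3
percentage points on the reported rates.

## Known limitations

* Indels are located only as (motif label, state offset); the genomic
  coordinate within the repeat is intentionally not resolved, and VCF
  records use the locus start position.
* Motifs with many identical reference copies dilute the alternative
  hypothesis (carrier fraction 1/(2u)); when 1/(2u) approaches ε the
  test has no power, whatever the coverage.
* Indels of size close to w/2 in GC-rich repeats sit near the
  expressibility limit of 150 bp single-end reads: reads overlapping
  the event near their ends legitimately prefer a spurious re-alignment,
  so realised support falls below the binomial expectation and
  occasional misses remain.
* Substitutions are tracked only for hyper-variability masking, never
  reported as variants.
* The catalog similarity filter between a repeat and other repeats'
  flanking regions is not implemented; the catalog is taken as given.
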