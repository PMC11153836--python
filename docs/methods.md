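# Methods

## Coordinates and variant normalization

All internal coordinates are 0-based half-open. Conversion from 1-based
conventions happens exactly once, at parse time: VCF `POS` → `start = POS−1`;
VCF `INFO/END` (1-based inclusive) is used directly as the 0-based exclusive
`end`; AnnotSV `SV_start`/`SV_end` (1-based inclusive) become
`start = SV_start−1`, `end = SV_end`. When `END` and `SVLEN` are both present
and disagree, `END` wins (it is positional; `SVLEN` is derived) and a warning
is logged. A `<DUP>` without subtype is treated as a tandem duplication, the
convention of the SV callers whose abbreviations these tags follow.

Literal records classify as SNP (1 bp ref and alt) or indel; the
indel-vs-SV boundary is the community-standard 50 bp of net length change,
though the incorporation machinery is identical for literal alleles of any
size. Symbolic `<INS>` and `<CNV>`-like tags are *unsupported*: the
replacement sequence is not provided by upstream callers, so no faithful ALT
window can be built. Unsupported and malformed records (e.g. unpaired
breakends) are reported in the rejected TSV with a reason, never silently
dropped: `|kept| + |rejected|` always equals the input count.

Multi-allelic lines are split into independent variants, consistent with
one-at-a-time incorporation. Breakend mates pair by `MATEID` (or reciprocal
coordinates when absent) into a single canonical junction — the
lexicographically smaller breakend — so each novel adjacency is scored once.

## Window construction

The variant is anchored at the midpoint of its reference footprint
`[start, end)` and centered in a window of `seq_len` bases (`seq_len` must
be even so the center is well defined). Positive `shift` slides the window
right, which moves the variant left within the emitted sequence. Windows
are confined to a single chromosome arm: a window overhanging an arm end is
slid back inside (`clamped=True`) rather than truncated or N-padded, because
edge-adjacent model predictions degrade and padding would fabricate
sequence. When no arm table is supplied, each chromosome counts as one arm.
Every emitted sequence therefore has length exactly `seq_len` and consists
entirely of real genomic sequence; the variant's relative position is
reported per sequence because clamping and shifting move it.

The default maximum variant length is `floor(2·seq_len/3)`; longer variants
are rejected (`exceeds_limit`). Variant length is `|svlen|` for
length-changing types, `end − start` for inversions, and 0 for SNPs.

## ALT construction in edited-arm coordinates

Every non-BND variant reduces to one edit `(start, end, replacement)`:
SNP/indel splice the literal allele; DEL removes `[start, end)`; tandem DUP
replaces the span with two copies; INV with its reverse complement. The ALT
window is defined on the *edited arm* (the arm string with the edit applied)
and materialized by piecewise fetches, so memory stays O(seq_len) while
being provably equal to a naive whole-chromosome string edit followed by
window extraction — the test suite checks this equivalence byte-exactly on
fuzzed variants. Net length changes are absorbed by re-balancing the flanks
symmetrically (deletions borrow `|svlen|/2` extra bp per side, insertions
trim likewise), with the odd base taken from the right flank as a
deterministic tie-break. REF-allele mismatches against the genome warn
rather than abort, so synthetic or custom perturbations can be scored.

Reverse-complement output is applied last to all sequences of a pair, with
relative positions remapped to `seq_len − pos − footprint`.

## Breakend fusion

A breakend ALT `t[p[`, `t]p]`, `]p]t`, or `[p[t` selects which flank of the
local locus and which flank (and strand) of the mate locus fuse. The fused
ALT is `left_segment + inserted_bases + right_segment` with the junction at
`seq_len/2 − shift`. The two REF windows (local and mate) are defined as the
unique `seq_len` windows that agree base-for-base with the ALT on the
corresponding flank segment — reverse-complemented for orientations that
read the mate in reverse — so REF and ALT bins align exactly on each side
of the junction with no residual offset. `write_pairs` records the
forward-strand coordinates with an `rc` flag. If a flank would leave its
arm, the junction placement is adjusted to the nearest feasible offset
(`clamped=True`); an infeasible junction rejects the variant.

No published recipe exists for aligning breakend maps, so the comparison
scheme is this package's design: the ALT map's left-flank square block is
compared to the local REF map, the right-flank block to the mate REF map,
the junction-straddling bins and the inter-flank quadrants (which have no
REF counterpart) are excluded, and each metric is combined across the two
half comparisons weighted by their defined-entry counts.

## Map alignment and masking

A bin is variant-spanning if its half-open genomic interval intersects the
variant by ≥ 1 bp. For a deletion of *d* such bins, those bins are removed
from the REF map (the ALT genome never contained them) and *d* compensating
bins from the ALT map's edges — `d//2` left, the rest right, mirroring the
bp flank extension (mirrored again under reverse complement). Duplications
are the mirror image: the second copy's bins leave the ALT map, edge bins
leave the REF map. Balanced variants (SNPs, sub-bin indels, inversions)
remove nothing; masks are intersected. The aligned dimension is always
`map_dim − removed`, and in fully bin-aligned configurations the surviving
same-side flank entries of the toy predictor agree exactly. Sub-bin indel
flank shifts (< 1 bin) are tolerated without removal; at realistic bin
sizes (~2 kb) this is well below map resolution.

## Metrics

Thirteen metrics are registered; `mse` and `spearman` are the defaults.
All operate on the defined upper-triangle entries of the aligned pair:

| metric | definition |
| --- | --- |
| mse | mean squared difference |
| spearman | Spearman ρ (average ranks on ties) |
| pearson | Pearson r |
| mae | mean absolute difference |
| l2 | Euclidean norm of the difference |
| max_abs | maximum absolute difference |
| local_mse / local_spearman | same, restricted to ±8 bins of the variant |
| insulation_diff | mean \|Δ\| of 3-bin diamond-window insulation profiles |
| di_diff | mean \|Δ\| of a 3-bin directionality index |
| decay_diff | mean \|Δ\| of per-diagonal means (contact decay) |
| track_max | maximum of the disruption track |
| track_rank | normalized rank of the variant bin within the track |

Only the two defaults are canonical; the remaining eleven form a
replaceable registry covering the common map-comparison families
(global error, correlation, variant-local, insulation/directionality,
decay, track summaries). Error-type metrics read "higher = more
disruption"; correlation metrics are reported raw with polarity flagged in
`METRICS[...].higher_is_more_disruptive`, so a named statistic is never
silently transformed. Window constants (±8 local bins, 3-bin
insulation/DI windows) are fixed package choices, scaled to the toy map
sizes used in testing.

The disruption track is `t_i = mean over defined j of (ref[i,j] −
alt[i,j])²`; rows with no defined entries report 0.

## Augmentation

Scores may be averaged over an ordered list of (shift, revcomp)
augmentations; the default four-member spec is the unshifted window, ±1 bp
shifts, and the reverse complement. The reported value is the arithmetic
mean of per-augmentation values, which are retained. A failing augmentation
fails the variant rather than shrinking the mean, keeping means comparable
across perturbations.

## Toy predictor

`toy_predict` maps a sequence to a symmetric matrix
`values[i,j] = −|i−j|/n + f_i·f_j` for `|i−j| ≥ 2` (NaN inside the 2-bin
diagonal band), where `f_i` is the CG-dinucleotide count of bin *i* divided
by the bin size, with `cropped_bins` removed per edge. It is deterministic,
exactly local (an edit inside bin *k* touches only row/column *k*), and
revcomp-covariant (the map of a reverse-complemented input is the 180°
rotation of the original) — precisely the properties the masking,
alignment, and augmentation machinery need for exact tests. It emulates
nothing about real chromatin beyond distance decay plus a sequence-driven
outer-product term; in particular it cannot see substitutions that leave
per-bin CG counts unchanged, and it assigns breakends a score of zero
because all cross-junction signal lies in the excluded quadrants. Passing
tests therefore validate the *machinery* — coordinates, splicing, masking,
averaging, determinism — not any biological prediction; trained models plug
in behind the `PredictorSpec` contract (input length, bin size, cropped
bins) and must supply their own geometry.

## Problem sizes and numerical choices

Tests and the acceptance script run on seeded toy genomes of 10 kb + 6 kb
with windows of 300–512 bp, 32 bp bins, and 0–1 cropped bins — the smallest
geometry that exercises multi-bin SVs, cropping, and 16-bin maps. The
fuzzed oracle corpus is 500 variants. Scores are written with 10
significant digits; pipeline outputs are byte-identical across runs and
batch sizes, and the split (sequences, then score) and fused paths produce
identical score tables.

## Known limitations

- Symbolic insertions and CNVs are rejected by design (no sequence).
- Single (unpaired) breakends are rejected as malformed.
- One variant per output pair: no multi-variant haplotypes, no genotypes,
  no phasing, no multi-sample VCF support.
- Breakend flank alignment assumes the junction offset is bin-aligned after
  cropping (exact for the default centered placement); clamped breakend
  windows fall back to bin-floored alignment.
- The arm table is an input; no centromere annotation is bundled.
- No 2bit/bgzip genome support and no liftover.
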