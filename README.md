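# ismkit

**In silico mutagenesis for sequence-to-profile models: one-variant-at-a-time
sequence generation and 3D-genome disruption scoring.**

Sequence-based machine-learning models (Akita-class genome-folding networks,
expression and chromatin models) consume fixed-length DNA windows. Asking
"what does this variant do?" with such a model means building *two* windows —
one from the reference allele (REF) and one from the alternate allele (ALT) —
feeding both to the model, and comparing the predictions. Doing that
correctly is easy for a SNP and surprisingly hard for structural variants
(SVs): symbolic VCF alleles carry no literal sequence, deletions and
duplications change the sequence length (so windows must be re-balanced, and
predicted contact maps un-padded and masked before they are comparable),
breakends fuse two loci with four different bracket orientations, and models
are sensitive enough to window placement that scores should be averaged over
shifted and reverse-complemented inputs.

`ismkit` handles all of that for the variant classes whose sequence is
actually determined by the call: **SNPs, indels, DEL, DUP (tandem), INV, and
BND** rearrangements. Symbolic insertions and CNVs are classified
unsupported, because no caller provides their inserted sequence. Variants
are incorporated **one at a time** — never collapsed into a haplotype — so
every score is attributable to a single perturbation, and no phasing is
required.

## What it computes

For a variant *v* and window length *L* (`seq_len`):

- a REF window of exactly *L* bp centered on the variant midpoint (slid by
  `shift`, confined to one chromosome arm), and an ALT window of exactly
  *L* bp cut from the edited sequence with flanks re-balanced symmetrically;
- predicted contact maps `M_ref`, `M_alt` (square log(obs/exp) matrices) via
  any predictor implementing the `PredictorSpec` contract — a deterministic
  toy CG-content predictor ships for testing; trained models plug in behind
  the same seam;
- an aligned map pair: for a deletion of *d* bins, the *d* variant bins are
  removed from `M_ref` and *d* compensating edge bins from `M_alt`
  (mirrored for duplications), so homologous flanking bins compare
  index-for-index;
- disruption scores over the defined upper-triangle entries. Thirteen
  metrics are registered; defaults are

  `mse = mean((M_ref − M_alt)²)` and Spearman's ρ of the flattened
  defined entries;

- optionally, per-bin disruption tracks `t_i = mean_j (M_ref[i,j] −
  M_alt[i,j])²` and per-variant map dumps;
- optionally, scores averaged over augmentations (default: unshifted,
  ±1 bp shifts, reverse complement).

Input formats: VCF 4.1/4.2 (literal, symbolic, and bracketed BND alleles,
multi-allelic lines split), whitespace `txt`, BED-like TSV, and
AnnotSV-style TSV. All coordinates are normalized to 0-based half-open at
parse time.

## Worked example

Build a toy genome and a small VCF, then run the two subcommands:

```python
from ismkit import make_toy_genome
make_toy_genome({"chr1": 10000, "chr2": 6000}, seed=11, out_path="toy.fa")
```

with `variants.vcf` containing a SNP, a 100 bp deletion, an 80 bp tandem
duplication, and a breakend mate pair:

```
chr1  501   snp1  A  G             .  PASS  .
chr1  1001  del1  A  <DEL>         .  PASS  SVTYPE=DEL;END=1100
chr1  2001  dup1  T  <DUP:TANDEM>  .  PASS  SVTYPE=DUP;END=2080
chr1  4001  bndU  C  C[chr2:2001[  .  PASS  SVTYPE=BND;MATEID=bndV
chr2  2001  bndV  T  ]chr1:4001]T  .  PASS  SVTYPE=BND;MATEID=bndU
```

```sh
ismkit sequences --input variants.vcf --genome toy.fa --seq-len 384 --out-dir run
ismkit score     --input variants.vcf --genome toy.fa --seq-len 384 \
                 --augment default --out-dir run
```

`run/sequences.fa` holds one REF and one ALT record per variant (plus a
second REF window for the breakend mate locus), with the window, the
variant's relative position, shift, and strand encoded in each header:

```
>snp1|REF|chr1:308-692|relpos=192|shift=0|rc=0
GGGGAATGCCTGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACC...
```

`run/scores.tsv` (first three columns; the toy CG-content predictor is in
use here):

```
variant_id  mse           spearman
snp1        0             1
del1        0.08890987767 0.90675707
dup1        0.04785948065 0.7895313261
bndU        0             1
```

The deletion disrupts the predicted map most (high `mse`, depressed
Spearman), the duplication less so. The SNP scores zero because an A→G
substitution that neither creates nor destroys a CG dinucleotide is
invisible to the toy predictor's per-bin CG feature; the breakend scores
zero because the toy predictor is strictly local and the cross-junction
quadrants — where a real folding model would react — have no REF
counterpart and are excluded by construction. With a trained model plugged
in, those entries carry the biology.

## Layout

| module | role |
| --- | --- |
| `ismkit.reference_genome` | indexed FASTA access, chromosome-arm table, toy-genome generator |
| `ismkit.variant_io` | VCF/txt/BED-like/AnnotSV parsing, classification, length filter |
| `ismkit.mutator` | window construction, variant incorporation, breakend fusion, FASTA/TSV output |
| `ismkit.predictor` | predictor contract and deterministic toy contact-map predictor |
| `ismkit.scoring` | map alignment/masking, 13-metric registry, tracks, augmentation averaging |
| `ismkit.pipeline` / `ismkit.cli` | batched end-to-end runs, `ismkit sequences` / `ismkit score` |

See `docs/methods.md` for the model conventions, parameter semantics, and
design decisions.
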