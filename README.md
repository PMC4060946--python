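# wgaprof

Simulation and QC profiling of Illumina paired-end libraries built from
**whole-genome-amplified (WGA) DNA**.

Sequencing from femto- to nanogram DNA inputs — single cells, archived or
clinical material, individual small organisms — requires whole-genome
amplification before library construction, and amplification leaves
fingerprints in the reads: chimeric fragments, uneven coverage correlated
with repeat content, and library-construction biases such as GC enrichment
in mate-pair (long-insert) libraries.  `wgaprof` is for people who build or
consume such libraries and want to quantify these artifacts — and for
method developers who need a simulator with complete ground truth to test
detection and correction approaches against.

## What it models and measures

**Chimeras.**  Strand-displacement amplification (MDA/Phi29) produces two
chimera classes.  *Priming chimeras* join a segment `a` to a downstream,
reverse-complemented segment `c`, deleting the intervening `b`; in read
space they appear as pairs with both mates on the same strand ('→→'/'←←')
whose apparent insert spreads over the deletion scale.  *Fold-back
(inverted-duplication) products* carry the same sequence on both fragment
ends with one copy inverted; their read pairs are same-orientation mates
that **overlap**, with start-to-start distance peaked at 0 bp.  Because a
longer sequenced span is likelier to bridge the duplicated ends, the
wrong-orientation fraction grows with insert length — ~3 kb mate-pair
libraries show roughly an order of magnitude more of it than ~450 bp
libraries from the same amplified material.

**Pair taxonomy.**  Aligned pairs are classified under a fixed precedence
into `proper`, `duplicate`, `singleton`, `both_unmapped`,
`interchromosomal`, `same_orientation` (the chimera signature class),
`wrong_facing` (outies in short-insert, innies in long-insert libraries)
and `incorrect_insert`, with per-library conventions (inward facing,
≤600 bp, ≥80% aligned for short; outward, ≤100 kb, ≥50% for long).
Insert size is the outer span for opposite-strand pairs and the
start-to-start distance for same-orientation pairs — the statistic that
lets fully overlapping fold-back mates report ≈0.

**Coverage and bias.**  From proper, non-duplicate pairs the package
computes per-base depth; the evenness curve (quantile function of
normalized depth vs cumulative genome fraction, constant 1 for a perfectly
uniform library) with its deviation score `mean |depth/mean − 1|`; 10 kb
window tables of median coverage, GC and repeat content; Spearman
correlations of window coverage against tandem/inverted-repeat fractions
(the simulator's generative counterpart is a log-linear per-bin gain,
`gain = exp(β_t·t + β_i·i + β_g·(g−ḡ))`);
and read-GC distributions against the theoretical distribution of all
same-length genomic spans, summarized by a mean-GC shift.

**SNP-call concordance.**  A reference SNP set is intersected from two
unamplified replicates; each reference SNP's *fate* in amplified replicates
is classified as `no_low_coverage`, `not_called_same`,
`called_in_one_replicate` or `called_in_both_replicates`, and extra
amplified calls are cross-checked against the unamplified data.  A bundled
toy threshold caller demonstrates the dropout mechanism: thinning het-site
depth drives allele fractions from 0.5 and converts het calls to hom.

**Simulator.**  All of the above is exercised end-to-end by a simulator
that generates genomes with planted repeats (optionally GC-heterogeneous),
WGA fragment pools with both chimera mechanisms, and short/long libraries
with PCR duplicates, non-junction reads and circular contaminants —
emitting FASTQ, a truth-tagged SAM, a repeat BED and a truth table, all
byte-deterministic per seed.

## Worked example

```python
import wgaprof as w

spec = w.GenomeSpec(length=500_000, gc_target=0.36,
                    tandem_repeats=((25, 40, 40),),
                    inverted_repeats=((2000, 200, 10),),
                    arm_cluster_fraction=0.7, seed=1)
genome = w.generate_genome(spec)
gain = w.amplification_gain(genome, w.BiasModel(beta_tandem=-2.0))
frags = w.simulate_fragments(genome, gain, 3000,
                             p_priming=0.03, p_inverted_dup=0.05, seed=2)
lib = w.simulate_short_library(frags,
                               w.LibraryParams.short(n_pairs=50_000, seed=3))

conv = w.LibraryConvention.short()
summary = w.summarize_library(lib.frame, conv)
sig = w.chimera_signature(lib.frame, conv, read_length=100,
                          genome_length=len(genome))
track = w.depth_from_alignments(lib.frame, conv, len(genome))
curve = w.evenness_curve(track)
corr = w.repeat_coverage_correlation(w.window_stats(track, genome))
```

which prints (formatted):

```
proper pairs:            99.52% of reads
same-orientation pairs:  0.37% of reads
truth chimeric pairs:    0.39%
median insert (proper):  450 bp
mate-overlap fraction:   0.68
mean depth:              19.9x
evenness deviation:      0.230
rho(coverage, tandem):   -0.56  (p = 2.3e-05)
```

Reading this: the classifier recovers the simulated chimeric-pair rate
(0.37% vs 0.39% truth) from orientation alone; most same-orientation mates
overlap (0.68), the fold-back hallmark; the repeat-suppressing gain
(`beta_tandem = −2`) produces a significantly negative coverage–tandem
correlation across 10 kb windows and inflates the evenness deviation above
what Poisson sampling alone would give at this depth (≈0.18 at 20×).

The same stages run from the shell:

```bash
wga sim --genome-spec spec.json --library short --n-pairs 50000 \
    --p-inverted-dup 0.05 --p-priming 0.03 --seed 1 --out sim/run
wga classify --sam sim/run.truth.sam --library short --out sim/cls
wga coverage --sam sim/run.truth.sam --fasta sim/run.genome.fasta \
    --repeats sim/run.repeats.bed --out sim/cov
wga snp-fates --unamp1 u1.vcf --unamp2 u2.vcf --amp1 a1.vcf --out sim/fates
wga run --config run.yaml        # full pipeline from one config
```

`wga classify` and `wga coverage` accept any coordinate-complete SAM/BAM,
so real alignments can be profiled with the identical code paths.

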