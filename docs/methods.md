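# Methods

`wgaprof` models the error and bias structure of Illumina paired-end
sequencing from whole-genome-amplified (WGA) DNA, in particular from
multiple displacement amplification (MDA) with the strand-displacing Phi29
polymerase.  It has two halves: a generative half (synthetic genomes, WGA
fragment pools, short- and long-insert libraries with complete truth
records) and an analysis half (read-pair taxonomy, coverage-evenness and
bias profiling, SNP-call concordance).  The generative half exists so that
every analysis can be validated against known truth; this note records the
models, their assumptions, and what passing the synthetic benchmarks does
and does not establish about real data.

## Synthetic genomes

A genome is an i.i.d. nucleotide sequence at a target GC fraction (default
0.36, typical of AT-rich nematode genomes) with two kinds of repeats planted
on top and recorded as truth features:

* **tandem repeats** — a random unit of `unit_length` bases copied
  `copy_number` times;
* **inverted repeats** — an arm, a spacer, and the arm's reverse
  complement.

`arm_cluster_fraction` confines that fraction of repeat instances to the
terminal thirds of the sequence, reproducing the clustering of repetitive
sequence on autosome arms that makes amplification bias visibly
chromosome-patterned.  Placement is rejection-sampled without overlap.

Optionally, the background GC probability is drawn per block
(`gc_sd`, `gc_block`; default off).  This matters for GC-bias experiments:
an i.i.d. sequence has only binomial window-to-window GC variance
(s.d. ≈ 0.005 at 10 kb), far below the few-percent variation of real
genomes — even ones whose *average* GC is nearly uniform — so without block
heterogeneity a window-scale GC bias has nothing measurable to act on.

What the generator does **not** emulate: real repeat families (it plants
random units, not biologically derived motifs), homopolymer/GGC-motif
dropout, chromatin-correlated structure, and multi-chromosome genomes.
Conclusions about those features cannot be drawn from these benchmarks.

## Amplification gain

Amplification bias is encoded as a log-linear gain per genome bin
(default 1 kb):

    gain(bin) = exp(β_t·t + β_i·i + β_g·(g − ḡ))

with `t`, `i`, `g` the bin's tandem, inverted and GC fractions and `ḡ` the
genome mean GC, normalized to mean 1.  Fragment start positions are sampled
proportionally to gain × bin length.  The exponential form is a convenience:
only the *sign* and *detectability* of the induced coverage correlations are
treated as meaningful, matching how such biases are reported (Spearman rank
correlations of window coverage against repeat/GC content).  Negative
`β_t`/`β_i` emulate Phi29-style repeat suppression; a positive `β_i`
emulates the primase-based (Rapisome-like) protocols whose coverage rises
with inverted-repeat content; positive `β_g` emulates the GC enrichment of
long-insert library construction.

Because fragments are 5–20 kb, bin-scale gain variation is smoothed by
roughly a fragment length before it reaches read coverage; effects are
therefore calibrated (and should be interpreted) at the 10 kb window scale.

## WGA fragments and chimera mechanisms

Fragments carry a *segment map* — an ordered list of
`(length, genome_start, strand)` pieces — from which both the sequence and
the true origin of any sub-window derive exactly.  Three mechanisms:

* **normal** — one contiguous forward piece; lengths log-uniform 5–20 kb by
  default (MDA products run well past 10 kb).
* **priming chimera** — re-priming from a displaced 3′ terminus: segment
  *a* joined to a downstream segment *c* copied in reverse complement, with
  the intervening segment *b* (log-uniform 100 bp – 20 kb by default)
  deleted.  In read space this produces same-orientation pairs whose
  apparent insert spreads over the deletion-length scale.
* **inverted duplication (fold-back)** — the displaced strand anneals back
  on itself: the fragment begins with a long arm `s` and ends with
  `revcomp(s)`, separated by a short turnaround loop (20–80 bp of
  contiguous downstream genomic sequence, standing in for the unknown
  junction sequence so that interior reads map normally).  Arms are
  log-uniform 2.5–10 kb, i.e. fold-back products sit on the same length
  scale as normal products.

Per-mechanism probabilities are free parameters of the experiment, not
estimates; the canonical benchmarks use 3% priming and 5% fold-back, which
put short-library wrong-orientation rates in the sub-percent-to-few-percent
range characteristic of amplified libraries.

### Shearing fold-back products: the mirrored-cut model

This is the package's most consequential modeling decision.  A fold-back
product is physically a *folded duplex*: the two palindromic arms are
base-paired, with the loop at one end.  Mechanical shearing cuts the folded
molecule at a physical point, so a piece containing the loop, once
linearized, is a palindrome whose two ends come from the *same* cut — i.e.
the same genomic coordinate, up to end-repair slop.  The simulator
implements exactly that: a shear window overlapping the loop is emitted
with mirror-symmetric cut points about the apex plus a Gaussian end-repair
jitter (s.d. 25 bp); windows on either side of the loop are ordinary
genomic inserts.  The probability that a window of length `I` contains the
loop grows with `I` (≈ `I/L` for fragment length `L`), which by itself
yields both observed hallmarks:

* end-bridging pairs map to the same locus on the same strand with
  start-to-start distance peaked at 0 (mates overlap);
* the wrong-orientation fraction rises with the sequenced span (3 kb
  mate-pair libraries recover roughly an order of magnitude more
  same-orientation pairs than 450 bp libraries from the same pool).

The alternative — shearing the linearized palindrome uniformly with
independent cut points — was rejected because it is inconsistent with the
physics and with observation: it predicts start-to-start distances roughly
uniform on `[0, I − 2·read_length]`, i.e. only ~40% of bridging pairs
overlapping at 450 bp inserts and ~4% at 3 kb, rather than a sharp peak at
zero in both.

## Libraries

* **short** (450 ± 45 bp default): an insert is sheared from a
  gain-weighted fragment, mates read inward.
* **long** (3000 ± 300 bp default): the two ends of a ~3 kb span are read
  outward (circularization).  Two construction artifacts are injected at
  configurable rates: *non-junction* pairs (reads from a circle segment
  lacking the junction adaptor — short, inward-facing, the "innies" of
  long-library QC; insert ~N(450, 50)) and *circular contaminants*
  (circles that escaped the 1.5 kb size selection — correctly
  outward-facing but with inserts below 1.5 kb, drawn ~N(800, 250)
  truncated to <1500; they surface as a bump in the proper-pair insert
  distribution rather than as an improper category).

PCR duplicates re-emit a previously emitted pair verbatim (truth copied,
artifact class `pcr_duplicate`).  The error model is uniform substitutions
only, applied at FASTQ writing; qualities are constant (no quality model,
since trimming is out of scope).  Reads that straddle a chimeric junction
are recorded with the majority segment as their origin and a proportionally
reduced aligned fraction, mimicking a soft-clipped alignment.

Truth is emitted three ways, all consistent by construction: a pair frame
(TSV), a truth SAM whose per-mate tags carry mechanism, artifact class,
aligned fraction and a bridging flag, and FASTQ mate files.  Identical
parameters and seeds give byte-identical outputs.

## Pair taxonomy

Pairs are classified with a fixed precedence (first match wins):

    both_unmapped → singleton → duplicate → interchromosomal →
    same_orientation → wrong_facing → incorrect_insert → proper

Conventions per library type: inward facing, ≤600 bp inserts, ≥80% of the
read aligned (short); outward facing, ≤100 kb, ≥50% (long).  A mate below
the aligned-fraction filter counts as unmapped.  The precedence order is
not canonical in the field; it is fixed so the categories partition, with
duplicates removed before the orientation classes so duplicate chimeras are
not double-counted.

Insert size is the outer span (mates included) for opposite-strand pairs.
For same-orientation pairs the **start-to-start distance** is used instead:
an outer span floors at one read length and cannot express the
fully-overlapping-mates signature, whereas start-to-start reports ≈0 for a
fold-back pair.  This choice is deliberate and divergence-sensitive —
any comparison with other toolkits must account for it.

Duplicate marking is by exact mapped coordinates of both mates
(order-insensitive), keeping the first pair in input order — deterministic
without base qualities.  Facing ties (equal starts) resolve by end
coordinate; identical intervals on opposite strands count as inward.

## Coverage profiling

Depth counts each aligned base of each *proper*, non-duplicate mate.  The
evenness curve is the empirical quantile function of normalized (mean-1)
per-base depth against cumulative genome fraction; its deviation score is
the area between the curve and the constant-1 line, i.e.
`mean |depth/mean − 1|`, zero iff coverage is constant.

A floor on this score exists for any finite-depth sampler: at mean depth μ
the per-base depth is marginally ~Poisson(μ), so the deviation cannot fall
below `E|Poisson(μ)/μ − 1| ≈ sqrt(2/(πμ))` — about 0.146 at 30×.
Simulated genomes add a chromosome-end taper (fragments cannot overhang the
ends), bringing a 200 kb genome at 30× to ≈0.19.  Deviation scores are
therefore only comparable *between* libraries at matched depth — which is
how they are used here (biased vs unbiased at equal depth) — not against an
absolute smallness threshold.

Window statistics use 10 kb non-overlapping windows: median depth
(normalized by the mean of full-window medians), GC, and
tandem/inverted-repeat covered fractions; trailing partial windows are kept
but flagged and excluded from normalization and correlations.  Correlations
are Spearman (midrank ties), with the t-approximation for n > 30 and a
seeded 10 000-draw permutation null otherwise.

Read-GC distributions are computed on *reference spans* of mapped reads
(1% bins), against the theoretical distribution of read-length windows at
every genomic position; computing GC on the reference rather than the read
sequence keeps the comparison independent of the error model.  The shift
statistic is observed minus theoretical mean GC.  The short-vs-long
comparison takes the per-window normalized coverage difference
(long − short) on a shared grid and correlates it with window GC.

## SNP-call concordance

The reference set is the intersection of two unamplified replicates
(identical alt allele *and* zygosity).  Fates in amplified replicates, in
rule order: `no_low_coverage` (uncalled, depth < 5 in every amplified
replicate — the threshold matches the caller's minimum-coverage setting and
is configurable; it is a category rule, distinct from the empirical
observation that most dropouts sit at depth ≤2), `not_called_same`
(different allele or zygosity anywhere, or uncalled despite adequate depth
everywhere), `called_in_both`, `called_in_one`.  With a single amplified
replicate, called-in-both is reported as not applicable.  The
low-coverage test requires *all* available replicates to be under
threshold; this is a documented choice, configurable via the depth
accessors.  Extra calls (absent from the reference set) are classified by
their status in the unamplified data.  Indels and multiallelic records are
excluded throughout.

A deliberately naive allele-fraction threshold caller (het at ≥0.2, hom at
≥0.8, minimum depth 5) ships for the dropout benchmark only: thinning het
sites binomially drives allele fractions away from 0.5 and converts het
calls into hom calls, the mechanism behind under-called heterozygotes in
amplified libraries.  It is not part of the analysis path and is no
substitute for a genotype-likelihood caller.

## Canonical experiments and problem sizes

`wgaprof.experiments` fixes the benchmark conditions (also used by
`scripts/acceptance.py`): a 200 kb genome with 50 000 short pairs for
chimera recovery; 20 replicates of 5 000 pairs each for the short-vs-long
comparison; 30× depth on 200 kb for evenness; a 5 Mb genome (500 full
10 kb windows, 75 000 pairs, ~3× depth) for repeat correlations; a 2 Mb
GC-heterogeneous genome with 25 000 long pairs for GC bias; and 800 het
sites at 30× base depth for the dropout curve.  These sizes make every
signature statistically decisive (permutation/binomial margins well beyond
their thresholds) while each experiment completes in seconds on one core.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally, 1-based in SAM, 0-based
half-open in BED.  All randomness flows through `numpy` Generators from
explicit seeds; the pipeline derives per-stage seeds from one master seed.
Empty inputs (no fragments, no proper pairs, all-zero depth, <10 full
windows, mismatched window grids) raise `ValueError` rather than returning
degenerate numbers; undefined correlations (a constant variable) are
reported as `None`.  Inserts are truncated below at one read length;
fragments too short for a requested span trigger resampling from eligible
fragments and an error if none exists.

## Known limitations

No aligner is modeled: classification operates on truth alignments (or any
externally produced SAM/BAM), so mapping ambiguity in repeats — a real
confounder of repeat-coverage correlations — is absent.  No indel or
structural error model; no base-quality model; no amplicon-length decay or
branching model of MDA beyond the two chimera mechanisms; single-chromosome
genomes (interchromosomal pairs arise only in hand-built inputs).  The
fold-back mirrored-cut model treats the loop as fully intact through
shearing; partial loop degradation would broaden the zero-distance peak.
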