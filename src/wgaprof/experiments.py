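"""Canonical synthetic experiments reproducing the study's QC signatures.

Each function builds a self-contained simulation at fixed study conditions
(genome composition, chimera rates, library sizes), runs the corresponding
analysis, and returns the measured quantities.  They are the package's
benchmark scenarios: chimera-rate recovery, the near-zero insert signature
of fold-back chimeras, the insert-length dependence of chimera counts,
coverage evenness under amplification bias, repeat-content coverage
correlations, GC bias of long-insert libraries, and het-SNP dropout under
depth thinning.
"""

from __future__ import annotations

import numpy as np

from . import coverage as cov
from .bias import BiasModel, amplification_gain
from .fragments import log_uniform, simulate_fragments
from .genome import GenomeSpec, generate_genome
from .libraries import LibraryParams, simulate_library
from .pairs import (LibraryConvention, PairCategory, classify_frame,
                    insert_sizes_frame)
from .variants import (HET, NOT_CALLED_SAME, VariantCall, classify_fates,
                       threshold_caller)

SHORT_CONV = LibraryConvention.short()
LONG_CONV = LibraryConvention.long()

# Chimera rates used throughout: free parameters of the fragment pool, set
# to produce short-library wrong-orientation percentages in the few-tenths
# to few-percent range seen in amplified libraries.
P_PRIMING = 0.03
P_INVERTED_DUP = 0.05
DELETION_DIST = log_uniform(1_000, 20_000)


def _seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def chimera_recovery(seed: int = 0, n_pairs: int = 50_000,
                     genome_length: int = 200_000, n_fragments: int = 3_000):
    """Short-insert run with both chimera mechanisms at known rates.

    Returns truth and classifier-recovered same-orientation fractions plus
    the insert-size signature split by source mechanism.
    """
    s1, s2, s3 = _seeds(seed, 3)
    genome = generate_genome(GenomeSpec(length=genome_length, seed=s1))
    gain = amplification_gain(genome, BiasModel())
    frags = simulate_fragments(genome, gain, n_fragments,
                               p_priming=P_PRIMING,
                               p_inverted_dup=P_INVERTED_DUP,
                               deletion_len_dist=DELETION_DIST, seed=s2)
    lib = simulate_library(frags, LibraryParams.short(
        n_pairs=n_pairs, error_rate=0.0, seed=s3))
    frame = lib.frame
    cats = classify_frame(frame, SHORT_CONV)
    so = cats == PairCategory.SAME_ORIENTATION.value
    rl = lib.params.read_length

    sub = frame.loc[so]
    ins = insert_sizes_frame(sub)
    inv = (sub["mechanism"] == "inverted_dup").to_numpy()
    prim = (sub["mechanism"] == "priming_chimera").to_numpy()
    return {
        "n_pairs": n_pairs,
        "read_length": rl,
        "truth_fraction": float(frame["bridging"].mean()),
        "classified_fraction": float(so.mean()),
        "invdup_n": int(inv.sum()),
        "invdup_frac_insert_leq_read_length":
            float((ins[inv] <= rl).mean()) if inv.any() else float("nan"),
        "priming_n": int(prim.sum()),
        "priming_median_insert":
            float(np.median(ins[prim])) if prim.any() else float("nan"),
    }


def length_monotonicity(seed: int = 0, n_replicates: int = 20,
                        n_pairs: int = 5_000, genome_length: int = 200_000,
                        n_fragments: int = 2_000):
    """Same fragment pool sequenced as 450 bp and 3 kb libraries.

    Longer sequenced spans are likelier to bridge a fold-back junction or a
    priming join, so the same-orientation fraction should rise with insert
    length.  Returns per-replicate (short, long) fraction pairs.
    """
    out = []
    for s in _seeds(seed, n_replicates):
        s1, s2, s3 = _seeds(s, 3)
        genome = generate_genome(GenomeSpec(length=genome_length, seed=s1))
        gain = amplification_gain(genome, BiasModel())
        frags = simulate_fragments(genome, gain, n_fragments,
                                   p_priming=P_PRIMING,
                                   p_inverted_dup=P_INVERTED_DUP,
                                   deletion_len_dist=DELETION_DIST, seed=s2)
        fracs = []
        for maker, conv in ((LibraryParams.short, SHORT_CONV),
                            (LibraryParams.long, LONG_CONV)):
            lib = simulate_library(frags, maker(n_pairs=n_pairs, seed=s3))
            cats = classify_frame(lib.frame, conv)
            fracs.append(float(
                (cats == PairCategory.SAME_ORIENTATION.value).mean()))
        out.append(tuple(fracs))
    return out


_EVENNESS_GENOME = dict(length=200_000, gc_target=0.36,
                        tandem_repeats=((25, 80, 20),),
                        arm_cluster_fraction=0.5)


def evenness_experiment(seed: int = 0, depth: float = 30.0,
                        n_fragments: int = 4_000, beta_tandem: float = -2.0):
    """Evenness deviation of an unbiased vs a repeat-biased library at the
    given mean read depth.  Returns (deviation_unbiased, deviation_biased).
    """
    s1, s2, s3 = _seeds(seed, 3)
    genome = generate_genome(GenomeSpec(seed=s1, **_EVENNESS_GENOME))
    n_pairs = int(depth * len(genome) / 200)   # 2 mates x 100 bp
    devs = []
    for beta in (0.0, beta_tandem):
        gain = amplification_gain(genome, BiasModel(beta_tandem=beta))
        frags = simulate_fragments(genome, gain, n_fragments, seed=s2)
        lib = simulate_library(frags, LibraryParams.short(
            n_pairs=n_pairs, seed=s3))
        track = cov.depth_from_alignments(lib.frame, SHORT_CONV, len(genome))
        devs.append(cov.evenness_curve(track).deviation)
    return tuple(devs)


_WINDOW_GENOME = dict(length=5_000_000, gc_target=0.36,
                      tandem_repeats=((25, 80, 150),),
                      inverted_repeats=((2_000, 200, 120),),
                      arm_cluster_fraction=0.7)


def repeat_correlation_experiment(seed: int = 0, beta_tandem: float = 0.0,
                                  beta_inverted: float = 0.0,
                                  n_fragments: int = 8_000,
                                  n_pairs: int = 75_000):
    """500-window coverage-vs-repeat-content correlation experiment.

    Simulates a short-insert library over a 5 Mb genome under the given
    bias coefficients and returns the Spearman correlations of normalized
    10 kb window coverage against tandem and inverted repeat fractions.
    """
    s1, s2, s3 = _seeds(seed, 3)
    genome = generate_genome(GenomeSpec(seed=s1, **_WINDOW_GENOME))
    gain = amplification_gain(genome, BiasModel(beta_tandem=beta_tandem,
                                                beta_inverted=beta_inverted))
    frags = simulate_fragments(genome, gain, n_fragments, seed=s2)
    lib = simulate_library(frags, LibraryParams.short(n_pairs=n_pairs,
                                                      seed=s3))
    track = cov.depth_from_alignments(lib.frame, SHORT_CONV, len(genome))
    table = cov.window_stats(track, genome)
    res = cov.repeat_coverage_correlation(table, seed=s3)
    res["n_windows"] = int((~table["partial"]).sum())
    return res


_GC_GENOME = dict(length=2_000_000, gc_target=0.36, gc_sd=0.04,
                  gc_block=20_000)


def gc_bias_experiment(seed: int = 0, beta_gc: float = 8.0,
                       n_fragments: int = 20_000, n_pairs: int = 25_000):
    """Long-insert GC-bias experiment on a GC-heterogeneous genome.

    Returns the observed-minus-theoretical mean read GC shift (positive
    under a GC-favoring amplification/construction bias).  ``n_pairs``
    pairs give 2 x n_pairs mapped reads.
    """
    s1, s2, s3 = _seeds(seed, 3)
    genome = generate_genome(GenomeSpec(seed=s1, **_GC_GENOME))
    gain = amplification_gain(genome, BiasModel(beta_gc=beta_gc))
    frags = simulate_fragments(genome, gain, n_fragments, seed=s2)
    lib = simulate_library(frags, LibraryParams.long(n_pairs=n_pairs,
                                                     seed=s3))
    dist = cov.read_gc_distribution(lib.frame, genome,
                                    lib.params.read_length)
    return {"shift": dist.shift, "n_reads": 2 * n_pairs}


def dropout_experiment(seed: int = 0, n_sites: int = 800,
                       base_depth: int = 30,
                       keep_fractions=(1.0, 0.4, 0.15)):
    """Het-SNP dropout under binomial depth thinning.

    Reference het sites are re-called by a simple allele-fraction threshold
    caller after thinning reads to each keep fraction; returns the
    miscalled-het (not-called-the-same) rate per thinning level.
    """
    rng = np.random.default_rng(seed)
    ref = {}
    alt_counts = {}
    for i in range(n_sites):
        pos = 10 * (i + 1)
        ref[("chr1", pos)] = VariantCall("chr1", pos, "A", "T", HET,
                                         base_depth)
        alt_counts[pos] = int(rng.binomial(base_depth, 0.5))
    rates = []
    for keep in keep_fractions:
        sites = []
        for (chrom, pos), c in ref.items():
            d = int(rng.binomial(base_depth, keep))
            a = (int(rng.hypergeometric(alt_counts[pos],
                                        base_depth - alt_counts[pos], d))
                 if d else 0)
            sites.append((chrom, pos, "A", "T", d, a))
        amp = threshold_caller(sites)
        amp.depth_of = lambda c, p: 0
        fc = classify_fates(ref, amp, min_depth=5)
        rates.append(fc[NOT_CALLED_SAME] / len(ref))
    return {"keep_fractions": list(keep_fractions),
            "miscall_rates": rates, "n_sites": n_sites}
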