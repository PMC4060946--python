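"""Shared fixtures: a small genome and libraries with known truth.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

import wgaprof as w


@pytest.fixture(scope="session")
def genome():
    spec = w.GenomeSpec(length=100_000, gc_target=0.36,
                        tandem_repeats=((25, 40, 8),),
                        inverted_repeats=((300, 100, 8),),
                        arm_cluster_fraction=0.5, seed=11)
    return w.generate_genome(spec)


@pytest.fixture(scope="session")
def flat_gain(genome):
    return w.amplification_gain(genome, w.BiasModel())


@pytest.fixture(scope="session")
def chimeric_fragments(genome, flat_gain):
    """Fragment pool with both chimera mechanisms at known rates."""
    return w.simulate_fragments(genome, flat_gain, 1500,
                                p_priming=0.05, p_inverted_dup=0.08, seed=21)


@pytest.fixture(scope="session")
def short_library(chimeric_fragments):
    return w.simulate_short_library(
        chimeric_fragments, w.LibraryParams.short(n_pairs=8000, seed=31))


@pytest.fixture(scope="session")
def long_library(chimeric_fragments):
    return w.simulate_long_library(
        chimeric_fragments,
        w.LibraryParams.long(n_pairs=8000, seed=32, dup_rate=0.02,
                             nonjunction_rate=0.03,
                             circular_contaminant_rate=0.02))


def binomial_ci(p: float, n: int, conf: float = 0.95):
    """Exact (Clopper-Pearson-style central) binomial CI for a proportion,
    via the binomial quantiles of the simulated rate."""
    from scipy import stats
    alpha = 1.0 - conf
    lo = stats.binom.ppf(alpha / 2, n, p) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, p) / n
    return float(lo), float(hi)
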