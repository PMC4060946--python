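"""Coverage evenness, window statistics, GC and repeat-content bias.

All quantities derive from the per-base depth of *properly paired* reads
(duplicates excluded): the evenness curve (quantile function of normalized
per-base depth against cumulative genome fraction; a perfectly uniform
library is the constant-1 line), 10 kb window tables of median coverage and
sequence composition, Spearman correlations of window coverage against
repeat content, and read-GC distributions against the theoretical
distribution of all same-length genomic spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome import SyntheticGenome, gc_mask
from .pairs import (LibraryConvention, PairCategory, ReadPair, classify_frame,
                    classify_pair)


@dataclass
class DepthTrack:
    """Per-base depth of one chromosome plus its normalization constant."""

    chrom: str
    depth: np.ndarray  # int counts

    @property
    def mean(self) -> float:
        return float(self.depth.mean())

    def median(self) -> float:
        return float(np.median(self.depth))

    def normalized(self) -> np.ndarray:
        """Depth divided by its mean (mean of the result is 1)."""
        mu = self.mean
        if mu == 0:
            raise ValueError("all-zero depth track")
        return self.depth / mu

    def depth_at(self, chrom: str, pos: int) -> int:
        if chrom != self.chrom:
            raise KeyError(chrom)
        return int(self.depth[pos])


def depth_from_alignments(pairs, conv: LibraryConvention,
                          genome_length: int,
                          chrom: str = "chr1") -> DepthTrack:
    """Per-base depth from proper pairs (each mate's aligned interval
    increments depth by 1; duplicates and improper pairs excluded)."""
    inc = np.zeros(genome_length + 1, dtype=np.int64)
    if isinstance(pairs, pd.DataFrame):
        cats = classify_frame(pairs, conv)
        sub = pairs.loc[cats == PairCategory.PROPER.value]
        if len(sub) == 0:
            raise ValueError("no proper pairs")
        for i in (1, 2):
            np.add.at(inc, sub[f"start{i}"].to_numpy(), 1)
            np.add.at(inc, sub[f"end{i}"].to_numpy(), -1)
    else:
        n = 0
        for p in pairs:
            if classify_pair(p, conv) != PairCategory.PROPER:
                continue
            n += 1
            for m in (p.mate1, p.mate2):
                inc[m.start] += 1
                inc[m.end] -= 1
        if n == 0:
            raise ValueError("no proper pairs")
    return DepthTrack(chrom=chrom, depth=np.cumsum(inc[:-1]))


@dataclass
class EvennessCurve:
    """Quantile function of normalized depth vs cumulative genome fraction.

    ``deviation`` is the area between the curve and the constant-1 line,
    i.e. the mean absolute deviation of normalized per-base depth from 1;
    it is 0 iff depth is constant.
    """

    genome_fraction: np.ndarray
    depth_quantile: np.ndarray
    deviation: float


def evenness_curve(track: DepthTrack, n_points: int = 500) -> EvennessCurve:
    norm = track.normalized()
    deviation = float(np.abs(norm - 1.0).mean())
    qs = np.linspace(0.0, 1.0, n_points)
    quants = np.quantile(norm, qs)
    return EvennessCurve(genome_fraction=qs, depth_quantile=quants,
                         deviation=deviation)


def window_stats(track: DepthTrack, genome: SyntheticGenome,
                 features: Optional[list] = None,
                 window: int = 10_000) -> pd.DataFrame:
    """Per-window median depth and sequence composition.

    Windows tile the chromosome without overlap; a trailing partial window
    is kept (flagged ``partial``) but excluded from the normalization
    constant, which is the mean of full-window medians.  Normalized median
    depth, GC fraction and repeat-covered fractions are reported per window.
    """
    if features is None:
        features = genome.repeat_features
    n = len(genome)
    if n != len(track.depth):
        raise ValueError("depth track and genome length differ")
    starts = np.arange(0, n, window)
    ends = np.minimum(starts + window, n)

    gc = gc_mask(genome.sequence)
    tmask = np.zeros(n, dtype=bool)
    imask = np.zeros(n, dtype=bool)
    for f in features:
        (tmask if f.kind == "tandem" else imask)[f.start:f.end] = True

    med = np.array([np.median(track.depth[s:e]) for s, e in zip(starts, ends)])
    csum_gc = np.concatenate([[0], np.cumsum(gc)])
    csum_t = np.concatenate([[0], np.cumsum(tmask)])
    csum_i = np.concatenate([[0], np.cumsum(imask)])
    lengths = ends - starts
    table = pd.DataFrame({
        "chrom": track.chrom, "start": starts, "end": ends,
        "median_depth": med,
        "gc": (csum_gc[ends] - csum_gc[starts]) / lengths,
        "tandem_frac": (csum_t[ends] - csum_t[starts]) / lengths,
        "inverted_frac": (csum_i[ends] - csum_i[starts]) / lengths,
        "partial": lengths < window,
    })
    full = ~table["partial"]
    norm_const = table.loc[full, "median_depth"].mean() if full.any() \
        else table["median_depth"].mean()
    if norm_const == 0:
        raise ValueError("zero median coverage in all windows")
    table["norm_median"] = table["median_depth"] / norm_const
    table.attrs["normalization"] = {"mean_of_window_medians": float(norm_const),
                                    "mean_depth": track.mean}
    return table


def _spearman(x: np.ndarray, y: np.ndarray, seed: int = 0,
              n_perm: int = 10_000):
    """Spearman rho with midrank ties; exact-permutation p for n <= 30."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None, None
    if len(x) > 30:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    # vectorized permutation null: rank correlation under shuffles of y
    perms = np.argsort(rng.random((n_perm, len(y))), axis=1)
    null = (ryc[perms] @ rxc) / denom
    count = int((np.abs(null) >= abs(rho) - 1e-12).sum())
    return rho, (count + 1) / (n_perm + 1)


def repeat_coverage_correlation(table: pd.DataFrame, seed: int = 0) -> dict:
    """Spearman correlation of normalized window coverage against tandem and
    inverted repeat fractions (full windows only; two-sided p-values).

    Returns {"rho_tandem", "p_tandem", "rho_inverted", "p_inverted"}; values
    are None when a variable is constant (correlation undefined).
    """
    full = table.loc[~table["partial"]]
    if len(full) < 10:
        raise ValueError("need at least 10 full windows")
    cov = full["norm_median"].to_numpy()
    rho_t, p_t = _spearman(full["tandem_frac"].to_numpy(), cov, seed)
    rho_i, p_i = _spearman(full["inverted_frac"].to_numpy(), cov, seed)
    return {"rho_tandem": rho_t, "p_tandem": p_t,
            "rho_inverted": rho_i, "p_inverted": p_i}


@dataclass
class GCDistribution:
    """Observed vs theoretical read-GC histograms (1% bins, each sums to 1)."""

    bin_edges: np.ndarray
    observed: np.ndarray
    theoretical: np.ndarray
    observed_mean: float
    theoretical_mean: float

    @property
    def shift(self) -> float:
        """Observed minus theoretical mean GC; positive = GC-rich bias."""
        return self.observed_mean - self.theoretical_mean


def read_gc_distribution(pairs, genome: SyntheticGenome,
                         read_length: int) -> GCDistribution:
    """GC distribution of mapped reads' reference spans vs the genome.

    The observed histogram uses the reference GC of every mapped read span;
    the theoretical one the GC of read-length windows at every genomic
    position.  GC is computed on the reference, not the read sequence, so
    the comparison is immune to the sequencing error model.
    """
    gc = gc_mask(genome.sequence).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(gc)])
    if isinstance(pairs, pd.DataFrame):
        starts = np.concatenate([pairs["start1"].to_numpy(),
                                 pairs["start2"].to_numpy()])
        ends = np.concatenate([pairs["end1"].to_numpy(),
                               pairs["end2"].to_numpy()])
    else:
        starts, ends = [], []
        for p in pairs:
            for m in (p.mate1, p.mate2):
                if m.mapped:
                    starts.append(m.start)
                    ends.append(m.end)
        starts, ends = np.array(starts, int), np.array(ends, int)
    if len(starts) == 0:
        raise ValueError("no mapped reads")
    obs_gc = (csum[ends] - csum[starts]) / (ends - starts)

    n = len(genome)
    pos = np.arange(0, n - read_length + 1)
    theo_gc = (csum[pos + read_length] - csum[pos]) / read_length

    edges = np.linspace(0.0, 1.0, 102)  # 1% bins, right-closed last
    obs_h, _ = np.histogram(obs_gc, bins=edges)
    theo_h, _ = np.histogram(theo_gc, bins=edges)
    return GCDistribution(
        bin_edges=edges,
        observed=obs_h / obs_h.sum(),
        theoretical=theo_h / theo_h.sum(),
        observed_mean=float(obs_gc.mean()),
        theoretical_mean=float(theo_gc.mean()))


def library_gc_difference(table_short: pd.DataFrame,
                          table_long: pd.DataFrame) -> pd.DataFrame:
    """Per-window normalized coverage difference (long - short) vs GC.

    Both tables must share an identical window grid.  The returned frame
    carries the per-window difference and, in ``attrs``, the Spearman
    correlation of the difference with window GC (full windows only).
    """
    for col in ("chrom", "start", "end"):
        if not table_short[col].equals(table_long[col]):
            raise ValueError("window grids differ")
    out = table_short[["chrom", "start", "end", "gc", "partial"]].copy()
    out["coverage_difference"] = (table_long["norm_median"]
                                  - table_short["norm_median"])
    full = out.loc[~out["partial"]]
    rho, p = _spearman(full["gc"].to_numpy(),
                       full["coverage_difference"].to_numpy())
    out.attrs["spearman"] = {"rho": rho, "p": p}
    return out
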