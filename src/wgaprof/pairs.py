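"""Read-pair classification: the improper-pair taxonomy of WGA library QC.

Aligned read pairs are partitioned into mutually exclusive categories under a
fixed precedence:

    BOTH_UNMAPPED > SINGLETON > DUPLICATE > INTERCHROMOSOMAL >
    SAME_ORIENTATION > WRONG_FACING > INCORRECT_INSERT > PROPER

``SAME_ORIENTATION`` ('->->' / '<-<-') is the chimera signature: both mates
on the same strand.  ``WRONG_FACING`` covers opposite-strand pairs facing the
wrong way for their library type ("outies" in short-insert libraries,
"innies" in long-insert ones).  A mate aligning less than the library's
minimum aligned fraction counts as unmapped for classification.

Insert size is the distance between the two mates including the reads
themselves (outer span) for opposite-strand pairs; for same-orientation
pairs the start-to-start distance is used instead, so a pair whose mates
fully overlap reports an insert near 0 — the hallmark of fold-back
(inverted-end-duplication) chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
from scipy import stats


class PairCategory(str, Enum):
    PROPER = "proper"
    DUPLICATE = "duplicate"
    SINGLETON = "singleton"
    BOTH_UNMAPPED = "both_unmapped"
    INTERCHROMOSOMAL = "interchromosomal"
    WRONG_FACING = "wrong_facing"
    SAME_ORIENTATION = "same_orientation"
    INCORRECT_INSERT = "incorrect_insert"


@dataclass
class AlignmentRecord:
    """One mate's alignment (0-based half-open coordinates)."""

    read_id: str
    mate_index: int
    mapped: bool
    chrom: Optional[str] = None
    start: int = 0
    end: int = 0
    strand: str = "+"
    aligned_fraction: float = 1.0
    duplicate: bool = False

    def __post_init__(self):
        if self.mate_index not in (1, 2):
            raise ValueError("mate_index must be 1 or 2")
        if self.mapped and self.start >= self.end:
            raise ValueError("mapped record requires start < end")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must lie in [0, 1]")


@dataclass
class ReadPair:
    mate1: AlignmentRecord
    mate2: AlignmentRecord

    def __post_init__(self):
        if {self.mate1.mate_index, self.mate2.mate_index} != {1, 2}:
            raise ValueError("pair requires mate indices {1, 2}")
        if self.mate1.mate_index == 2:
            self.mate1, self.mate2 = self.mate2, self.mate1

    @property
    def read_id(self) -> str:
        return self.mate1.read_id

    def mates(self):
        return (self.mate1, self.mate2)


@dataclass(frozen=True)
class LibraryConvention:
    """Alignment-filter and facing conventions of a library type.

    Defaults follow mapping practice for the two library designs: inward
    facing, <=600 bp inserts and >=80% of the read aligned for short-insert
    libraries; outward facing, <=100 kb and >=50% for long-insert ones.
    """

    library_type: str
    proper_facing: str
    max_insert: int
    min_aligned_fraction: float

    def __post_init__(self):
        if self.max_insert <= 0:
            raise ValueError("max_insert must be positive")

    @classmethod
    def short(cls, max_insert: int = 600,
              min_aligned_fraction: float = 0.80) -> "LibraryConvention":
        return cls("short", "inward", max_insert, min_aligned_fraction)

    @classmethod
    def long(cls, max_insert: int = 100_000,
             min_aligned_fraction: float = 0.50) -> "LibraryConvention":
        return cls("long", "outward", max_insert, min_aligned_fraction)


def effectively_mapped(rec: AlignmentRecord, conv: LibraryConvention) -> bool:
    return rec.mapped and rec.aligned_fraction >= conv.min_aligned_fraction


def mark_duplicates(pairs: Iterable[ReadPair]) -> list:
    """Flag PCR duplicates by exact mapped coordinates.

    Among pairs whose two mates share identical (chrom, start, end, strand)
    tuples, all but the first in input order are flagged.  Pairs with an
    unmapped mate are never flagged.  Idempotent.
    """
    pairs = list(pairs)
    seen = set()
    for p in pairs:
        if not (p.mate1.mapped and p.mate2.mapped):
            continue
        key = tuple(sorted(
            (m.chrom, m.start, m.end, m.strand) for m in p.mates()))
        if key in seen:
            p.mate1.duplicate = p.mate2.duplicate = True
        else:
            seen.add(key)
            p.mate1.duplicate = p.mate2.duplicate = False
    return pairs


def compute_insert(pair: ReadPair) -> Optional[int]:
    """Insert size of a pair, or None when undefined.

    Opposite strands: outer span (max end - min start), the distance between
    mates including the reads themselves.  Same strand: start-to-start
    distance, which reports ~0 for fully overlapping same-orientation mates.
    """
    m1, m2 = pair.mates()
    if not (m1.mapped and m2.mapped) or m1.chrom != m2.chrom:
        return None
    if m1.strand == m2.strand:
        return abs(m1.start - m2.start)
    return max(m1.end, m2.end) - min(m1.start, m2.start)


def _facing(m1: AlignmentRecord, m2: AlignmentRecord) -> str:
    """'inward' if the leftmost mate is on +, else 'outward'.

    Ties at equal starts resolve by end coordinate; pairs with identical
    intervals on opposite strands count as inward.
    """
    if (m1.start, m1.end) == (m2.start, m2.end):
        return "inward"
    left = m1 if (m1.start, m1.end) < (m2.start, m2.end) else m2
    return "inward" if left.strand == "+" else "outward"


def classify_pair(pair: ReadPair, conv: LibraryConvention) -> PairCategory:
    """Assign a pair to its category (first matching rule wins)."""
    m1, m2 = pair.mates()
    ok1, ok2 = (effectively_mapped(m, conv) for m in (m1, m2))
    if not ok1 and not ok2:
        return PairCategory.BOTH_UNMAPPED
    if ok1 != ok2:
        return PairCategory.SINGLETON
    if m1.duplicate or m2.duplicate:
        return PairCategory.DUPLICATE
    if m1.chrom != m2.chrom:
        return PairCategory.INTERCHROMOSOMAL
    if m1.strand == m2.strand:
        return PairCategory.SAME_ORIENTATION
    if _facing(m1, m2) != conv.proper_facing:
        return PairCategory.WRONG_FACING
    if compute_insert(pair) > conv.max_insert:
        return PairCategory.INCORRECT_INSERT
    return PairCategory.PROPER


# ---------------------------------------------------------------------------
# vectorized frame interface (the simulator's truth frame, or any DataFrame
# with the same mate columns)


def mark_duplicates_frame(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized duplicate flags over a pair frame (first-seen kept).

    The key is the mate-order-insensitive pair of (start, end, strand)
    coordinate triples, so a duplicate is any later pair sharing both mates'
    exact mapped coordinates.
    """
    a1 = frame["start1"].to_numpy(); e1 = frame["end1"].to_numpy()
    s1 = frame["strand1"].to_numpy()
    a2 = frame["start2"].to_numpy(); e2 = frame["end2"].to_numpy()
    s2 = frame["strand2"].to_numpy()
    first = (a1 < a2) | ((a1 == a2) & ((e1 < e2) | ((e1 == e2) & (s1 <= s2))))
    key = pd.DataFrame({
        "a": np.where(first, a1, a2), "b": np.where(first, e1, e2),
        "c": np.where(first, s1, s2), "d": np.where(first, a2, a1),
        "e": np.where(first, e2, e1), "f": np.where(first, s2, s1),
        "g": frame["chrom"].astype(str),
    })
    return key.duplicated(keep="first").to_numpy()


def classify_frame(frame: pd.DataFrame, conv: LibraryConvention,
                   duplicates: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized classify_pair over a pair frame.

    Returns an object array of category value strings (PairCategory.*.value).
    Strands are +/-1 integers in frames; mates below the aligned-fraction
    filter count as unmapped.
    """
    if duplicates is None:
        duplicates = mark_duplicates_frame(frame)
    ok1 = frame["frac1"].to_numpy() >= conv.min_aligned_fraction
    ok2 = frame["frac2"].to_numpy() >= conv.min_aligned_fraction
    s1 = frame["strand1"].to_numpy()
    s2 = frame["strand2"].to_numpy()
    a1, a2 = frame["start1"].to_numpy(), frame["start2"].to_numpy()
    e1, e2 = frame["end1"].to_numpy(), frame["end2"].to_numpy()

    # pair frames carry one chrom column: both mates share it by construction
    same_chrom = np.ones(len(frame), dtype=bool)

    outer = np.maximum(e1, e2) - np.minimum(a1, a2)
    # leftmost mate by (start, end) lexicographic order
    first_left = (a1 < a2) | ((a1 == a2) & (e1 <= e2))
    left_strand = np.where(first_left, s1, s2)
    identical = (a1 == a2) & (e1 == e2)
    inward = (left_strand > 0) | identical
    facing_ok = inward if conv.proper_facing == "inward" else (
        ~inward & ~identical)

    order = [PairCategory.BOTH_UNMAPPED, PairCategory.SINGLETON,
             PairCategory.DUPLICATE, PairCategory.INTERCHROMOSOMAL,
             PairCategory.SAME_ORIENTATION, PairCategory.WRONG_FACING,
             PairCategory.INCORRECT_INSERT, PairCategory.PROPER]
    codes = np.select(
        [~ok1 & ~ok2, ok1 != ok2, duplicates, ~same_chrom, s1 == s2,
         ~facing_ok, outer > conv.max_insert],
        np.arange(7), default=7)
    # plain value strings: numpy comparisons against str enums are unreliable
    lut = np.array([c.value for c in order], dtype=object)
    return lut[codes]


def insert_sizes_frame(frame: pd.DataFrame) -> np.ndarray:
    s1, s2 = frame["strand1"].to_numpy(), frame["strand2"].to_numpy()
    a1, a2 = frame["start1"].to_numpy(), frame["start2"].to_numpy()
    e1, e2 = frame["end1"].to_numpy(), frame["end2"].to_numpy()
    same = s1 == s2
    return np.where(same, np.abs(a1 - a2),
                    np.maximum(e1, e2) - np.minimum(a1, a2))


def frame_to_pairs(frame: pd.DataFrame, conv: Optional[LibraryConvention] = None
                   ) -> list:
    """Materialize ReadPair objects from a pair frame."""
    out = []
    for row in frame.itertuples(index=False):
        mates = []
        for i in (1, 2):
            mates.append(AlignmentRecord(
                read_id=f"pair{row.pair_id:08d}", mate_index=i, mapped=True,
                chrom=row.chrom,
                start=int(getattr(row, f"start{i}")),
                end=int(getattr(row, f"end{i}")),
                strand="+" if getattr(row, f"strand{i}") > 0 else "-",
                aligned_fraction=float(getattr(row, f"frac{i}"))))
        out.append(ReadPair(*mates))
    return out


def read_pairs_from_sam(path) -> list:
    """Assemble ReadPairs from a (name-grouped or unsorted) SAM/BAM file."""
    by_name: dict = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate_index = 1 if rec.is_read1 else 2
            if rec.is_unmapped:
                ar = AlignmentRecord(rec.query_name, mate_index, mapped=False)
            else:
                if rec.has_tag("ZF"):
                    frac = float(rec.get_tag("ZF"))
                else:
                    aligned = sum(l for op, l in (rec.cigartuples or [])
                                  if op == 0)
                    qlen = rec.infer_read_length() or aligned
                    frac = aligned / qlen if qlen else 0.0
                ar = AlignmentRecord(
                    rec.query_name, mate_index, mapped=True,
                    chrom=rec.reference_name, start=rec.reference_start,
                    end=rec.reference_end, strand="-" if rec.is_reverse else "+",
                    aligned_fraction=frac,
                    duplicate=rec.is_duplicate)
            by_name.setdefault(rec.query_name, {})[mate_index] = ar
    pairs = []
    for name, mates in by_name.items():
        if len(mates) == 2:
            pairs.append(ReadPair(mates[1], mates[2]))
    return pairs


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PairSummary:
    """Library mapping summary; all percentages relative to total reads."""

    total_reads: int
    mapped_pct: float
    duplicates_pct: float
    proper_pct: float
    both_mapped_pct: float
    category_pct: dict
    median_insert: Optional[float]
    median_depth: Optional[float] = None

    def to_dict(self) -> dict:
        d = {"total_reads": self.total_reads, "mapped_pct": self.mapped_pct,
             "duplicates_pct": self.duplicates_pct,
             "proper_pct": self.proper_pct,
             "both_mapped_pct": self.both_mapped_pct,
             "median_insert": self.median_insert,
             "median_depth": self.median_depth}
        d.update({f"{k}_pct": v for k, v in self.category_pct.items()})
        return d


def _summary_from_arrays(cats: np.ndarray, inserts: np.ndarray,
                         ok1: np.ndarray, ok2: np.ndarray,
                         depth_track=None) -> PairSummary:
    n = len(cats)
    if n == 0:
        raise ValueError("empty input")
    total_reads = 2 * n
    mapped = int(ok1.sum() + ok2.sum())
    both = int((ok1 & ok2).sum())
    counts = {c: int((cats == c.value).sum()) for c in PairCategory}
    proper_mask = cats == PairCategory.PROPER.value
    med_ins = float(np.median(inserts[proper_mask])) if proper_mask.any() else None
    med_depth = None
    if depth_track is not None:
        med_depth = float(depth_track.median())
    pct = {c.value: 100.0 * 2 * counts[c] / total_reads for c in PairCategory}
    return PairSummary(
        total_reads=total_reads,
        mapped_pct=100.0 * mapped / total_reads,
        duplicates_pct=pct[PairCategory.DUPLICATE.value],
        proper_pct=pct[PairCategory.PROPER.value],
        both_mapped_pct=100.0 * 2 * both / total_reads,
        category_pct=pct, median_insert=med_ins, median_depth=med_depth)


def summarize_library(pairs, conv: LibraryConvention,
                      depth_track=None) -> PairSummary:
    """Mapping-statistics summary over classified pairs.

    ``pairs`` may be a list of ReadPair or a pair frame.  Each pair counts
    as two reads; the median insert is taken over proper pairs only.
    """
    if isinstance(pairs, pd.DataFrame):
        cats = classify_frame(pairs, conv)
        inserts = insert_sizes_frame(pairs)
        ok1 = pairs["frac1"].to_numpy() >= conv.min_aligned_fraction
        ok2 = pairs["frac2"].to_numpy() >= conv.min_aligned_fraction
        return _summary_from_arrays(cats, inserts, ok1, ok2, depth_track)
    pairs = list(pairs)
    cats = np.array([classify_pair(p, conv).value for p in pairs],
                    dtype=object)
    inserts = np.array([compute_insert(p) or 0 for p in pairs], dtype=float)
    ok1 = np.array([effectively_mapped(p.mate1, conv) for p in pairs])
    ok2 = np.array([effectively_mapped(p.mate2, conv) for p in pairs])
    return _summary_from_arrays(cats, inserts, ok1, ok2, depth_track)


@dataclass
class ChimeraSignature:
    """Summary of the same-orientation (chimera) pair signature."""

    fraction: float                 # SAME_ORIENTATION share of all reads
    histogram_edges: np.ndarray     # insert-size bin edges (first bin [0, rl])
    histogram: np.ndarray           # counts per bin
    mate_overlap_fraction: float    # mates' intervals intersect
    chrom_bin_counts: Optional[np.ndarray]
    uniformity_chi2: Optional[float]
    uniformity_p: Optional[float]

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "histogram_edges": list(map(float, self.histogram_edges)),
            "histogram": list(map(int, self.histogram)),
            "mate_overlap_fraction": self.mate_overlap_fraction,
            "chrom_bin_counts": (None if self.chrom_bin_counts is None
                                 else list(map(int, self.chrom_bin_counts))),
            "uniformity_chi2": self.uniformity_chi2,
            "uniformity_p": self.uniformity_p,
        }


def chimera_signature(pairs, conv: LibraryConvention, *, read_length: int,
                      genome_length: Optional[int] = None,
                      n_chrom_bins: int = 20,
                      max_insert: int = 1_000_000) -> ChimeraSignature:
    """Quantify the same-orientation chimera signature of a library.

    Reports the same-orientation fraction of reads, the insert-size
    histogram of those pairs (a [0, read_length] bin followed by log-spaced
    bins), the fraction whose mate intervals overlap, and — when
    ``genome_length`` is given — per-genome-bin counts with a chi-square
    uniformity test.
    """
    if isinstance(pairs, pd.DataFrame):
        frame = pairs
        cats = classify_frame(frame, conv)
        mask = cats == PairCategory.SAME_ORIENTATION.value
        sub = frame.loc[mask]
        inserts = insert_sizes_frame(sub)
        ov = (np.minimum(sub["end1"], sub["end2"])
              > np.maximum(sub["start1"], sub["start2"])).to_numpy()
        mids = ((np.minimum(sub["start1"], sub["start2"])
                 + np.maximum(sub["end1"], sub["end2"])) // 2).to_numpy()
        n = len(frame)
    else:
        pairs = list(pairs)
        n = len(pairs)
        so = [p for p in pairs
              if classify_pair(p, conv) == PairCategory.SAME_ORIENTATION]
        inserts = np.array([compute_insert(p) for p in so], dtype=float)
        ov = np.array([min(p.mate1.end, p.mate2.end)
                       > max(p.mate1.start, p.mate2.start) for p in so])
        mids = np.array([(min(p.mate1.start, p.mate2.start)
                          + max(p.mate1.end, p.mate2.end)) // 2 for p in so])

    edges = np.concatenate([[0.0, float(read_length)],
                            np.geomspace(read_length, max_insert, 25)[1:]])
    if len(inserts) == 0:
        return ChimeraSignature(0.0, edges, np.zeros(len(edges) - 1, int),
                                0.0, None, None, None)
    hist, _ = np.histogram(np.clip(inserts, 0, max_insert - 1), bins=edges)
    frac = len(inserts) / n
    overlap = float(ov.mean())
    bin_counts = chi2 = pval = None
    if genome_length is not None:
        bin_counts, _ = np.histogram(mids, bins=n_chrom_bins,
                                     range=(0, genome_length))
        chi2_res = stats.chisquare(bin_counts)
        chi2, pval = float(chi2_res.statistic), float(chi2_res.pvalue)
    return ChimeraSignature(frac, edges, hist, overlap, bin_counts, chi2, pval)
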