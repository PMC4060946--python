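"""Pair classification: taxonomy rules, oracle equivalence, signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wgaprof as w
from wgaprof.pairs import (AlignmentRecord, PairCategory, ReadPair,
                           classify_frame, frame_to_pairs,
                           insert_sizes_frame, mark_duplicates,
                           mark_duplicates_frame)


def mk_pair(chrom1="chr1", s1=100, e1=200, st1="+", chrom2="chr1", s2=400,
            e2=500, st2="-", mapped1=True, mapped2=True, f1=1.0, f2=1.0,
            dup=False, rid="r"):
    m1 = AlignmentRecord(rid, 1, mapped1, chrom1, s1, e1, st1, f1, dup)
    m2 = AlignmentRecord(rid, 2, mapped2, chrom2, s2, e2, st2, f2, dup)
    return ReadPair(m1, m2)


SHORT = w.LibraryConvention.short()
LONG = w.LibraryConvention.long()


# ---------------------------------------------------------------------------
# independent brute-force rule evaluator (kept deliberately naive)

def oracle_classify(pair, conv):
    mates = sorted(pair.mates(), key=lambda m: m.mate_index)
    mapped = [m.mapped and m.aligned_fraction >= conv.min_aligned_fraction
              for m in mates]
    if mapped == [False, False]:
        return PairCategory.BOTH_UNMAPPED
    if mapped.count(True) == 1:
        return PairCategory.SINGLETON
    if any(m.duplicate for m in mates):
        return PairCategory.DUPLICATE
    if mates[0].chrom != mates[1].chrom:
        return PairCategory.INTERCHROMOSOMAL
    if mates[0].strand == mates[1].strand:
        return PairCategory.SAME_ORIENTATION
    # leftmost mate by (start, end); equal intervals count as inward
    a, b = mates
    if (a.start, a.end) == (b.start, b.end):
        facing = "inward"
    else:
        left = a if (a.start, a.end) < (b.start, b.end) else b
        facing = "inward" if left.strand == "+" else "outward"
    if facing != conv.proper_facing:
        return PairCategory.WRONG_FACING
    span = max(a.end, b.end) - min(a.start, b.start)
    if span > conv.max_insert:
        return PairCategory.INCORRECT_INSERT
    return PairCategory.PROPER


def random_pairs(n, rng, interchrom=True):
    out = []
    for i in range(n):
        chrom2 = "chr2" if (interchrom and rng.random() < 0.1) else "chr1"
        s1 = int(rng.integers(0, 5000))
        s2 = int(rng.integers(0, 5000))
        l1 = int(rng.integers(50, 150))
        l2 = int(rng.integers(50, 150))
        p = mk_pair("chr1", s1, s1 + l1, rng.choice(["+", "-"]),
                    chrom2, s2, s2 + l2, rng.choice(["+", "-"]),
                    mapped1=rng.random() > 0.1, mapped2=rng.random() > 0.1,
                    f1=float(rng.choice([1.0, 0.9, 0.6, 0.3])),
                    f2=float(rng.choice([1.0, 0.9, 0.6, 0.3])),
                    dup=bool(rng.random() < 0.1), rid=f"r{i}")
        out.append(p)
    return out


@pytest.mark.parametrize("conv", [SHORT, LONG], ids=["short", "long"])
def test_classifier_matches_bruteforce_oracle(conv):
    rng = np.random.default_rng(42)
    for p in random_pairs(1000, rng):
        assert w.classify_pair(p, conv) == oracle_classify(p, conv)


# ---------------------------------------------------------------------------
# taxonomy examples

def test_proper_short_pair():
    assert w.classify_pair(mk_pair(), SHORT) == PairCategory.PROPER


def test_innie_is_wrong_facing_in_long_library():
    p = mk_pair(s1=100, e1=200, st1="+", s2=300, e2=400, st2="-")
    assert w.classify_pair(p, LONG) == PairCategory.WRONG_FACING


def test_outie_is_wrong_facing_in_short_library():
    p = mk_pair(s1=100, e1=200, st1="-", s2=300, e2=400, st2="+")
    assert w.classify_pair(p, SHORT) == PairCategory.WRONG_FACING
    assert w.classify_pair(p, LONG) == PairCategory.PROPER


def test_interchromosomal():
    p = mk_pair(chrom2="chr2")
    assert w.classify_pair(p, SHORT) == PairCategory.INTERCHROMOSOMAL


def test_incorrect_insert():
    p = mk_pair(s1=100, e1=200, s2=4900, e2=5100)
    assert w.classify_pair(p, SHORT) == PairCategory.INCORRECT_INSERT


def test_same_orientation_precedes_facing():
    p = mk_pair(st1="+", st2="+")
    assert w.classify_pair(p, SHORT) == PairCategory.SAME_ORIENTATION
    assert w.classify_pair(p, LONG) == PairCategory.SAME_ORIENTATION


def test_low_aligned_fraction_counts_as_unmapped():
    p = mk_pair(f2=0.7)   # below the 0.8 short-library filter
    assert w.classify_pair(p, SHORT) == PairCategory.SINGLETON
    assert w.classify_pair(p, LONG) != PairCategory.SINGLETON


def test_mate_swap_symmetry():
    rng = np.random.default_rng(7)
    for p in random_pairs(200, rng):
        q = ReadPair(p.mate2, p.mate1)
        assert w.classify_pair(p, SHORT) == w.classify_pair(q, SHORT)


# ---------------------------------------------------------------------------
# insert size

def test_insert_outer_span():
    assert w.compute_insert(mk_pair(s1=100, e1=200, s2=400, e2=500)) == 400


def test_insert_same_strand_start_to_start():
    p = mk_pair(s1=100, e1=200, st1="+", s2=100, e2=200, st2="+")
    assert w.compute_insert(p) == 0
    q = mk_pair(s1=100, e1=200, st1="-", s2=130, e2=230, st2="-")
    assert w.compute_insert(q) == 30


def test_insert_undefined_cases():
    assert w.compute_insert(mk_pair(chrom2="chr2")) is None
    assert w.compute_insert(mk_pair(mapped2=False)) is None


@given(s1=st.integers(0, 2000), s2=st.integers(0, 2000),
       l1=st.integers(1, 300), l2=st.integers(1, 300))
@settings(max_examples=100, deadline=None)
def test_insert_symmetry_property(s1, s2, l1, l2):
    p = mk_pair(s1=s1, e1=s1 + l1, s2=s2, e2=s2 + l2)
    q = mk_pair(s1=s2, e1=s2 + l2, s2=s1, e2=s1 + l1)
    assert w.compute_insert(p) == w.compute_insert(q)
    assert w.compute_insert(p) >= 0


# ---------------------------------------------------------------------------
# duplicates

def test_mark_duplicates_flags_all_but_first():
    pairs = [mk_pair(rid="a"), mk_pair(rid="b"), mk_pair(rid="c", s1=111)]
    mark_duplicates(pairs)
    assert not pairs[0].mate1.duplicate
    assert pairs[1].mate1.duplicate and pairs[1].mate2.duplicate
    assert not pairs[2].mate1.duplicate
    mark_duplicates(pairs)   # idempotent
    assert [p.mate1.duplicate for p in pairs] == [False, True, False]


def test_mark_duplicates_ignores_unmapped():
    pairs = [mk_pair(mapped1=False, rid="a"), mk_pair(mapped1=False, rid="b")]
    mark_duplicates(pairs)
    assert not any(p.mate1.duplicate or p.mate2.duplicate for p in pairs)


def test_simulated_duplicates_recovered(genome):
    from wgaprof.fragments import AmplifiedFragment
    frags = [AmplifiedFragment(mechanism=w.NORMAL, pieces=[(20_000, 0, +1)],
                               length=20_000, genome=genome)]
    lib = w.simulate_library(frags, w.LibraryParams.short(
        n_pairs=4000, dup_rate=0.2, seed=13))
    flagged = mark_duplicates_frame(lib.frame)
    truth = (lib.frame["artifact"] == "pcr_duplicate").to_numpy()
    # every injected duplicate shares coordinates with its source
    assert flagged.sum() >= truth.sum()
    # collisions beyond injected duplicates are rare
    assert flagged.sum() - truth.sum() < 0.02 * len(lib.frame)


# ---------------------------------------------------------------------------
# frame/object agreement and partition

def test_frame_matches_object_classification(short_library):
    frame = short_library.frame.head(1500)
    pairs = mark_duplicates(frame_to_pairs(frame))
    obj = [w.classify_pair(p, SHORT).value for p in pairs]
    vec = list(classify_frame(frame, SHORT))
    assert obj == vec


def test_category_partition(short_library):
    cats = classify_frame(short_library.frame, SHORT)
    counts = {c.value: int((cats == c.value).sum()) for c in PairCategory}
    assert sum(counts.values()) == len(short_library.frame)
    s = w.summarize_library(short_library.frame, SHORT)
    assert sum(s.category_pct.values()) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# summaries

def test_summary_all_proper():
    pairs = [mk_pair(rid=f"r{i}", s1=100 * i, e1=100 * i + 100,
                     s2=100 * i + 300, e2=100 * i + 400)
             for i in range(10)]
    s = w.summarize_library(mark_duplicates(pairs), SHORT)
    assert s.proper_pct == 100.0
    assert s.median_insert == 400
    assert s.total_reads == 20


def test_summary_mapped_percentage():
    pairs = [mk_pair(rid=f"r{i}", s1=10_000 * i, s2=10_000 * i + 300,
                     e1=10_000 * i + 100, e2=10_000 * i + 400)
             for i in range(3)]
    pairs.append(mk_pair(rid="s", mapped2=False))
    s = w.summarize_library(mark_duplicates(pairs), SHORT)
    assert s.mapped_pct == pytest.approx(87.5)   # 7 of 8 reads
    assert s.category_pct["singleton"] == pytest.approx(25.0)


def test_summary_empty_input_rejected():
    with pytest.raises(ValueError):
        w.summarize_library([], SHORT)


# ---------------------------------------------------------------------------
# chimera signature

def test_signature_zero_when_all_proper():
    pairs = [mk_pair(rid=f"r{i}", s1=100 * i, e1=100 * i + 100,
                     s2=100 * i + 300, e2=100 * i + 400) for i in range(20)]
    sig = w.chimera_signature(mark_duplicates(pairs), SHORT, read_length=100,
                              genome_length=10_000)
    assert sig.fraction == 0.0
    assert sig.histogram.sum() == 0
    assert sig.uniformity_p is None


def test_signature_foldback_mode_near_zero(genome, flat_gain):
    frags = w.simulate_fragments(genome, flat_gain, 300, p_inverted_dup=1.0,
                                 seed=15)
    lib = w.simulate_short_library(
        frags, w.LibraryParams.short(n_pairs=5000, seed=16))
    sig = w.chimera_signature(lib.frame, SHORT, read_length=100,
                              genome_length=len(genome))
    assert sig.fraction > 0.01
    # the [0, read_length] bin dominates and mates overlap
    assert sig.histogram[0] == sig.histogram.max()
    assert sig.mate_overlap_fraction > 0.5
    assert sig.uniformity_p is not None


def test_signature_priming_mass_above_read_length(genome, flat_gain):
    frags = w.simulate_fragments(genome, flat_gain, 300, p_priming=1.0,
                                 seed=17)
    lib = w.simulate_short_library(
        frags, w.LibraryParams.short(n_pairs=5000, seed=18))
    sig = w.chimera_signature(lib.frame, SHORT, read_length=100)
    assert sig.histogram[0] < 0.2 * sig.histogram.sum()


def test_insert_sizes_frame_matches_object(short_library):
    frame = short_library.frame.head(500)
    obj = [w.compute_insert(p) for p in frame_to_pairs(frame)]
    vec = insert_sizes_frame(frame)
    assert list(vec) == obj
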