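"""SNP-fate concordance: reference-set logic, fates, dropout mechanism."""

import numpy as np
import pytest

import wgaprof as w
from wgaprof.variants import (CALLED_IN_BOTH, CALLED_IN_ONE,
                              DIFF_IN_BOTH_UNAMP, HET, HOM_ALT,
                              NO_LOW_COVERAGE, NOT_CALLED_SAME, CallSet,
                              VariantCall, fates_table, threshold_caller)

BASES = "ACGT"


def call(pos, genotype=HET, alt="T", depth=20, chrom="chr1", ref="A"):
    return VariantCall(chrom, pos, ref, alt, genotype, depth)


def callset(calls, name="s", depth_of=None):
    cs = CallSet(sample=name, depth_of=depth_of)
    for c in calls:
        cs.add(c)
    return cs


# -- reference set -------------------------------------------------------

def test_reference_set_definition():
    u1 = callset([call(10, HET), call(20, HOM_ALT), call(30, HET),
                  call(40, HET, alt="G")])
    u2 = callset([call(10, HET), call(20, HOM_ALT), call(40, HET, alt="C"),
                  call(50, HOM_ALT)])
    hom, het = w.build_reference_set(u1, u2)
    assert set(het) == {("chr1", 10)}       # same call in both
    assert set(hom) == {("chr1", 20)}
    # site 30: one replicate only; site 40: different alt; site 50: one rep


def test_reference_set_zygosity_must_match():
    u1 = callset([call(10, HET)])
    u2 = callset([call(10, HOM_ALT)])
    hom, het = w.build_reference_set(u1, u2)
    assert not hom and not het


def test_reference_set_symmetry():
    rng = np.random.default_rng(5)
    sets = []
    for _ in range(2):
        sets.append(callset([
            call(int(p), rng.choice([HET, HOM_ALT]),
                 alt=rng.choice(list("CGT")))
            for p in rng.choice(5000, size=300, replace=False)]))
    f, r = w.build_reference_set(*sets), w.build_reference_set(sets[1],
                                                               sets[0])
    assert f[0] == r[0] and f[1] == r[1]


def test_reference_set_matches_bruteforce_enumeration():
    rng = np.random.default_rng(6)

    def random_set():
        return callset([
            call(int(p), rng.choice([HET, HOM_ALT]),
                 alt=rng.choice(list("CGT")))
            for p in rng.choice(2000, size=400, replace=False)])

    u1, u2 = random_set(), random_set()
    hom, het = w.build_reference_set(u1, u2)
    # brute force: loop over every site mentioned anywhere
    want_hom, want_het = {}, {}
    for site in set(u1.calls) | set(u2.calls):
        c1, c2 = u1.get(site), u2.get(site)
        if c1 and c2 and c1.alt == c2.alt and c1.genotype == c2.genotype:
            (want_hom if c1.genotype == HOM_ALT else want_het)[site] = c1
    assert hom == want_hom and het == want_het


# -- fates ---------------------------------------------------------------

def test_fate_no_low_coverage():
    ref = {("chr1", 10): call(10, HET)}
    depth = {10: 1, 99: 50}
    amp1 = callset([], depth_of=lambda c, p: depth.get(p, 2))
    amp2 = callset([], depth_of=lambda c, p: 1)
    fc = w.classify_fates(ref, amp1, amp2)
    assert fc[NO_LOW_COVERAGE] == 1


def test_fate_uncalled_with_depth_is_not_called_same():
    ref = {("chr1", 10): call(10, HET)}
    amp1 = callset([], depth_of=lambda c, p: 30)
    amp2 = callset([], depth_of=lambda c, p: 30)
    fc = w.classify_fates(ref, amp1, amp2)
    assert fc[NOT_CALLED_SAME] == 1


def test_fate_het_called_hom_is_not_called_same():
    ref = {("chr1", 10): call(10, HET)}
    fc = w.classify_fates(ref, callset([call(10, HOM_ALT)]),
                          callset([call(10, HET)]))
    assert fc[NOT_CALLED_SAME] == 1


def test_fate_called_in_both_and_one():
    ref = {("chr1", 10): call(10, HOM_ALT), ("chr1", 20): call(20, HOM_ALT)}
    amp1 = callset([call(10, HOM_ALT), call(20, HOM_ALT)],
                   depth_of=lambda c, p: 30)
    amp2 = callset([call(10, HOM_ALT)], depth_of=lambda c, p: 30)
    fc = w.classify_fates(ref, amp1, amp2)
    assert fc[CALLED_IN_BOTH] == 1
    assert fc[CALLED_IN_ONE] == 1


def test_single_replicate_reports_both_as_na():
    ref = {("chr1", 10): call(10, HOM_ALT)}
    fc = w.classify_fates(ref, callset([call(10, HOM_ALT)]))
    assert fc.to_dict()[CALLED_IN_BOTH] is None
    assert fc[CALLED_IN_ONE] == 1


def test_fate_partition():
    rng = np.random.default_rng(7)
    ref = {("chr1", int(p)): call(int(p), rng.choice([HET, HOM_ALT]))
           for p in rng.choice(3000, size=500, replace=False)}
    amp_calls = []
    for site, c in ref.items():
        r = rng.random()
        if r < 0.4:
            amp_calls.append(c)
        elif r < 0.6:
            amp_calls.append(call(c.pos, HOM_ALT if c.genotype == HET
                                  else HET, alt=c.alt))
    amp1 = callset(amp_calls, depth_of=lambda c, p: int(p) % 9)
    amp2 = callset([], depth_of=lambda c, p: (int(p) + 3) % 9)
    fc = w.classify_fates(ref, amp1, amp2)
    assert sum(fc.counts.values()) == len(ref) == fc.n_reference


# -- extra calls ---------------------------------------------------------

def test_extra_called_differently_in_both():
    u1 = callset([call(10, HOM_ALT)])
    u2 = callset([call(10, HOM_ALT)])
    amp = callset([call(10, HET)])
    # site 10 is in the reference hom set?  it is - so exclude via ref sets
    hom, het = w.build_reference_set(u1, u2)
    extra = w.extra_call_fates((hom, het), [amp], u1, u2)
    # amp call at a reference site is not an "extra" call
    assert extra[HET][DIFF_IN_BOTH_UNAMP] == 0

    u1 = callset([call(10, HOM_ALT, alt="G")])
    u2 = callset([call(10, HOM_ALT, alt="C")])
    extra = w.extra_call_fates(w.build_reference_set(u1, u2), [amp], u1, u2)
    assert extra[HET][DIFF_IN_BOTH_UNAMP] == 1


def test_extra_called_in_one_replicate():
    u1 = callset([call(10, HET)])
    u2 = callset([])
    amp = callset([call(10, HET)])
    extra = w.extra_call_fates(w.build_reference_set(u1, u2), [amp], u1, u2)
    assert extra[HET][CALLED_IN_ONE] == 1


def test_extra_calls_match_bruteforce_enumeration():
    rng = np.random.default_rng(8)

    def random_set(n=300):
        return callset([
            call(int(p), rng.choice([HET, HOM_ALT]),
                 alt=rng.choice(list("CGT")))
            for p in rng.choice(1500, size=n, replace=False)])

    u1, u2, a1, a2 = (random_set() for _ in range(4))
    refs = w.build_reference_set(u1, u2)
    got = w.extra_call_fates(refs, [a1, a2], u1, u2)

    ref_sites = set(refs[0]) | set(refs[1])
    want = {HOM_ALT: {DIFF_IN_BOTH_UNAMP: 0, CALLED_IN_ONE: 0},
            HET: {DIFF_IN_BOTH_UNAMP: 0, CALLED_IN_ONE: 0}}
    seen = set()
    for rep in (a1, a2):
        for site, c in rep.calls.items():
            if site in ref_sites or (site, c.alt, c.genotype) in seen:
                continue
            seen.add((site, c.alt, c.genotype))
            u1c, u2c = u1.get(site), u2.get(site)
            if (u1c and u2c and not c.same_call(u1c)
                    and not c.same_call(u2c)):
                want[c.genotype][DIFF_IN_BOTH_UNAMP] += 1
            elif sum(1 for u in (u1c, u2c)
                     if u and c.same_call(u)) == 1:
                want[c.genotype][CALLED_IN_ONE] += 1
    assert got == want


# -- dropout mechanism ---------------------------------------------------

def test_depth_thinning_increases_het_miscalls():
    """Binomial thinning of het-site depth monotonically increases the rate
    of het reference SNPs miscalled (mostly as homozygous) - the allele
    dropout mechanism behind under-called heterozygotes."""
    rng = np.random.default_rng(9)
    n_sites = 800
    base_depth = 30
    ref = {}
    alt_counts = {}
    for i in range(n_sites):
        pos = 10 * (i + 1)
        ref[("chr1", pos)] = call(pos, HET)
        alt_counts[pos] = int(rng.binomial(base_depth, 0.5))

    rates = []
    for keep in (1.0, 0.4, 0.15):
        sites = []
        for (chrom, pos), c in ref.items():
            d = int(rng.binomial(base_depth, keep))
            a = int(rng.hypergeometric(alt_counts[pos],
                                       base_depth - alt_counts[pos], d)
                    ) if d else 0
            sites.append((chrom, pos, "A", "T", d, a))
        amp = threshold_caller(sites)
        amp.depth_of = lambda c, p: 0
        fc = w.classify_fates(ref, amp, min_depth=5)
        rates.append(fc[NOT_CALLED_SAME] / len(ref))
    assert rates[0] < rates[1] < rates[2]


# -- IO ------------------------------------------------------------------

def test_table_round_trip(tmp_path):
    import pandas as pd
    df = pd.DataFrame({"chrom": "chr1", "pos": [5, 9], "ref": "A",
                       "alt": ["T", "G"], "genotype": [HET, HOM_ALT],
                       "depth": [12, 20]})
    path = tmp_path / "calls.tsv"
    df.to_csv(path, sep="\t", index=False)
    cs = CallSet.from_table(path)
    assert len(cs) == 2
    assert cs.get(("chr1", 9)).genotype == HOM_ALT


def test_vcf_round_trip(tmp_path):
    path = tmp_path / "calls.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        "##contig=<ID=chr1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/1:18\n"
        "chr1\t200\t.\tC\tG\t50\tPASS\t.\tGT:DP\t1/1:9\n"
        "chr1\t300\t.\tC\tGT\t50\tPASS\t.\tGT:DP\t1/1:9\n")  # indel skipped
    cs = CallSet.from_vcf(path)
    assert len(cs) == 2
    assert cs.get(("chr1", 100)).genotype == HET
    assert cs.get(("chr1", 200)).genotype == HOM_ALT
    assert cs.get(("chr1", 200)).depth == 9
    assert cs.skipped_records == 1


def test_fates_table_shape():
    ref = {("chr1", 10): call(10, HOM_ALT)}
    fc = w.classify_fates(ref, callset([call(10, HOM_ALT)],
                                       depth_of=lambda c, p: 9))
    het_fc = w.classify_fates({}, callset([], depth_of=lambda c, p: 9))
    extra = {HOM_ALT: {DIFF_IN_BOTH_UNAMP: 0, CALLED_IN_ONE: 0},
             HET: {DIFF_IN_BOTH_UNAMP: 1, CALLED_IN_ONE: 2}}
    tab = fates_table(fc, het_fc, extra)
    assert set(tab["block"]) == {"reference_snps", "extra_calls"}
    assert len(tab) == 12
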