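"""SNP-call concordance between unamplified and amplified replicates.

The reference SNP set is the intersection of two unamplified technical
replicates (identical alt allele and zygosity at a site).  Each reference
SNP is then assigned a *fate* in the amplified replicates:

``no_low_coverage``
    Uncalled, with depth below ``min_depth`` in every amplified replicate —
    the site failed to amplify.
``not_called_same``
    Called with a different allele or zygosity in at least one replicate
    (classically a het reference miscalled as homozygous after allele
    dropout), or uncalled despite adequate depth everywhere.
``called_in_both``
    Identically recovered in both amplified replicates.
``called_in_one``
    Identically recovered in exactly one.

A second table classifies the *extra* calls of amplified replicates (sites
absent from the reference set) by their status in the unamplified data.
Only biallelic SNPs are considered; indels and multiallelic records are
skipped on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import pandas as pd

HOM_ALT = "hom_alt"
HET = "het"

NO_LOW_COVERAGE = "no_low_coverage"
NOT_CALLED_SAME = "not_called_same"
CALLED_IN_ONE = "called_in_one_replicate"
CALLED_IN_BOTH = "called_in_both_replicates"
DIFF_IN_BOTH_UNAMP = "called_differently_in_both_unamplified"

_FATES = (NO_LOW_COVERAGE, NOT_CALLED_SAME, CALLED_IN_ONE, CALLED_IN_BOTH)


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int          # 1-based
    ref: str
    alt: str
    genotype: str     # HOM_ALT | HET
    depth: int = 0

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.genotype not in (HOM_ALT, HET):
            raise ValueError(f"genotype must be {HOM_ALT} or {HET}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def site(self):
        return (self.chrom, self.pos)

    def same_call(self, other: "VariantCall") -> bool:
        return (self.site == other.site and self.alt == other.alt
                and self.genotype == other.genotype)


@dataclass
class CallSet:
    """Genotyped SNP calls of one sample plus a site-depth accessor.

    ``depth_of`` supplies coverage at *uncalled* sites (e.g. from the
    sample's own depth track); it defaults to 0 everywhere, which treats
    uncalled sites as unamplified.
    """

    sample: str
    calls: dict = field(default_factory=dict)  # (chrom, pos) -> VariantCall
    depth_of: Optional[Callable] = None

    def add(self, call: VariantCall) -> None:
        if call.site in self.calls:
            raise ValueError(f"duplicate call at {call.site}")
        self.calls[call.site] = call

    def get(self, site) -> Optional[VariantCall]:
        return self.calls.get(site)

    def depth_at(self, site) -> int:
        call = self.calls.get(site)
        if call is not None:
            return call.depth
        if self.depth_of is None:
            return 0
        return int(self.depth_of(*site))

    def __len__(self):
        return len(self.calls)

    @classmethod
    def from_vcf(cls, path, sample: Optional[str] = None,
                 depth_of: Optional[Callable] = None) -> "CallSet":
        """Load biallelic SNPs from a VCF (genotype from GT, depth from DP).

        Indels and multiallelic records are skipped with a warning count in
        ``attrs``-style return; heterozygous = one ref allele in GT.
        """
        import pysam
        cs = cls(sample=sample or str(path), depth_of=depth_of)
        skipped = 0
        with pysam.VariantFile(str(path)) as vcf:
            sname = sample or (list(vcf.header.samples)[0]
                               if len(vcf.header.samples) else None)
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    skipped += 1
                    continue
                ref, alt = rec.ref, rec.alts[0]
                if len(ref) != 1 or len(alt) != 1:
                    skipped += 1
                    continue
                if sname is not None:
                    s = rec.samples[sname]
                    gt = s.get("GT")
                    if gt is None or None in gt or not any(gt):
                        continue
                    genotype = HOM_ALT if all(gt) else HET
                    depth = s.get("DP") or rec.info.get("DP") or 0
                else:
                    genotype = HOM_ALT
                    depth = rec.info.get("DP") or 0
                cs.add(VariantCall(rec.chrom, rec.pos, ref, alt, genotype,
                                   int(depth)))
        cs.skipped_records = skipped
        return cs

    @classmethod
    def from_table(cls, path, sample: Optional[str] = None,
                   depth_of: Optional[Callable] = None) -> "CallSet":
        """Load calls from a TSV with columns chrom, pos, ref, alt,
        genotype, depth (the simulator/caller exchange format)."""
        df = pd.read_csv(path, sep="\t")
        cs = cls(sample=sample or str(path), depth_of=depth_of)
        for row in df.itertuples(index=False):
            cs.add(VariantCall(str(row.chrom), int(row.pos), row.ref, row.alt,
                               row.genotype, int(row.depth)))
        return cs


def build_reference_set(unamp_rep1: CallSet, unamp_rep2: CallSet):
    """Reference SNPs: called in both unamplified replicates with identical
    alt allele and zygosity; returned as (hom_set, het_set) dicts."""
    hom, het = {}, {}
    for site, c1 in unamp_rep1.calls.items():
        c2 = unamp_rep2.get(site)
        if c2 is None or not c1.same_call(c2):
            continue
        (hom if c1.genotype == HOM_ALT else het)[site] = c1
    return hom, het


@dataclass
class FateCounts:
    """Fate-category counts of a reference SNP set in amplified replicates."""

    counts: dict
    n_reference: int
    two_replicates: bool

    def __getitem__(self, fate):
        return self.counts[fate]

    def to_dict(self) -> dict:
        d = dict(self.counts)
        if not self.two_replicates:
            d[CALLED_IN_BOTH] = None  # not applicable with one replicate
        return d


def _fate_of(ref_call: VariantCall, amp_reps: list, min_depth: int) -> str:
    site = ref_call.site
    calls = [rep.get(site) for rep in amp_reps]
    present = [c for c in calls if c is not None]
    if not present:
        depths = [rep.depth_at(site) for rep in amp_reps]
        if all(d < min_depth for d in depths):
            return NO_LOW_COVERAGE
        return NOT_CALLED_SAME
    if any(not c.same_call(ref_call) for c in present):
        return NOT_CALLED_SAME
    if len(amp_reps) == 2 and len(present) == 2:
        return CALLED_IN_BOTH
    return CALLED_IN_ONE


def classify_fates(reference: dict, amp_rep1: CallSet,
                   amp_rep2: Optional[CallSet] = None,
                   min_depth: int = 5) -> FateCounts:
    """Classify the fate of each reference SNP in the amplified replicates.

    ``reference`` is one zygosity class from build_reference_set.  With a
    single amplified replicate the called-in-both category is reported as
    not applicable and identical recovery counts as called-in-one.
    """
    amp_reps = [amp_rep1] + ([amp_rep2] if amp_rep2 is not None else [])
    counts = {f: 0 for f in _FATES}
    for site, ref_call in reference.items():
        counts[_fate_of(ref_call, amp_reps, min_depth)] += 1
    return FateCounts(counts=counts, n_reference=len(reference),
                      two_replicates=amp_rep2 is not None)


def extra_call_fates(reference_sets, amplified: list,
                     unamp_rep1: CallSet, unamp_rep2: CallSet) -> dict:
    """Classify amplified calls absent from the reference set, per zygosity.

    For each such call: ``called_differently_in_both_unamplified`` when both
    unamplified replicates carry a *different* call at the site, and
    ``called_in_one_replicate`` when exactly one unamplified replicate
    carries the *same* call.
    """
    ref_sites = set()
    for rs in reference_sets:
        ref_sites.update(rs.keys())
    out = {HOM_ALT: {DIFF_IN_BOTH_UNAMP: 0, CALLED_IN_ONE: 0},
           HET: {DIFF_IN_BOTH_UNAMP: 0, CALLED_IN_ONE: 0}}
    seen = set()
    for rep in amplified:
        for site, call in rep.calls.items():
            if site in ref_sites:
                continue
            key = (site, call.alt, call.genotype)
            if key in seen:
                continue
            seen.add(key)
            u1, u2 = unamp_rep1.get(site), unamp_rep2.get(site)
            both_diff = (u1 is not None and u2 is not None
                         and not call.same_call(u1)
                         and not call.same_call(u2))
            matches = sum(1 for u in (u1, u2)
                          if u is not None and call.same_call(u))
            if both_diff:
                out[call.genotype][DIFF_IN_BOTH_UNAMP] += 1
            elif matches == 1:
                out[call.genotype][CALLED_IN_ONE] += 1
    return out


def threshold_caller(sites, min_depth: int = 5, het_min: float = 0.2,
                     hom_min: float = 0.8, sample: str = "toy") -> CallSet:
    """Toy allele-fraction threshold caller for dropout experiments.

    ``sites`` is an iterable of (chrom, pos, ref, alt, depth, alt_count).
    A site is called when depth >= min_depth: hom_alt at alt fraction >=
    hom_min, het at >= het_min.  This is a didactic caller used to
    demonstrate how binomial depth thinning converts het calls into hom
    calls; it is not part of the analysis path.
    """
    cs = CallSet(sample=sample)
    for chrom, pos, ref, alt, depth, alt_count in sites:
        if depth < min_depth or depth == 0:
            continue
        frac = alt_count / depth
        if frac >= hom_min:
            cs.add(VariantCall(chrom, pos, ref, alt, HOM_ALT, depth))
        elif frac >= het_min:
            cs.add(VariantCall(chrom, pos, ref, alt, HET, depth))
    return cs


def fates_table(hom: FateCounts, het: FateCounts, extra: dict) -> pd.DataFrame:
    """Assemble the two fate blocks as one tidy table."""
    rows = []
    for zyg, fc in (("hom", hom), ("het", het)):
        for fate, cnt in fc.to_dict().items():
            rows.append({"block": "reference_snps", "zygosity": zyg,
                         "fate": fate, "count": cnt})
    for zyg_key, zyg in ((HOM_ALT, "hom"), (HET, "het")):
        for fate, cnt in extra[zyg_key].items():
            rows.append({"block": "extra_calls", "zygosity": zyg,
                         "fate": fate, "count": cnt})
    return pd.DataFrame(rows)
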