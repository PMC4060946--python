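"""End-to-end orchestration: simulate -> classify -> profile -> concordance.

A single RunConfig drives the stages; all randomness flows from one master
seed through per-stage derived seeds, so identical configurations produce
identical numeric reports.  Each stage writes its own outputs under the run
directory and contributes a section to ``report.json``; a ``manifest.json``
echoes the full configuration and every file written.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import coverage as cov
from .bias import BiasModel, amplification_gain
from .fragments import simulate_fragments
from .genome import GenomeSpec, generate_genome
from .libraries import LibraryParams, simulate_library
from .pairs import LibraryConvention, chimera_signature, summarize_library
from .variants import (CallSet, build_reference_set, classify_fates,
                       extra_call_fates, fates_table)

log = logging.getLogger("wgaprof")


@dataclass
class RunConfig:
    """Declarative configuration of a full synthetic run."""

    out_dir: str
    seed: int = 0
    genome: dict = field(default_factory=lambda: {
        "length": 200_000, "gc_target": 0.36,
        "tandem_repeats": [[25, 40, 20]],
        "inverted_repeats": [[300, 100, 20]],
        "arm_cluster_fraction": 0.7})
    bias: dict = field(default_factory=dict)      # BiasModel fields
    n_fragments: int = 5_000
    p_priming: float = 0.03
    p_inverted_dup: float = 0.05
    short: dict = field(default_factory=lambda: {"n_pairs": 20_000})
    long: dict = field(default_factory=lambda: {
        "n_pairs": 20_000, "dup_rate": 0.03, "nonjunction_rate": 0.02,
        "circular_contaminant_rate": 0.02})
    window: int = 10_000
    write_reads: bool = True
    stages: tuple = ("sim", "classify", "coverage")
    # optional variant-concordance inputs (VCF or TSV call tables)
    unamp_vcfs: Optional[list] = None
    amp_vcfs: Optional[list] = None
    min_depth: int = 5

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _stage_seed(master: int, label: str) -> int:
    tag = zlib.crc32(label.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([master, tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the consolidated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    files: list = []

    gspec = GenomeSpec(seed=_stage_seed(config.seed, "genome"),
                       **{k: tuple(tuple(x) for x in v)
                          if isinstance(v, list) else v
                          for k, v in config.genome.items()})
    genome = generate_genome(gspec)
    model = BiasModel(**config.bias)
    gain = amplification_gain(genome, model)

    log.info("genome: %d bp, GC %.3f, %d repeat features",
             len(genome), genome.gc, len(genome.repeat_features))

    libs = {}
    if "sim" in config.stages:
        frags = simulate_fragments(
            genome, gain, config.n_fragments,
            p_priming=config.p_priming, p_inverted_dup=config.p_inverted_dup,
            seed=_stage_seed(config.seed, "fragments"))
        genome.write_fasta(out / "genome.fasta")
        genome.write_bed(out / "repeats.bed")
        files += ["genome.fasta", "repeats.bed"]
        for lt in ("short", "long"):
            params_dict = dict(getattr(config, lt))
            params_dict.setdefault("seed", _stage_seed(config.seed, f"lib-{lt}"))
            params = (LibraryParams.short(**params_dict) if lt == "short"
                      else LibraryParams.long(**params_dict))
            lib = simulate_library(frags, params)
            libs[lt] = lib
            lib.write_truth_sam(out / f"{lt}.truth.sam")
            lib.write_truth_table(out / f"{lt}.truth.tsv")
            lib.write_manifest(out / f"{lt}.manifest.json")
            files += [f"{lt}.truth.sam", f"{lt}.truth.tsv",
                      f"{lt}.manifest.json"]
            if config.write_reads:
                lib.write_fastq(out / lt)
                files += [f"{lt}_1.fastq", f"{lt}_2.fastq"]
        mech_counts = {m: int((libs["short"].frame["mechanism"] == m).sum())
                       for m in libs["short"].frame["mechanism"].unique()}
        report["sim"] = {"n_fragments": config.n_fragments,
                         "genome_length": len(genome),
                         "genome_gc": round(genome.gc, 4),
                         "short_pair_mechanisms": mech_counts}

    if "classify" in config.stages and libs:
        section = {}
        for lt, lib in libs.items():
            conv = (LibraryConvention.short() if lt == "short"
                    else LibraryConvention.long())
            summary = summarize_library(lib.frame, conv)
            sig = chimera_signature(lib.frame, conv,
                                    read_length=lib.params.read_length,
                                    genome_length=len(genome))
            section[lt] = {"summary": summary.to_dict(),
                           "chimera_signature": sig.to_dict()}
            pd_frame = lib.frame
            pd_frame.to_csv(out / f"{lt}.pairs.tsv", sep="\t", index=False)
            files.append(f"{lt}.pairs.tsv")
        report["classify"] = section

    if "coverage" in config.stages and libs:
        section = {}
        tables = {}
        for lt, lib in libs.items():
            conv = (LibraryConvention.short() if lt == "short"
                    else LibraryConvention.long())
            track = cov.depth_from_alignments(lib.frame, conv, len(genome),
                                              chrom=genome.name)
            curve = cov.evenness_curve(track)
            table = cov.window_stats(track, genome, window=config.window)
            tables[lt] = table
            table.to_csv(out / f"{lt}.windows.tsv", sep="\t", index=False)
            files.append(f"{lt}.windows.tsv")
            try:
                corr = cov.repeat_coverage_correlation(
                    table, seed=_stage_seed(config.seed, f"corr-{lt}"))
            except ValueError as exc:
                log.warning("repeat correlation skipped (%s): %s", lt, exc)
                corr = None
            gcd = cov.read_gc_distribution(lib.frame, genome,
                                           lib.params.read_length)
            section[lt] = {
                "mean_depth": track.mean,
                "evenness_deviation": curve.deviation,
                "repeat_correlation": corr,
                "gc_shift": gcd.shift,
            }
        diff = cov.library_gc_difference(tables["short"], tables["long"])
        section["long_minus_short_gc"] = diff.attrs["spearman"]
        report["coverage"] = section

    if config.unamp_vcfs and config.amp_vcfs:
        loader = (CallSet.from_vcf if str(config.unamp_vcfs[0]).endswith(
            (".vcf", ".vcf.gz")) else CallSet.from_table)
        u1, u2 = (loader(p) for p in config.unamp_vcfs[:2])
        amps = [loader(p) for p in config.amp_vcfs[:2]]
        hom_ref, het_ref = build_reference_set(u1, u2)
        amp2 = amps[1] if len(amps) > 1 else None
        hom_fc = classify_fates(hom_ref, amps[0], amp2, config.min_depth)
        het_fc = classify_fates(het_ref, amps[0], amp2, config.min_depth)
        extra = extra_call_fates((hom_ref, het_ref), amps, u1, u2)
        table = fates_table(hom_fc, het_fc, extra)
        table.to_csv(out / "snp_fates.tsv", sep="\t", index=False)
        files.append("snp_fates.tsv")
        report["snp_fates"] = {
            "n_reference_hom": len(hom_ref), "n_reference_het": len(het_ref),
            "hom": hom_fc.to_dict(), "het": het_fc.to_dict(),
            "extra": extra}

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    files.append("report.json")

    manifest = {"config": asdict(config), "files": sorted(set(files))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
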