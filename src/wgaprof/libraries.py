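"""Illumina-style library simulation from WGA fragment pools.

Two library types are modeled:

``short``
    Standard ~450 bp paired-end library: a fragment is sheared to an insert
    ~N(insert_mean, insert_sd), and the two reads face inward on the genome.
``long``
    ~3 kb mate-pair library: the two ends of a ~3 kb span are sequenced and
    face outward after circularization.  Two construction artifacts are
    injected at configurable rates: *non-junction* pairs (reads from a
    circularized-template segment lacking the junction adaptor — short,
    inward-facing) and *circular contaminants* (under-size-selected circles
    < 1.5 kb — short but correctly outward-facing).

PCR duplicates re-emit an existing pair verbatim.  Every emitted pair has
exactly one truth record (a row of the library's truth frame) giving each
mate's true origin, the source-fragment mechanism and the artifact class.

Shearing of fold-back (inverted-duplication) fragments honors the physics of
the folded molecule: the palindromic arms are base-paired, so one physical
cut of the folded duplex produces *both* ends of the linearized palindrome.
A shear window crossing the fold-back apex therefore has mirror-symmetric
end points about the apex, up to a small end-repair jitter — which is what
makes the two reads of an end-bridging pair map to the same locus on the
same strand with a start-to-start distance peaked at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .fragments import (AmplifiedFragment, INVERTED_DUP, NORMAL, PRIMING,
                        locate_window, pieces_sequence, slice_pieces)
from .genome import SyntheticGenome, revcomp

SHORT = "short"
LONG = "long"

CLEAN = "clean"
PCR_DUPLICATE = "pcr_duplicate"
NONJUNCTION = "nonjunction"
CIRCULAR = "circular_contaminant"

# End-repair jitter (bases, s.d.) between the two cut points of an
# apex-crossing shear of a folded palindrome.
APEX_JITTER_SD = 25.0

# Insert-size scales of the two long-library artifact classes: non-junction
# pairs are ordinary ~450 bp shears of the circle; circular contaminants are
# under-size-selected circles below the 1.5 kb selection cut-off.
NONJUNCTION_INSERT = (450.0, 50.0)
CIRCULAR_INSERT = (800.0, 250.0)
CIRCULAR_MAX = 1500


@dataclass(frozen=True)
class LibraryParams:
    """Parameters of a simulated sequencing library."""

    library_type: str
    insert_mean: float = 450.0
    insert_sd: float = 45.0
    read_length: int = 100
    n_pairs: int = 1000
    dup_rate: float = 0.0
    nonjunction_rate: float = 0.0
    circular_contaminant_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.library_type not in (SHORT, LONG):
            raise ValueError("library_type must be 'short' or 'long'")
        for r, name in [(self.dup_rate, "dup_rate"),
                        (self.nonjunction_rate, "nonjunction_rate"),
                        (self.circular_contaminant_rate,
                         "circular_contaminant_rate"),
                        (self.error_rate, "error_rate")]:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.library_type == SHORT and (
                self.nonjunction_rate or self.circular_contaminant_rate):
            raise ValueError("artifact rates apply to long libraries only")

    @classmethod
    def short(cls, **kw) -> "LibraryParams":
        kw.setdefault("insert_mean", 450.0)
        kw.setdefault("insert_sd", 45.0)
        return cls(library_type=SHORT, **kw)

    @classmethod
    def long(cls, **kw) -> "LibraryParams":
        kw.setdefault("insert_mean", 3000.0)
        kw.setdefault("insert_sd", 300.0)
        return cls(library_type=LONG, **kw)


_FRAME_COLUMNS = [
    "pair_id", "mechanism", "artifact", "frag_idx", "ins_start", "ins_len",
    "apex_h1", "chrom", "start1", "end1", "strand1", "frac1", "clip1",
    "start2", "end2", "strand2", "frac2", "clip2", "bridging",
]


@dataclass
class SimulatedLibrary:
    """A simulated library: truth frame plus writers for FASTQ/SAM/TSV."""

    frame: pd.DataFrame
    params: LibraryParams
    genome: SyntheticGenome
    fragments: list = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    # -- sequence reconstruction ------------------------------------------

    def _insert_pieces(self, row):
        frag = self.fragments[int(row.frag_idx)]
        I = int(row.ins_len)
        if int(row.ins_start) >= 0:
            x = int(row.ins_start)
            return slice_pieces(frag.pieces, x, x + I)
        # apex-crossing shear of a fold-back fragment
        loop = frag.loop_length
        h1 = int(row.apex_h1)
        h2 = I - loop - h1
        m = frag.apex
        return [(h1 + loop, m - h1, +1), (h2, m - h2, -1)]

    def _mate_seqs(self, row):
        rl = self.params.read_length
        seq = pieces_sequence(self.genome, self._insert_pieces(row))
        outward = _is_outward(self.params.library_type, row.artifact)
        if outward:
            return revcomp(seq[:rl]), seq[-rl:]
        return seq[:rl], revcomp(seq[-rl:])

    # -- writers -----------------------------------------------------------

    def write_fastq(self, prefix) -> tuple:
        """Write mate FASTQ files ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``.

        Substitution errors at ``error_rate`` are applied here; quality
        strings are constant high quality (no quality model).
        """
        rl = self.params.read_length
        qual = "I" * rl
        err_rng = np.random.default_rng([self.params.seed, 104729])
        p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for row in self.frame.itertuples(index=False):
                s1, s2 = self._mate_seqs(row)
                if self.params.error_rate > 0:
                    s1 = _mutate(s1, self.params.error_rate, err_rng)
                    s2 = _mutate(s2, self.params.error_rate, err_rng)
                name = f"pair{row.pair_id:08d}"
                f1.write(f"@{name}/1\n{s1}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{qual}\n")
        return p1, p2

    def write_truth_sam(self, path) -> None:
        """Write truth alignments (each mate's own origin locus) as SAM.

        Custom tags: ZM source-fragment mechanism, ZA artifact class,
        ZF aligned fraction of the read, ZB 1 if the pair bridges a chimeric
        junction (truth same-orientation pair).
        """
        rl = self.params.read_length
        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": self.genome.name, "LN": len(self.genome)}]}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for row in self.frame.itertuples(index=False):
                for mate in (1, 2):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"pair{row.pair_id:08d}"
                    start = int(getattr(row, f"start{mate}"))
                    end = int(getattr(row, f"end{mate}"))
                    strand = int(getattr(row, f"strand{mate}"))
                    frac = float(getattr(row, f"frac{mate}"))
                    clip_start = bool(getattr(row, f"clip{mate}"))
                    flag = 0x1 | (0x40 if mate == 1 else 0x80)
                    if strand < 0:
                        flag |= 0x10
                    other = 2 if mate == 1 else 1
                    if int(getattr(row, f"strand{other}")) < 0:
                        flag |= 0x20
                    a.flag = flag
                    a.reference_id = 0
                    a.reference_start = start
                    a.mapping_quality = 60
                    aligned = end - start
                    clip = rl - aligned
                    if clip == 0:
                        a.cigartuples = [(0, rl)]
                    elif clip_start:
                        a.cigartuples = [(4, clip), (0, aligned)]
                    else:
                        a.cigartuples = [(0, aligned), (4, clip)]
                    a.next_reference_id = 0
                    a.next_reference_start = int(getattr(row, f"start{other}"))
                    a.set_tags([("ZM", row.mechanism), ("ZA", row.artifact),
                                ("ZF", round(frac, 4), "f"),
                                ("ZB", int(row.bridging))])
                    out.write(a)

    def write_truth_table(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def write_manifest(self, path, extra: Optional[dict] = None) -> None:
        man = {"library": asdict(self.params), "genome": self.genome.name,
               "genome_length": len(self.genome),
               "n_fragments": len(self.fragments),
               "n_pairs": int(self.n_pairs)}
        if extra:
            man.update(extra)
        with open(path, "w") as fh:
            json.dump(man, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def _is_outward(library_type: str, artifact: str) -> bool:
    """Read facing of a pair: inward for short-library shears and
    non-junction artifacts, outward for mate-pair junction reads and
    circular contaminants (which circularized correctly, just too small)."""
    if library_type == SHORT:
        return False
    return artifact != NONJUNCTION


# ---------------------------------------------------------------------------
# pair generation


def _truncated_insert(rng, n, mean, sd, lo, hi=None):
    vals = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    for _ in range(100):
        bad = (vals < lo) | ((vals > hi) if hi is not None else False)
        if not bad.any():
            break
        vals[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(
            np.int64)
    np.clip(vals, lo, hi, out=vals)
    return vals


def _chimeric_pair(rng, frag: AmplifiedFragment, I: int, rl: int,
                   outward: bool):
    """Draw one insert from a chimeric fragment; returns truth mate fields.

    For fold-back fragments the apex-crossing branch uses mirror-symmetric
    cut points (see module docstring); other windows shear uniformly and
    mates are located on the genome via the fragment's segment map.
    """
    L = frag.length
    I = min(I, L)
    pieces = None
    ins_start = -1
    apex_h1 = -1
    if frag.mechanism == INVERTED_DUP:
        loop = frag.loop_length
        arm = frag.dup_arm_length
        # Any window overlapping the fold-back loop is an apex piece: the
        # folded duplex cannot be cut "half-way across" the hairpin, so one
        # physical cut yields both ends of the linearized palindrome.
        T = L - I + 1
        b0, b1 = max(0, arm - I + 1), min(arm + loop - 1, L - I)
        B = max(0, b1 - b0 + 1) if I - loop >= 2 * rl else 0
        if B and rng.random() < min(1.0, B / T):
            span = I - loop
            max_d = span - 2 * rl
            delta = int(np.clip(round(rng.normal(0.0, APEX_JITTER_SD)),
                                -max_d, max_d))
            h1 = (span + delta) // 2
            h1 = min(max(h1, rl), span - rl)
            h2 = span - h1
            m = frag.apex
            pieces = [(h1 + loop, m - h1, +1), (h2, m - h2, -1)]
            apex_h1 = h1
        else:
            # uniform shear over the windows wholly on one side of the apex
            for _ in range(1000):
                x = int(rng.integers(0, L - I + 1))
                if not (b0 <= x <= b1) or B == 0:
                    break
            pieces = slice_pieces(frag.pieces, x, x + I)
            ins_start = x
    else:
        x = int(rng.integers(0, L - I + 1))
        pieces = slice_pieces(frag.pieces, x, x + I)
        ins_start = x

    o1 = locate_window(pieces, 0, rl)
    o2 = locate_window(pieces, I - rl, I)
    # read sense: inward extraction reads mate1 forward / mate2 reverse,
    # outward extraction the opposite; mapped strand = piece strand for a
    # forward-sense read, flipped for a reverse-sense read.
    s1 = o1.piece_strand * (-1 if outward else +1)
    s2 = o2.piece_strand * (+1 if outward else -1)
    return dict(ins_start=ins_start, ins_len=I, apex_h1=apex_h1,
                start1=o1.gstart, end1=o1.gend, strand1=s1,
                frac1=o1.aligned_frac, clip1=o1.clip_start,
                start2=o2.gstart, end2=o2.gend, strand2=s2,
                frac2=o2.aligned_frac, clip2=o2.clip_start)


def simulate_library(fragments: list, params: LibraryParams) -> SimulatedLibrary:
    """Simulate a paired-read library from a WGA fragment pool.

    Deterministic for fixed fragments and params (including seed).  Raises
    if the pool is empty or no fragment can accommodate a required span.
    """
    if not fragments:
        raise ValueError("fragment pool is empty")
    genome = fragments[0].genome
    rl = params.read_length
    rng = np.random.default_rng(params.seed)

    n = params.n_pairs
    n_dup = int(rng.binomial(n, params.dup_rate)) if params.dup_rate else 0
    n_new = n - n_dup
    if n_new == 0:
        raise ValueError("dup_rate too high: no original pairs to duplicate")

    flen = np.array([f.length for f in fragments], dtype=np.int64)
    order = np.argsort(flen)
    sorted_len = flen[order]

    frag_idx = rng.integers(0, len(fragments), size=n_new)

    # artifact classes (long-library construction artifacts)
    artifact = np.full(n_new, CLEAN, dtype=object)
    if params.library_type == LONG:
        u = rng.random(n_new)
        nj, cc = params.nonjunction_rate, params.circular_contaminant_rate
        artifact[u < nj] = NONJUNCTION
        artifact[(u >= nj) & (u < nj + cc)] = CIRCULAR

    # insert lengths by class
    ins_len = np.empty(n_new, dtype=np.int64)
    clean = artifact == CLEAN
    ins_len[clean] = _truncated_insert(
        rng, int(clean.sum()), params.insert_mean, params.insert_sd, rl)
    if params.library_type == LONG:
        m = artifact == NONJUNCTION
        if m.any():
            ins_len[m] = _truncated_insert(rng, int(m.sum()),
                                           *NONJUNCTION_INSERT, rl)
        m = artifact == CIRCULAR
        if m.any():
            ins_len[m] = _truncated_insert(rng, int(m.sum()),
                                           *CIRCULAR_INSERT, rl,
                                           hi=CIRCULAR_MAX - 1)

    # fragments must accommodate the span: re-draw from eligible fragments
    too_short = ins_len > flen[frag_idx]
    if too_short.any():
        ks = np.searchsorted(sorted_len, ins_len[too_short])
        if (ks >= len(fragments)).any():
            raise ValueError("no fragment can accommodate a required span")
        pick = ks + (rng.random(int(too_short.sum()))
                     * (len(fragments) - ks)).astype(np.int64)
        frag_idx[too_short] = order[pick]

    mech = np.array([fragments[i].mechanism for i in frag_idx], dtype=object)

    cols = {
        "mechanism": mech, "artifact": artifact, "frag_idx": frag_idx,
        "ins_start": np.full(n_new, -1, dtype=np.int64),
        "ins_len": ins_len,
        "apex_h1": np.full(n_new, -1, dtype=np.int64),
        "start1": np.zeros(n_new, dtype=np.int64),
        "end1": np.zeros(n_new, dtype=np.int64),
        "strand1": np.zeros(n_new, dtype=np.int64),
        "frac1": np.ones(n_new), "clip1": np.zeros(n_new, dtype=bool),
        "start2": np.zeros(n_new, dtype=np.int64),
        "end2": np.zeros(n_new, dtype=np.int64),
        "strand2": np.zeros(n_new, dtype=np.int64),
        "frac2": np.ones(n_new), "clip2": np.zeros(n_new, dtype=bool),
    }

    # vectorized path: inserts from normal (contiguous) fragments
    vec = mech == NORMAL
    if vec.any():
        vi = np.nonzero(vec)[0]
        L = flen[frag_idx[vi]]
        I = ins_len[vi]
        fstart = np.array([fragments[i].pieces[0][1] for i in frag_idx[vi]],
                          dtype=np.int64)
        x = (rng.random(len(vi)) * (L - I + 1)).astype(np.int64)
        g = fstart + x
        outward = np.array([_is_outward(params.library_type, a)
                            for a in artifact[vi]])
        cols["ins_start"][vi] = x
        cols["start1"][vi] = g
        cols["end1"][vi] = g + rl
        cols["strand1"][vi] = np.where(outward, -1, +1)
        cols["start2"][vi] = g + I - rl
        cols["end2"][vi] = g + I
        cols["strand2"][vi] = np.where(outward, +1, -1)

    # per-pair path: inserts from chimeric fragments
    for i in np.nonzero(~vec)[0]:
        frag = fragments[frag_idx[i]]
        out = _is_outward(params.library_type, artifact[i])
        d = _chimeric_pair(rng, frag, int(ins_len[i]), rl, out)
        for k, v in d.items():
            cols[k][i] = v

    frame = pd.DataFrame(cols)

    # PCR duplicates re-emit an existing pair, truth copied verbatim except
    # for the artifact class
    if n_dup:
        src = rng.integers(0, n_new, size=n_dup)
        dups = frame.iloc[src].copy()
        dups["artifact"] = PCR_DUPLICATE
        frame = pd.concat([frame, dups], ignore_index=True)

    perm = rng.permutation(len(frame))
    frame = frame.iloc[perm].reset_index(drop=True)
    frame.insert(0, "pair_id", np.arange(len(frame), dtype=np.int64))
    frame.insert(7, "chrom", genome.name)
    frame["bridging"] = frame["strand1"] == frame["strand2"]
    frame = frame[_FRAME_COLUMNS]

    return SimulatedLibrary(frame=frame, params=params, genome=genome,
                            fragments=fragments)


def simulate_short_library(fragments, params: LibraryParams) -> SimulatedLibrary:
    if params.library_type != SHORT:
        raise ValueError("params.library_type must be 'short'")
    return simulate_library(fragments, params)


def simulate_long_library(fragments, params: LibraryParams) -> SimulatedLibrary:
    if params.library_type != LONG:
        raise ValueError("params.library_type must be 'long'")
    return simulate_library(fragments, params)
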