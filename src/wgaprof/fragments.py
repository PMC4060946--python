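"""WGA fragment populations: normal products and the two chimera mechanisms.

Strand-displacement amplification yields three fragment classes modeled here:

``normal``
    An exact contiguous copy of the genome.
``priming_chimera``
    Re-priming from a displaced 3' terminus joins a segment *a* to a
    downstream segment *c* copied in reverse complement, deleting the
    intervening segment *b*: fragment = a + revcomp(c).
``inverted_dup``
    A fold-back product: the displaced strand anneals back on itself, so the
    fragment begins with a sequence s and ends with revcomp(s), separated by
    a short stretch of unknown (here: contiguous downstream genomic)
    sequence at the turnaround.

Every fragment carries a *segment map* — an ordered list of
``(length, genome_start, strand)`` pieces — from which its sequence and the
true genomic origin of any sub-window can be derived exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .bias import GainTrack, sample_positions
from .genome import SyntheticGenome, revcomp

NORMAL = "normal"
PRIMING = "priming_chimera"
INVERTED_DUP = "inverted_dup"

# A piece is (length, genome_start, strand) with strand +1 (forward copy)
# or -1 (reverse-complemented copy); genome interval is
# [genome_start, genome_start + length) regardless of strand.
Piece = tuple


def pieces_sequence(genome: SyntheticGenome, pieces) -> str:
    parts = []
    for length, gstart, strand in pieces:
        chunk = genome.sequence[gstart:gstart + length]
        parts.append(chunk if strand > 0 else revcomp(chunk))
    return "".join(parts)


def slice_pieces(pieces, start: int, end: int):
    """Sub-map of fragment coordinates [start, end)."""
    out = []
    off = 0
    for length, gstart, strand in pieces:
        lo, hi = max(start, off), min(end, off + length)
        if lo < hi:
            a, b = lo - off, hi - off          # within-piece offsets
            if strand > 0:
                out.append((hi - lo, gstart + a, strand))
            else:
                out.append((hi - lo, gstart + length - b, strand))
        off += length
    return out


@dataclass
class MateOrigin:
    """True genomic origin of a read window on a fragment.

    ``aligned_frac`` is the fraction of the window lying in its majority
    piece; windows straddling a chimeric junction align only partially, like
    a soft-clipped read.  ``clip_start`` reports whether the unaligned part
    sits at the window start (in window coordinates).
    """

    gstart: int
    gend: int
    piece_strand: int
    aligned_frac: float
    clip_start: bool


def locate_window(pieces, wstart: int, wend: int) -> MateOrigin:
    """Locate a fragment-coordinate window on the genome via its majority piece."""
    best = None
    off = 0
    for length, gstart, strand in pieces:
        lo, hi = max(wstart, off), min(wend, off + length)
        if hi - lo > 0 and (best is None or hi - lo > best[0]):
            best = (hi - lo, lo, hi, length, gstart, strand, off)
        off += length
    if best is None:
        raise ValueError("window outside fragment")
    ov, lo, hi, plen, gstart, strand, poff = best
    a, b = lo - poff, hi - poff
    if strand > 0:
        g0, g1 = gstart + a, gstart + b
    else:
        g0, g1 = gstart + plen - b, gstart + plen - a
    return MateOrigin(gstart=g0, gend=g1, piece_strand=strand,
                      aligned_frac=ov / (wend - wstart),
                      clip_start=(lo > wstart))


@dataclass
class AmplifiedFragment:
    """A single WGA product with its truth segment map."""

    mechanism: str
    pieces: list
    length: int
    genome: SyntheticGenome = field(repr=False)
    seg_a: Optional[tuple] = None          # (start, end, strand)
    seg_b_deleted: Optional[tuple] = None  # (start, end)
    seg_c: Optional[tuple] = None          # (start, end, strand)
    dup_arm_length: Optional[int] = None
    loop_length: Optional[int] = None

    @property
    def sequence(self) -> str:
        """Materialize the fragment sequence (lazy; maps stay compact)."""
        return pieces_sequence(self.genome, self.pieces)

    @property
    def apex(self) -> Optional[int]:
        """Genomic coordinate of the fold-back turnaround (inverted_dup only)."""
        if self.mechanism != INVERTED_DUP:
            return None
        return self.seg_a[0] + self.dup_arm_length


# ---------------------------------------------------------------------------
# Length distributions.  Each is a callable rng -> int so callers can swap in
# arbitrary models; the defaults reflect MDA product scales (fragments well
# above 10 kb were observed after amplification) and chimera deletions that
# reach beyond 10 kb.

def log_uniform(lo: int, hi: int) -> Callable:
    la, lb = math.log(lo), math.log(hi)

    def draw(rng: np.random.Generator) -> int:
        return int(round(math.exp(rng.uniform(la, lb))))
    return draw


def uniform_int(lo: int, hi: int) -> Callable:
    def draw(rng: np.random.Generator) -> int:
        return int(rng.integers(lo, hi + 1))
    return draw


DEFAULT_FRAG_LEN = log_uniform(5_000, 20_000)
DEFAULT_DELETION_LEN = log_uniform(100, 20_000)
DEFAULT_DUP_ARM = log_uniform(2_500, 10_000)
DEFAULT_LOOP_LEN = uniform_int(20, 80)

_MIN_SEG = 200      # minimum priming-chimera segment length
_MAX_TRIES = 200


def _sample_start(track, rng, glen, span):
    """Gain-weighted start position leaving room for ``span`` bases."""
    for _ in range(_MAX_TRIES):
        pos = int(sample_positions(track, 1, rng, glen)[0])
        if pos + span <= glen:
            return pos
    raise ValueError(
        f"cannot place a fragment of span {span} in a genome of {glen} bases")


def simulate_fragments(genome: SyntheticGenome,
                       gain: GainTrack,
                       n: int,
                       *,
                       p_priming: float = 0.0,
                       p_inverted_dup: float = 0.0,
                       frag_len_dist: Callable = DEFAULT_FRAG_LEN,
                       deletion_len_dist: Callable = DEFAULT_DELETION_LEN,
                       dup_arm_dist: Callable = DEFAULT_DUP_ARM,
                       loop_len_dist: Callable = DEFAULT_LOOP_LEN,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> list:
    """Simulate ``n`` amplified fragments with gain-weighted placement.

    Each fragment's mechanism is drawn independently with probabilities
    ``p_priming`` and ``p_inverted_dup`` (remainder: normal).  Start
    positions are sampled proportionally to the gain track.  Fragments that
    cannot be placed (longer than the genome allows) raise after bounded
    retries.
    """
    if p_priming < 0 or p_inverted_dup < 0 or p_priming + p_inverted_dup > 1:
        raise ValueError("mechanism probabilities must be >=0 and sum to <=1")
    if rng is None:
        rng = np.random.default_rng(seed)
    glen = len(genome)
    mech = rng.choice(
        3, size=n, p=[1.0 - p_priming - p_inverted_dup, p_priming,
                      p_inverted_dup])

    frags = []
    for m in mech:
        if m == 0:
            L = frag_len_dist(rng)
            start = _sample_start(gain, rng, glen, L)
            frags.append(AmplifiedFragment(
                mechanism=NORMAL, pieces=[(L, start, +1)], length=L,
                genome=genome))
        elif m == 1:
            L = frag_len_dist(rng)
            len_a = int(rng.integers(_MIN_SEG, max(_MIN_SEG + 1, L - _MIN_SEG)))
            len_c = L - len_a
            dlen = deletion_len_dist(rng)
            start = _sample_start(gain, rng, glen, len_a + dlen + len_c)
            a = (start, start + len_a, +1)
            b = (start + len_a, start + len_a + dlen)
            c = (b[1], b[1] + len_c, -1)
            frags.append(AmplifiedFragment(
                mechanism=PRIMING, length=L,
                pieces=[(len_a, a[0], +1), (len_c, c[0], -1)],
                genome=genome, seg_a=a, seg_b_deleted=b, seg_c=c))
        else:
            arm = dup_arm_dist(rng)
            loop = loop_len_dist(rng)
            L = 2 * arm + loop
            start = _sample_start(gain, rng, glen, arm + loop)
            frags.append(AmplifiedFragment(
                mechanism=INVERTED_DUP, length=L,
                pieces=[(arm + loop, start, +1), (arm, start, -1)],
                genome=genome, seg_a=(start, start + arm, +1),
                dup_arm_length=arm, loop_length=loop))
    return frags
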