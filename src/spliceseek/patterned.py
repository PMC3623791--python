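"""Patterned fragment-pair alignment: the core junction-finding heuristic.

Each read that fails contiguous alignment is split at systematic cutoffs p
into left/right fragment pairs.  Pairs whose fragments both place uniquely
on the genome ("double matches") bracket a candidate intron directly; when
no double match exists, the longest uniquely aligned fragment anchors a
windowed local search for the complementary fragment ("single-match
rescue").  The exon-intron boundary of every candidate is then refined by
shifting the cutoff a few nucleotides to minimize alignment mismatches, and
the resulting introns are scored with the junction model; the best-scoring
candidate is the read's putative junction.

Internally every candidate is canonicalized to forward-strand geometry: for
a minus-strand placement the reverse-complemented read is used, so the
"left" fragment is always the genomically upstream one.  The biological
strand of the junction is assigned later from the splice-signal orientation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._dna import N_CODE, encode, revcomp
from .aligner import AlignmentHit, SeedIndex, align_fragment, local_align_candidates
from .io_formats import Genome, ReadRecord
from .junction_model import JunctionModel, detect_signal

logger = logging.getLogger(__name__)


@dataclass
class PatternParams:
    """Tunable parameters of the patterned-alignment procedure.

    m: minimum genome-alignable fragment size (nt).
    s: stepping distance between cutoffs (nt).
    min_local: minimum fragment size for windowed local alignment (nt).
    window: span of the local-alignment search region (bp).
    adjust: boundary adjustment radius around a cutoff (nt).
    """

    m: int = 14
    s: int = 4
    min_local: int = 6
    window: int = 100_000
    adjust: int = 2
    max_mismatches: int = 2
    min_intron: int = 20
    max_intron: int = 500_000
    local_divisor: int = 7
    max_local_candidates: int = 50

    def __post_init__(self):
        if self.min_local > self.m:
            raise ValueError("min_local must not exceed m")
        if self.s < 1 or self.adjust < 1:
            raise ValueError("s and adjust must be >= 1")


@dataclass(frozen=True)
class FragmentPair:
    """One split of a read at cutoff p; alignability flags mark which sides
    are long enough for whole-genome placement (length >= m)."""

    p: int
    left_len: int
    right_len: int
    left_alignable: bool
    right_alignable: bool

    @property
    def double(self) -> bool:
        return self.left_alignable and self.right_alignable


def generate_fragment_pairs(n: int, params: PatternParams) -> List[FragmentPair]:
    """Cutoff descriptors for a read of length n.

    Cutoffs lie on the arithmetic grid p = m + i*s (i integer, possibly
    negative) restricted to min(p, n-p) >= min_local: the [m, n-m] stretch
    gives double-alignable pairs, the extension below m / above n-m gives
    one-alignable pairs for the single-match path.
    """
    if n < 2 * params.min_local:
        logger.warning("read length %d < 2*min_local; no fragment pairs", n)
        return []
    lo = params.min_local
    hi = n - params.min_local
    # first grid point >= lo
    i0 = -((params.m - lo) // params.s)
    p = params.m + i0 * params.s
    out = []
    while p <= hi:
        out.append(
            FragmentPair(
                p=p,
                left_len=p,
                right_len=n - p,
                left_alignable=p >= params.m,
                right_alignable=(n - p) >= params.m,
            )
        )
        p += params.s
    return out


@dataclass(frozen=True)
class Candidate:
    """A bracketing of a candidate intron, in forward-strand geometry.

    ``seq`` is the read oriented to the forward strand (reverse-complemented
    when ``orient`` is '-').  The left fragment seq[:p] starts at
    ``left_start``; the right fragment seq[p:] ends at ``right_end``; the
    implied intron is [left_start+p, right_end-(n-p)), whose length
    right_end - left_start - n is invariant under cutoff shifts.
    """

    chromosome: str
    left_start: int
    right_end: int
    p: int
    seq: str
    orient: str

    @property
    def intron_length(self) -> int:
        return self.right_end - self.left_start - len(self.seq)


def _unique_hit(hits: List[AlignmentHit]) -> Optional[AlignmentHit]:
    return hits[0] if hits and hits[0].unique else None


def find_double_matches(
    read_seq: str,
    pairs: Sequence[FragmentPair],
    index: SeedIndex,
    genome: Genome,
    params: PatternParams,
) -> List[Candidate]:
    """Candidates from patterned pairs whose fragments both align uniquely.

    Left and right hits must share chromosome and strand, with the right
    fragment downstream of the left in read orientation and an implied
    intron length within [min_intron, max_intron].
    """
    n = len(read_seq)
    rc = None
    out: List[Candidate] = []
    seen = set()
    for pair in pairs:
        if not pair.double:
            continue
        p = pair.p
        lh = _unique_hit(align_fragment(index, genome, read_seq[:p], params.max_mismatches))
        if lh is None:
            continue
        rh = _unique_hit(align_fragment(index, genome, read_seq[p:], params.max_mismatches))
        if rh is None:
            continue
        if lh.chromosome != rh.chromosome or lh.strand != rh.strand:
            continue
        if lh.strand == "+":
            cand = Candidate(
                chromosome=lh.chromosome,
                left_start=lh.start,
                right_end=rh.start + (n - p),
                p=p,
                seq=read_seq,
                orient="+",
            )
        else:
            if rc is None:
                rc = revcomp(read_seq)
            cand = Candidate(
                chromosome=lh.chromosome,
                left_start=rh.start,
                right_end=lh.start + p,
                p=n - p,
                seq=rc,
                orient="-",
            )
        if not (params.min_intron <= cand.intron_length <= params.max_intron):
            continue
        key = (cand.chromosome, cand.left_start, cand.right_end, cand.p)
        if key not in seen:
            seen.add(key)
            out.append(cand)
    return out


@dataclass(frozen=True)
class RefinedBoundary:
    p_star: int
    donor_end: int
    acceptor_start: int
    mismatches: int
    evaluated_cutoffs: Tuple[int, ...]


def refinement_cutoffs(p: int, adjust: int, n: int) -> List[int]:
    """Cutoffs evaluated when refining a boundary detected at cutoff p."""
    return [q for q in range(p - adjust, p + adjust + 1) if 1 <= q <= n - 1]


def refine_boundary(
    candidate: Candidate, genome: Genome, params: PatternParams
) -> RefinedBoundary:
    """Mismatch-minimizing boundary refinement around the detected cutoff.

    Evaluates cutoffs p' in [p-adjust, p+adjust]; for each, the left fragment
    seq[:p'] sits at the left hit's locus and the right fragment seq[p':]
    ends where the right hit ends.  Ties prefer a cutoff whose implied intron
    carries a recognized splice signal, then the smallest |p'-p|, then the
    smaller p'.  Never increases mismatches relative to the unrefined cutoff.
    """
    arr = genome.arrays()[candidate.chromosome]
    seq = candidate.seq
    n = len(seq)
    codes = encode(seq)
    ls, re_ = candidate.left_start, candidate.right_end
    cutoffs = refinement_cutoffs(candidate.p, params.adjust, n)

    # per-base mismatch indicators against the two anchored loci
    def _cmp(genome_start: int) -> np.ndarray:
        out = np.ones(n, dtype=bool)
        g0 = max(0, genome_start)
        g1 = min(len(arr), genome_start + n)
        if g1 > g0:
            i0 = g0 - genome_start
            i1 = g1 - genome_start
            gslice = arr[g0:g1]
            out[i0:i1] = (gslice != codes[i0:i1]) | (gslice == N_CODE)
        return out

    left_cmp = np.cumsum(np.concatenate(([False], _cmp(ls))))
    right_cmp_arr = _cmp(re_ - n)
    right_cmp = np.cumsum(np.concatenate(([False], right_cmp_arr)))
    right_total = right_cmp[-1]

    best = None
    for q in cutoffs:
        if ls + q > len(arr) or re_ - (n - q) < 0:
            continue
        mm = int(left_cmp[q] + (right_total - right_cmp[q]))
        donor = ls + q
        acceptor = re_ - (n - q)
        sig, _ = detect_signal(genome, candidate.chromosome, donor, acceptor)
        sig_rank = {"GT-AG": 0, "GC-AG": 1, "AT-AC": 2}.get(sig, 3)
        key = (mm, sig_rank, abs(q - candidate.p), q)
        if best is None or key < best[0]:
            best = (key, q, donor, acceptor, mm)
    if best is None:  # every adjusted cutoff fell outside the chromosome
        q = candidate.p
        return RefinedBoundary(q, ls + q, re_ - (n - q), n, tuple(cutoffs))
    _, q, donor, acceptor, mm = best
    return RefinedBoundary(q, donor, acceptor, mm, tuple(cutoffs))


def rescue_single_match(
    read_seq: str,
    pairs: Sequence[FragmentPair],
    index: SeedIndex,
    genome: Genome,
    params: PatternParams,
    mate_anchor: Optional[Tuple[str, int, int]] = None,
) -> List[Candidate]:
    """Single-match path: anchor by the longest uniquely aligned fragment and
    locally align the complementary fragment within a bounded window.

    The search window lies on the intron-side flank of the anchor (downstream
    when the anchor is the 5' fragment, upstream otherwise) and is clipped by
    the mate span when ``mate_anchor`` (chrom, start, end) is given.  Around
    the anchor's grid cutoff, remainder cutoffs within the boundary
    adjustment radius are also tried, and every minimal-mismatch placement is
    kept as a candidate — the junction model arbitrates between them.
    """
    n = len(read_seq)
    anchors = []  # (length, mismatches, side, p, hit)
    for pair in pairs:
        for side, flen, frag in (
            ("L", pair.left_len, read_seq[: pair.p]),
            ("R", pair.right_len, read_seq[pair.p :]),
        ):
            if (side == "L" and not pair.left_alignable) or (
                side == "R" and not pair.right_alignable
            ):
                continue
            h = _unique_hit(align_fragment(index, genome, frag, params.max_mismatches))
            if h is not None:
                anchors.append((flen, h.mismatches, side, pair.p, h))
    if not anchors:
        return []
    anchors.sort(key=lambda a: (-a[0], a[1], a[2], a[3]))
    best_len = anchors[0][0]
    out: List[Candidate] = []
    seen = set()
    for flen, _, side, p, hit in anchors:
        if flen != best_len:
            break
        # canonicalize to forward-strand geometry
        if hit.strand == "+":
            cseq, cside, p0 = read_seq, side, p
        else:
            cseq, cside, p0 = revcomp(read_seq), ("R" if side == "L" else "L"), n - p
        chrom = hit.chromosome
        chrlen = len(genome.sequences[chrom])
        for q in refinement_cutoffs(p0, params.adjust, n):
            if min(q, n - q) < params.min_local:
                continue
            if cside == "L":
                a = hit.start
                remainder = cseq[q:]
                ws = a + q + params.min_intron
                we = a + q + params.window
                if mate_anchor is not None and mate_anchor[0] == chrom:
                    # the mate delimits the downstream search only when it
                    # actually lies downstream (minus-strand pairs flip)
                    clipped = min(we, mate_anchor[2])
                    if clipped - ws >= len(remainder):
                        we = clipped
                placements = local_align_candidates(
                    genome, remainder, chrom, ws, we,
                    anchor_pos=a + q,
                    mismatch_divisor=params.local_divisor,
                    max_candidates=params.max_local_candidates,
                )
                for ph in placements:
                    cand = Candidate(
                        chromosome=chrom,
                        left_start=a,
                        right_end=ph.start + (n - q),
                        p=q,
                        seq=cseq,
                        orient=hit.strand,
                    )
                    key = (cand.left_start, cand.right_end, cand.p)
                    if key not in seen and (
                        params.min_intron <= cand.intron_length <= params.max_intron
                    ):
                        seen.add(key)
                        out.append(cand)
            else:
                b = hit.start  # anchor fragment cseq[p0:] starts at b
                right_end = b + (n - p0)
                remainder = cseq[:q]
                we = b - params.min_intron
                ws = b - params.window
                if mate_anchor is not None and mate_anchor[0] == chrom:
                    clipped = max(ws, mate_anchor[1])
                    if we - clipped >= len(remainder):
                        ws = clipped
                placements = local_align_candidates(
                    genome, remainder, chrom, ws, we,
                    anchor_pos=b - q,
                    mismatch_divisor=params.local_divisor,
                    max_candidates=params.max_local_candidates,
                )
                for ph in placements:
                    cand = Candidate(
                        chromosome=chrom,
                        left_start=ph.start,
                        right_end=right_end,
                        p=q,
                        seq=cseq,
                        orient=hit.strand,
                    )
                    key = (cand.left_start, cand.right_end, cand.p)
                    if key not in seen and (
                        params.min_intron <= cand.intron_length <= params.max_intron
                    ):
                        seen.add(key)
                        out.append(cand)
        if out:
            break  # the longest anchor produced candidates
    return out


@dataclass
class PutativeJunction:
    """One read's evidence for an intron, after boundary refinement.

    donor_end / acceptor_start delimit the intron [donor_end, acceptor_start)
    in 0-based genomic coordinates; strand comes from the splice-signal
    orientation ('.' when unresolved).  ``orient`` records the read's
    alignment orientation, ``cutoff``/``left_start`` the refined placement
    (enough to reconstruct the spliced SAM record).
    """

    read_id: str
    chromosome: str
    strand: str
    donor_end: int
    acceptor_start: int
    total_mismatches: int
    anchor_len: int
    signal_class: str
    score: float
    orient: str
    cutoff: int
    left_start: int
    seq: str = field(repr=False, default="")
    is_best: bool = False

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


def process_read(
    read: ReadRecord,
    index: SeedIndex,
    genome: Genome,
    params: PatternParams,
    model: JunctionModel,
    mate_anchor: Optional[Tuple[str, int, int]] = None,
) -> List[PutativeJunction]:
    """All scored junction candidates for one unaligned read; the best-scoring
    candidate is marked (``is_best``).

    Double-match candidates are collected first; the single-match rescue runs
    only when there are none.  Every candidate's boundary is refined, its
    intron featurized and scored with the junction model.
    """
    seq = read.sequence
    n = len(seq)
    if n < 2 * params.min_local:
        logger.warning("read %s shorter than 2*min_local; skipped", read.read_id)
        return []
    pairs = generate_fragment_pairs(n, params)
    cands = find_double_matches(seq, pairs, index, genome, params)
    refined = [(c, refine_boundary(c, genome, params)) for c in cands]
    # A read overlapping the junction by less than m on one side has no
    # clean double-alignable cutoff; its double matches are mis-cut pairs
    # whose spanning fragment aligned with a lucky mismatch budget, and the
    # true boundary can sit beyond the adjustment radius.  The fast path is
    # trusted only when some double match refines to a perfect placement
    # with a recognized splice signal; otherwise the single-match rescue
    # supplements the candidate set and the junction model arbitrates.
    def _clean(cand: Candidate, ref: RefinedBoundary) -> bool:
        if ref.mismatches > 0:
            return False
        sig, _ = detect_signal(
            genome, cand.chromosome, ref.donor_end, ref.acceptor_start
        )
        return sig != "other"

    if not any(_clean(c, r) for c, r in refined):
        extra = rescue_single_match(
            seq, pairs, index, genome, params, mate_anchor=mate_anchor
        )
        known = {(c.chromosome, c.left_start, c.right_end, c.p) for c in cands}
        for c in extra:
            if (c.chromosome, c.left_start, c.right_end, c.p) not in known:
                refined.append((c, refine_boundary(c, genome, params)))
    juncs: List[PutativeJunction] = []
    seen: Dict[Tuple[str, int, int], int] = {}
    for cand, ref in refined:
        ilen = ref.acceptor_start - ref.donor_end
        if not (params.min_intron <= ilen <= params.max_intron):
            continue
        key = (cand.chromosome, ref.donor_end, ref.acceptor_start)
        if key in seen:
            prev = juncs[seen[key]]
            if ref.mismatches >= prev.total_mismatches:
                continue
        anchor_len = min(ref.p_star, n - ref.p_star)
        z, sig, strand = model.features(
            genome,
            cand.chromosome,
            ref.donor_end,
            ref.acceptor_start,
            mismatches=ref.mismatches,
            read_length=n,
            anchor_len=anchor_len,
        )
        pj = PutativeJunction(
            read_id=read.read_id,
            chromosome=cand.chromosome,
            strand=strand,
            donor_end=ref.donor_end,
            acceptor_start=ref.acceptor_start,
            total_mismatches=ref.mismatches,
            anchor_len=anchor_len,
            signal_class=sig,
            score=model.score(z),
            orient=cand.orient,
            cutoff=ref.p_star,
            left_start=cand.left_start,
            seq=cand.seq,
        )
        if key in seen:
            juncs[seen[key]] = pj
        else:
            seen[key] = len(juncs)
            juncs.append(pj)
    if juncs:
        best = max(
            range(len(juncs)),
            key=lambda i: (
                juncs[i].score,
                -juncs[i].total_mismatches,
                -juncs[i].donor_end,
            ),
        )
        juncs[best].is_best = True
    return juncs
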