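"""Built-in short-fragment aligner: k-mer seed index plus windowed local search.

``align_fragment`` places a fragment genome-wide with bounded mismatches and
returns the exact hit set: when the fragment is long enough for pigeonhole
seeding ((max_mismatches+1) disjoint seeds) candidates come from the index
and are verified against the genome; shorter fragments fall back to a
vectorized scan of every position, so the reported hit set is identical to a
brute-force enumeration at every fragment length.

Fragments overlapping N runs in the genome never produce hits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._dna import N_CODE, encode, revcomp
from .io_formats import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a fragment: 0-based start on the forward strand.

    A '-' strand hit means the fragment matches the reverse complement of
    ``genome[start:start+len]``.  ``unique`` is true iff no other hit has
    equal or fewer mismatches.
    """

    chromosome: str
    start: int
    strand: str
    mismatches: int
    unique: bool


@dataclass
class SeedIndex:
    """Exact k-mer positions over both strands.

    Each genomic offset is stored under its forward k-mer with strand '+'
    and under the reverse-complement k-mer with strand '-'; palindromic
    k-mers therefore hold both entries under a single key.  K-mers
    containing N are excluded.
    """

    k: int
    positions: Dict[str, List[Tuple[str, int, str]]]


def build_index(genome: Genome, k: int) -> SeedIndex:
    if not genome.sequences:
        raise ValueError("cannot index an empty genome")
    if k > max(genome.lengths.values()):
        raise ValueError(f"k={k} exceeds the length of every chromosome")
    positions: Dict[str, List[Tuple[str, int, str]]] = {}
    for chrom, seq in genome.sequences.items():
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            positions.setdefault(kmer, []).append((chrom, off, "+"))
            positions.setdefault(revcomp(kmer), []).append((chrom, off, "-"))
    for entries in positions.values():
        entries.sort()
    return SeedIndex(k=k, positions=positions)


def _mismatch_profile(arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Mismatch count of ``codes`` at every start position of ``arr``.

    Positions whose genome window contains N are forced above any usable
    threshold (fragments over N never hit).
    """
    L = len(codes)
    n = len(arr)
    m = n - L + 1
    if m <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(m, dtype=np.int32)
    for i in range(L):
        mm += arr[i : m + i] != codes[i]
    ncum = np.concatenate(([0], np.cumsum(arr == N_CODE, dtype=np.int64)))
    has_n = (ncum[L:] - ncum[:-L]) > 0
    mm[has_n] = L + 1
    return mm


def _finalize(hits: List[Tuple[int, str, int, str]], frag_len: int) -> List[AlignmentHit]:
    hits.sort()
    unique_first = len(hits) == 1 or (len(hits) > 1 and hits[1][0] > hits[0][0])
    out = []
    for i, (mm, chrom, start, strand) in enumerate(hits):
        out.append(
            AlignmentHit(chrom, start, strand, mm, unique=(i == 0 and unique_first))
        )
    return out


def _scan_all(genome: Genome, fragment: str, max_mismatches: int) -> List[AlignmentHit]:
    fwd = encode(fragment)
    rev = encode(revcomp(fragment))
    hits: List[Tuple[int, str, int, str]] = []
    for chrom, arr in genome.arrays().items():
        for strand, codes in (("+", fwd), ("-", rev)):
            mm = _mismatch_profile(arr, codes)
            for pos in np.flatnonzero(mm <= max_mismatches):
                hits.append((int(mm[pos]), chrom, int(pos), strand))
    return _finalize(hits, len(fragment))


def align_fragment(
    index: SeedIndex, genome: Genome, fragment: str, max_mismatches: int = 2
) -> List[AlignmentHit]:
    """All genome placements of ``fragment`` with at most ``max_mismatches``.

    Hits are sorted by (mismatches, chromosome, start); the unique flag marks
    a best hit with no runner-up at equal or fewer mismatches.
    """
    L = len(fragment)
    k = index.k
    if L < k:
        raise ValueError(
            f"fragment length {L} < seed size {k}; use local_align for short fragments"
        )
    n_seeds = max_mismatches + 1
    if L < n_seeds * k:
        return _scan_all(genome, fragment, max_mismatches)

    seg = L // n_seeds
    arrays = genome.arrays()
    fwd = encode(fragment)
    rev = encode(revcomp(fragment))
    candidates = set()
    for s in range(n_seeds):
        off = s * seg
        seed = fragment[off : off + k]
        if "N" in seed:
            continue
        for chrom, pos, strand in index.positions.get(seed, ()):
            if strand == "+":
                candidates.add((chrom, pos - off, "+"))
            else:
                candidates.add((chrom, pos + off + k - L, "-"))
    hits: List[Tuple[int, str, int, str]] = []
    for chrom, start, strand in candidates:
        arr = arrays[chrom]
        if start < 0 or start + L > len(arr):
            continue
        window = arr[start : start + L]
        if (window == N_CODE).any():
            continue
        codes = fwd if strand == "+" else rev
        mm = int((window != codes).sum())
        if mm <= max_mismatches:
            hits.append((mm, chrom, start, strand))
    return _finalize(hits, L)


def local_align_candidates(
    genome: Genome,
    fragment: str,
    chromosome: str,
    window_start: int,
    window_end: int,
    anchor_pos: Optional[int] = None,
    mismatch_divisor: int = 7,
    max_candidates: int = 50,
) -> List[AlignmentHit]:
    """All minimal-mismatch ungapped placements of ``fragment`` in a window.

    Placements are on the forward strand (callers orient the fragment).
    Returns the placements achieving the minimal mismatch count, provided it
    does not exceed ``len(fragment) // mismatch_divisor``, ordered by
    distance to ``anchor_pos`` then position (leftmost first when no anchor).
    """
    arr = genome.arrays().get(chromosome)
    if arr is None:
        return []
    ws = max(0, int(window_start))
    we = min(len(arr), int(window_end))
    L = len(fragment)
    if we - ws < L:
        return []
    mm = _mismatch_profile(arr[ws:we], encode(fragment))
    best = int(mm.min())
    if best > L // mismatch_divisor:
        return []
    starts = [int(q) + ws for q in np.flatnonzero(mm == best)]
    uniq = len(starts) == 1
    if anchor_pos is not None:
        starts.sort(key=lambda q: (abs(q - anchor_pos), q))
    starts = starts[:max_candidates]
    return [AlignmentHit(chromosome, q, "+", best, unique=uniq) for q in starts]


def local_align(
    genome: Genome,
    fragment: str,
    chromosome: str,
    window_start: int,
    window_end: int,
    anchor_pos: Optional[int] = None,
    mismatch_divisor: int = 7,
) -> Optional[AlignmentHit]:
    """Best ungapped placement of the full fragment within a window, or None.

    Minimizes mismatches; ties break to the position nearest the anchored
    mate fragment, then leftmost.  None when the best mismatch count exceeds
    ``len(fragment) // mismatch_divisor`` or the window is empty.
    """
    cands = local_align_candidates(
        genome,
        fragment,
        chromosome,
        window_start,
        window_end,
        anchor_pos=anchor_pos,
        mismatch_divisor=mismatch_divisor,
        max_candidates=1,
    )
    return cands[0] if cands else None
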