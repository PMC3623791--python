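"""End-to-end detection driver: contiguous alignment, patterned alignment of
the failures, scoring, clustering and output writing.

Reads that place contiguously on the genome (within the mismatch budget) are
reported in the SAM output and contribute no junctions; the rest go through
the patterned-alignment path and each contributes its best-scoring putative
junction.  Per-read junctions are clustered into predictions; predictions
scoring below ``min_score`` are dropped (the score is a calibrated
probability, so 0.5 marks "more likely real than decoy").

Results are invariant to the worker count: reads are processed independently
and merged in input order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._dna import encode, revcomp
from .aligner import AlignmentHit, SeedIndex, align_fragment, build_index
from .io_formats import (
    AnnotatedJunctionSet,
    Genome,
    ReadRecord,
    SamRecord,
    write_junction_bedgraph,
    write_junction_table,
    write_sam,
)
from .junction_caller import (
    PredictedJunction,
    annotate_known,
    cluster_junctions,
    predictions_from_clusters,
)
from .junction_model import JunctionModel
from .patterned import PatternParams, PutativeJunction, process_read

logger = logging.getLogger(__name__)

DEFAULT_INDEX_K = 8


@dataclass
class DetectResult:
    predictions: List[PredictedJunction]
    putative: List[PutativeJunction]
    sam_records: List[SamRecord]
    stats: Dict[str, object] = field(default_factory=dict)
    known_summary: Optional[Dict[str, float]] = None


def _contiguous_sam(read_id: str, seq: str, qual: str, hit: AlignmentHit) -> SamRecord:
    if hit.strand == "-":
        seq, qual = revcomp(seq), qual[::-1]
    return SamRecord(
        read_id=read_id,
        chromosome=hit.chromosome,
        start=hit.start,
        strand=hit.strand,
        cigar=f"{len(seq)}M",
        sequence=seq,
        qualities=qual,
        mismatches=hit.mismatches,
        mapq=60 if hit.unique else 0,
    )


def _spliced_sam(pj: PutativeJunction, qual: str) -> SamRecord:
    n = len(pj.seq)
    p = pj.cutoff
    ilen = pj.intron_length
    if pj.orient == "-":
        qual = qual[::-1]
    return SamRecord(
        read_id=pj.read_id,
        chromosome=pj.chromosome,
        start=pj.left_start,
        strand=pj.orient,
        cigar=f"{p}M{ilen}N{n - p}M",
        sequence=pj.seq,
        qualities=qual,
        mismatches=pj.total_mismatches,
        mapq=60,
    )


# worker globals for multiprocessing (fork start method)
_W: Dict[str, object] = {}


def _init_worker(genome, index, params, model):
    _W.update(genome=genome, index=index, params=params, model=model)


def _work_chunk(chunk):
    out = []
    for read, mate_anchor in chunk:
        juncs = process_read(
            read, _W["index"], _W["genome"], _W["params"], _W["model"],
            mate_anchor=mate_anchor,
        )
        best = next((j for j in juncs if j.is_best), None)
        out.append(best)
    return out


def _mapped_ids_from_sam(path) -> set:
    import pysam

    mapped = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if not rec.is_unmapped:
                mapped.add(rec.query_name)
    return mapped


def detect_junctions(
    genome: Genome,
    reads: Sequence[ReadRecord],
    model: JunctionModel,
    params: Optional[PatternParams] = None,
    *,
    index: Optional[SeedIndex] = None,
    index_k: int = DEFAULT_INDEX_K,
    known: Optional[AnnotatedJunctionSet] = None,
    cluster_tolerance: int = 5,
    min_score: float = 0.5,
    threads: int = 1,
    prealigned_sam=None,
    emit_sam: bool = True,
) -> DetectResult:
    """Run the full junction-detection pipeline over a read collection."""
    params = params or PatternParams()
    if index is None:
        index = build_index(genome, index_k)

    prealigned = (
        _mapped_ids_from_sam(prealigned_sam) if prealigned_sam is not None else None
    )

    sam_records: List[SamRecord] = []
    todo: List[Tuple[ReadRecord, Optional[Tuple[str, int, int]]]] = []
    n_contiguous = 0
    n_skipped = 0
    n_stub = 0

    arrays = genome.arrays()
    stub = params.min_local - 1

    def _terminal_stub_hit(seq: str):
        """Best contiguous placement whose mismatches are all confined to one
        terminal stub shorter than min_local.

        Such a read ends (or starts) within min_local-1 nt of an exon
        boundary at most: the overhang is below the placement resolution of
        the local-alignment step, so the read carries no usable junction
        evidence and is reported as a contiguous alignment instead of
        feeding the rescue path with unplaceable fragments.
        """
        n = len(seq)
        budget = stub
        if budget < 1 or n <= 2 * stub:
            return None
        for hit in align_fragment(index, genome, seq, budget):
            arr = arrays[hit.chromosome]
            window = arr[hit.start : hit.start + n]
            codes = encode(seq if hit.strand == "+" else revcomp(seq))
            bad = np.flatnonzero(window != codes)
            if len(bad) and (bad.max() < stub or bad.min() >= n - stub):
                return AlignmentHit(
                    hit.chromosome, hit.start, hit.strand, len(bad), hit.unique
                )
        return None

    def _route(read_id: str, seq: str, qual: str, mate_anchor):
        """Contiguously align one sequence; queue it for the patterned path
        on failure.  Returns the hit (or None)."""
        nonlocal n_contiguous, n_stub, n_skipped
        if len(seq) < 2 * params.min_local:
            logger.warning("read %s too short; skipped", read_id)
            n_skipped += 1
            return None, True
        hits = align_fragment(index, genome, seq, params.max_mismatches)
        if hits:
            n_contiguous += 1
            if emit_sam:
                sam_records.append(_contiguous_sam(read_id, seq, qual, hits[0]))
            return hits[0], True
        sh = _terminal_stub_hit(seq)
        if sh is not None:
            n_contiguous += 1
            n_stub += 1
            if emit_sam:
                sam_records.append(_contiguous_sam(read_id, seq, qual, sh))
            return sh, True
        return None, False

    for read in reads:
        if prealigned is not None and read.read_id in prealigned:
            n_contiguous += 1
            continue
        if not read.paired:
            _, done = _route(read.read_id, read.sequence, read.qualities, None)
            if not done:
                todo.append((read, None))
        else:
            h1, done1 = _route(
                read.read_id + "/1", read.sequence, read.qualities, None
            )
            h2, done2 = _route(
                read.read_id + "/2", read.mate_sequence, read.mate_qualities, None
            )
            if not done1:
                anchor = (
                    (h2.chromosome, h2.start, h2.start + len(read.mate_sequence))
                    if h2
                    else None
                )
                todo.append(
                    (
                        ReadRecord(read.read_id + "/1", read.sequence, read.qualities),
                        anchor,
                    )
                )
            if not done2:
                anchor = (
                    (h1.chromosome, h1.start, h1.start + len(read.sequence))
                    if h1
                    else None
                )
                todo.append(
                    (
                        ReadRecord(
                            read.read_id + "/2",
                            read.mate_sequence,
                            read.mate_qualities,
                        ),
                        anchor,
                    )
                )

    bests: List[Optional[PutativeJunction]] = []
    if threads > 1 and len(todo) > 1:
        import multiprocessing as mp

        chunksize = max(1, len(todo) // (threads * 4))
        chunks = [todo[i : i + chunksize] for i in range(0, len(todo), chunksize)]
        ctx = mp.get_context("fork")
        with ctx.Pool(
            threads, initializer=_init_worker, initargs=(genome, index, params, model)
        ) as pool:
            for part in pool.map(_work_chunk, chunks):
                bests.extend(part)
    else:
        _init_worker(genome, index, params, model)
        bests = _work_chunk(todo)

    putative: List[PutativeJunction] = []
    quals = {r.read_id: r.qualities for r, _ in todo}
    for best in bests:
        if best is None:
            continue
        putative.append(best)
        if emit_sam:
            sam_records.append(_spliced_sam(best, quals.get(best.read_id, "")))

    clusters = cluster_junctions(putative, tolerance=cluster_tolerance)
    predictions = predictions_from_clusters(clusters)
    n_low_score = sum(p.score < min_score for p in predictions)
    predictions = [p for p in predictions if p.score >= min_score]

    known_summary = None
    if known is not None:
        predictions, known_summary = annotate_known(predictions, known)

    stats: Dict[str, object] = {
        "n_reads": len(reads),
        "n_contiguous": n_contiguous,
        "n_terminal_stub": n_stub,
        "n_unaligned": len(todo),
        "n_skipped_short": n_skipped,
        "n_putative": len(putative),
        "n_clusters": len(clusters),
        "n_predictions": len(predictions),
        "n_below_min_score": n_low_score,
        "min_score": min_score,
        "cluster_tolerance": cluster_tolerance,
    }
    return DetectResult(
        predictions=predictions,
        putative=putative,
        sam_records=sam_records,
        stats=stats,
        known_summary=known_summary,
    )


def write_outputs(
    result: DetectResult,
    genome: Genome,
    out_dir,
) -> Dict[str, str]:
    """Write BedGraph, sidecar TSV, SAM and stats for a detection result."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bedgraph": str(out_dir / "junctions.bedgraph"),
        "table": str(out_dir / "junctions.tsv"),
        "sam": str(out_dir / "alignments.sam"),
        "stats": str(out_dir / "stats.json"),
    }
    write_junction_bedgraph(result.predictions, paths["bedgraph"])
    write_junction_table(result.predictions, paths["table"])
    write_sam(result.sam_records, genome, paths["sam"])
    payload = dict(result.stats)
    if result.known_summary is not None:
        payload["known_summary"] = result.known_summary
    with open(paths["stats"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
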