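"""Readers and writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open everywhere in memory; an intron is the
interval ``[donor_end, acceptor_start)`` over intronic bases.  SAM output
converts to 1-based on write; BedGraph stays 0-based.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import encode

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


@dataclass
class Genome:
    """In-memory reference genome: chromosome name -> uppercase DNA string."""

    sequences: Dict[str, str]
    _arrays: Optional[Dict[str, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def arrays(self) -> Dict[str, np.ndarray]:
        """uint8-encoded chromosome sequences, cached for alignment."""
        if self._arrays is None:
            self._arrays = {c: encode(s) for c, s in self.sequences.items()}
        return self._arrays


@dataclass
class ReadRecord:
    """One sequencing read, optionally with its mate."""

    read_id: str
    sequence: str
    qualities: str
    mate_sequence: Optional[str] = None
    mate_qualities: Optional[str] = None

    @property
    def paired(self) -> bool:
        return self.mate_sequence is not None


JunctionKey = Tuple[str, int, int, str]  # chrom, intron start, intron end, strand


@dataclass
class AnnotatedJunctionSet:
    """Set of annotated introns: (chromosome, start, end, strand) tuples."""

    junctions: Set[JunctionKey]
    source: str = ""

    def coords(self) -> Set[Tuple[str, int, int]]:
        """Strand-free coordinate set, for exact-match lookups."""
        return {(c, s, e) for c, s, e, _ in self.junctions}

    def __len__(self) -> int:
        return len(self.junctions)


def read_fasta(path) -> Genome:
    """Load a FASTA file into a Genome.

    Lowercase is normalized to uppercase; IUPAC ambiguity codes other than N
    are mapped to N (with a logged count).  A malformed file raises a
    ValueError naming the offending line.
    """
    sequences: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    n_ambiguous = 0

    def _flush():
        nonlocal n_ambiguous
        if name is None:
            return
        seq = "".join(parts).upper()
        cleaned = []
        for ch in seq:
            if ch in _VALID_BASES:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_ambiguous += 1
        sequences[name] = "".join(cleaned)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                parts = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                if not re.fullmatch(r"[A-Za-z*.-]+", line):
                    raise ValueError(f"{path}: malformed sequence at line {lineno}")
                parts.append(line)
        _flush()

    if n_ambiguous:
        logger.warning("%s: %d ambiguous bases mapped to N", path, n_ambiguous)
    if not sequences:
        logger.warning("%s: empty FASTA, genome has zero chromosomes", path)
    return Genome(sequences)


_MATE_SUFFIX = re.compile(r"(/[12]|[._][12])$")


def _strip_mate(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def read_fastq(path, mate_path=None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (pair of files for paired-end).

    Mate files must have equal record counts and identifiers matching up to a
    /1 or /2 (or space) suffix; mismatches raise a ValueError naming the
    record.
    """
    if mate_path is None:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        return

    with open(path) as fh1, open(mate_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for i, (rec1, rec2) in enumerate(zip_longest(it1, it2), start=1):
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"record count mismatch between {path} and {mate_path} "
                    f"at record {i}"
                )
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            id1, id2 = t1.split()[0], t2.split()[0]
            if _strip_mate(id1) != _strip_mate(id2):
                raise ValueError(
                    f"mate identifier mismatch at record {i}: {id1!r} vs {id2!r}"
                )
            yield ReadRecord(_strip_mate(id1), s1.upper(), q1, s2.upper(), q2)


def junctions_from_gtf(path) -> AnnotatedJunctionSet:
    """Extract the intron set implied by the exon features of a GTF/GFF file.

    For each transcript with k >= 2 exons the k-1 gaps between consecutive
    exons (sorted by coordinate) are emitted as introns; duplicates across
    transcripts collapse.  Transcripts with overlapping exons are skipped
    with a warning.
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3")):
        gr = pr.read_gff3(path)
        tx_col = "Parent"
    else:
        gr = pr.read_gtf(path)
        tx_col = "transcript_id"
    df = gr.df if hasattr(gr, "df") else gr
    if len(df) == 0:
        return AnnotatedJunctionSet(set(), source=path)
    exons = df[df["Feature"] == "exon"]
    junctions: Set[JunctionKey] = set()
    for tx, grp in exons.groupby(tx_col):
        grp = grp.sort_values("Start")
        starts = grp["Start"].to_numpy()
        ends = grp["End"].to_numpy()
        if len(starts) < 2:
            continue
        if (starts[1:] < ends[:-1]).any():
            logger.warning("transcript %s has overlapping exons; skipped", tx)
            continue
        chrom = str(grp["Chromosome"].iloc[0])
        strand = str(grp["Strand"].iloc[0])
        for a, b in zip(ends[:-1], starts[1:]):
            junctions.add((chrom, int(a), int(b), strand))
    return AnnotatedJunctionSet(junctions, source=path)


def write_junction_bedgraph(junctions: Sequence, path) -> None:
    """Write predicted junctions as BedGraph: chrom, start, end, coverage.

    The single BedGraph value column carries coverage; score/signal details
    go to the companion TSV (:func:`write_junction_table`).
    """
    rows = []
    for j in junctions:
        cov = j.coverage
        if not math.isfinite(float(cov)):
            raise ValueError(f"non-finite coverage for junction {j}")
        rows.append((j.chromosome, int(j.donor_end), int(j.acceptor_start), int(cov)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("track type=bedGraph name=spliceseek_junctions\n")
        for chrom, start, end, cov in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{cov}\n")


def read_junction_bedgraph(path) -> List[Tuple[str, int, int, int]]:
    """Re-parse a junction BedGraph into (chrom, start, end, coverage) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, cov = line.split("\t")
            out.append((chrom, int(start), int(end), int(cov)))
    return out


TABLE_COLUMNS = [
    "chromosome",
    "intron_start",
    "intron_end",
    "strand",
    "coverage",
    "score",
    "signal",
    "mismatches",
    "known",
]


def write_junction_table(junctions: Sequence, path) -> None:
    """Companion TSV with per-junction score, splice-signal class and details."""
    import pandas as pd

    rows = [
        {
            "chromosome": j.chromosome,
            "intron_start": j.donor_end,
            "intron_end": j.acceptor_start,
            "strand": j.strand,
            "coverage": j.coverage,
            "score": round(float(j.score), 6),
            "signal": j.signal_class,
            "mismatches": j.mismatches,
            "known": "" if j.known is None else str(bool(j.known)),
        }
        for j in junctions
    ]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df.sort_values(["chromosome", "intron_start", "intron_end"])
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SamRecord:
    """A placed read ready for SAM output.

    ``start`` is 0-based; ``sequence``/``qualities`` are already oriented to
    the forward genome strand (``strand`` only sets FLAG bit 16).  Spliced
    placements encode the intron as an N operation in ``cigar``.
    """

    read_id: str
    chromosome: str
    start: int
    strand: str
    cigar: str
    sequence: str
    qualities: str
    mismatches: int = 0
    mapq: int = 60


_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")


def cigar_query_length(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_OP.findall(cigar) if op in _QUERY_OPS)


def write_sam(records, genome: Genome, path) -> None:
    """Write placed reads as SAM with @HD/@SQ headers from the genome."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": l} for c, l in genome.lengths.items()],
    }
    names = list(genome.sequences)
    tid = {c: i for i, c in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in records:
            if cigar_query_length(r.cigar) != len(r.sequence):
                raise ValueError(
                    f"CIGAR {r.cigar} inconsistent with sequence length "
                    f"{len(r.sequence)} for read {r.read_id}"
                )
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = tid[r.chromosome]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(r.qualities)
            a.set_tag("NM", int(r.mismatches))
            fh.write(a)
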