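"""Synthetic RNA-Seq generator and evaluation harness.

Emulates the standard junction-detection benchmark design: multi-exon genes
placed on a random background genome, intron lengths drawn from a Pareto
law, splice signals written at configurable class frequencies (GT-AG 96%,
GC-AG 3%, AT-AC 1% by default), reads sampled uniformly along transcripts at
a chosen depth, with sequencing errors at 1/1000 bp and sample-level SNPs at
5/1000 bp.  Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._dna import revcomp
from .io_formats import (
    AnnotatedJunctionSet,
    Genome,
    JunctionKey,
    ReadRecord,
)
from .junction_model import DEFAULT_BPS_PWM, SIGNAL_CLASSES

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the simulation.

    depth is mean read coverage per transcript nucleotide; reads per
    transcript = depth * transcript_length / read_length.  error_rate is the
    per-base sequencing error frequency (default 1/1000), snp_rate the
    per-base polymorphism frequency applied once per gene haplotype
    (default 5/1000).
    """

    genome_length: int = 200_000
    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (3, 7)
    exon_length: Tuple[int, int] = (100, 300)
    intron_alpha: float = 1.5
    intron_xm: float = 60.0
    max_intron: int = 10_000
    read_length: int = 50
    depth: float = 4.0
    error_rate: float = 0.001
    snp_rate: float = 0.005
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    seed: int = 0
    signal_fracs: Tuple[float, float, float] = (0.96, 0.03, 0.01)
    # every spliced intron carries a branch point; motif strength varies
    # through PWM sampling, so the planting probability is 1
    bps_prob: float = 1.0
    chromosome: str = "chr1"
    intergenic: Tuple[int, int] = (200, 800)

    def __post_init__(self):
        for r in (self.error_rate, self.snp_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if abs(sum(self.signal_fracs) - 1.0) > 1e-9:
            raise ValueError("signal fractions must sum to 1")


@dataclass
class Gene:
    name: str
    chromosome: str
    strand: str
    exons: List[Tuple[int, int]]  # 0-based half-open, sorted

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class TruthSet:
    """Ground-truth junctions plus per-junction spanning-read counts."""

    junctions: AnnotatedJunctionSet
    spanning_reads: Dict[JunctionKey, int] = field(default_factory=dict)

    def detectable(self) -> List[JunctionKey]:
        return [k for k, n in self.spanning_reads.items() if n >= 1]


def _sample_intron(rng: np.random.Generator, cfg: SimConfig) -> int:
    x = cfg.intron_xm * (1.0 + rng.pareto(cfg.intron_alpha))
    return int(min(round(x), cfg.max_intron))


def simulate_genome(config: SimConfig) -> Tuple[Genome, List[Gene], TruthSet]:
    """Generate a random genome with non-overlapping multi-exon genes.

    Intron lengths are Pareto(alpha, xm) truncated at max_intron; splice
    signals are written at the configured class frequencies; a branch-point
    consensus sampled from the PWM is planted 25-40 bp upstream of most
    acceptors.  Byte-identical outputs under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    genes: List[Gene] = []
    cursor = 0
    chrom = config.chromosome
    structures = []
    for gi in range(config.n_genes):
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=k
        )
        intron_lens = [_sample_intron(rng, config) for _ in range(k - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((exon_lens, intron_lens, strand))

    for gi, (exon_lens, intron_lens, strand) in enumerate(structures):
        gap = int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))
        start = cursor + gap
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += intron_lens[i]
        cursor = pos
        genes.append(Gene(f"gene{gi:04d}", chrom, strand, exons))
    if cursor + config.intergenic[0] > config.genome_length:
        raise ValueError(
            f"genes span {cursor} bp but genome_length is {config.genome_length}; "
            "increase genome_length or reduce gene content"
        )

    seq = rng.integers(0, 4, size=config.genome_length)
    bases = _BASES[seq].tolist()

    signal_names = [c[0] for c in SIGNAL_CLASSES]
    junctions = set()
    for gene in genes:
        for (istart, iend) in gene.introns:
            ci = int(rng.choice(3, p=list(config.signal_fracs)))
            _, donor, acceptor = SIGNAL_CLASSES[ci]
            if gene.strand == "+":
                bases[istart : istart + 2] = list(donor)
                bases[iend - 2 : iend] = list(acceptor)
            else:
                bases[istart : istart + 2] = list(revcomp(acceptor))
                bases[iend - 2 : iend] = list(revcomp(donor))
            ilen = iend - istart
            if ilen >= 60 and rng.random() < config.bps_prob:
                motif = "".join(
                    _BASES[int(rng.choice(4, p=row))] for row in DEFAULT_BPS_PWM
                )
                off = int(rng.integers(26, 38))  # motif start = 3' site - off
                if gene.strand == "+":
                    mstart = iend - off
                    if mstart >= istart + 2 and mstart + 7 <= iend - 2:
                        bases[mstart : mstart + 7] = list(motif)
                else:
                    mstart = istart + off - 7
                    if mstart >= istart + 2 and mstart + 7 <= iend - 2:
                        bases[mstart : mstart + 7] = list(revcomp(motif))
            junctions.add((chrom, istart, iend, gene.strand))

    genome = Genome({chrom: "".join(bases)})
    truth = TruthSet(AnnotatedJunctionSet(junctions, source="simulated"))
    return genome, genes, truth


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: Sequence[Gene], path) -> None:
    """One transcript per gene, exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            for (s, e) in g.exons:
                attrs = f'gene_id "{g.name}"; transcript_id "{g.name}.t1";'
                fh.write(
                    f"{g.chromosome}\tspliceseek_sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def transcript_sequence(genome: Genome, gene: Gene) -> str:
    seq = "".join(genome.sequences[gene.chromosome][s:e] for s, e in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


def _transcript_junction_map(gene: Gene) -> List[Tuple[int, JunctionKey]]:
    """Transcript coordinate of each junction with its genomic intron key."""
    exon_lens = [e - s for s, e in gene.exons]
    total = sum(exon_lens)
    cums = np.cumsum(exon_lens)[:-1]
    out = []
    for i, c in enumerate(cums):
        key = (gene.chromosome, gene.exons[i][1], gene.exons[i + 1][0], gene.strand)
        t = int(c) if gene.strand == "+" else total - int(c)
        out.append((t, key))
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> Tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr.tolist()), len(idx)


def simulate_reads(
    genome: Genome,
    genes: Sequence[Gene],
    config: SimConfig,
    truth: Optional[TruthSet] = None,
    spanning_flank: int = 6,
) -> Tuple[List[ReadRecord], TruthSet, Dict[str, int]]:
    """Sample reads uniformly along gene transcripts at the configured depth.

    SNPs are applied once per gene haplotype at snp_rate; sequencing errors
    per read base at error_rate.  Read names encode gene and transcript
    offset (``gene|start|i``) so evaluations can recover the source.  The
    returned TruthSet carries, for every junction, the number of simulated
    reads overlapping both flanks by >= ``spanning_flank`` nt.
    """
    rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        junctions = {
            (g.chromosome, s, e, g.strand) for g in genes for (s, e) in g.introns
        }
        truth = TruthSet(AnnotatedJunctionSet(junctions, source="simulated"))
    spanning: Dict[JunctionKey, int] = {
        k: 0 for k in truth.junctions.junctions
    }
    reads: List[ReadRecord] = []
    stats = {"n_reads": 0, "n_bases": 0, "n_errors": 0, "n_snps": 0}
    rl = config.read_length
    qual = "I" * rl
    for gene in genes:
        tx = transcript_sequence(genome, gene)
        L = len(tx)
        if L < rl:
            logger.warning("transcript %s shorter than read length; skipped", gene.name)
            continue
        hap, n_snps = _mutate(tx, config.snp_rate, rng)
        stats["n_snps"] += n_snps
        jmap = _transcript_junction_map(gene)
        n_reads = int(round(config.depth * L / rl))
        if config.paired:
            for i in range(n_reads // 2):
                flen = int(np.clip(round(rng.normal(config.fragment_mean,
                                                    config.fragment_sd)), rl, L))
                start = int(rng.integers(0, L - flen + 1))
                r1, e1 = _mutate(hap[start : start + rl], config.error_rate, rng)
                r2raw = hap[start + flen - rl : start + flen]
                r2m, e2 = _mutate(r2raw, config.error_rate, rng)
                r2 = revcomp(r2m)
                stats["n_errors"] += e1 + e2
                stats["n_bases"] += 2 * rl
                stats["n_reads"] += 2
                for seg_start in (start, start + flen - rl):
                    for t, key in jmap:
                        if t - seg_start >= spanning_flank and seg_start + rl - t >= spanning_flank:
                            spanning[key] += 1
                reads.append(
                    ReadRecord(f"{gene.name}|{start}|{i}", r1, qual, r2, qual)
                )
        else:
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            for i, start in enumerate(starts):
                start = int(start)
                r, ne = _mutate(hap[start : start + rl], config.error_rate, rng)
                stats["n_errors"] += ne
                stats["n_bases"] += rl
                stats["n_reads"] += 1
                for t, key in jmap:
                    if t - start >= spanning_flank and start + rl - t >= spanning_flank:
                        spanning[key] += 1
                reads.append(ReadRecord(f"{gene.name}|{start}|{i}", r, qual))
    return reads, TruthSet(truth.junctions, spanning), stats


def write_fastq(reads: Sequence[ReadRecord], path, mate_path=None) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = "/1" if r.paired else ""
            fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n{r.qualities}\n")
    if mate_path is not None:
        with open(mate_path, "w") as fh:
            for r in reads:
                if r.paired:
                    fh.write(
                        f"@{r.read_id}/2\n{r.mate_sequence}\n+\n{r.mate_qualities}\n"
                    )


def write_truth(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tintron_start\tintron_end\tstrand\tspanning_reads\n")
        for (c, s, e, st) in sorted(truth.junctions.junctions):
            n = truth.spanning_reads.get((c, s, e, st), 0)
            fh.write(f"{c}\t{s}\t{e}\t{st}\t{n}\n")


def read_truth(path) -> TruthSet:
    junctions = set()
    spanning: Dict[JunctionKey, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            c, s, e, st, n = line.rstrip("\n").split("\t")
            key = (c, int(s), int(e), st)
            junctions.add(key)
            spanning[key] = int(n)
    return TruthSet(AnnotatedJunctionSet(junctions, source=str(path)), spanning)


def evaluate(predicted: Sequence, truth: TruthSet) -> Dict[str, float]:
    """Sensitivity / FP / FN of predictions against the truth set.

    TP: predictions exactly matching a truth junction.  FN: truth junctions
    with at least one qualifying spanning read but no prediction.  FP:
    predictions matching no truth junction.
    """
    truth_coords = {(c, s, e) for (c, s, e, _) in truth.junctions.junctions}
    detectable = {(c, s, e) for (c, s, e, _) in truth.detectable()}
    pred_coords = {(p.chromosome, p.donor_end, p.acceptor_start) for p in predicted}
    tp = len(pred_coords & truth_coords)
    fp = len(pred_coords - truth_coords)
    fn = len(detectable - pred_coords)
    n_det = len(detectable)
    sensitivity = (n_det - fn) / n_det if n_det else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_detectable": n_det,
        "n_predictions": len(pred_coords),
        "sensitivity": sensitivity,
        "fn_rate": fn / n_det if n_det else float("nan"),
        "fp_rate": fp / len(pred_coords) if pred_coords else 0.0,
    }
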