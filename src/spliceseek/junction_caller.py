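"""Cluster per-read putative junctions into coverage-annotated predictions.

Putative junctions from different reads that point at (nearly) the same
intron are grouped by single-linkage clustering on both boundaries; the
highest-scoring member becomes the cluster representative and fixes the
predicted position, while the member count is reported as junction coverage.
Clusters of coverage 1 are always emitted — there is no coverage filtering.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import AnnotatedJunctionSet
from .patterned import PutativeJunction


@dataclass
class JunctionCluster:
    members: List[PutativeJunction]
    representative: PutativeJunction

    @property
    def coverage(self) -> int:
        return len(self.members)


@dataclass
class PredictedJunction:
    """Cluster representative: position, coverage, score, signal, annotation."""

    chromosome: str
    donor_end: int
    acceptor_start: int
    strand: str
    coverage: int
    score: float
    signal_class: str
    mismatches: int
    known: Optional[bool] = None

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _representative(members: List[PutativeJunction]) -> PutativeJunction:
    # max score; ties broken by the member whose exact boundary has the most
    # mismatch-free support in the cluster, then leftmost donor
    support: Dict[Tuple[int, int], int] = {}
    for m in members:
        if m.total_mismatches == 0:
            key = (m.donor_end, m.acceptor_start)
            support[key] = support.get(key, 0) + 1
    return max(
        members,
        key=lambda m: (
            m.score,
            support.get((m.donor_end, m.acceptor_start), 0),
            -m.donor_end,
            -m.acceptor_start,
        ),
    )


def cluster_junctions(
    putative: Sequence[PutativeJunction], tolerance: int = 5
) -> List[JunctionCluster]:
    """Single-linkage grouping of putative junctions whose donor AND acceptor
    positions each differ by at most ``tolerance`` nt (same chromosome and
    strand).  Output order is deterministic by (chrom, donor, acceptor) of
    the representative; shuffling the input cannot change the result.
    """
    groups: Dict[Tuple[str, str], List[PutativeJunction]] = {}
    for pj in putative:
        groups.setdefault((pj.chromosome, pj.strand), []).append(pj)
    clusters: List[JunctionCluster] = []
    for _, items in sorted(groups.items()):
        items.sort(key=lambda m: (m.donor_end, m.acceptor_start, m.read_id))
        uf = _UnionFind(len(items))
        for i in range(len(items)):
            j = i - 1
            while j >= 0 and items[i].donor_end - items[j].donor_end <= tolerance:
                if abs(items[i].acceptor_start - items[j].acceptor_start) <= tolerance:
                    uf.union(i, j)
                j -= 1
        buckets: Dict[int, List[PutativeJunction]] = {}
        for i, m in enumerate(items):
            buckets.setdefault(uf.find(i), []).append(m)
        for members in buckets.values():
            clusters.append(JunctionCluster(members, _representative(members)))
    clusters.sort(
        key=lambda c: (
            c.representative.chromosome,
            c.representative.donor_end,
            c.representative.acceptor_start,
        )
    )
    return clusters


def predictions_from_clusters(clusters: Sequence[JunctionCluster]) -> List[PredictedJunction]:
    out = []
    for c in clusters:
        r = c.representative
        out.append(
            PredictedJunction(
                chromosome=r.chromosome,
                donor_end=r.donor_end,
                acceptor_start=r.acceptor_start,
                strand=r.strand,
                coverage=c.coverage,
                score=r.score,
                signal_class=r.signal_class,
                mismatches=r.total_mismatches,
            )
        )
    return out


def annotate_known(
    predicted: Sequence[PredictedJunction], known: AnnotatedJunctionSet
) -> Tuple[List[PredictedJunction], Dict[str, float]]:
    """Set the known flag by exact (chrom, donor, acceptor) match against an
    annotation, and report summary counts."""
    coords = known.coords()
    out = []
    n_known = 0
    n_canonical = 0
    for p in predicted:
        is_known = (p.chromosome, p.donor_end, p.acceptor_start) in coords
        n_known += is_known
        n_canonical += p.signal_class == "GT-AG"
        out.append(
            PredictedJunction(
                chromosome=p.chromosome,
                donor_end=p.donor_end,
                acceptor_start=p.acceptor_start,
                strand=p.strand,
                coverage=p.coverage,
                score=p.score,
                signal_class=p.signal_class,
                mismatches=p.mismatches,
                known=is_known,
            )
        )
    n = len(out)
    summary = {
        "known": n_known,
        "novel": n - n_known,
        "canonical_fraction": (n_canonical / n) if n else float("nan"),
    }
    return out, summary


def summarize(
    predicted: Sequence[PredictedJunction],
    coverage_thresholds: Sequence[int] = (1, 2, 5, 10),
):
    """Junction count, mean score and canonical (GT-AG) fraction stratified by
    coverage, for each threshold t: rows for coverage <= t and > t."""
    import pandas as pd

    rows = []
    for t in coverage_thresholds:
        for name, members in (
            (f"cov<={t}", [p for p in predicted if p.coverage <= t]),
            (f"cov>{t}", [p for p in predicted if p.coverage > t]),
        ):
            n = len(members)
            rows.append(
                {
                    "threshold": t,
                    "stratum": name,
                    "junctions": n,
                    "mean_score": (
                        sum(p.score for p in members) / n if n else float("nan")
                    ),
                    "canonical_fraction": (
                        sum(p.signal_class == "GT-AG" for p in members) / n
                        if n
                        else float("nan")
                    ),
                }
            )
    cols = ["threshold", "stratum", "junctions", "mean_score", "canonical_fraction"]
    if not predicted:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
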