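"""QTL segment definition, cross-trait overlap, and candidate-gene search.

A significant SNP seeds an interval of +/-100 kb (clipped to the chromosome);
overlapping or exactly abutting intervals on the same chromosome are merged
transitively, so segments are deterministic and order-independent. Each merged
segment is summarized by its peak SNP — the minimum-p marker inside it, ties
broken by the leftmost position. Candidate genes are annotation features whose
span intersects a +/-150 kb window around the peak SNP; distance is measured
from the peak to the nearest edge of the gene span (0 when the span contains
the peak).

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, CoordinateError, NamingError

__all__ = [
    "Segment",
    "GeneRecord",
    "CandidateHit",
    "define_segments",
    "overlap_segments",
    "candidate_genes",
    "read_gff3_genes",
    "segments_to_frame",
]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    stop: int
    peak_pos: int
    peak_p: float
    trait: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.stop):
            raise ValueError("peak position outside segment")
        if self.start < 1:
            raise ValueError("segment start must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    stop: int
    strand: str = "."
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError("gene start > stop")


@dataclass(frozen=True)
class CandidateHit:
    segment: Segment
    gene_id: str
    distance: int  # bp from peak SNP to nearest gene edge, 0 if overlapping
    description: str = ""


def define_segments(
    markers,
    flank: int = 100_000,
    chrom_lengths: dict | None = None,
    trait: str = "",
    environment: str = "",
) -> list[Segment]:
    """Merge flanked windows around significant SNPs into segments.

    ``markers`` is an iterable of (chrom, pos, p), sorted by (chrom, pos).
    Each marker seeds [pos - flank, pos + flank] clipped to [1, chrom length];
    intervals that overlap or abut (stop + 1 = start) merge transitively.
    """
    rows = [(str(c), int(pos), float(p)) for c, pos, p in markers]
    if rows != sorted(rows, key=lambda r: (r[0], r[1])):
        raise ContractError("markers must be sorted by (chrom, pos)")
    segments: list[Segment] = []
    cur: dict | None = None
    for chrom, pos, p in rows:
        length = None if chrom_lengths is None else chrom_lengths.get(chrom)
        if length is not None and pos > length:
            raise CoordinateError(f"{chrom}:{pos} beyond chromosome length {length}")
        start = max(1, pos - flank)
        stop = pos + flank if length is None else min(pos + flank, length)
        if cur is not None and cur["chrom"] == chrom and start <= cur["stop"] + 1:
            cur["stop"] = max(cur["stop"], stop)
            if p < cur["peak_p"]:  # strict: ties keep the leftmost marker
                cur["peak_p"], cur["peak_pos"] = p, pos
        else:
            if cur is not None:
                segments.append(Segment(trait=trait, environment=environment, **cur))
            cur = {"chrom": chrom, "start": start, "stop": stop, "peak_pos": pos, "peak_p": p}
    if cur is not None:
        segments.append(Segment(trait=trait, environment=environment, **cur))
    return segments


def _check_sorted_disjoint(segs: list[Segment], name: str) -> None:
    prev: Segment | None = None
    for s in segs:
        if prev is not None and prev.chrom == s.chrom:
            if s.start <= prev.stop:
                raise ContractError(f"{name} segments overlap or are unsorted")
            if s.start < prev.start:
                raise ContractError(f"{name} segments unsorted")
        prev = s


def overlap_segments(
    set_a: list[Segment], set_b: list[Segment]
) -> list[tuple[Segment, Segment, tuple[str, int, int]]]:
    """Pairs of segments sharing >= 1 bp, with the intersection interval.

    Both inputs must be internally sorted and non-overlapping. N-way queries
    (segments common to several environments) compose by intersecting the
    shared intervals of successive pairwise calls.
    """
    for segs, name in ((set_a, "A"), (set_b, "B")):
        ordered = sorted(segs, key=lambda s: (s.chrom, s.start))
        if list(segs) != ordered:
            raise ContractError(f"set {name} must be sorted by (chrom, start)")
        _check_sorted_disjoint(list(segs), name)
    out = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in set_b:
        by_chrom.setdefault(s.chrom, []).append(s)
    for a in set_a:
        for b in by_chrom.get(a.chrom, []):
            lo = max(a.start, b.start)
            hi = min(a.stop, b.stop)
            if lo <= hi:
                out.append((a, b, (a.chrom, lo, hi)))
    return out


def candidate_genes(
    segments: list[Segment],
    annotation: list[GeneRecord],
    radius: int = 150_000,
) -> list[CandidateHit]:
    """Genes whose span intersects +/-radius around each segment's peak SNP.

    Distance is 0 when the gene span contains the peak, else the distance to
    the nearest gene edge. Hits are sorted by distance within each segment.
    Raises :class:`NamingError` when segment chromosomes are absent from the
    annotation entirely.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    unmatched = sorted({s.chrom for s in segments} - set(by_chrom))
    if unmatched and by_chrom:
        raise NamingError(f"annotation has no genes on chromosome(s): {unmatched}")
    hits: list[CandidateHit] = []
    for seg in segments:
        lo, hi = seg.peak_pos - radius, seg.peak_pos + radius
        seg_hits = []
        for g in by_chrom.get(seg.chrom, []):
            if g.stop < lo or g.start > hi:
                continue
            if g.start <= seg.peak_pos <= g.stop:
                dist = 0
            else:
                dist = min(abs(seg.peak_pos - g.start), abs(seg.peak_pos - g.stop))
            seg_hits.append(CandidateHit(seg, g.gene_id, dist, g.description))
        seg_hits.sort(key=lambda h: (h.distance, h.gene_id))
        hits.extend(seg_hits)
    return hits


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Load gene-type features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("gene_id") or [feat.id])[0]
        desc = (attrs.get("description") or attrs.get("Note") or [""])[0]
        genes.append(
            GeneRecord(gene_id, str(feat.seqid), feat.start, feat.end, feat.strand or ".", desc)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Segments as the 1-based report table (chrom, start, stop, peak SNP, p)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "stop": s.stop,
                "peak_pos": s.peak_pos,
                "peak_p": s.peak_p,
                "trait": s.trait,
                "environment": s.environment,
            }
            for s in segments
        ]
    )
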