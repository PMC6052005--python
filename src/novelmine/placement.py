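"""Placing novel contigs on the reference via one-end-anchored read pairs.

A one-end anchor (OEA) is a read pair in which one mate aligns uniquely to
the genome and the other aligns uniquely to an assembled contig, both with
mapq >= 30.  Fragment-length arithmetic then projects the contig onto the
genome:

with ``g`` the genome mate's leftmost position, ``F`` the expected insert
and ``r`` the read length, the missing mate's expected leftmost genome
position is ``m = g + F - r`` when the genome mate is on '+' (the fragment
extends right) and ``m = g + r - F`` on '-' (it extends left).  With ``c``
the contig-side mate's leftmost position on the contig's forward strand and
``L`` the contig length, the contig's predicted genome start is ``m - c``
when the contig lies genome-forward and ``m + c + r - L`` when it lies
genome-reverse; the orientation follows from the strand pair (a '+' genome
mate pairs with a genome-reverse mate, which reads a genome-forward contig
on its '-' strand, and vice versa).

Anchors are clustered per (target, orientation) by single linkage on their
predicted intervals; clusters below ``min_support`` anchors are dropped.
Because anchors from the two junctions of a pure insertion disagree about
the contig start by the insertion length (the insertion occupies no
reference space), anchors whose predicted intervals overlap are treated as
evidence for the same physical locus, and the reported locus interval is
the intersection of the median predictions of the left-junction ('+'
genome-mate) and right-junction ('-' genome-mate) anchor groups.  Contigs
are classified by locus multiplicity (single / two / more than two), and
single-locus predictions are verified by local realignment of the contig
against the padded reference window.
"""

from __future__ import annotations

import dataclasses
from statistics import median_low
from typing import Iterable, Sequence

from . import io, mapper
from .io import AlignmentRecord

FIVE_PRIME = "FIVE_PRIME"
THREE_PRIME = "THREE_PRIME"


@dataclasses.dataclass
class OeaAnchor:
    pair_id: str
    genome_target: str
    genome_pos: int
    genome_strand: str
    genome_mapq: int
    contig_id: str
    contig_pos: int
    contig_strand: str
    contig_mapq: int
    contig_end: str  # FIVE_PRIME | THREE_PRIME
    predicted_start: int
    orientation: str  # contig orientation on the genome: '+' | '-'


@dataclasses.dataclass
class Locus:
    target: str
    start: int
    end: int
    orientation: str
    support: int
    verified: bool = False


@dataclasses.dataclass
class ContigPlacement:
    contig_id: str
    contig_length: int
    loci: list[Locus]
    classification: str  # SINGLE | TWO | MULTI | UNPLACED
    n_anchors: int = 0

    @staticmethod
    def classify(n_loci: int) -> str:
        if n_loci == 0:
            return "UNPLACED"
        if n_loci == 1:
            return "SINGLE"
        if n_loci == 2:
            return "TWO"
        return "MULTI"


def predict_locus(
    genome_pos: int,
    genome_strand: str,
    contig_pos: int,
    contig_strand: str,
    insert_mean: int,
    read_length: int,
    contig_length: int,
) -> tuple[int, str]:
    """Project one anchor to (predicted contig genome start, orientation).

    Self-consistency is enforced by a round-trip oracle in the test suite:
    simulating a single error-free OEA pair from a known placement and
    inverting it recovers the placement exactly for all four strand
    configurations.
    """
    if genome_strand == "+":
        m = genome_pos + insert_mean - read_length
        forward = contig_strand == "-"
    else:
        m = genome_pos + read_length - insert_mean
        forward = contig_strand == "+"
    if forward:
        return m - contig_pos, "+"
    return m + contig_pos + read_length - contig_length, "-"


def make_anchor(
    pair_id: str,
    genome_aln: AlignmentRecord,
    contig_aln: AlignmentRecord,
    insert_mean: int,
    contig_length: int,
    min_mapq: int = 30,
) -> OeaAnchor | None:
    """Build one anchor from a genome-side and a contig-side alignment.

    Returns None unless both sides reach ``min_mapq`` (the uniqueness
    filter: scores >= 30 in both genome and assembly).
    """
    if genome_aln.mapq < min_mapq or contig_aln.mapq < min_mapq:
        return None
    read_length = contig_aln.query_length or insert_mean
    start, orientation = predict_locus(
        genome_aln.target_start,
        genome_aln.strand,
        contig_aln.target_start,
        contig_aln.strand,
        insert_mean,
        read_length,
        contig_length,
    )
    # a mate within one insert of a contig end anchors that end
    if contig_aln.target_start < insert_mean:
        end = FIVE_PRIME
    elif contig_aln.target_start + read_length > contig_length - insert_mean:
        end = THREE_PRIME
    else:
        mid = contig_length / 2
        end = FIVE_PRIME if contig_aln.target_start < mid else THREE_PRIME
    return OeaAnchor(
        pair_id=pair_id,
        genome_target=genome_aln.target_id,
        genome_pos=genome_aln.target_start,
        genome_strand=genome_aln.strand,
        genome_mapq=genome_aln.mapq,
        contig_id=contig_aln.target_id,
        contig_pos=contig_aln.target_start,
        contig_strand=contig_aln.strand,
        contig_mapq=contig_aln.mapq,
        contig_end=end,
        predicted_start=start,
        orientation=orientation,
    )


def harvest_anchors(
    oea_pairs: Iterable[
        tuple[str, AlignmentRecord | None, AlignmentRecord | None, AlignmentRecord | None, AlignmentRecord | None]
    ],
    contig_lengths: dict[str, int],
    insert_mean: int,
    min_mapq: int = 30,
) -> tuple[list[OeaAnchor], dict[str, int]]:
    """Harvest anchors from per-pair (genome aln x2, contig aln x2) evidence.

    Each row is (pair_id, genome_aln1, genome_aln2, contig_aln1,
    contig_aln2).  An anchor is emitted when exactly one mate maps to the
    genome and the *other* mate maps to a contig, both at ``min_mapq``.
    Pairs with both mates on the genome or both on contigs are skipped and
    counted.
    """
    anchors: list[OeaAnchor] = []
    counts = {"pairs": 0, "anchors": 0, "both_genome": 0, "both_contig": 0, "no_anchor": 0}
    for pair_id, g1, g2, c1, c2 in oea_pairs:
        counts["pairs"] += 1
        if g1 is not None and g2 is not None:
            counts["both_genome"] += 1
            continue
        if g1 is None and g2 is None and (c1 is not None or c2 is not None):
            counts["both_contig"] += 1
            continue
        genome_aln, contig_aln = (g1, c2) if g1 is not None else (g2, c1)
        if genome_aln is None or contig_aln is None:
            counts["no_anchor"] += 1
            continue
        anchor = make_anchor(
            pair_id,
            genome_aln,
            contig_aln,
            insert_mean,
            contig_lengths[contig_aln.target_id],
            min_mapq=min_mapq,
        )
        if anchor is None:
            counts["no_anchor"] += 1
        else:
            anchors.append(anchor)
            counts["anchors"] += 1
    return anchors, counts


def anchors_from_sams(
    genome_sam: str,
    assembly_sam: str,
    contig_lengths: dict[str, int],
    insert_mean: int,
    min_mapq: int = 30,
) -> tuple[list[OeaAnchor], dict[str, int]]:
    """Harvest anchors from two SAM files keyed by pair id (external-mapper path)."""
    genome: dict[str, dict[int, AlignmentRecord | None]] = {}
    for name, _r1, _r2, a1, a2 in io.read_pair_sam(genome_sam):
        genome[name] = {1: a1, 2: a2}
    rows = []
    for name, _r1, _r2, a1, a2 in io.read_pair_sam(assembly_sam):
        g = genome.get(name, {1: None, 2: None})
        rows.append((name, g[1], g[2], a1, a2))
    return harvest_anchors(rows, contig_lengths, insert_mean, min_mapq)


def cluster_and_classify(
    anchors: Sequence[OeaAnchor],
    contig_length: int,
    cluster_radius: int,
    min_support: int = 2,
) -> ContigPlacement:
    """Cluster one contig's anchors into loci and classify by multiplicity.

    Single-linkage joins anchors whose predicted starts are within
    ``max(cluster_radius, contig_length)`` on the same (target,
    orientation) - i.e. whose predicted intervals overlap or nearly touch.
    Within a cluster the locus interval is the intersection of the median
    left-junction and median right-junction predictions (each an interval
    of the contig's length); with only one junction represented, its median
    prediction is used directly.
    """
    if not anchors:
        return ContigPlacement("", contig_length, [], "UNPLACED", 0)
    contig_id = anchors[0].contig_id
    link = max(cluster_radius, contig_length)
    loci: list[Locus] = []
    by_key: dict[tuple[str, str], list[OeaAnchor]] = {}
    for a in anchors:
        by_key.setdefault((a.genome_target, a.orientation), []).append(a)
    for (target, orientation), group in sorted(by_key.items()):
        group.sort(key=lambda a: a.predicted_start)
        cluster: list[OeaAnchor] = []
        clusters: list[list[OeaAnchor]] = []
        for a in group:
            if cluster and a.predicted_start - cluster[-1].predicted_start > link:
                clusters.append(cluster)
                cluster = []
            cluster.append(a)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_support:
                continue
            left = [a.predicted_start for a in cl if a.genome_strand == "+"]
            right = [a.predicted_start for a in cl if a.genome_strand == "-"]
            if left and right:
                s1 = median_low(left)
                s2 = median_low(right)
                start = max(s1, s2)
                end = min(s1, s2) + contig_length
                if end <= start:  # inconsistent junctions; fall back to overall median
                    start = median_low([a.predicted_start for a in cl])
                    end = start + contig_length
            else:
                start = median_low([a.predicted_start for a in cl])
                end = start + contig_length
            loci.append(Locus(target, int(start), int(end), orientation, len(cl)))
    loci.sort(key=lambda l: (-l.support, l.target, l.start))
    return ContigPlacement(
        contig_id, contig_length, loci, ContigPlacement.classify(len(loci)), len(anchors)
    )


def place_contigs(
    anchors: Sequence[OeaAnchor],
    contig_lengths: dict[str, int],
    insert_mean: int,
    cluster_radius: int | None = None,
    min_support: int = 2,
) -> dict[str, ContigPlacement]:
    """Cluster anchors per contig; contigs without anchors are UNPLACED."""
    if cluster_radius is None:
        cluster_radius = 2 * insert_mean
    by_contig: dict[str, list[OeaAnchor]] = {cid: [] for cid in contig_lengths}
    for a in anchors:
        by_contig[a.contig_id].append(a)
    out: dict[str, ContigPlacement] = {}
    for cid, group in by_contig.items():
        p = cluster_and_classify(group, contig_lengths[cid], cluster_radius, min_support)
        p.contig_id = cid
        out[cid] = p
    return out


def verify_placements(
    placements: dict[str, ContigPlacement],
    contigs: dict[str, str],
    reference: dict[str, str],
    pad: int,
    min_score: int = 60,
    min_matches: int = 40,
    verify_two: bool = False,
) -> dict[str, ContigPlacement]:
    """Verify SINGLE (optionally TWO) loci by local realignment.

    A locus is verified when a local alignment of the contig against the
    reference window (locus +/- pad) scores >= ``min_score`` with >=
    ``min_matches`` matched bases and overlaps the predicted interval.  For
    a novel insertion only the junction-spanning flanks of the contig can
    align, which is sufficient - hence an anchor-strength criterion rather
    than a whole-alignment identity one (the local optimum may extend a
    perfect flank match into the novel interior).
    """
    for p in placements.values():
        if p.classification == "UNPLACED":
            continue
        if p.classification != "SINGLE" and not (verify_two and p.classification == "TWO"):
            continue
        seq = contigs.get(p.contig_id)
        if seq is None:
            continue
        for locus in p.loci:
            ref = reference.get(locus.target)
            if ref is None:
                continue
            w0 = max(0, locus.start - pad)
            w1 = min(len(ref), locus.end + pad)
            if w1 <= w0:
                continue  # window outside the reference: stays unverified
            for aln in mapper.align_local(
                seq, ref[w0:w1], min_score=min_score, max_n=5, both_strands=True
            ):
                if aln.score < min_score or aln.matches < min_matches:
                    continue
                t0, t1 = w0 + aln.target_start, w0 + aln.target_end
                if t0 < locus.end and t1 > locus.start:
                    locus.verified = True
                    break
    return placements


def classification_summary(placements: dict[str, ContigPlacement]) -> dict[str, int]:
    """Locus-multiplicity table: total / predicted / single / two / multi."""
    summary = {
        "total_contigs": len(placements),
        "predicted": 0,
        "high_quality": 0,
        "single": 0,
        "two": 0,
        "multi": 0,
        "verified_single": 0,
    }
    for p in placements.values():
        if p.n_anchors > 0:
            summary["predicted"] += 1
        if p.classification == "UNPLACED":
            continue
        summary["high_quality"] += 1
        key = p.classification.lower()
        if key in summary:
            summary[key] += 1
        if p.classification == "SINGLE" and p.loci and p.loci[0].verified:
            summary["verified_single"] += 1
    return summary


def placements_to_bed(placements: dict[str, ContigPlacement]) -> list[tuple]:
    rows = []
    for cid in sorted(placements):
        p = placements[cid]
        for locus in p.loci:
            rows.append(
                (
                    locus.target,
                    locus.start,
                    locus.end,
                    cid,
                    locus.support,
                    locus.orientation,
                    p.classification,
                    int(locus.verified),
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    return rows
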