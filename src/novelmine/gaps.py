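"""Gap intersection and closure accounting.

Reference assembly gaps are maximal N-runs (or a user-supplied BED).  A
placed contig is a *gap contig* when its genomic interval overlaps a gap by
at least 1 bp; a gap is *closed* when the union of overlapping contig
intervals covers it entirely - two distinct definitions, so that partially
filled sequence and fully closed gaps can both be counted.  Gaps are
*genic* when they overlap an exon, splice site (modelled as the 2 bp at
each intron end), UTR, intron, or ncRNA feature.  Gap contigs are
cross-referenced against BAC clone-insert placements; gap contigs with no
BAC overlap are the "novel, no-BAC" set.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import Feature

GENIC_CLASSES = ("exon", "splice_site", "five_prime_UTR", "three_prime_UTR", "intron", "ncRNA")

_N_RUN = re.compile(r"[Nn]+")


@dataclasses.dataclass(frozen=True)
class GapInterval:
    target: str
    start: int
    end: int
    gap_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class GapRow:
    gap_id: str
    target: str
    start: int
    end: int
    contig_ids: list[str]
    filled_bp: int
    closed: bool
    genic_classes: list[str]
    gene_ids: list[str]
    bac_covered: bool


@dataclasses.dataclass
class GapClosureReport:
    rows: list[GapRow]
    n_gap_contigs: int
    n_gaps_closed: int
    total_filled_bp: int
    n_genic_gaps: int
    n_genic_gap_contigs: int
    n_novel_no_bac_contigs: int
    n_novel_no_bac_gaps: int
    gap_contig_ids: list[str]
    novel_no_bac_contig_ids: list[str]


def find_gaps(reference: dict[str, str]) -> list[GapInterval]:
    """Maximal N-runs of each target, as 0-based half-open intervals."""
    gaps: list[GapInterval] = []
    n = 0
    for target in sorted(reference):
        for m in _N_RUN.finditer(reference[target]):
            n += 1
            gaps.append(GapInterval(target, m.start(), m.end(), f"gap{n}"))
    return gaps


def gaps_from_bed(rows: Iterable[tuple]) -> list[GapInterval]:
    out = []
    for i, row in enumerate(rows):
        gid = str(row[3]) if len(row) > 3 else f"gap{i + 1}"
        out.append(GapInterval(str(row[0]), int(row[1]), int(row[2]), gid))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def intersect_gaps(
    placements: Sequence[tuple[str, int, int, str]],
    gaps: Sequence[GapInterval],
) -> dict[str, dict]:
    """Assign placed contigs to gaps.

    ``placements`` rows are (target, start, end, contig_id).  Returns per-gap
    dicts with contig ids, union filled_bp (clipped to the gap) and the
    closed flag (union covers the whole gap).
    """
    trees: dict[str, IntervalTree] = {}
    for i, (target, start, end, cid) in enumerate(placements):
        if end <= start:
            raise ValueError(f"placement row {i + 1}: malformed interval {target}:{start}-{end}")
        trees.setdefault(target, IntervalTree()).addi(start, end, cid)
    out: dict[str, dict] = {}
    for gap in gaps:
        overlaps = []
        tree = trees.get(gap.target)
        if tree is not None:
            for iv in sorted(tree.overlap(gap.start, gap.end)):
                clipped = (max(iv.begin, gap.start), min(iv.end, gap.end))
                overlaps.append((iv.data, clipped))
        filled = _union_length([c for _cid, c in overlaps])
        out[gap.gap_id] = {
            "gap": gap,
            "contig_ids": sorted({cid for cid, _ in overlaps}),
            "filled_bp": filled,
            "closed": filled == gap.length and gap.length > 0,
        }
    return out


def splice_sites(features: Sequence[Feature], width: int = 2) -> list[Feature]:
    """Derive splice-site windows: ``width`` bp at each end of every intron."""
    out = []
    for f in features:
        if f.ftype != "intron" or f.end - f.start < 2 * width:
            continue
        out.append(Feature(f.chrom, f.start, f.start + width, f.strand, "splice_site", f.gene_id))
        out.append(Feature(f.chrom, f.end - width, f.end, f.strand, "splice_site", f.gene_id))
    return out


def classify_genic(
    gaps: Sequence[GapInterval],
    features: Sequence[Feature],
    splice_width: int = 2,
) -> dict[str, dict]:
    """Label each gap with every genic feature class it overlaps.

    A gap is genic iff it overlaps >= 1 of exon / splice_site / UTR /
    intron / ncRNA.  Splice sites are derived from intron ends; unknown
    feature types are ignored.
    """
    feats = list(features) + splice_sites(features, splice_width)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f in feats:
        if f.ftype not in GENIC_CLASSES:
            continue
        if f.end <= f.start:
            continue
        trees.setdefault((f.chrom, f.ftype), IntervalTree()).addi(f.start, f.end, f.gene_id)
    out: dict[str, dict] = {}
    for gap in gaps:
        classes: list[str] = []
        genes: set[str] = set()
        for klass in GENIC_CLASSES:
            tree = trees.get((gap.target, klass))
            if tree is None:
                continue
            hits = tree.overlap(gap.start, gap.end)
            if hits:
                classes.append(klass)
                genes |= {iv.data for iv in hits}
        out[gap.gap_id] = {"classes": classes, "genes": sorted(genes), "genic": bool(classes)}
    return out


def bac_crossref(
    gap_assignments: dict[str, dict],
    placements: Sequence[tuple[str, int, int, str]],
    bacs: Sequence[tuple[str, int, int]] | None,
) -> dict[str, bool]:
    """Per-contig BAC coverage: does the contig's interval overlap any BAC?

    With no BAC file supplied, every gap contig is novel-no-BAC.
    """
    trees: dict[str, IntervalTree] = {}
    for row in bacs or []:
        target, start, end = str(row[0]), int(row[1]), int(row[2])
        if end > start:
            trees.setdefault(target, IntervalTree()).addi(start, end)
    covered: dict[str, bool] = {}
    gap_contigs = set()
    for info in gap_assignments.values():
        gap_contigs.update(info["contig_ids"])
    for target, start, end, cid in placements:
        if cid not in gap_contigs:
            continue
        tree = trees.get(target)
        hit = bool(tree.overlap(start, end)) if tree is not None else False
        covered[cid] = covered.get(cid, False) or hit
    return covered


def build_report(
    placements: Sequence[tuple[str, int, int, str]],
    gaps: Sequence[GapInterval],
    features: Sequence[Feature] | None = None,
    bacs: Sequence[tuple[str, int, int]] | None = None,
) -> GapClosureReport:
    """Full per-gap and aggregate gap-closure accounting.

    A contig overlapping two gaps is counted once in ``n_gap_contigs``;
    (contig, gap) pairs are visible in the per-gap rows.
    """
    assignments = intersect_gaps(placements, gaps)
    genic = classify_genic(gaps, features or [])
    bac_cover = bac_crossref(assignments, placements, bacs)
    rows: list[GapRow] = []
    gap_contigs: set[str] = set()
    genic_gap_contigs: set[str] = set()
    no_bac_contigs: set[str] = set()
    no_bac_gaps: set[str] = set()
    for gap in gaps:
        info = assignments[gap.gap_id]
        g = genic.get(gap.gap_id, {"classes": [], "genes": [], "genic": False})
        cids = info["contig_ids"]
        gap_contigs.update(cids)
        if g["genic"]:
            genic_gap_contigs.update(cids)
        gap_no_bac = [cid for cid in cids if not bac_cover.get(cid, False)]
        no_bac_contigs.update(gap_no_bac)
        if cids and gap_no_bac:
            no_bac_gaps.add(gap.gap_id)
        rows.append(
            GapRow(
                gap_id=gap.gap_id,
                target=gap.target,
                start=gap.start,
                end=gap.end,
                contig_ids=cids,
                filled_bp=info["filled_bp"],
                closed=info["closed"],
                genic_classes=g["classes"],
                gene_ids=g["genes"],
                bac_covered=all(bac_cover.get(cid, False) for cid in cids) if cids else False,
            )
        )
    return GapClosureReport(
        rows=rows,
        n_gap_contigs=len(gap_contigs),
        n_gaps_closed=sum(r.closed for r in rows),
        total_filled_bp=sum(r.filled_bp for r in rows),
        n_genic_gaps=sum(1 for r in rows if r.genic_classes),
        n_genic_gap_contigs=len(genic_gap_contigs),
        n_novel_no_bac_contigs=len(no_bac_contigs),
        n_novel_no_bac_gaps=len(no_bac_gaps),
        gap_contig_ids=sorted(gap_contigs),
        novel_no_bac_contig_ids=sorted(no_bac_contigs),
    )
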