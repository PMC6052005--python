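"""OEA anchor geometry, clustering, classification and verification."""

import numpy as np
import pytest

from novelmine import io, placement
from novelmine.io import AlignmentRecord
from novelmine.placement import (
    ContigPlacement,
    cluster_and_classify,
    harvest_anchors,
    make_anchor,
    predict_locus,
)

INSERT = 290
READ = 100


def simulate_oea_pair(contig_start, contig_len, orientation, junction):
    """Brute-force oracle: derive the (genome mate, contig mate) coordinates
    of one error-free OEA pair from a known contig placement.

    The contig occupies [contig_start, contig_start + contig_len) on the
    genome with the given orientation.  ``junction`` selects the fragment
    spanning the left ('L': genome mate on '+') or right ('R': genome mate
    on '-') contig boundary.  Returns (g_pos, g_strand, c_pos, c_strand).
    """
    if junction == "L":
        g_pos = contig_start - 150  # genome mate wholly left of the contig
        g_strand = "+"
        partner_genome_left = g_pos + INSERT - READ  # fragment extends right
        partner_genome_strand = "-"
    else:
        g_pos = contig_start + contig_len + 50
        g_strand = "-"
        partner_genome_left = g_pos + READ - INSERT  # fragment extends left
        partner_genome_strand = "+"
    off = partner_genome_left - contig_start  # partner offset inside the contig
    assert 0 <= off <= contig_len - READ
    if orientation == "+":
        c_pos = off
        c_strand = partner_genome_strand
    else:
        c_pos = contig_len - off - READ
        c_strand = "-" if partner_genome_strand == "+" else "+"
    return g_pos, g_strand, c_pos, c_strand


class TestPredictLocus:
    @pytest.mark.parametrize("orientation", ["+", "-"])
    @pytest.mark.parametrize("junction", ["L", "R"])
    def test_round_trip_all_four_strand_configurations(self, orientation, junction):
        """Simulating one error-free OEA pair from a known placement and
        inverting recovers the placement exactly."""
        contig_start, contig_len = 10_000, 2_000
        g_pos, g_strand, c_pos, c_strand = simulate_oea_pair(
            contig_start, contig_len, orientation, junction
        )
        start, orient = predict_locus(
            g_pos, g_strand, c_pos, c_strand, INSERT, READ, contig_len
        )
        assert start == contig_start
        assert orient == orientation

    def test_worked_forward_case(self):
        # g=10,000 (+), insert 290, read 100, c=0, contig-side '-', 2 kb contig
        start, orient = predict_locus(10_000, "+", 0, "-", 290, 100, 2_000)
        assert (start, orient) == (10_190, "+")

    def test_worked_mirrored_case(self):
        # genome mate on '-': m = 10,000 + 100 - 290 = 9,810
        start, orient = predict_locus(10_000, "-", 0, "+", 290, 100, 2_000)
        assert (start, orient) == (9_810, "+")

    def test_degenerate_insert_equals_read_length(self):
        # insert == read length: the missing mate abuts the anchor
        start, _ = predict_locus(10_000, "+", 0, "-", 100, 100, 500)
        assert start == 10_000


def genome_aln(pos, strand="+", mapq=60):
    return AlignmentRecord("p", "chr1", pos, strand, "100M", mapq, query_length=100)


def contig_aln(cid, pos, strand="-", mapq=60):
    return AlignmentRecord("p", cid, pos, strand, "100M", mapq, query_length=100)


class TestHarvestAnchors:
    LENGTHS = {"c1": 2000}

    def test_anchor_emitted_for_qualifying_pair(self):
        rows = [("p1", genome_aln(5000), None, None, contig_aln("c1", 10))]
        anchors, counts = harvest_anchors(rows, self.LENGTHS, INSERT)
        assert len(anchors) == 1 and counts["anchors"] == 1
        a = anchors[0]
        assert a.contig_end == placement.FIVE_PRIME
        assert a.predicted_start == 5000 + INSERT - 100 - 10

    def test_mapq_filter_both_sides(self):
        # ambiguous contig-side mate (mapq 0): no anchor
        rows = [("p1", genome_aln(5000), None, None, contig_aln("c1", 10, mapq=0))]
        anchors, counts = harvest_anchors(rows, self.LENGTHS, INSERT)
        assert anchors == [] and counts["no_anchor"] == 1
        rows = [("p1", genome_aln(5000, mapq=0), None, None, contig_aln("c1", 10))]
        anchors, _ = harvest_anchors(rows, self.LENGTHS, INSERT)
        assert anchors == []

    def test_lowering_mapq_never_decreases_anchor_count(self):
        rows = [
            ("p1", genome_aln(5000, mapq=60), None, None, contig_aln("c1", 10, mapq=60)),
            ("p2", genome_aln(6000, mapq=30), None, None, contig_aln("c1", 20, mapq=0)),
            ("p3", genome_aln(7000, mapq=0), None, None, contig_aln("c1", 30, mapq=0)),
        ]
        n = {}
        for q in (0, 30, 60):
            anchors, _ = harvest_anchors(rows, self.LENGTHS, INSERT, min_mapq=q)
            n[q] = len(anchors)
        assert n[0] >= n[30] >= n[60]
        assert n[0] == 3 and n[30] == 1

    def test_both_sides_mapped_pairs_skipped_and_counted(self):
        rows = [
            ("p1", genome_aln(5000), genome_aln(5200, "-"), None, contig_aln("c1", 10)),
            ("p2", None, None, contig_aln("c1", 10), contig_aln("c1", 500)),
        ]
        anchors, counts = harvest_anchors(rows, self.LENGTHS, INSERT)
        assert anchors == []
        assert counts["both_genome"] == 1 and counts["both_contig"] == 1

    def test_three_prime_end_assignment(self):
        rows = [("p1", genome_aln(5000, "-"), None, None, contig_aln("c1", 1950, "+"))]
        anchors, _ = harvest_anchors(rows, self.LENGTHS, INSERT)
        assert anchors[0].contig_end == placement.THREE_PRIME


def mk_anchor(start, g_strand="+", target="chr1", cid="c1"):
    return placement.OeaAnchor(
        pair_id=f"p{start}",
        genome_target=target,
        genome_pos=0,
        genome_strand=g_strand,
        genome_mapq=60,
        contig_id=cid,
        contig_pos=0,
        contig_strand="-",
        contig_mapq=60,
        contig_end=placement.FIVE_PRIME,
        predicted_start=start,
        orientation="+",
    )


class TestClusterAndClassify:
    def test_single_cluster_uses_median(self):
        anchors = [mk_anchor(s) for s in (10_190, 10_194, 10_201)]
        p = cluster_and_classify(anchors, contig_length=2000, cluster_radius=580)
        assert p.classification == "SINGLE"
        assert p.loci[0].start == 10_194

    def test_two_distant_clusters(self):
        anchors = [mk_anchor(s) for s in (10_190, 10_194, 1_000_000, 1_000_004)]
        p = cluster_and_classify(anchors, contig_length=2000, cluster_radius=580)
        assert p.classification == "TWO"

    def test_three_clusters_is_multi(self):
        anchors = [
            mk_anchor(s)
            for s in (10_000, 10_001, 500_000, 500_002, 1_000_000, 1_000_001)
        ]
        p = cluster_and_classify(anchors, contig_length=2000, cluster_radius=580)
        assert p.classification == "MULTI"

    def test_min_support_drops_singletons(self):
        anchors = [mk_anchor(10_190), mk_anchor(10_194), mk_anchor(900_000)]
        p = cluster_and_classify(anchors, contig_length=2000, cluster_radius=580, min_support=2)
        assert p.classification == "SINGLE"

    def test_unplaced_without_anchors(self):
        p = cluster_and_classify([], contig_length=2000, cluster_radius=580)
        assert p.classification == "UNPLACED"

    def test_insertion_junction_groups_intersect(self):
        """Anchors from the two junctions of a pure insertion disagree on the
        start by ~the insertion length; the locus interval is the
        intersection of the junction-group medians and its midpoint sits at
        the insertion point."""
        L = 2000  # contig: 80 bp flank + 1840 bp insertion + 80 bp flank
        p_ins = 50_000
        left = [mk_anchor(p_ins - 80, "+") for _ in range(3)]
        right = [mk_anchor(p_ins + 80 - L, "-") for _ in range(3)]
        p = cluster_and_classify(left + right, contig_length=L, cluster_radius=580)
        assert p.classification == "SINGLE"
        locus = p.loci[0]
        assert locus.start == p_ins - 80 and locus.end == p_ins + 80
        assert abs((locus.start + locus.end) / 2 - p_ins) <= 80


class TestVerifyPlacements:
    def test_gap_fill_contig_verified_and_wrong_locus_not(self, rng):
        ref_seq = io.random_dna(rng, 12_000)
        fill = io.random_dna(rng, 600)
        # reference has a gap at [5000, 5600); contig restores it with flanks
        reference = {"chr1": ref_seq[:5000] + "N" * 600 + ref_seq[5600:]}
        contig_seq = ref_seq[4920:5000] + fill + ref_seq[5600:5680]
        loci_ok = [placement.Locus("chr1", 4920, 5680, "+", 5)]
        loci_bad = [placement.Locus("chr1", 9000, 9760, "+", 5)]
        placements = {
            "good": ContigPlacement("good", len(contig_seq), loci_ok, "SINGLE", 5),
            "bad": ContigPlacement("bad", len(contig_seq), loci_bad, "SINGLE", 5),
        }
        placement.verify_placements(
            placements, {"good": contig_seq, "bad": contig_seq}, reference, pad=580
        )
        assert placements["good"].loci[0].verified
        assert not placements["bad"].loci[0].verified

    def test_unplaced_untouched(self):
        placements = {"u": ContigPlacement("u", 500, [], "UNPLACED", 0)}
        placement.verify_placements(placements, {"u": "ACGT" * 200}, {"chr1": "ACGT" * 5000}, pad=580)
        assert placements["u"].loci == []

    def test_window_outside_reference_stays_unverified(self, rng):
        seq = io.random_dna(rng, 1000)
        loci = [placement.Locus("chrX", 100, 700, "+", 3)]
        placements = {"c": ContigPlacement("c", 600, loci, "SINGLE", 3)}
        placement.verify_placements(placements, {"c": seq[:600]}, {"chr1": seq}, pad=100)
        assert not placements["c"].loci[0].verified
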