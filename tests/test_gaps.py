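"""Gap discovery, intersection arithmetic, genic classes, BAC cross-reference."""

import numpy as np
import pytest

from novelmine import gaps as gaps_mod
from novelmine import io
from novelmine.gaps import GapInterval, build_report, classify_genic, find_gaps, intersect_gaps
from novelmine.io import Feature


def scan_oracle(seq):
    runs, start = [], None
    for i, ch in enumerate(seq + "x"):
        if ch in "Nn":
            start = i if start is None else start
        elif start is not None:
            runs.append((start, i))
            start = None
    return runs


class TestFindGaps:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTNNNNACGT", [(4, 8)]),
            ("ACGTACGT", []),
            ("NNACGT", [(0, 2)]),
            ("ACGTNN", [(4, 6)]),
            ("NNNN", [(0, 4)]),
            ("AnNnA", [(1, 4)]),
        ],
    )
    def test_worked_cases(self, seq, expected):
        gaps = find_gaps({"c": seq})
        assert [(g.start, g.end) for g in gaps] == expected

    def test_matches_scan_oracle_on_random(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 120))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
            gaps = find_gaps({"c": seq})
            assert [(g.start, g.end) for g in gaps] == scan_oracle(seq)


def per_base_overlap_oracle(placements, gap):
    """Brute-force per-base membership oracle for filled bp / closure."""
    covered = np.zeros(gap.end - gap.start, dtype=bool)
    for target, s, e, _cid in placements:
        if target != gap.target:
            continue
        lo, hi = max(s, gap.start), min(e, gap.end)
        if hi > lo:
            covered[lo - gap.start : hi - gap.start] = True
    return int(covered.sum()), bool(covered.all())


class TestIntersectGaps:
    def test_contained_gap_closed(self):
        gaps = [GapInterval("c", 1000, 1500, "g1")]
        res = intersect_gaps([("c", 900, 1600, "k1")], gaps)
        assert res["g1"]["filled_bp"] == 500 and res["g1"]["closed"]

    def test_partial_overlap_not_closed(self):
        gaps = [GapInterval("c", 1000, 1500, "g1")]
        res = intersect_gaps([("c", 1200, 1600, "k1")], gaps)
        assert res["g1"]["filled_bp"] == 300 and not res["g1"]["closed"]

    def test_union_of_two_contigs_closes(self):
        gaps = [GapInterval("c", 1000, 1500, "g1")]
        res = intersect_gaps(
            [("c", 900, 1250, "k1"), ("c", 1240, 1600, "k2")], gaps
        )
        assert res["g1"]["closed"] and res["g1"]["contig_ids"] == ["k1", "k2"]

    def test_malformed_interval_raises_with_row(self):
        with pytest.raises(ValueError, match="row 1"):
            intersect_gaps([("c", 500, 400, "k1")], [GapInterval("c", 0, 10, "g1")])

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(300):
            gap = GapInterval("c", 2000, 2000 + int(rng.integers(100, 900)), "g1")
            placements = []
            for j in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, 9500))
                placements.append(("c", s, s + int(rng.integers(50, 1500)), f"k{j}"))
            res = intersect_gaps(placements, [gap])["g1"]
            filled, closed = per_base_overlap_oracle(placements, gap)
            assert res["filled_bp"] == filled
            assert res["closed"] == closed

    def test_filled_conservation(self, rng):
        gaps = [
            GapInterval("c", 1000, 1400, "g1"),
            GapInterval("c", 5000, 5600, "g2"),
        ]
        placements = [("c", 900, 1500, "k1"), ("c", 5100, 5300, "k2")]
        res = intersect_gaps(placements, gaps)
        total_filled = sum(r["filled_bp"] for r in res.values())
        total_gap = sum(g.length for g in gaps)
        assert total_filled <= total_gap
        assert (total_filled == total_gap) == all(r["closed"] for r in res.values())


GENE = [
    Feature("c", 1000, 5000, "+", "gene", "g"),
    Feature("c", 1000, 1300, "+", "exon", "g"),
    Feature("c", 1000, 1100, "+", "five_prime_UTR", "g"),
    Feature("c", 1300, 4600, "+", "intron", "g"),
    Feature("c", 4600, 5000, "+", "exon", "g"),
    Feature("c", 4900, 5000, "+", "three_prime_UTR", "g"),
    Feature("c", 8000, 8600, "+", "ncRNA", "nc"),
]


class TestClassifyGenic:
    def test_gap_inside_intron(self):
        gaps = [GapInterval("c", 2000, 2400, "g1")]
        res = classify_genic(gaps, GENE)
        assert res["g1"]["classes"] == ["intron"] and res["g1"]["genic"]

    def test_intergenic_gap(self):
        gaps = [GapInterval("c", 6000, 6400, "g1")]
        res = classify_genic(gaps, GENE)
        assert not res["g1"]["genic"]

    def test_exon_intron_boundary_includes_splice_site(self):
        gaps = [GapInterval("c", 1250, 1350, "g1")]
        res = classify_genic(gaps, GENE)
        assert set(res["g1"]["classes"]) == {"exon", "splice_site", "intron"}

    def test_splice_site_is_two_bp_window(self):
        # a gap touching only the first 2 bp of the intron
        res = classify_genic([GapInterval("c", 1300, 1302, "g1")], GENE)
        assert "splice_site" in res["g1"]["classes"]
        res = classify_genic([GapInterval("c", 1303, 1310, "g1")], GENE)
        assert "splice_site" not in res["g1"]["classes"]

    def test_ncrna_and_utr_classes(self):
        res = classify_genic([GapInterval("c", 8100, 8200, "g1")], GENE)
        assert res["g1"]["classes"] == ["ncRNA"]
        res = classify_genic([GapInterval("c", 1050, 1060, "g2")], GENE)
        assert "five_prime_UTR" in res["g2"]["classes"]

    def test_unknown_feature_types_ignored(self):
        feats = GENE + [Feature("c", 2000, 2400, "+", "mystery_type", "g")]
        res = classify_genic([GapInterval("c", 6000, 6400, "g1")], feats)
        assert not res["g1"]["genic"]


class TestHandBuiltToy:
    """A printed toy: 3 gaps, 4 placed contigs, hand-computed accounting.

    gaps:   gA [1000,1400)  genic (inside the intron of gene g)
            gB [5000,5500)  genic (overlaps the 3' exon region)... see GENE2
            gC [9000,9300)  intergenic
    contigs k1 [900,1450)   covers gA fully
            k2 [4950,5200)  left part of gB
            k3 [5190,5600)  right part of gB  (union closes gB)
            k4 [9100,9200)  partial middle of gC
    BACs    [800,2000) only  -> k1 BAC-covered; k2,k3,k4 novel-no-BAC
    """

    GAPS = [
        GapInterval("c", 1000, 1400, "gA"),
        GapInterval("c", 5000, 5500, "gB"),
        GapInterval("c", 9000, 9300, "gC"),
    ]
    PLACEMENTS = [
        ("c", 900, 1450, "k1"),
        ("c", 4950, 5200, "k2"),
        ("c", 5190, 5600, "k3"),
        ("c", 9100, 9200, "k4"),
    ]
    FEATURES = [
        Feature("c", 500, 2500, "+", "gene", "g"),
        Feature("c", 500, 800, "+", "exon", "g"),
        Feature("c", 800, 2200, "+", "intron", "g"),
        Feature("c", 2200, 2500, "+", "exon", "g"),
        Feature("c", 4800, 5100, "+", "ncRNA", "nc1"),
    ]
    BACS = [("c", 800, 2000, "bac1")]

    def test_hand_computed_report(self):
        report = build_report(self.PLACEMENTS, self.GAPS, self.FEATURES, self.BACS)
        rows = {r.gap_id: r for r in report.rows}
        # gA: fully covered by k1 -> filled 400, closed, intron class, BAC-covered
        assert rows["gA"].filled_bp == 400 and rows["gA"].closed
        assert rows["gA"].genic_classes == ["intron"]
        assert rows["gA"].bac_covered
        # gB: k2 fills [5000,5200)=200, k3 fills [5190,5500)=310; union 500 -> closed
        assert rows["gB"].filled_bp == 500 and rows["gB"].closed
        assert rows["gB"].contig_ids == ["k2", "k3"]
        assert rows["gB"].genic_classes == ["ncRNA"]
        assert not rows["gB"].bac_covered
        # gC: k4 fills 100 of 300 -> not closed, intergenic
        assert rows["gC"].filled_bp == 100 and not rows["gC"].closed
        assert rows["gC"].genic_classes == []
        # aggregates
        assert report.n_gap_contigs == 4
        assert report.n_gaps_closed == 2
        assert report.total_filled_bp == 1000
        assert report.n_genic_gaps == 2
        assert report.n_genic_gap_contigs == 3  # k1 (gA), k2, k3 (gB)
        assert report.n_novel_no_bac_contigs == 3  # k2, k3, k4
        assert report.n_novel_no_bac_gaps == 2  # gB, gC

    def test_no_bac_file_all_novel(self):
        report = build_report(self.PLACEMENTS, self.GAPS, self.FEATURES, None)
        assert report.n_novel_no_bac_contigs == 4
        assert all(not r.bac_covered for r in report.rows if r.contig_ids)

    def test_contig_overlapping_two_gaps_counted_once(self):
        gaps = [GapInterval("c", 1000, 1200, "g1"), GapInterval("c", 1500, 1700, "g2")]
        report = build_report([("c", 900, 1800, "k1")], gaps, [], None)
        assert report.n_gap_contigs == 1
        assert {r.gap_id for r in report.rows if r.contig_ids} == {"g1", "g2"}
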