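"""Synthetic-data generator: construction invariants and determinism."""

import re

import numpy as np
import pytest

from novelmine import io, simulate
from tests.conftest import small_config


def scan_n_runs(seq: str) -> list[tuple[int, int]]:
    """Naive character-scan oracle for maximal N-runs."""
    runs = []
    start = None
    for i, ch in enumerate(seq + "x"):
        if ch in "Nn":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    return runs


class TestBuildReference:
    def test_gap_records_equal_maximal_n_runs(self, small_sim):
        cfg, ref, _donor, _truth = small_sim
        for chrom, seq in ref.sequences.items():
            expected = scan_n_runs(seq)
            emitted = [(s, e) for c, s, e in ref.gaps if c == chrom]
            assert sorted(emitted) == expected
        assert len(ref.gaps) == cfg.n_gaps

    def test_gap_lengths_within_range(self, small_sim):
        cfg, ref, _donor, _truth = small_sim
        lo, hi = cfg.gap_length_range
        for _c, s, e in ref.gaps:
            assert lo <= e - s <= hi

    def test_gaps_spaced_from_ends_and_each_other(self, small_sim):
        cfg, ref, _d, _t = small_sim
        margin = 2 * cfg.insert_mean
        by_chrom: dict = {}
        for c, s, e in ref.gaps:
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            L = len(ref.sequences[c])
            ivs.sort()
            for i, (s, e) in enumerate(ivs):
                assert s >= margin and e <= L - margin
                if i:
                    assert s - ivs[i - 1][1] >= margin

    def test_no_gaps_means_no_n(self):
        cfg = small_config(n_gaps=0, n_novel_at_gap=0)
        ref = simulate.build_reference(cfg)
        assert all("N" not in s for s in ref.sequences.values())
        assert ref.gaps == []

    def test_some_gaps_genic_some_not(self, small_sim):
        from novelmine import gaps as gaps_mod

        _cfg, ref, _d, _t = small_sim
        gap_list = [
            gaps_mod.GapInterval(c, s, e, f"gap{i}") for i, (c, s, e) in enumerate(ref.gaps)
        ]
        genic = gaps_mod.classify_genic(gap_list, ref.features)
        flags = [genic[g.gap_id]["genic"] for g in gap_list]
        assert any(flags) and not all(flags)

    def test_gene_models_have_exons_and_utrs(self, small_sim):
        _cfg, ref, _d, _t = small_sim
        types = {f.ftype for f in ref.features}
        assert {"gene", "exon", "intron", "five_prime_UTR", "three_prime_UTR"} <= types
        by_gene: dict = {}
        for f in ref.features:
            by_gene.setdefault(f.gene_id, []).append(f)
        for gid, feats in by_gene.items():
            kinds = {f.ftype for f in feats}
            if "ncRNA" in kinds:
                continue
            assert sum(1 for f in feats if f.ftype == "exon") >= 2, gid

    def test_infeasible_config_raises(self):
        with pytest.raises(simulate.SimulationError):
            simulate.build_reference(
                small_config(genome_length=5_000, n_gaps=4, gap_length_range=(800, 900))
            )

    def test_deterministic(self):
        a = simulate.build_reference(small_config())
        b = simulate.build_reference(small_config())
        assert a.sequences == b.sequences
        assert a.gaps == b.gaps


class TestBuildDonor:
    def test_reconstruction_oracle(self):
        """apply(truth, reference) reproduces the donor exactly (snp_rate=0)."""
        cfg = small_config(snp_rate=0.0)
        ref = simulate.build_reference(cfg)
        donor, truth = simulate.build_donor(ref, cfg)
        assert simulate.reconstruct_donor(ref, truth) == donor

    def test_no_novelty_no_snps_donor_equals_reference(self):
        cfg = small_config(n_novel_at_gap=0, n_novel_nongap=0, snp_rate=0.0)
        ref = simulate.build_reference(cfg)
        donor, truth = simulate.build_donor(ref, cfg)
        assert donor == ref.sequences
        assert truth == []

    def test_gap_fill_coordinates(self, small_sim):
        cfg, ref, donor, truth = small_sim
        fills = [t for t in truth if t.kind == "gap_fill"]
        assert len(fills) == cfg.n_novel_at_gap
        gap_set = {(c, s, e) for c, s, e in ref.gaps}
        for t in fills:
            assert (t.chrom, t.ref_start, t.ref_end) in gap_set
            assert t.length == t.ref_end - t.ref_start
            segment = donor[t.chrom][t.donor_start : t.donor_end]
            assert segment == t.sequence
            assert "N" not in segment

    def test_nongap_insertions_are_points_away_from_gaps(self, small_sim):
        cfg, ref, donor, truth = small_sim
        for t in truth:
            if t.kind != "nongap_insertion":
                continue
            assert t.ref_start == t.ref_end
            assert donor[t.chrom][t.donor_start : t.donor_end] == t.sequence
            for c, s, e in ref.gaps:
                if c == t.chrom:
                    assert not (s - cfg.insert_mean < t.ref_start < e + cfg.insert_mean)

    def test_truth_segments_do_not_overlap(self, small_sim):
        _cfg, _ref, _donor, truth = small_sim
        by_chrom: dict = {}
        for t in truth:
            by_chrom.setdefault(t.chrom, []).append((t.donor_start, t.donor_end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_config(
            base_error_rate=0.0, low_qual_tail_fraction=0.0, snp_rate=0.0, coverage=2.0
        )
        ref = simulate.build_reference(cfg)
        donor, _ = simulate.build_donor(ref, cfg)
        pairs = simulate.simulate_reads(donor, cfg, "S1", 5)
        for r1, r2 in pairs[:500]:
            _s, chrom, s, e = simulate.fragment_coords_from_name(r1.name)
            assert donor[chrom][s : s + cfg.read_length] == r1.sequence
            assert donor[chrom][e - cfg.read_length : e] == io.revcomp(r2.sequence)

    def test_pair_count_matches_coverage_formula(self, small_sim):
        cfg, _ref, donor, _truth = small_sim
        pairs = simulate.simulate_reads(donor, cfg, "S1", 5)
        total = sum(len(s) for s in donor.values())
        expected = cfg.coverage * total / (2 * cfg.read_length)
        assert abs(len(pairs) - expected) <= 0.01 * expected

    def test_no_fragment_overlaps_an_n_run(self, small_sim):
        cfg, _ref, donor, _truth = small_sim
        pairs = simulate.simulate_reads(donor, cfg, "S1", 5)
        for r1, _r2 in pairs[:2000]:
            _s, chrom, s, e = simulate.fragment_coords_from_name(r1.name)
            assert "N" not in donor[chrom][s:e]

    def test_deterministic_and_seed_sensitive(self, small_sim):
        cfg, _ref, donor, _truth = small_sim
        a = simulate.simulate_reads(donor, cfg, "S1", 5)
        b = simulate.simulate_reads(donor, cfg, "S1", 5)
        c = simulate.simulate_reads(donor, cfg, "S1", 6)
        assert a == b
        assert a != c

    def test_zero_coverage_rejected(self, small_sim):
        cfg, _ref, donor, _truth = small_sim
        import dataclasses

        bad = dataclasses.replace(cfg, coverage=0.0)
        with pytest.raises(simulate.SimulationError):
            simulate.simulate_reads(donor, bad, "S1", 5)


class TestDatasetFiles:
    def test_dataset_round_trip_and_determinism(self, tmp_path):
        cfg = small_config(coverage=1.0, n_samples=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate.simulate_dataset(cfg, str(d1))
        simulate.simulate_dataset(cfg, str(d2))
        for name in ("reference.fa", "donor.fa", "gaps.bed", "genes.gff3", "truth.tsv", "S1_1.fastq"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
        ref = io.read_fasta(str(d1 / "reference.fa"))
        bed = io.read_bed(str(d1 / "gaps.bed"))
        for chrom, s, e, _gid in bed:
            assert set(ref[chrom][s:e]) == {"N"}
        feats = io.read_gff3(str(d1 / "genes.gff3"))
        assert {f.ftype for f in feats} >= {"exon", "intron"}
        truth = simulate.load_truth(str(d1 / "truth.tsv"))
        assert all(t.kind in ("gap_fill", "nongap_insertion") for t in truth)

    def test_config_invariants_enforced(self):
        with pytest.raises(simulate.SimulationError):
            simulate.SimulationConfig(read_length=40)
        with pytest.raises(simulate.SimulationError):
            simulate.SimulationConfig(insert_mean=90, read_length=100)
        with pytest.raises(simulate.SimulationError):
            simulate.SimulationConfig(n_gaps=2, n_novel_at_gap=3)
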