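"""Synthetic genomes, donors with planted novel sequence, and paired reads.

The generator emulates the data a resequencing study of a non-reference
individual produces: a reference genome whose assembly gaps are runs of N,
gene models over it, a donor genome that (i) restores sequence inside some
gap loci (``gap_fill``), (ii) carries individual- or group-specific novel
insertions at non-gap loci (``nongap_insertion``) and (iii) differs by SNPs
elsewhere, plus Illumina-like 100 bp paired-end reads with a ~290 bp insert.
A machine-readable truth table records every planted segment so that each
downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np

from . import io
from .io import Feature

PHRED_GOOD = 37
PHRED_BAD = 2


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised (never silently truncated)."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the standard study conditions used throughout the test
    suite: a 2 Mb single-chromosome reference with 10 gaps of 300-800 bp,
    five of which are restored in the donor, five extra novel insertions of
    1-3 kb at non-gap loci, three samples sequenced to 10x with 100 bp pairs
    at 290 +/- 30 bp insert and 0.2% per-base error.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    n_gaps: int = 10
    gap_length_range: tuple[int, int] = (300, 800)
    n_novel_at_gap: int = 5
    n_novel_nongap: int = 5
    novel_length_range: tuple[int, int] = (1000, 3000)
    read_length: int = 100
    insert_mean: int = 290
    insert_sd: float = 30.0
    coverage: float = 10.0
    base_error_rate: float = 0.002
    n_genes: int = 20
    snp_rate: float = 0.001
    n_samples: int = 3
    # quality model: constant phred 37 with a low-quality tail on a fraction
    # of reads, so the trimming stage has real work to do
    low_qual_tail_fraction: float = 0.1
    tail_max_length: int = 30
    tail_error_rate: float = 0.1
    # fraction of gaps covered by a simulated BAC clone insert
    bac_gap_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise SimulationError("read_length must be >= 50")
        if self.insert_mean < self.read_length:
            raise SimulationError("insert_mean must be >= read_length")
        for name in ("n_gaps", "n_novel_at_gap", "n_novel_nongap", "n_genes", "n_samples"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        lo, hi = self.gap_length_range
        if not (0 < lo <= hi):
            raise SimulationError("gap_length_range must be a positive (lo, hi) pair")
        lo, hi = self.novel_length_range
        if not (0 < lo <= hi):
            raise SimulationError("novel_length_range must be a positive (lo, hi) pair")
        if self.n_novel_at_gap > self.n_gaps:
            raise SimulationError("n_novel_at_gap cannot exceed n_gaps")
        if self.n_chromosomes < 1:
            raise SimulationError("n_chromosomes must be >= 1")

    def chrom_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        out = {}
        for i in range(self.n_chromosomes):
            extra = self.genome_length % self.n_chromosomes if i == 0 else 0
            out[f"chr{i + 1}"] = base + extra
        return out


@dataclasses.dataclass
class TruthRecord:
    """Ground truth for one planted novel segment."""

    novel_id: str
    kind: str  # 'gap_fill' | 'nongap_insertion'
    chrom: str
    ref_start: int
    ref_end: int  # == ref_start for nongap_insertion (a point)
    donor_start: int
    donor_end: int
    length: int
    sequence: str


@dataclasses.dataclass
class Reference:
    sequences: dict[str, str]
    gaps: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    features: list[Feature]
    bacs: list[tuple[str, int, int, str]]


# ---------------------------------------------------------------------------
# reference


def _place_intervals(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: Sequence[int],
    margin: int,
    min_separation: int,
    max_tries: int = 2000,
) -> list[int]:
    """Place non-overlapping intervals, >= margin from ends, separated by
    >= min_separation.  Raises SimulationError when infeasible."""
    need = sum(lengths) + (len(lengths) - 1) * min_separation + 2 * margin
    if lengths and need > chrom_len:
        raise SimulationError(
            f"cannot place {len(lengths)} intervals totalling {sum(lengths)} bp "
            f"in a {chrom_len} bp chromosome with margin {margin}"
        )
    for _ in range(max_tries):
        starts = np.sort(rng.integers(margin, chrom_len - margin, size=len(lengths)))
        ok = True
        for i in range(len(lengths)):
            if starts[i] + lengths[i] > chrom_len - margin:
                ok = False
                break
            if i and starts[i] < starts[i - 1] + lengths[i - 1] + min_separation:
                ok = False
                break
        if ok:
            return [int(s) for s in starts]
    raise SimulationError("failed to place intervals after bounded retries")


def _make_gene_features(
    chrom: str, start: int, strand: str, exon_lens: list[int], intron_lens: list[int], gene_id: str
) -> list[Feature]:
    """Lay out a multi-exon gene; terminal exons carry 50 bp UTRs."""
    feats: list[Feature] = []
    pos = start
    blocks: list[tuple[str, int, int]] = []
    for i, elen in enumerate(exon_lens):
        blocks.append(("exon", pos, pos + elen))
        pos += elen
        if i < len(intron_lens):
            blocks.append(("intron", pos, pos + intron_lens[i]))
            pos += intron_lens[i]
    end = pos
    feats.append(Feature(chrom, start, end, strand, "gene", gene_id))
    for ftype, s, e in blocks:
        feats.append(Feature(chrom, s, e, strand, ftype, gene_id))
    # UTRs: 50 bp at the outer edge of each terminal exon
    utr = min(50, exon_lens[0] - 10, exon_lens[-1] - 10)
    if utr > 0:
        left = Feature(chrom, start, start + utr, strand, "", gene_id)
        right = Feature(chrom, end - utr, end, strand, "", gene_id)
        if strand == "+":
            left.ftype, right.ftype = "five_prime_UTR", "three_prime_UTR"
        else:
            left.ftype, right.ftype = "three_prime_UTR", "five_prime_UTR"
        feats += [left, right]
    return feats


def build_reference(config: SimulationConfig) -> Reference:
    """Generate the reference: random sequence, N-run gaps, gene models.

    Gaps are placed >= 2 * insert_mean from sequence ends and from each
    other.  Alternating gaps are made genic by constructing a gene around
    them so the gap falls in an intron, an exon, or an ncRNA (cycling
    through the three), leaving the remaining gaps intergenic.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom_lengths = config.chrom_lengths()
    margin = 2 * config.insert_mean
    # leave room for the +/- ~700 bp gene scaffold built around genic gaps
    separation = max(margin, 2000)

    sequences: dict[str, str] = {}
    gaps: list[tuple[str, int, int]] = []
    features: list[Feature] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    # distribute gaps across chromosomes proportionally to length
    chroms = list(chrom_lengths)
    gap_chrom = [chroms[i % len(chroms)] for i in range(config.n_gaps)]
    gap_lens = rng.integers(
        config.gap_length_range[0], config.gap_length_range[1] + 1, size=config.n_gaps
    )

    gene_counter = 0
    for chrom, length in chrom_lengths.items():
        seq = np.frombuffer(io.random_dna(rng, length).encode(), dtype=np.uint8).copy()
        idx = [i for i in range(config.n_gaps) if gap_chrom[i] == chrom]
        lens = [int(gap_lens[i]) for i in idx]
        starts = _place_intervals(rng, length, lens, margin, separation) if lens else []
        for gi, (s, L) in zip(idx, zip(starts, lens)):
            seq[s : s + L] = ord("N")
            gaps.append((chrom, s, s + L))
            occupied[chrom].append((s - 800, s + L + 800))
            # alternate genic / intergenic gaps; cycle the genic class
            if gi % 2 == 0:
                gene_counter += 1
                gid = f"gene{gene_counter}"
                klass = ("intron", "exon", "ncRNA")[(gi // 2) % 3]
                gs, ge = s, s + L
                if klass == "intron":
                    feats = [
                        Feature(chrom, gs - 500, ge + 500, "+", "gene", gid),
                        Feature(chrom, gs - 500, gs - 350, "+", "exon", gid),
                        Feature(chrom, gs - 500, gs - 450, "+", "five_prime_UTR", gid),
                        Feature(chrom, gs - 350, ge + 350, "+", "intron", gid),
                        Feature(chrom, ge + 350, ge + 500, "+", "exon", gid),
                        Feature(chrom, ge + 450, ge + 500, "+", "three_prime_UTR", gid),
                    ]
                elif klass == "exon":
                    feats = [
                        Feature(chrom, gs - 600, ge + 100, "+", "gene", gid),
                        Feature(chrom, gs - 600, gs - 450, "+", "exon", gid),
                        Feature(chrom, gs - 600, gs - 550, "+", "five_prime_UTR", gid),
                        Feature(chrom, gs - 450, gs - 100, "+", "intron", gid),
                        Feature(chrom, gs - 100, ge + 100, "+", "exon", gid),
                    ]
                else:  # ncRNA
                    feats = [Feature(chrom, gs - 200, ge + 200, "+", "ncRNA", gid)]
                features += feats
        sequences[chrom] = seq.tobytes().decode()

    # remaining genes placed in free space
    n_left = max(0, config.n_genes - gene_counter)
    for _ in range(n_left):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = chrom_lengths[chrom]
        n_exons = int(rng.integers(2, 6))
        exon_lens = [int(x) for x in rng.integers(120, 300, size=n_exons)]
        intron_lens = [int(x) for x in rng.integers(200, 800, size=n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        placed = False
        for _try in range(200):
            start = int(rng.integers(margin, length - margin - span))
            if all(
                start + span <= s or start >= e
                for s, e in occupied[chrom]
            ):
                placed = True
                break
        if not placed:
            continue
        gene_counter += 1
        gid = f"gene{gene_counter}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if rng.integers(0, 4) == 0:
            features.append(Feature(chrom, start, start + min(span, 800), strand, "ncRNA", gid))
            occupied[chrom].append((start - 200, start + min(span, 800) + 200))
        else:
            features += _make_gene_features(chrom, start, strand, exon_lens, intron_lens, gid)
            occupied[chrom].append((start - 200, start + span + 200))

    gaps.sort()
    # simulated BAC clone inserts over a fraction of the gaps
    bacs: list[tuple[str, int, int, str]] = []
    n_bac = int(round(config.bac_gap_fraction * len(gaps)))
    for i, (chrom, s, e) in enumerate(gaps[:n_bac]):
        pad_l = int(rng.integers(2000, 6000))
        pad_r = int(rng.integers(2000, 6000))
        bacs.append((chrom, max(0, s - pad_l), min(chrom_lengths[chrom], e + pad_r), f"bac{i + 1}"))

    return Reference(sequences=sequences, gaps=gaps, features=features, bacs=bacs)


# ---------------------------------------------------------------------------
# donor


def build_donor(
    reference: Reference, config: SimulationConfig
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant novel segments and SNPs into a copy of the reference.

    gap_fill segments replace a gap's N-run with random sequence of the same
    length; nongap insertions are inserted at points >= insert_mean away
    from any gap.  SNPs are applied outside novel segments at ``snp_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    chrom_lengths = {c: len(s) for c, s in reference.sequences.items()}

    # choose which gaps are filled (deterministic under the seed)
    gap_idx = rng.choice(len(reference.gaps), size=config.n_novel_at_gap, replace=False)
    filled_gaps = sorted(int(i) for i in gap_idx)

    events: dict[str, list[tuple[int, int, str, str]]] = {c: [] for c in chrom_lengths}
    truth: list[TruthRecord] = []
    novel_n = 0
    for gi in filled_gaps:
        chrom, s, e = reference.gaps[gi]
        novel_n += 1
        seq = io.random_dna(rng, e - s)
        events[chrom].append((s, e, seq, f"novel{novel_n}|gap_fill"))

    # nongap insertion points: away from gaps, ends, and each other
    margin = 2 * config.insert_mean
    min_gap_dist = config.insert_mean
    placed_points: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for _ in range(config.n_novel_nongap):
        length = int(
            rng.integers(config.novel_length_range[0], config.novel_length_range[1] + 1)
        )
        ok = False
        for _try in range(1000):
            chrom = list(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
            p = int(rng.integers(margin, chrom_lengths[chrom] - margin))
            near_gap = any(
                c == chrom and s - min_gap_dist < p < e + min_gap_dist
                for c, s, e in reference.gaps
            )
            near_other = any(abs(p - q) < 2 * config.insert_mean for q in placed_points[chrom])
            if not near_gap and not near_other:
                ok = True
                break
        if not ok:
            raise SimulationError("could not place a nongap insertion after bounded retries")
        placed_points[chrom].append(p)
        novel_n += 1
        seq = io.random_dna(rng, length)
        events[chrom].append((p, p, seq, f"novel{novel_n}|nongap_insertion"))

    donor: dict[str, str] = {}
    for chrom, ref_seq in reference.sequences.items():
        arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
        # SNPs outside novel segments and outside gaps
        if config.snp_rate > 0:
            n_snp = rng.binomial(len(arr), config.snp_rate)
            pos = rng.choice(len(arr), size=n_snp, replace=False)
            forbidden = np.zeros(len(arr), dtype=bool)
            for c, s, e in reference.gaps:
                if c == chrom:
                    forbidden[s:e] = True
            for s, e, _seq, _nid in events[chrom]:
                lo, hi = max(0, s - 1), min(len(arr), e + 1)
                forbidden[lo:hi] = True
            pos = pos[~forbidden[pos]]
            if len(pos):
                shift = rng.integers(1, 4, size=len(pos))
                codes = io._CODE[arr[pos]].astype(np.int64)
                arr[pos] = io._BASES[(codes + shift) % 4]
        snpped = arr.tobytes().decode()

        parts: list[str] = []
        cursor = 0
        offset = 0
        for s, e, seq, nid in sorted(events[chrom]):
            parts.append(snpped[cursor:s])
            offset += s - cursor
            d_start = offset
            parts.append(seq)
            offset += len(seq)
            name, kind = nid.split("|")
            truth.append(
                TruthRecord(
                    novel_id=name,
                    kind=kind,
                    chrom=chrom,
                    ref_start=s,
                    ref_end=e,
                    donor_start=d_start,
                    donor_end=offset,
                    length=len(seq),
                    sequence=seq,
                )
            )
            cursor = e
        parts.append(snpped[cursor:])
        donor[chrom] = "".join(parts)

    truth.sort(key=lambda t: (t.chrom, t.ref_start))
    return donor, truth


def reconstruct_donor(
    reference: Reference, truth: list[TruthRecord]
) -> dict[str, str]:
    """Independently rebuild the donor from reference + truth (snp_rate=0).

    Used as the truth-consistency oracle: apply(truth, reference) == donor.
    """
    donor: dict[str, str] = {}
    for chrom, ref_seq in reference.sequences.items():
        recs = sorted(
            (t for t in truth if t.chrom == chrom), key=lambda t: t.ref_start
        )
        parts = []
        cursor = 0
        for t in recs:
            parts.append(ref_seq[cursor : t.ref_start])
            parts.append(t.sequence)
            cursor = t.ref_end
        parts.append(ref_seq[cursor:])
        donor[chrom] = "".join(parts)
    return donor


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    donor: dict[str, str],
    config: SimulationConfig,
    sample_id: str,
    sample_seed: int,
) -> list[tuple[io.FastqRecord, io.FastqRecord]]:
    """Simulate paired-end reads from the donor.

    Fragment starts are uniform; insert length ~ Normal(insert_mean,
    insert_sd) truncated to >= read_length; mate1 is the fragment's 5' read
    and mate2 the reverse complement of its 3' end.  Fragments overlapping an
    N run (an unfilled gap) are redrawn: a real sequencer reads molecules,
    and no molecule consists of Ns.  Read names encode the true fragment
    coordinates (sample:index:chrom:start:end).
    """
    if config.coverage <= 0:
        raise SimulationError("coverage must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([sample_seed, 303]))
    rl = config.read_length
    chroms = list(donor)
    lens = np.array([len(donor[c]) for c in chroms], dtype=np.int64)
    for c in chroms:
        if len(donor[c]) <= config.insert_mean + 4 * config.insert_sd:
            raise SimulationError(f"{c}: donor too short for the insert distribution")
    total = int(lens.sum())
    n_pairs = int(round(config.coverage * total / (2 * rl)))

    # N masks for fragment rejection
    has_n = {}
    for c in chroms:
        mask = np.frombuffer(donor[c].encode(), dtype=np.uint8) == ord("N")
        has_n[c] = np.concatenate([[0], np.cumsum(mask)])

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lens / total)
    frag = np.maximum(
        rng.normal(config.insert_mean, config.insert_sd, size=n_pairs).round().astype(np.int64),
        rl,
    )
    starts = np.empty(n_pairs, dtype=np.int64)
    for ci in range(len(chroms)):
        sel = chrom_idx == ci
        hi = lens[ci] - frag[sel] + 1
        starts[sel] = (rng.random(int(sel.sum())) * hi).astype(np.int64)
    # reject fragments containing N (bounded redraw)
    for _round in range(200):
        bad = np.zeros(n_pairs, dtype=bool)
        for ci, c in enumerate(chroms):
            sel = chrom_idx == ci
            cs = has_n[c]
            s, e = starts[sel], starts[sel] + frag[sel]
            bad[sel] = (cs[e] - cs[s]) > 0
        if not bad.any():
            break
        n_bad = int(bad.sum())
        for ci in range(len(chroms)):
            sel = bad & (chrom_idx == ci)
            if sel.any():
                hi = lens[ci] - frag[sel] + 1
                starts[sel] = (rng.random(int(sel.sum())) * hi).astype(np.int64)
        del n_bad
    else:
        raise SimulationError("could not draw N-free fragments (genome mostly gaps?)")

    # low-quality tails
    tail_sel = rng.random(2 * n_pairs) < config.low_qual_tail_fraction
    tail_len = rng.integers(1, config.tail_max_length + 1, size=2 * n_pairs)
    n_err = rng.binomial(rl, config.base_error_rate, size=2 * n_pairs)

    good_q = chr(PHRED_GOOD + 33)
    bad_q = chr(PHRED_BAD + 33)

    pairs: list[tuple[io.FastqRecord, io.FastqRecord]] = []
    for i in range(n_pairs):
        c = chroms[int(chrom_idx[i])]
        s = int(starts[i])
        f = int(frag[i])
        name = f"{sample_id}:{i}:{c}:{s}:{s + f}"
        seq1 = donor[c][s : s + rl]
        seq2 = io.revcomp(donor[c][s + f - rl : s + f])
        out = []
        for m, seq in enumerate((seq1, seq2)):
            j = 2 * i + m
            qual = good_q * rl
            tl = 0
            if tail_sel[j]:
                tl = int(tail_len[j])
                qual = good_q * (rl - tl) + bad_q * tl
            k = int(n_err[j])
            if tl:
                k += rng.binomial(tl, config.tail_error_rate)
            if k:
                arr = bytearray(seq.encode())
                pos = rng.integers(0, rl, size=k)
                subs = rng.integers(1, 4, size=k)
                for p, sh in zip(pos, subs):
                    code = io._CODE[arr[p]]
                    if code < 4:
                        arr[p] = io._BASES[(int(code) + int(sh)) % 4]
                seq = arr.decode()
            out.append(io.FastqRecord(name, seq, qual))
        pairs.append((out[0], out[1]))
    return pairs


# ---------------------------------------------------------------------------
# dataset writer


def simulate_dataset(config: SimulationConfig, outdir: str) -> dict:
    """Generate and write the full dataset; returns the manifest dict.

    Files: reference.fa, donor.fa, gaps.bed, genes.gff3, genes.bed (BED12),
    bacs.bed, truth.tsv, {sample}_1.fastq / {sample}_2.fastq per sample,
    config.json, manifest.json.
    """
    import pandas as pd

    io.ensure_dir(outdir)
    ref = build_reference(config)
    donor, truth = build_donor(ref, config)

    io.write_fasta(os.path.join(outdir, "reference.fa"), sorted(ref.sequences.items()))
    io.write_fasta(os.path.join(outdir, "donor.fa"), sorted(donor.items()))
    io.write_bed(
        os.path.join(outdir, "gaps.bed"),
        [(c, s, e, f"gap{i + 1}") for i, (c, s, e) in enumerate(ref.gaps)],
    )
    io.write_gff3(os.path.join(outdir, "genes.gff3"), ref.features)
    io.write_bed(os.path.join(outdir, "genes.bed"), io.features_to_bed12(ref.features))
    io.write_bed(os.path.join(outdir, "bacs.bed"), ref.bacs)
    truth_cols = [f.name for f in dataclasses.fields(TruthRecord)]
    pd.DataFrame([dataclasses.asdict(t) for t in truth], columns=truth_cols).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )

    samples = []
    ss = np.random.SeedSequence([config.seed, 404])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_samples)]
    for i in range(config.n_samples):
        sid = f"S{i + 1}"
        pairs = simulate_reads(donor, config, sid, child_seeds[i])
        p1 = os.path.join(outdir, f"{sid}_1.fastq")
        p2 = os.path.join(outdir, f"{sid}_2.fastq")
        io.write_fastq_pairs(p1, p2, pairs)
        samples.append({"sample_id": sid, "fastq1": p1, "fastq2": p2, "group": "G1"})

    manifest = {
        "reference": os.path.join(outdir, "reference.fa"),
        "donor": os.path.join(outdir, "donor.fa"),
        "gaps": os.path.join(outdir, "gaps.bed"),
        "genes_gff3": os.path.join(outdir, "genes.gff3"),
        "genes_bed": os.path.join(outdir, "genes.bed"),
        "bacs": os.path.join(outdir, "bacs.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "samples": samples,
    }
    io.write_json(os.path.join(outdir, "config.json"), dataclasses.asdict(config))
    io.write_json(os.path.join(outdir, "manifest.json"), manifest)
    return manifest


def load_truth(path: str) -> list[TruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    return [TruthRecord(**row) for row in df.to_dict("records")]


def fragment_coords_from_name(name: str) -> tuple[str, str, int, int]:
    """Parse (sample, chrom, start, end) out of a simulated read name."""
    sample, _idx, chrom, s, e = name.split(":")
    return sample, chrom, int(s), int(e)
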