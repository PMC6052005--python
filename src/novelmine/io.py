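"""File-format helpers and shared record types.

Everything downstream speaks a small set of plain formats: FASTA/FASTQ
(phred+33), a SAM subset (flags, POS, MAPQ, CIGAR), 3-column and 12-column
BED, GFF3, and tab-separated report tables.  All coordinates are 0-based
half-open internally; GFF3 is converted (1-based, closed) at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Iterable, Iterator

import numpy as np
import pysam

# ---------------------------------------------------------------------------
# sequence primitives

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# base -> 2-bit code; N and anything unexpected -> 4 (never matches)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def revcomp(seq: str) -> str:
    """Reverse complement (N-aware, case-preserving for ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = _BASES[codes[ok]]
    return out.tobytes().decode()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def qual_to_phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33


def phred_to_qual(phred: np.ndarray) -> str:
    return (np.asarray(phred, dtype=np.uint8) + 33).tobytes().decode()


# ---------------------------------------------------------------------------
# records


@dataclasses.dataclass
class FastqRecord:
    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class AlignmentRecord:
    """One mate's placement on a target (genome or contig).

    ``target_start`` is 0-based; ``mapq`` is the 3-valued surrogate
    {0, 30, 60} produced by the micro-mapper (or whatever an external SAM
    carries).  ``n_candidate_loci`` counts distinct loci that met the
    identity threshold.
    """

    query_id: str
    target_id: str
    target_start: int
    strand: str  # '+' or '-'
    cigar: str
    mapq: int
    n_candidate_loci: int = 1
    query_length: int = 0
    identity: float = 1.0
    score: int = 0


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            seqs[entry.name] = entry.sequence
    return seqs


def read_fasta_descriptions(path: str) -> dict[str, str]:
    desc: dict[str, str] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            desc[entry.name] = entry.comment or ""
    return desc


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> Iterator[FastqRecord]:
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield FastqRecord(entry.name, entry.sequence, entry.quality)


def read_fastq_pairs(path1: str, path2: str) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    with pysam.FastxFile(path1) as fh1, pysam.FastxFile(path2) as fh2:
        for e1, e2 in zip(fh1, fh2, strict=True):
            if e1.name != e2.name:
                raise ValueError(f"FASTQ pair out of sync: {e1.name} vs {e2.name}")
            yield (
                FastqRecord(e1.name, e1.sequence, e1.quality),
                FastqRecord(e2.name, e2.sequence, e2.quality),
            )


def write_fastq(path: str, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def write_fastq_pairs(
    path1: str, path2: str, pairs: Iterable[tuple[FastqRecord, FastqRecord]]
) -> None:
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for r1, r2 in pairs:
            fh1.write(f"@{r1.name}\n{r1.sequence}\n+\n{r1.quality}\n")
            fh2.write(f"@{r2.name}\n{r2.sequence}\n+\n{r2.quality}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[tuple]:
    """Read BED rows as tuples (chrom, start, end, *rest); skips blank lines."""
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start: {line!r}")
            rows.append((parts[0], start, end, *parts[3:]))
    return rows


def write_bed(path: str, rows: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# GFF3 (1-based closed on disk, 0-based half-open in memory)


@dataclasses.dataclass
class Feature:
    """A genomic feature interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    gene_id: str


def write_gff3(path: str, features: Iterable[Feature], source: str = "novelmine") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = f"ID={f.ftype}:{f.gene_id}:{i};Parent={f.gene_id}"
            if f.ftype in ("gene", "ncRNA"):
                attrs = f"ID={f.gene_id}"
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feats: list[Feature] = []
    for f in db.all_features():
        gid = f.attributes.get("Parent", f.attributes.get("ID", [f.id]))[0]
        feats.append(
            Feature(f.seqid, f.start - 1, f.end, f.strand or ".", f.featuretype, gid)
        )
    return feats


def features_to_bed12(features: list[Feature]) -> list[tuple]:
    """Collapse exon features per gene into BED12 rows (one row per gene)."""
    by_gene: dict[str, list[Feature]] = {}
    meta: dict[str, Feature] = {}
    for f in features:
        if f.ftype in ("gene", "ncRNA"):
            meta[f.gene_id] = f
        by_gene.setdefault(f.gene_id, []).append(f)
    rows = []
    for gid in sorted(meta):
        g = meta[gid]
        blocks = sorted(
            (f.start, f.end) for f in by_gene[gid] if f.ftype in ("exon", "ncRNA")
        )
        if not blocks:
            blocks = [(g.start, g.end)]
        sizes = ",".join(str(e - s) for s, e in blocks)
        starts = ",".join(str(s - g.start) for s, e in blocks)
        rows.append(
            (
                g.chrom,
                g.start,
                g.end,
                gid,
                0,
                g.strand,
                g.start,
                g.end,
                "0,0,0",
                len(blocks),
                sizes,
                starts,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# SAM subset

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def sam_header(target_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in target_lengths.items()],
        }
    )


def _segment(
    header: pysam.AlignmentHeader,
    name: str,
    read: FastqRecord | None,
    aln: AlignmentRecord | None,
    is_read1: bool,
    mate_aln: AlignmentRecord | None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    flag = _FLAG_PAIRED | (_FLAG_READ1 if is_read1 else _FLAG_READ2)
    if aln is None:
        flag |= _FLAG_UNMAPPED
    elif aln.strand == "-":
        flag |= _FLAG_REVERSE
    if mate_aln is None:
        flag |= _FLAG_MATE_UNMAPPED
    elif mate_aln.strand == "-":
        flag |= _FLAG_MATE_REVERSE
    seg.flag = flag
    if read is not None:
        seq = read.sequence if aln is None or aln.strand == "+" else revcomp(read.sequence)
        qual = read.quality if aln is None or aln.strand == "+" else read.quality[::-1]
        seg.query_sequence = seq
        seg.query_qualities = pysam.qualitystring_to_array(qual)
    if aln is not None:
        seg.reference_name = aln.target_id
        seg.reference_start = aln.target_start
        seg.mapping_quality = aln.mapq
        seg.cigarstring = aln.cigar or f"{len(read.sequence) if read else 0}M"
    elif mate_aln is not None:
        # SAM convention: unmapped mate placed at its mapped partner's locus
        seg.reference_name = mate_aln.target_id
        seg.reference_start = mate_aln.target_start
    return seg


def write_pair_sam(
    path: str,
    target_lengths: dict[str, int],
    rows: Iterable[
        tuple[str, FastqRecord | None, FastqRecord | None, AlignmentRecord | None, AlignmentRecord | None]
    ],
) -> None:
    """Write (pair_id, read1, read2, aln1, aln2) rows as a SAM subset."""
    header = sam_header(target_lengths)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for pair_id, r1, r2, a1, a2 in rows:
            out.write(_segment(header, pair_id, r1, a1, True, a2))
            out.write(_segment(header, pair_id, r2, a2, False, a1))


def read_pair_sam(
    path: str,
) -> Iterator[tuple[str, FastqRecord | None, FastqRecord | None, AlignmentRecord | None, AlignmentRecord | None]]:
    """Inverse of :func:`write_pair_sam` (best-effort for external SAM).

    Secondary/supplementary records are skipped; mates are matched by QNAME.
    """
    pending: dict[str, dict] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            slot = 1 if seg.is_read1 or not seg.is_read2 else 2
            read = None
            if seg.query_sequence:
                seq = seg.query_sequence
                qual = (
                    pysam.array_to_qualitystring(seg.query_qualities)
                    if seg.query_qualities is not None
                    else "I" * len(seq)
                )
                if not seg.is_unmapped and seg.is_reverse:
                    seq, qual = revcomp(seq), qual[::-1]
                read = FastqRecord(seg.query_name, seq, qual)
            aln = None
            if not seg.is_unmapped:
                aln = AlignmentRecord(
                    query_id=seg.query_name,
                    target_id=seg.reference_name,
                    target_start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=seg.cigarstring or "",
                    mapq=seg.mapping_quality,
                    query_length=seg.query_length or (len(read) if read else 0),
                )
            entry = pending.setdefault(seg.query_name, {})
            entry[slot] = (read, aln)
            if 1 in entry and 2 in entry:
                r1, a1 = entry[1]
                r2, a2 = entry[2]
                yield seg.query_name, r1, r2, a1, a2
                del pending[seg.query_name]
    for name, entry in pending.items():
        r1, a1 = entry.get(1, (None, None))
        r2, a2 = entry.get(2, (None, None))
        yield name, r1, r2, a1, a2


# ---------------------------------------------------------------------------
# misc


def write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
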