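"""Screening assembled contigs against the reference for novelty.

A contig already present in the reference at 100% identity and 100%
coverage (exact containment, either orientation) is KNOWN and removed from
the novel set; a contig with a high-identity but partial hit is PARTIAL and
retained; a contig with no qualifying hit at all is NOVEL.  Exact
containment is decided by literal string search (k-mer anchored in spirit,
but exactness makes alignment unnecessary); partial hits are measured with
the local aligner around seeded candidate loci.

Cross-sample support replays an outgroup read set (reads from the reference
individual) against the contigs: contigs representing reference errors or
gaps attract outgroup coverage, while group-specific novel sequence does
not.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from . import io, mapper
from .assembler import Contig


@dataclasses.dataclass
class NoveltyVerdict:
    contig_id: str
    status: str  # 'KNOWN' | 'PARTIAL' | 'NOVEL'
    best_identity: float
    best_coverage: float


def screen_against_reference(
    contigs: Sequence[Contig],
    reference: dict[str, str],
    index: mapper.KmerIndex | None = None,
    min_partial_identity: float = 0.9,
    min_partial_length: int = 50,
) -> list[NoveltyVerdict]:
    """Classify each contig as KNOWN / PARTIAL / NOVEL against the reference."""
    if index is None:
        index = mapper.KmerIndex(reference, k=mapper.DEFAULT_K)
    verdicts: list[NoveltyVerdict] = []
    for c in contigs:
        seq = c.sequence
        rc = io.revcomp(seq)
        known = any(seq in ref or rc in ref for ref in reference.values())
        if known:
            verdicts.append(NoveltyVerdict(c.contig_id, "KNOWN", 1.0, 1.0))
            continue
        best_id, best_cov = _best_partial_hit(seq, reference, index)
        if best_id >= min_partial_identity and best_cov * len(seq) >= min_partial_length:
            verdicts.append(NoveltyVerdict(c.contig_id, "PARTIAL", best_id, best_cov))
        else:
            verdicts.append(NoveltyVerdict(c.contig_id, "NOVEL", best_id, best_cov))
    return verdicts


def _best_partial_hit(
    seq: str, reference: dict[str, str], index: mapper.KmerIndex
) -> tuple[float, float]:
    """Best (identity, query coverage) of any local hit of seq on the reference."""
    k = index.k
    codes = io.encode(seq)
    hits: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for strand in "+-":
        qc = codes if strand == "+" else io.encode(io.revcomp(seq))
        kmers, valid = mapper._pack_kmers(qc, k)
        step = max(1, (len(seq) - k) // 40) if len(seq) > k else 1
        for p in range(0, len(kmers), step):
            if not valid[p]:
                continue
            for gpos in index.lookup(kmers[p])[:20]:
                target, local = index.resolve(int(gpos))
                hits.setdefault((target, strand), []).append(local - p)
    best_id, best_cov = 0.0, 0.0
    seen_windows: set[tuple[str, int]] = set()
    for (target, strand), diags in hits.items():
        for d in sorted(set(np.asarray(diags) // 500 * 500)):
            key = (target, int(d))
            if key in seen_windows:
                continue
            seen_windows.add(key)
            ref = reference[target]
            w0 = max(0, int(d) - 600)
            w1 = min(len(ref), int(d) + len(seq) + 1100)
            q = seq if strand == "+" else io.revcomp(seq)
            for aln in mapper.align_local(q, ref[w0:w1], min_score=30, max_n=2):
                if aln.identity > best_id or (
                    aln.identity == best_id and aln.coverage_of / len(seq) > best_cov
                ):
                    best_id = aln.identity
                    best_cov = aln.coverage_of / len(seq)
    return best_id, best_cov


def filter_novel(
    contigs: Sequence[Contig], verdicts: Sequence[NoveltyVerdict]
) -> list[Contig]:
    """Drop KNOWN contigs; PARTIAL and NOVEL are retained."""
    status = {v.contig_id: v.status for v in verdicts}
    return [c for c in contigs if status.get(c.contig_id) != "KNOWN"]


def cross_sample_support(
    contigs: Sequence[Contig],
    outgroup_reads: Iterable[io.FastqRecord | tuple[str, str]],
    min_mapq: int = 30,
    min_identity: float = 0.9,
) -> tuple[dict[str, float], float]:
    """Fraction of each contig covered by high-quality outgroup alignments.

    Returns (per-contig covered fraction, fraction of contigs with any
    qualifying alignment).  An empty outgroup yields all zeros.
    """
    seqs = {c.contig_id: c.sequence for c in contigs}
    if not seqs:
        return {}, 0.0
    cover = {cid: np.zeros(len(s), dtype=bool) for cid, s in seqs.items()}
    reads = list(outgroup_reads)
    if reads:
        index = mapper.KmerIndex(seqs, k=mapper.DEFAULT_K)
        alns = mapper.map_reads(reads, index, min_identity=min_identity)
        for aln in alns.values():
            if aln is None or aln.mapq < min_mapq:
                continue
            mask = cover[aln.target_id]
            mask[aln.target_start : aln.target_start + aln.query_length] = True
    fractions = {cid: float(m.mean()) for cid, m in cover.items()}
    any_hit = sum(1 for m in cover.values() if m.any())
    return fractions, any_hit / len(cover)
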