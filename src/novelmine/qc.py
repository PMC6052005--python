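"""Per-contig quality metrics: GC, triplet complexity, duplication.

DUST and entropy complexity are both computed from overlapping-triplet
statistics over the whole contig and reported on a 0-100 scale:

* DUST: 100 * sum_t c_t(c_t-1)/2 / (k(k-1)/2) over the k = L-2 triplet
  windows with counts c_t - higher means LOWER complexity (100 for a
  homopolymer, 0 when all triplets are distinct).
* Entropy: 100 * (-sum_t p_t ln p_t) / ln(min(k, 64)) - higher means HIGHER
  complexity (0 for a homopolymer, 100 when the observed triplets are
  equally frequent and distinct, k <= 64).  The log base cancels in the
  ratio, so natural log is used throughout.

A windowed mode (64-base windows, step 32, score = max over windows) is
available for parity with windowing QC tools; the whole-sequence mode is
the default because one score is reported per contig.

Thresholds dust > 7 or entropy < 70 mark a contig low-complexity; the flags
are report-only by default and filtering on them is opt-in.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from math import log
from typing import Iterable, Sequence

from . import io
from .assembler import Contig

DUST_FLAG_THRESHOLD = 7.0
ENTROPY_FLAG_THRESHOLD = 70.0


def _triplet_counts(sequence: str) -> tuple[Counter, int]:
    seq = sequence.upper()
    counts: Counter = Counter()
    k = 0
    for i in range(len(seq) - 2):
        t = seq[i : i + 3]
        if "N" in t:
            continue
        counts[t] += 1
        k += 1
    return counts, k


def gc_content(sequence: str) -> float | None:
    """GC percentage over A/C/G/T bases only; None for an all-N sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


def dust_score(sequence: str) -> float | None:
    """Triplet-repeat DUST score in [0, 100]; None when undefined (< 3 bp)."""
    if len(sequence) < 3:
        return None
    counts, k = _triplet_counts(sequence)
    if k < 2:
        return None
    rep = sum(c * (c - 1) / 2 for c in counts.values())
    return min(100.0, max(0.0, 100.0 * rep / (k * (k - 1) / 2)))


def entropy_score(sequence: str) -> float | None:
    """Normalised triplet Shannon entropy in [0, 100]; None when undefined."""
    if len(sequence) < 3:
        return None
    counts, k = _triplet_counts(sequence)
    if k < 1:
        return None
    if k == 1:
        return 0.0
    h = -sum((c / k) * log(c / k) for c in counts.values())
    return min(100.0, max(0.0, 100.0 * h / log(min(k, 64))))


def _windowed(metric, sequence: str, window: int = 64, step: int = 32) -> float | None:
    if len(sequence) <= window:
        return metric(sequence)
    vals = [
        metric(sequence[i : i + window])
        for i in range(0, len(sequence) - window + step, step)
    ]
    vals = [v for v in vals if v is not None]
    return max(vals) if vals else None


def dust_score_windowed(sequence: str, window: int = 64, step: int = 32) -> float | None:
    return _windowed(dust_score, sequence, window, step)


def entropy_score_windowed(sequence: str, window: int = 64, step: int = 32) -> float | None:
    return _windowed(entropy_score, sequence, window, step)


@dataclasses.dataclass
class ContigQC:
    contig_id: str
    length: int
    gc_percent: float | None
    dust: float | None
    entropy: float | None
    low_complexity: bool
    duplicate_of: str | None = None
    contaminant: bool = False


def dedup(contigs: Sequence[Contig]) -> tuple[list[Contig], dict[str, str]]:
    """Collapse exact sequence duplicates (including reverse complements).

    The representative kept for each duplicate group is the contig with the
    lexicographically smallest id, so the outcome is order-independent.
    Returns (kept contigs, removed_id -> kept_id map).
    """
    groups: dict[str, list[Contig]] = {}
    for c in contigs:
        key = min(c.sequence, io.revcomp(c.sequence))
        groups.setdefault(key, []).append(c)
    kept: list[Contig] = []
    removed: dict[str, str] = {}
    for group in groups.values():
        group.sort(key=lambda c: c.contig_id)
        kept.append(group[0])
        for c in group[1:]:
            removed[c.contig_id] = group[0].contig_id
    kept.sort(key=lambda c: c.contig_id)
    return kept, removed


def kmer_set(sequences: Iterable[str], k: int = 31) -> set[str]:
    """Canonical (strand-collapsed) k-mer set of contaminant sequences."""
    out: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            out.add(min(km, io.revcomp(km)))
    return out


def contaminant_screen(
    contigs: Sequence[Contig],
    contaminant_kmers: set[str],
    k: int = 31,
    min_fraction: float = 0.5,
) -> dict[str, bool]:
    """Flag contigs whose canonical k-mers hit the contaminant set.

    A contig is flagged iff at least ``min_fraction`` of its k-mers occur in
    the set.  An empty set passes everything (with a warning upstream).
    """
    flags: dict[str, bool] = {}
    for c in contigs:
        seq = c.sequence.upper()
        total = 0
        hit = 0
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            total += 1
            if min(km, io.revcomp(km)) in contaminant_kmers:
                hit += 1
        flags[c.contig_id] = bool(contaminant_kmers) and total > 0 and hit / total >= min_fraction
    return flags


def run_qc(
    contigs: Sequence[Contig],
    contaminant_kmers: set[str] | None = None,
    contaminant_k: int = 31,
    contaminant_min_fraction: float = 0.5,
    windowed: bool = False,
    drop_duplicates: bool = True,
    drop_low_complexity: bool = False,
    drop_contaminants: bool = True,
) -> tuple[list[Contig], list[ContigQC]]:
    """QC a contig set; returns (filtered contigs, per-contig QC rows)."""
    kept, removed = dedup(contigs) if drop_duplicates else (list(contigs), {})
    cont_flags: dict[str, bool] = {}
    if contaminant_kmers is not None:
        cont_flags = contaminant_screen(
            kept, contaminant_kmers, contaminant_k, contaminant_min_fraction
        )
    d_metric = dust_score_windowed if windowed else dust_score
    e_metric = entropy_score_windowed if windowed else entropy_score
    rows: list[ContigQC] = []
    out: list[Contig] = []
    for c in sorted(contigs, key=lambda c: c.contig_id):
        d = d_metric(c.sequence)
        e = e_metric(c.sequence)
        low = (d is not None and d > DUST_FLAG_THRESHOLD) or (
            e is not None and e < ENTROPY_FLAG_THRESHOLD
        )
        qc = ContigQC(
            contig_id=c.contig_id,
            length=len(c.sequence),
            gc_percent=gc_content(c.sequence),
            dust=d,
            entropy=e,
            low_complexity=low,
            duplicate_of=removed.get(c.contig_id),
            contaminant=cont_flags.get(c.contig_id, False),
        )
        rows.append(qc)
        if qc.duplicate_of is not None:
            continue
        if drop_contaminants and qc.contaminant:
            continue
        if drop_low_complexity and low:
            continue
        out.append(c)
    return out, rows
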