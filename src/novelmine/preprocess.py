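"""Quality trimming and mapped / one-end-anchored / unmapped pair triage.

Trimming follows sliding-window semantics: leading and trailing bases at or
below a hard phred floor are clipped, then the read is scanned 5'->3' in
windows of ``window`` bases and cut at the start of the first window whose
mean phred falls below ``window_min_mean_phred``; anything shorter than
``min_length`` afterwards is discarded.

Triage assigns each aligned read pair exactly one class.  Pairs that align
concordantly to the reference are dropped from further analysis; pairs with
both mates unmapped (and, by default, discordant pairs) form the unaligned
pool that feeds pseudo-de novo assembly; pairs with exactly one mate
aligned are one-end anchors (OEA) and are kept aside for contig placement.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Iterator

import numpy as np

from . import io
from .io import AlignmentRecord, FastqRecord


@dataclasses.dataclass
class TrimPolicy:
    window: int = 4
    window_min_mean_phred: float = 20.0
    end_clip_max_phred: int = 3
    min_length: int = 50
    adapter: str | None = None  # optional exact-match 3' adapter clip

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


class PairClass(enum.Enum):
    MAPPED_CONCORDANT = "mapped_concordant"
    OEA = "oea"
    BOTH_UNMAPPED = "both_unmapped"
    DISCARDED = "discarded"


def trim_read(read: FastqRecord, policy: TrimPolicy = TrimPolicy()) -> FastqRecord | None:
    """Trim one read; returns None when the survivor is too short.

    The operation is idempotent: the quality-clipped ends of the output are
    above the floor and every window of the output passes the mean test.
    """
    seq, qual = read.sequence, read.quality
    if len(seq) != len(qual):
        raise ValueError(f"{read.name}: sequence/quality length mismatch")
    if policy.adapter:
        hit = seq.find(policy.adapter)
        if hit >= 0:
            seq, qual = seq[:hit], qual[:hit]

    def clip_ends(seq: str, qual: str) -> tuple[str, str]:
        p = io.qual_to_phred(qual)
        ok = p > policy.end_clip_max_phred
        if not ok.any():
            return "", ""
        lo = int(np.argmax(ok))
        hi = len(p) - int(np.argmax(ok[::-1]))
        return seq[lo:hi], qual[lo:hi]

    def window_cut(seq: str, qual: str) -> tuple[str, str]:
        phred = io.qual_to_phred(qual)
        w = policy.window
        if len(phred) < w:
            return seq, qual
        means = np.convolve(phred, np.ones(w) / w, mode="valid")
        failing = np.nonzero(means < policy.window_min_mean_phred - 1e-9)[0]
        if not len(failing):
            return seq, qual
        cut = int(failing[0])
        # keep individually good bases inside the failing window: a good
        # base dragged down by bad followers is retained
        while cut < len(phred) and phred[cut] >= policy.window_min_mean_phred:
            cut += 1
        return seq[:cut], qual[:cut]

    # iterate to a fixpoint so the operation is idempotent
    while True:
        before = len(seq)
        seq, qual = clip_ends(seq, qual)
        seq, qual = window_cut(seq, qual)
        seq, qual = clip_ends(seq, qual)
        if len(seq) == before:
            break

    if len(seq) < policy.min_length:
        return None
    return FastqRecord(read.name, seq, qual)


def classify_pair(
    aln1: AlignmentRecord | None,
    aln2: AlignmentRecord | None,
    insert_mean: int,
    insert_tolerance: float = 0.5,
) -> tuple[PairClass, bool]:
    """Classify one pair; returns (class, discordant_flag).

    Concordance requires both mates on the same target in forward/reverse
    orientation with an implied insert within ``insert_tolerance *
    insert_mean`` of the expectation.  Discordant both-mapped pairs are
    returned as BOTH_UNMAPPED (they join the assembly pool) with the flag
    set.
    """
    if aln1 is None and aln2 is None:
        return PairClass.BOTH_UNMAPPED, False
    if (aln1 is None) != (aln2 is None):
        return PairClass.OEA, False
    if aln1.target_id == aln2.target_id and aln1.strand != aln2.strand:
        plus, minus = (aln1, aln2) if aln1.strand == "+" else (aln2, aln1)
        implied = (minus.target_start + minus.query_length) - plus.target_start
        if (
            plus.target_start <= minus.target_start
            and abs(implied - insert_mean) <= insert_tolerance * insert_mean
        ):
            return PairClass.MAPPED_CONCORDANT, False
    return PairClass.BOTH_UNMAPPED, True


@dataclasses.dataclass
class TriageResult:
    pool: list[tuple[FastqRecord, FastqRecord]]
    oea: list[tuple[str, FastqRecord, FastqRecord, AlignmentRecord | None, AlignmentRecord | None]]
    counts: dict[str, int]


def extract_unaligned_pool(
    pairs: Iterable[
        tuple[FastqRecord | None, FastqRecord | None, AlignmentRecord | None, AlignmentRecord | None]
    ],
    insert_mean: int,
    insert_tolerance: float = 0.5,
    include_discordant: bool = True,
) -> TriageResult:
    """Triage classified pairs into the assembly pool and the OEA sidecar.

    A pair in which either mate was discarded by trimming arrives with that
    mate set to None and counts as DISCARDED.  Class counts always sum to
    the number of input pairs.
    """
    counts = {c.value: 0 for c in PairClass}
    counts["discordant"] = 0
    pool: list[tuple[FastqRecord, FastqRecord]] = []
    oea: list = []
    for r1, r2, a1, a2 in pairs:
        if r1 is None or r2 is None:
            counts[PairClass.DISCARDED.value] += 1
            continue
        cls, discordant = classify_pair(a1, a2, insert_mean, insert_tolerance)
        counts[cls.value] += 1
        counts["discordant"] += int(discordant)
        if cls is PairClass.BOTH_UNMAPPED:
            if discordant and not include_discordant:
                continue
            pool.append((r1, r2))
        elif cls is PairClass.OEA:
            oea.append((r1.name, r1, r2, a1, a2))
    counts["total"] = sum(counts[c.value] for c in PairClass)
    return TriageResult(pool=pool, oea=oea, counts=counts)
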