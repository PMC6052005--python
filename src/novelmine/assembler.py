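"""Two-tier greedy overlap-layout-consensus assembly of unaligned reads.

The primary tier assembles each sample's unaligned pool; the secondary tier
re-assembles the pooled primary contigs of a sample group and discards
"debris": secondary contigs supported by a single primary contig from a
single sample, which cannot be distinguished from sample-private noise.

The algorithm is deliberately simple and fully deterministic: qualifying
overlaps (exact k-mer seeded, gapless-verified at a minimum identity) are
merged longest-first; the consensus is a per-column weighted majority vote,
with base weights of 1 + phred/1000 so that quality only breaks ties.
Input order never matters: units are processed in lexicographic id order.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import Iterable, Sequence

import numpy as np

from . import io


@dataclasses.dataclass
class Contig:
    contig_id: str
    sequence: str
    n_reads: int
    sample_ids: frozenset
    tier: str  # 'primary' | 'secondary'
    read_ids: tuple = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    largest_bp: int
    n50_bp: int


def compute_stats(contigs: Sequence[Contig | str | int]) -> AssemblyStats:
    """N50 / total / largest summary of a contig set.

    N50 is the length L such that contigs of length >= L sum to at least
    half the total assembled bases.
    """
    lengths = sorted(
        (len(c.sequence) if isinstance(c, Contig) else (c if isinstance(c, int) else len(c)))
        for c in contigs
    )
    if not lengths:
        return AssemblyStats(0, 0, 0, 0)
    total = int(sum(lengths))
    acc = 0
    n50 = lengths[-1]
    for L in reversed(lengths):
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return AssemblyStats(len(lengths), total, int(lengths[-1]), int(n50))


# ---------------------------------------------------------------------------
# units


class _Unit:
    __slots__ = ("uid", "codes", "counts", "members", "samples")

    def __init__(self, uid: int, codes: np.ndarray, counts: np.ndarray, members: tuple, samples: frozenset):
        self.uid = uid
        self.codes = codes
        self.counts = counts
        self.members = members
        self.samples = samples

    def __len__(self) -> int:
        return len(self.codes)


def _consensus_codes(counts: np.ndarray) -> np.ndarray:
    codes = np.argmax(counts, axis=1).astype(np.uint8)
    codes[counts.sum(axis=1) == 0] = 4
    return codes


def _rc_unit_arrays(codes: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rc_codes = codes[::-1].copy()
    ok = rc_codes < 4
    rc_codes[ok] = 3 - rc_codes[ok]
    rc_counts = counts[::-1, ::-1].copy()  # reverse positions, swap A<->T / C<->G
    return rc_codes, rc_counts


@dataclasses.dataclass
class _Overlap:
    ovl: int
    a_uid: int
    b_uid: int
    strand: str  # orientation of b relative to a
    offset: int  # position of (oriented) b's origin in a coordinates


class _Assembler:
    SEED_K = 14
    REGISTER_STRIDE = 4

    def __init__(self, min_overlap: int, min_identity: float):
        if min_overlap < 20:
            raise ValueError("min_overlap must be >= 20")
        self.min_overlap = min_overlap
        self.min_identity = min_identity
        self.units: dict[int, _Unit] = {}
        self.index: dict[str, list[tuple[int, int]]] = {}
        self.heap: list[tuple[int, int, int, str, int]] = []
        self._next_uid = 0

    # -- unit management ----------------------------------------------------

    def add_unit(self, codes: np.ndarray, counts: np.ndarray, members: tuple, samples: frozenset) -> _Unit:
        uid = self._next_uid
        self._next_uid += 1
        unit = _Unit(uid, codes, counts, members, samples)
        self.units[uid] = unit
        return unit

    def register(self, unit: _Unit) -> None:
        k = self.SEED_K
        seq = io.decode(unit.codes)
        for p in range(0, max(1, len(seq) - k + 1), self.REGISTER_STRIDE):
            kmer = seq[p : p + k]
            if len(kmer) == k and "N" not in kmer:
                self.index.setdefault(kmer, []).append((unit.uid, p))

    # -- overlap detection --------------------------------------------------

    def find_overlaps(self, unit: _Unit) -> list[_Overlap]:
        k = self.SEED_K
        best: dict[tuple[int, str, int], _Overlap] = {}
        for strand in "+-":
            if strand == "+":
                codes = unit.codes
            else:
                codes, _ = _rc_unit_arrays(unit.codes, unit.counts)
            seq = io.decode(codes)
            seen_diag: set[tuple[int, str, int]] = set()
            for p in range(0, len(seq) - k + 1):
                kmer = seq[p : p + k]
                if "N" in kmer:
                    continue
                for other_uid, op in self.index.get(kmer, ()):  # noqa: B020
                    if other_uid == unit.uid or other_uid not in self.units:
                        continue
                    offset = op - p
                    key = (other_uid, strand, offset)
                    if key in seen_diag:
                        continue
                    seen_diag.add(key)
                    ov = self.verify(self.units[other_uid], codes, offset)
                    if ov is None:
                        continue
                    bkey = (other_uid, strand, offset)
                    best[bkey] = _Overlap(ov, other_uid, unit.uid, strand, offset)
        # keep only the best diagonal per (partner, strand)
        folded: dict[tuple[int, str], _Overlap] = {}
        for (ouid, strand, _off), o in best.items():
            cur = folded.get((ouid, strand))
            if cur is None or o.ovl > cur.ovl or (o.ovl == cur.ovl and o.offset < cur.offset):
                folded[(ouid, strand)] = o
        return list(folded.values())

    def verify(self, a: _Unit, b_codes: np.ndarray, offset: int) -> int | None:
        """Overlap length if b (oriented codes) at ``offset`` in a qualifies."""
        la, lb = len(a.codes), len(b_codes)
        s = max(0, offset)
        e = min(la, offset + lb)
        ov = e - s
        if ov <= 0:
            return None
        contained = ov == lb or ov == la
        if ov < self.min_overlap and not contained:
            return None
        asl = a.codes[s:e]
        bsl = b_codes[s - offset : e - offset]
        mm = int(np.count_nonzero((asl != bsl) | (asl >= 4)))
        if mm > (1 - self.min_identity) * ov:
            return None
        return ov

    # -- merging ------------------------------------------------------------

    def merge(self, a: _Unit, b: _Unit, strand: str, offset: int) -> _Unit:
        if strand == "+":
            b_codes, b_counts = b.codes, b.counts
        else:
            b_codes, b_counts = _rc_unit_arrays(b.codes, b.counts)
        start = min(0, offset)
        end = max(len(a.codes), offset + len(b_codes))
        L = end - start
        counts = np.zeros((L, 4), dtype=np.float32)
        counts[-start : -start + len(a.codes)] += a.counts
        counts[offset - start : offset - start + len(b_codes)] += b_counts
        codes = _consensus_codes(counts)
        del self.units[a.uid]
        del self.units[b.uid]
        unit = self.add_unit(
            codes, counts, tuple(sorted(set(a.members) | set(b.members))), a.samples | b.samples
        )
        return unit

    def push(self, overlaps: Iterable[_Overlap]) -> None:
        for o in overlaps:
            heapq.heappush(self.heap, (-o.ovl, o.a_uid, o.b_uid, o.strand, o.offset))

    def run(self) -> list[_Unit]:
        while self.heap:
            neg_ovl, a_uid, b_uid, strand, offset = heapq.heappop(self.heap)
            a = self.units.get(a_uid)
            b = self.units.get(b_uid)
            if a is None or b is None:
                continue
            if strand == "+":
                b_codes = b.codes
            else:
                b_codes, _ = _rc_unit_arrays(b.codes, b.counts)
            if self.verify(a, b_codes, offset) is None:
                continue
            merged = self.merge(a, b, strand, offset)
            self.register(merged)
            self.push(self.find_overlaps(merged))
        return sorted(self.units.values(), key=lambda u: (-len(u.codes), u.members))


# ---------------------------------------------------------------------------
# public entry points


def _read_counts(seq: str, qual: str | None, weight: float) -> np.ndarray:
    codes = io.encode(seq)
    counts = np.zeros((len(seq), 4), dtype=np.float32)
    ok = codes < 4
    w = np.full(len(seq), float(weight), dtype=np.float32)
    if qual is not None:
        w += io.qual_to_phred(qual).astype(np.float32) / 1000.0
    counts[np.nonzero(ok)[0], codes[ok]] = w[ok]
    return counts


def assemble_greedy(
    inputs: Iterable[tuple[str, str, str | None, str] | tuple[str, str, str | None, str, float]],
    min_overlap: int = 40,
    min_identity: float = 0.97,
    id_prefix: str = "c",
    tier: str = "primary",
) -> list[Contig]:
    """Greedy OLC over (id, sequence, quality|None, sample_id[, weight]) inputs.

    Merges the qualifying overlap with the greatest length first (ties broken
    by unit ids, which follow lexicographic input-id order); consensus is a
    per-column majority with quality-weighted tie-break.  Every input ends up
    in exactly one output contig (possibly as a singleton).
    """
    asm = _Assembler(min_overlap, min_identity)
    rows = sorted(inputs, key=lambda r: r[0])
    for row in rows:
        rid, seq, qual, sample = row[:4]
        weight = float(row[4]) if len(row) > 4 else 1.0
        if not seq:
            continue
        counts = _read_counts(seq, qual, weight)
        unit = asm.add_unit(io.encode(seq), counts, (rid,), frozenset([sample]))
        asm.register(unit)
    for uid in sorted(asm.units):
        asm.push(asm.find_overlaps(asm.units[uid]))
    final = asm.run()
    contigs = []
    for i, u in enumerate(final):
        contigs.append(
            Contig(
                contig_id=f"{id_prefix}{i + 1}",
                sequence=io.decode(u.codes),
                n_reads=len(u.members),
                sample_ids=u.samples,
                tier=tier,
                read_ids=u.members,
            )
        )
    return contigs


def secondary_assembly(
    primary_contigs: Iterable[Contig],
    min_overlap: int = 100,
    min_identity: float = 0.97,
    min_length: int = 0,
    id_prefix: str = "sec_c",
) -> tuple[list[Contig], list[Contig]]:
    """Pooled re-assembly of primary contigs; returns (kept, debris).

    A secondary contig supported by exactly one primary contig (necessarily
    from exactly one sample) is a singlet and is binned as debris.  An
    optional minimum-length filter is exposed but off by default.
    """
    inputs = []
    weights: dict[str, int] = {}
    samples: dict[str, frozenset] = {}
    for c in primary_contigs:
        inputs.append((c.contig_id, c.sequence, None, next(iter(c.sample_ids)), float(c.n_reads)))
        weights[c.contig_id] = c.n_reads
        samples[c.contig_id] = c.sample_ids
    raw = assemble_greedy(
        inputs, min_overlap=min_overlap, min_identity=min_identity, id_prefix=id_prefix, tier="secondary"
    )
    kept: list[Contig] = []
    debris: list[Contig] = []
    for c in raw:
        c.n_reads = sum(weights[m] for m in c.read_ids)
        c.sample_ids = frozenset().union(*(samples[m] for m in c.read_ids))
        if len(c.read_ids) == 1:
            debris.append(c)
        elif min_length and len(c.sequence) < min_length:
            debris.append(c)
        else:
            kept.append(c)
    return kept, debris
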