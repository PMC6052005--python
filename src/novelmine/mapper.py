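"""A minimal seed-and-extend paired-end read mapper and local aligner.

This stands in for a production short-read mapper and for BLAT-style local
alignment at desk scale.  Reads are located by exact k-mer seeds against a
2-bit packed, sorted k-mer index, candidate loci are scored by gapless
mismatch counting with a banded edit-distance fallback (edlib), and mapping
quality is a deliberate 3-valued surrogate:

* 60 - unique best locus with no close second,
* 30 - unique best locus with a weaker second,
* 0  - ambiguous (two or more equally good loci).

The pipeline only ever consumes the ``mapq >= 30`` threshold, so a
calibrated probabilistic MAPQ is intentionally out of scope.  Externally
produced SAM can be substituted at every stage of the pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import edlib
import numpy as np

from . import io
from .io import AlignmentRecord

DEFAULT_K = 21
DEFAULT_MIN_IDENTITY = 0.9


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Exact k-mer -> positions map over a set of target sequences.

    Targets are concatenated with k N spacers; windows containing an N are
    never indexed.  Lookup is binary search over a sorted packed-k-mer array
    (k <= 31 fits in a uint64).
    """

    def __init__(self, sequences: dict[str, str], k: int = DEFAULT_K):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        self.names: list[str] = []
        self.lengths: dict[str, int] = {}
        chunks = []
        offsets = []
        pos = 0
        for name, seq in sequences.items():
            if len(seq) < k:
                warnings.warn(f"target {name!r} shorter than k={k}; not indexed")
            self.names.append(name)
            self.lengths[name] = len(seq)
            offsets.append(pos)
            chunks.append(io.encode(seq))
            pos += len(seq)
            chunks.append(np.full(k, 4, dtype=np.uint8))  # spacer
            pos += k
        self.offsets = np.array(offsets, dtype=np.int64)
        self.codes = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
        kmers, valid = _pack_kmers(self.codes, k)
        positions = np.nonzero(valid)[0].astype(np.int64)
        kmers = kmers[valid]
        order = np.argsort(kmers, kind="stable")
        self._sorted_kmers = kmers[order]
        self._sorted_pos = positions[order]

    @property
    def n_indexed(self) -> int:
        return len(self._sorted_pos)

    def lookup(self, kmer: np.uint64) -> np.ndarray:
        """Global positions at which this packed k-mer occurs (sorted)."""
        lo = np.searchsorted(self._sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmer, side="right")
        return np.sort(self._sorted_pos[lo:hi])

    def lookup_many(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised lookup; returns (lo, hi) ranges into the position array."""
        lo = np.searchsorted(self._sorted_kmers, kmers, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmers, side="right")
        return lo, hi

    def positions(self, lo: int, hi: int) -> np.ndarray:
        return self._sorted_pos[lo:hi]

    def resolve(self, gpos: int) -> tuple[str, int]:
        """Global position -> (target name, local position)."""
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.offsets[i])

    def global_start(self, name: str) -> int:
        return int(self.offsets[self.names.index(name)])


def _pack_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit pack of all k-windows; second array flags N-free windows."""
    n = len(codes)
    if n < k:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    m = n - k + 1
    kmers = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        kmers = (kmers << np.uint64(2)) | (codes[i : m + i].astype(np.uint64) & np.uint64(3))
    bad = np.concatenate([[0], np.cumsum(codes >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return kmers, valid


# ---------------------------------------------------------------------------
# read mapping


@dataclasses.dataclass
class _Candidate:
    gstart: int  # global start of the read on the concatenated target
    strand: str
    mismatches: int


def _pack_read_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    return _pack_kmers(codes, k)


def map_read(
    read: io.FastqRecord | str,
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits_per_seed: int = 50,
) -> AlignmentRecord | None:
    """Map one read; returns None when no locus reaches ``min_identity``."""
    name = read if isinstance(read, str) else read.name
    seq = read if isinstance(read, str) else read.sequence
    res = map_reads([(name, seq)], index, min_identity, max_hits_per_seed)
    return res[name]


def map_reads(
    reads: Iterable[tuple[str, str] | io.FastqRecord],
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits_per_seed: int = 50,
) -> dict[str, AlignmentRecord | None]:
    """Map a batch of reads (name, sequence); vectorised seed lookups.

    Seeds are taken at the first, middle and last k-windows of the read, on
    both strands.  Candidate diagonals are scored by gapless mismatch count
    against the packed target; when the gapless score fails but seeds exist,
    a banded edit-distance alignment (edlib) around the best diagonal is
    attempted so that small indels do not fail the read outright.
    """
    k = index.k
    items = []
    for r in reads:
        if isinstance(r, io.FastqRecord):
            items.append((r.name, r.sequence))
        else:
            items.append((r[0], r[1]))

    out: dict[str, AlignmentRecord | None] = {}
    by_len: dict[int, list[int]] = {}
    for i, (_name, seq) in enumerate(items):
        by_len.setdefault(len(seq), []).append(i)

    tcodes = index.codes
    tlen = len(tcodes)
    for L, idxs in by_len.items():
        if L < k:
            for i in idxs:
                out[items[i][0]] = None
            continue
        n = len(idxs)
        mat = np.empty((n, L), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = io.encode(items[i][1])
        rc = 3 - mat[:, ::-1]
        rc[mat[:, ::-1] >= 4] = 4
        seed_offsets = sorted({0, (L - k) // 4, (L - k) // 2, 3 * (L - k) // 4, L - k})
        seed_vals = np.empty((n, 2, len(seed_offsets)), dtype=np.uint64)
        seed_bad = np.zeros((n, 2, len(seed_offsets)), dtype=bool)
        for si, off in enumerate(seed_offsets):
            for strand, m in ((0, mat), (1, rc)):
                window = m[:, off : off + k]
                v = np.zeros(n, dtype=np.uint64)
                for j in range(k):
                    v = (v << np.uint64(2)) | (window[:, j].astype(np.uint64) & np.uint64(3))
                seed_vals[:, strand, si] = v
                seed_bad[:, strand, si] = (window >= 4).any(axis=1)
        lo, hi = index.lookup_many(seed_vals.reshape(-1))
        lo = lo.reshape(n, 2, len(seed_offsets))
        hi = hi.reshape(n, 2, len(seed_offsets))

        for row, i in enumerate(idxs):
            name = items[i][0]
            cands: dict[tuple[str, int], int] = {}  # (strand, gstart) -> mismatches
            seen: set[tuple[str, int]] = set()
            for strand, m in (("+", mat[row]), ("-", rc[row])):
                s_i = 0 if strand == "+" else 1
                for si, off in enumerate(seed_offsets):
                    if seed_bad[row, s_i, si]:
                        continue
                    a, b = int(lo[row, s_i, si]), int(hi[row, s_i, si])
                    if b - a == 0 or b - a > max_hits_per_seed:
                        continue
                    for gpos in index.positions(a, b):
                        gstart = int(gpos) - off
                        key = (strand, gstart)
                        if key in seen:
                            continue
                        seen.add(key)
                        if gstart < 0 or gstart + L > tlen:
                            continue
                        mm = int(np.count_nonzero(tcodes[gstart : gstart + L] != m))
                        cands[key] = mm
            out[name] = _finalize(name, items[i][1], cands, index, L, min_identity, mat[row], rc[row])
    return out


def _finalize(
    name: str,
    seq: str,
    cands: dict[tuple[str, int], int],
    index: KmerIndex,
    L: int,
    min_identity: float,
    fwd_codes: np.ndarray,
    rc_codes: np.ndarray,
) -> AlignmentRecord | None:
    if not cands:
        return None
    max_mm = int((1 - min_identity) * L)
    ranked = sorted(cands.items(), key=lambda kv: (kv[1], kv[0][1], kv[0][0]))
    (best_strand, best_start), best_mm = ranked[0]
    cigar = f"{L}M"
    if best_mm > max_mm:
        # banded edit-distance fallback around the best seeded diagonal
        pad = max(8, L // 10)
        w0 = max(0, best_start - pad)
        w1 = min(len(index.codes), best_start + L + pad)
        window = io.decode(index.codes[w0:w1])
        q = seq if best_strand == "+" else io.revcomp(seq)
        res = edlib.align(q, window, mode="HW", task="path", k=max_mm)
        if res["editDistance"] < 0:
            return None
        best_mm = res["editDistance"]
        loc = res["locations"][0]
        best_start = w0 + loc[0]
        cigar = res["cigar"] or cigar
    qualifying = [kv for kv in ranked if kv[1] <= max_mm]
    n_loci = max(1, len(qualifying))
    if len(ranked) > 1:
        second_mm = ranked[1][1]
        if second_mm <= best_mm:
            mapq = 0
        elif second_mm - best_mm <= 3:
            mapq = 30
        else:
            mapq = 60
    else:
        mapq = 60
    target, local = index.resolve(best_start)
    if local + L > index.lengths.get(target, 0):
        return None  # spans a spacer boundary
    return AlignmentRecord(
        query_id=name,
        target_id=target,
        target_start=local,
        strand=best_strand,
        cigar=cigar,
        mapq=mapq,
        n_candidate_loci=n_loci,
        query_length=L,
        identity=1 - best_mm / L,
        score=L - best_mm,
    )


# ---------------------------------------------------------------------------
# local alignment (Smith-Waterman with linear gaps)

MATCH = 2
MISMATCH = -2
GAP = -3


@dataclasses.dataclass
class LocalAlignment:
    """A local alignment of a query against a target window."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    score: int
    matches: int
    length: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0

    @property
    def coverage_of(self) -> int:
        return self.query_end - self.query_start


def _sw_matrix(qc: np.ndarray, tc: np.ndarray) -> np.ndarray:
    """Full Smith-Waterman DP matrix, linear gap penalty, vectorised rows.

    Within-row (left-gap) dependencies are resolved with a running-max
    trick: for linear gaps, chains of left moves collapse so that
    H[i,j] = max(A[j], max_{k<j}(A[k] - g*(j-k))) where A holds the
    zero/diagonal/up candidates.
    """
    n, m = len(qc), len(tc)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    g = -GAP
    jidx = np.arange(1, m + 1, dtype=np.int32) * g
    for i in range(1, n + 1):
        sub = np.where((tc == qc[i - 1]) & (tc < 4), MATCH, MISMATCH).astype(np.int32)
        A = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + GAP)
        np.maximum(A, 0, out=A)
        C = A + jidx
        R = np.maximum.accumulate(C)
        A[1:] = np.maximum(A[1:], R[:-1] - jidx[1:])
        H[i, 1:] = A
    return H


def _traceback(
    H: np.ndarray, qc: np.ndarray, tc: np.ndarray, i: int, j: int
) -> LocalAlignment:
    matches = 0
    length = 0
    qi, tj = i, j
    while qi > 0 and tj > 0 and H[qi, tj] > 0:
        s = MATCH if (qc[qi - 1] == tc[tj - 1] and tc[tj - 1] < 4) else MISMATCH
        if H[qi, tj] == H[qi - 1, tj - 1] + s:
            matches += int(s == MATCH)
            length += 1
            qi -= 1
            tj -= 1
        elif H[qi, tj] == H[qi - 1, tj] + GAP:
            length += 1
            qi -= 1
        elif H[qi, tj] == H[qi, tj - 1] + GAP:
            length += 1
            tj -= 1
        else:
            break
    return LocalAlignment(
        query_start=qi,
        query_end=i,
        target_start=tj,
        target_end=j,
        strand="+",
        score=int(H[i, j]),
        matches=matches,
        length=length,
    )


def _sw_align(query: str, target: str, min_score: int, max_n: int) -> list[LocalAlignment]:
    qc = io.encode(query)
    tc = io.encode(target)
    H = _sw_matrix(qc, tc)
    out: list[LocalAlignment] = []
    Hwork = H.copy()
    for _ in range(max_n):
        best = int(Hwork.max())
        if best < min_score:
            break
        cells = np.argwhere(Hwork == best)
        # deterministic tie-break: lowest target coordinate, then lowest query
        cells = cells[np.lexsort((cells[:, 0], cells[:, 1]))]
        i, j = int(cells[0][0]), int(cells[0][1])
        aln = _traceback(H, qc, tc, i, j)
        out.append(aln)
        Hwork[:, max(0, aln.target_start) : aln.target_end + 1] = 0
    return out


def align_local(
    query: str,
    target: str,
    min_score: int = 20,
    max_n: int = 5,
    both_strands: bool = False,
) -> list[LocalAlignment]:
    """Highest-scoring local alignments of ``query`` against ``target``.

    Small instances run the exact full DP; larger ones are seeded with
    16-mers and the DP is run on a band of windows around candidate
    diagonals.  Alignments are reported best-first with deterministic
    tie-breaks (lowest target coordinate).
    """
    if not query:
        raise ValueError("empty query")
    if not target:
        return []
    alns = _align_one_strand(query, target, min_score, max_n)
    if both_strands:
        for a in _align_one_strand(io.revcomp(query), target, min_score, max_n):
            qlen = len(query)
            alns.append(
                LocalAlignment(
                    query_start=qlen - a.query_end,
                    query_end=qlen - a.query_start,
                    target_start=a.target_start,
                    target_end=a.target_end,
                    strand="-",
                    score=a.score,
                    matches=a.matches,
                    length=a.length,
                )
            )
        alns.sort(key=lambda a: (-a.score, a.target_start, a.query_start))
        alns = alns[:max_n]
    return alns


def _align_one_strand(query: str, target: str, min_score: int, max_n: int) -> list[LocalAlignment]:
    n, m = len(query), len(target)
    if n * m <= 4_000_000:
        return _sw_align(query, target, min_score, max_n)
    # seeded banding for big instances
    k = 16
    qkm, qok = _pack_kmers(io.encode(query), k)
    tkm, tok = _pack_kmers(io.encode(target), k)
    tmap: dict[int, list[int]] = {}
    step = 4
    for p in range(0, len(tkm), step):
        if tok[p]:
            tmap.setdefault(int(tkm[p]), []).append(p)
    diags: set[int] = set()
    for qp in range(0, len(qkm), 1):
        if not qok[qp]:
            continue
        for tp in tmap.get(int(qkm[qp]), ()):
            diags.add((tp - qp) // 200 * 200)
    out: list[LocalAlignment] = []
    band = 400
    seen_windows: set[tuple[int, int]] = set()
    for d in sorted(diags):
        w0 = max(0, d - band)
        w1 = min(m, d + n + band)
        key = (w0 // 100, w1 // 100)
        if key in seen_windows:
            continue
        seen_windows.add(key)
        for a in _sw_align(query, target[w0:w1], min_score, max_n):
            a.target_start += w0
            a.target_end += w0
            out.append(a)
    out.sort(key=lambda a: (-a.score, a.target_start, a.query_start))
    # drop duplicate hits covering the same target span
    dedup: list[LocalAlignment] = []
    for a in out:
        if not any(
            abs(a.target_start - b.target_start) < 50 and abs(a.target_end - b.target_end) < 50
            for b in dedup
        ):
            dedup.append(a)
    return dedup[:max_n]
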