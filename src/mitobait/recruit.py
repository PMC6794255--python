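"""Candidate mitochondrial read recruitment by seeded local alignment.

Short exact seeds (default k=10) with an optional one-mismatch seed
neighborhood are looked up in a positional index of the reference set;
seed hits are grouped by diagonal and extended by local alignment
(gapless extension with a banded Smith-Waterman rescue).  A read is
recruited iff it has at least one hit scoring >= a + b*ln(L).

Only the forward strand of each reference is indexed; queries are looked
up in both orientations, so minus-strand hits come from aligning the
reverse complement of the read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .seqio import Read, SeqRecord

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a DNA string (A=0 C=1 G=2 T=3, anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(enc: np.ndarray) -> str:
    return _DECODE[enc].tobytes().decode()


def revcomp_enc(enc: np.ndarray) -> np.ndarray:
    return np.where(enc < 4, 3 - enc, 4)[::-1]


def kmer_codes(enc: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes of an encoded sequence plus a validity mask.

    Codes are big-endian base-4 integers; windows containing N are invalid.
    """
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    w = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = w.astype(np.int64) @ powers
    valid = w.max(axis=1) < 4
    return codes, valid


def hamming1_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """For each code, the 3*k codes at Hamming distance 1 (shape n, 3k)."""
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    base = (codes[:, None] >> shifts) & 3  # (n, k)
    out = []
    for d in (1, 2, 3):
        nb = (base + d) & 3
        out.append(codes[:, None, None] + ((nb - base)[:, :, None] << shifts[None, :, None]))
    return np.concatenate(out, axis=2).reshape(len(codes), 3 * k)


@dataclass
class AlignParams:
    k: int = 10
    seed_mismatches: int = 1
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score_a: float = 20.0
    min_score_b: float = 8.0
    max_diagonals: int = 8  # candidate diagonals evaluated per strand
    sw_band: int = 8
    sw_rescue_margin: float = 12.0

    def min_score(self, length: int) -> float:
        return self.min_score_a + self.min_score_b * math.log(max(length, 2))


@dataclass
class AlignmentHit:
    read_id: str
    reference_id: str
    strand: str  # '+' or '-'
    read_start: int  # original read coordinates, half-open
    read_end: int
    ref_start: int
    ref_end: int
    score: int
    identity: float


class SeedIndex:
    """Sorted-array positional k-mer index over the forward strands."""

    def __init__(self, references: Sequence[SeqRecord], k: int = 10):
        if not references:
            raise ValueError("reference list must be non-empty")
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.k = k
        self.ref_ids: List[str] = []
        self.ref_enc: List[np.ndarray] = []
        codes_all, ref_all, pos_all = [], [], []
        for rec in references:
            if len(rec.sequence) < k:
                warnings.warn(
                    f"reference {rec.id!r} shorter than k={k}; skipped", stacklevel=2
                )
                continue
            idx = len(self.ref_ids)
            self.ref_ids.append(rec.id)
            enc = encode(rec.sequence)
            self.ref_enc.append(enc)
            codes, valid = kmer_codes(enc, k)
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[pos])
            ref_all.append(np.full(len(pos), idx, dtype=np.int32))
            pos_all.append(pos.astype(np.int32))
        if not self.ref_ids:
            raise ValueError("no reference is long enough to index")
        codes = np.concatenate(codes_all)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_ref = np.concatenate(ref_all)[order]
        self.sorted_pos = np.concatenate(pos_all)[order]

    @property
    def n_positions(self) -> int:
        return len(self.sorted_codes)

    def lookup(self, codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Gather all (query_idx, ref_idx, ref_pos) matches for code queries."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        ends = np.cumsum(cnt)
        starts = ends - cnt
        flat = np.arange(total) - np.repeat(starts, cnt) + np.repeat(lo, cnt)
        qidx = np.repeat(np.arange(len(codes)), cnt)
        return qidx, self.sorted_ref[flat], self.sorted_pos[flat]


def build_index(references: Sequence[SeqRecord], k: int = 10) -> SeedIndex:
    return SeedIndex(references, k)


def _gapless_extend(
    qenc: np.ndarray, renc: np.ndarray, diag: int, p: AlignParams
) -> Optional[Tuple[int, int, int, int]]:
    """Best-scoring local gapless run on a diagonal.

    Returns (score, q_start, q_end, n_matches) in query coordinates, or
    None if the diagonal does not intersect the reference.
    """
    L, R = len(qenc), len(renc)
    i0 = max(0, -diag)
    i1 = min(L, R - diag)
    if i1 - i0 < 1:
        return None
    a = qenc[i0:i1]
    b = renc[i0 + diag : i1 + diag]
    m = (a == b) & (a < 4)
    vals = np.where(m, p.match, p.mismatch).astype(np.int64)
    c = np.cumsum(vals)
    cm = np.concatenate(([0], c))
    run_min = np.minimum.accumulate(cm[:-1])
    diffs = c - run_min
    j = int(np.argmax(diffs))
    score = int(diffs[j])
    s = int(np.argmin(cm[: j + 1]))
    n_match = int(m[s : j + 1].sum())
    return score, i0 + s, i0 + j + 1, n_match


def _banded_sw(qenc: np.ndarray, renc: np.ndarray, diag: int, p: AlignParams):
    """Affine-gap Smith-Waterman on a reference window around a diagonal.

    Returns (score, q_start, q_end, identity, ref_start, ref_end) or None.
    Used only as a rescue when the gapless extension falls just short of
    the score threshold; intervals come from a lightweight path-start
    tracker rather than a full traceback.
    """
    L = len(qenc)
    w0 = max(0, diag - p.sw_band)
    w1 = min(len(renc), diag + L + p.sw_band)
    if w1 - w0 < 1:
        return None
    ref = renc[w0:w1]
    n = len(ref)
    NEG = -(10 ** 9)
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, NEG, dtype=np.int64)
    best = (0, 0, 0)
    # store H rows for traceback-free interval estimate: track start via parent arrays
    starts = np.arange(n + 1)  # ref start column of the best path ending here
    qstarts = np.zeros(n + 1, dtype=np.int64)
    best_cell = None
    for i in range(1, L + 1):
        prevH = H
        prev_starts, prev_qstarts = starts.copy(), qstarts.copy()
        H = np.zeros(n + 1, dtype=np.int64)
        starts = np.arange(n + 1)
        qstarts = np.full(n + 1, i, dtype=np.int64)
        F = NEG
        qi = qenc[i - 1]
        sub = np.where((ref == qi) & (qi < 4), p.match, p.mismatch).astype(np.int64)
        diagH = prevH[:-1] + sub
        E = np.maximum(E + p.gap_extend, prevH + p.gap_open)
        for j in range(1, n + 1):
            F = max(F + p.gap_extend, H[j - 1] + p.gap_open)
            h = max(0, diagH[j - 1], E[j], F)
            H[j] = h
            if h == diagH[j - 1] and h > 0:
                starts[j] = prev_starts[j - 1]
                qstarts[j] = prev_qstarts[j - 1] if prevH[j - 1] > 0 else i - 1
            elif h == E[j] and h > 0:
                starts[j] = prev_starts[j]
                qstarts[j] = prev_qstarts[j]
            elif h == F and h > 0:
                starts[j] = starts[j - 1]
                qstarts[j] = qstarts[j - 1]
        jbest = int(np.argmax(H))
        if H[jbest] > best[0]:
            best = (int(H[jbest]), i, jbest)
            best_cell = (int(starts[jbest]), int(qstarts[jbest]))
    if best[0] <= 0 or best_cell is None:
        return None
    score, qi_end, j_end = best
    ref_start_local, q_start = best_cell
    q_end = qi_end
    aln_len = max(q_end - q_start, j_end - ref_start_local)
    ident = min(1.0, (score + 0.0) / (p.match * aln_len)) if aln_len else 0.0
    # the caller needs the ref interval in full-reference coordinates
    return score, q_start, q_end, ident, w0 + ref_start_local, w0 + j_end  # type: ignore[return-value]


def align_sequence(
    seq: str, seq_id: str, index: SeedIndex, p: AlignParams
) -> List[AlignmentHit]:
    """Align one query sequence against the index; returns passing hits.

    Hits are sorted by score descending, ties broken by
    (reference_id, ref_start) for determinism.
    """
    L = len(seq)
    k = index.k
    if L < k:
        return []
    enc_f = encode(seq)
    strands = (("+", enc_f), ("-", revcomp_enc(enc_f)))
    # fast path: exact seeds only; the Hamming-1 neighborhood can only add
    # diagonals, so when exact seeds already yield a passing hit the
    # recruitment decision is identical and much cheaper
    hits = _align_strands(seq_id, strands, index, p, neighbors=False)
    if hits or not (p.seed_mismatches >= 1 and k <= 12):
        return hits
    return _align_strands(seq_id, strands, index, p, neighbors=True)


def _align_strands(
    seq_id: str, strands, index: SeedIndex, p: AlignParams, neighbors: bool
) -> List[AlignmentHit]:
    k = index.k
    L = len(strands[0][1])
    thresh = p.min_score(L)
    hits: List[AlignmentHit] = []
    for strand, enc in strands:
        codes, valid = kmer_codes(enc, k)
        offsets = np.nonzero(valid)[0]
        codes = codes[offsets]
        if len(codes) == 0:
            continue
        if neighbors:
            nb = hamming1_codes(codes, k)
            all_codes = np.concatenate([codes, nb.ravel()])
            all_off = np.concatenate(
                [offsets, np.repeat(offsets, 3 * k)]
            )
        else:
            all_codes, all_off = codes, offsets
        qidx, ridx, rpos = index.lookup(all_codes)
        if len(qidx) == 0:
            continue
        diags = rpos - all_off[qidx]
        key = ridx.astype(np.int64) * (1 << 33) + (diags + (1 << 31))
        ukey, counts = np.unique(key, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        for u in ukey[order[: p.max_diagonals]]:
            r = int(u >> 33)
            d = int((u & ((1 << 33) - 1)) - (1 << 31))
            renc = index.ref_enc[r]
            res = _gapless_extend(enc, renc, d, p)
            if res is None:
                continue
            score, qs, qe, n_match = res
            rs, re_ = d + qs, d + qe
            ident = n_match / (qe - qs) if qe > qs else 0.0
            if score < thresh and score >= thresh - p.sw_rescue_margin:
                sw = _banded_sw(enc, renc, d, p)
                if sw is not None and sw[0] > score:
                    score, qs, qe, ident, rs, re_ = sw
            if score >= thresh:
                if strand == "-":
                    q0, q1 = L - qe, L - qs
                else:
                    q0, q1 = qs, qe
                hits.append(
                    AlignmentHit(
                        seq_id, index.ref_ids[r], strand, q0, q1, rs, re_,
                        int(score), float(ident),
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.reference_id, h.ref_start))
    return hits


def align_local(read: Read, index: SeedIndex, p: Optional[AlignParams] = None) -> List[AlignmentHit]:
    return align_sequence(read.sequence, read.id, index, p or AlignParams())


def recruit_reads(
    reads: Iterable[Read],
    references,
    p: Optional[AlignParams] = None,
) -> Tuple[Set[str], List[AlignmentHit]]:
    """Recruit every read with at least one passing hit.

    ``references`` may be a list of SeqRecords or a prebuilt SeedIndex.
    Mates are recruited independently.  Returns the recruited read-id set
    and the best hit per recruited read.
    """
    p = p or AlignParams()
    index = references if isinstance(references, SeedIndex) else build_index(references, p.k)
    recruited: Set[str] = set()
    best_hits: List[AlignmentHit] = []
    for read in reads:
        hits = align_local(read, index, p)
        if hits:
            recruited.add(read.id)
            best_hits.append(hits[0])
    return recruited, best_hits


def filter_reads(reads: Iterable[Read], recruited_ids: Set[str]) -> List[Read]:
    """Input-order-preserving selection of recruited reads."""
    return [r for r in reads if r.id in recruited_ids]
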