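"""Single-k De Bruijn graph assembly of recruited reads.

Canonical k-mers (lexicographic min of a k-mer and its reverse
complement) with count >= min_kmer_count form the graph; tips shorter
than 2k are clipped, simple bubbles are popped keeping the
higher-coverage branch, and maximal unbranched paths are emitted as
contigs.  A k-mer cycle (a fully circular molecule) is emitted as a
linear contig carrying deliberate terminal redundancy so downstream
circularization can detect and trim it.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .recruit import encode, kmer_codes
from .seqio import Read, revcomp

_BASES = "ACGT"

# extra wrapped bases appended to cyclic contigs (beyond the inherent k-1)
CYCLE_EXTRA = 60


@dataclass
class AssemblyParams:
    dbg_k: int = 25
    min_contig_len: int = 150
    min_kmer_count: int = 2
    bubble_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.dbg_k % 2 == 0 or self.dbg_k < 15:
            raise ValueError("dbg_k must be odd and >= 15")
        if self.min_contig_len < self.dbg_k:
            raise ValueError("min_contig_len must be >= dbg_k")


@dataclass
class Contig:
    id: str
    sequence: str
    iteration_born: int = 0
    mean_kmer_coverage: float = 0.0
    supporting_read_ids: Set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << 2) | ((~tmp) & 3)
        tmp >>= 2
    return out


def _rc_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | ((~code) & 3)
        code >>= 2
    return out


def _decode_kmer(code: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(chars))


class _Graph:
    """Membership/count store for the solid k-mer set, both orientations."""

    def __init__(self, canon_codes: np.ndarray, counts: np.ndarray, k: int):
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        rc = _revcomp_codes(canon_codes, k)
        self.present: Set[int] = set(canon_codes.tolist()) | set(rc.tolist())
        self.count: Dict[int, int] = dict(
            zip(canon_codes.tolist(), counts.tolist())
        )
        self.canon_list: List[int] = sorted(self.count)

    def canon(self, code: int) -> int:
        return min(code, _rc_code(code, self.k))

    def successors(self, code: int) -> List[int]:
        base = (code << 2) & self.mask
        return [base | b for b in range(4) if (base | b) in self.present]

    def predecessors(self, code: int) -> List[int]:
        base = code >> 2
        k1 = 2 * (self.k - 1)
        return [(b << k1) | base for b in range(4) if ((b << k1) | base) in self.present]

    def remove(self, codes: Iterable[int]) -> None:
        for c in codes:
            rc = _rc_code(c, self.k)
            self.present.discard(c)
            self.present.discard(rc)
            self.count.pop(min(c, rc), None)
        self.canon_list = sorted(self.count)


@dataclass
class _Unitig:
    codes: List[int]  # oriented member k-mer codes
    sequence: str
    cyclic: bool = False

    def mean_coverage(self, g: _Graph) -> float:
        if not self.codes:
            return 0.0
        return float(np.mean([g.count[g.canon(c)] for c in self.codes]))


def _walk(g: _Graph, start: int) -> _Unitig:
    """Maximal unbranched path through ``start`` (both directions)."""
    k = g.k

    def extend_right(code: int, first: int) -> Tuple[List[int], bool]:
        path = []
        cur = code
        seen_local = {g.canon(first)}
        while True:
            succ = g.successors(cur)
            if len(succ) != 1:
                return path, False
            nxt = succ[0]
            if len(g.predecessors(nxt)) != 1:
                return path, False
            cn = g.canon(nxt)
            if cn == g.canon(first):
                return path, True  # closed a cycle
            if cn in seen_local or cn == g.canon(cur):
                return path, False  # palindrome/hairpin guard
            path.append(nxt)
            seen_local.add(cn)
            cur = nxt

    right, cyclic = extend_right(start, start)
    if cyclic:
        codes = [start] + right
    else:
        left_rc, _ = extend_right(_rc_code(start, k), start)
        left = [_rc_code(c, k) for c in reversed(left_rc)]
        codes = left + [start] + right
    seq = _decode_kmer(codes[0], k) + "".join(
        _BASES[c & 3] for c in codes[1:]
    )
    if cyclic and len(codes) > CYCLE_EXTRA:
        # total terminal redundancy: (k-1) + CYCLE_EXTRA bases
        seq = seq + "".join(_BASES[c & 3] for c in codes[:CYCLE_EXTRA])
    return _Unitig(codes, seq, cyclic)


def _extract_unitigs(g: _Graph) -> List[_Unitig]:
    visited: Set[int] = set()
    unitigs: List[_Unitig] = []
    for code in g.canon_list:
        if code in visited:
            continue
        u = _walk(g, code)
        for c in u.codes:
            visited.add(g.canon(c))
        unitigs.append(u)
    return unitigs


def _is_tip(g: _Graph, u: _Unitig) -> bool:
    if u.cyclic:
        return False
    first, last = u.codes[0], u.codes[-1]
    dead_left = len(g.predecessors(first)) == 0
    dead_right = len(g.successors(last)) == 0
    return dead_left != dead_right  # exactly one dead end hanging off a branch


def _pop_bubbles(g: _Graph, p: AssemblyParams) -> None:
    """Remove the lower-coverage branch of simple two-path bubbles."""
    unitigs = _extract_unitigs(g)
    anchors: Dict[Tuple[int, int], List[_Unitig]] = {}
    for u in unitigs:
        if u.cyclic:
            continue
        preds = g.predecessors(u.codes[0])
        succs = g.successors(u.codes[-1])
        if len(preds) == 1 and len(succs) == 1:
            key = (g.canon(preds[0]), g.canon(succs[0]))
            anchors.setdefault(key, []).append(u)
    doomed: List[int] = []
    for key, group in anchors.items():
        if len(group) < 2:
            continue
        group.sort(key=lambda u: (-u.mean_coverage(g), u.sequence))
        keep = group[0]
        for u in group[1:]:
            sim = max(
                difflib.SequenceMatcher(None, keep.sequence, u.sequence).ratio(),
                difflib.SequenceMatcher(
                    None, keep.sequence, revcomp(u.sequence)
                ).ratio(),
            )
            if sim >= p.bubble_identity:
                doomed.extend(u.codes)
    if doomed:
        g.remove(doomed)


def assemble(
    reads: Sequence[Read],
    p: Optional[AssemblyParams] = None,
    iteration: int = 0,
) -> List[Contig]:
    """Assemble reads into contigs; deterministic for identical inputs."""
    p = p or AssemblyParams()
    if not reads:
        raise ValueError("read set must be non-empty")
    k = p.dbg_k
    per_read_codes: List[np.ndarray] = []
    chunks: List[np.ndarray] = []
    for r in reads:
        enc = encode(r.sequence)
        codes, valid = kmer_codes(enc, k)
        if len(codes) == 0:
            per_read_codes.append(np.empty(0, dtype=np.int64))
            continue
        rc = _revcomp_codes(codes, k)
        canon = np.minimum(codes, rc)
        canon = canon[valid]
        per_read_codes.append(canon)
        chunks.append(canon)
    if not chunks:
        warnings.warn("all reads shorter than dbg_k; nothing to assemble", stacklevel=2)
        return []
    allc = np.concatenate(chunks)
    uniq, counts = np.unique(allc, return_counts=True)
    solid = counts >= p.min_kmer_count
    uniq, counts = uniq[solid], counts[solid]
    if len(uniq) == 0:
        return []
    g = _Graph(uniq, counts, k)

    for _ in range(2):  # tip clipping rounds
        tips = [u for u in _extract_unitigs(g) if _is_tip(g, u) and len(u.sequence) < 2 * k]
        if not tips:
            break
        g.remove([c for u in tips for c in u.codes])

    _pop_bubbles(g, p)

    unitigs = [u for u in _extract_unitigs(g) if len(u.sequence) >= p.min_contig_len]
    unitigs.sort(key=lambda u: (-len(u.sequence), u.sequence))
    contigs = [
        Contig(
            id=f"it{iteration}_c{i + 1}",
            sequence=u.sequence,
            iteration_born=iteration,
            mean_kmer_coverage=round(u.mean_coverage(g), 3),
        )
        for i, u in enumerate(unitigs)
    ]

    # assign each read to the contig sharing the most solid k-mers
    owner: Dict[int, int] = {}
    for ci, u in enumerate(unitigs):
        for c in u.codes:
            owner[g.canon(c)] = ci
    for r, canon in zip(reads, per_read_codes):
        votes: Dict[int, int] = {}
        for c in canon.tolist():
            ci = owner.get(c)
            if ci is not None:
                votes[ci] = votes.get(ci, 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            contigs[best].supporting_read_ids.add(r.id)
    return contigs


def contig_stats(contigs: Sequence[Contig]) -> Tuple[int, float, int, int]:
    """(n, mean_len, total_len, N50); all zeros for an empty set."""
    if not contigs:
        return 0, 0.0, 0, 0
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    return len(lengths), total / len(lengths), total, n50


def contigs_to_records(contigs: Sequence[Contig]):
    from .seqio import SeqRecord

    return [SeqRecord(c.id, c.sequence) for c in contigs]
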