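"""Post-iteration finishing: scaffold, gap-fill, circularize, annotate.

Contigs from the iterative loop are validated and ordered/oriented
against the closest non-conspecific guide reference, merged into a
guide-projected consensus, gap-filled from the raw reads with a small
overlap-layout-consensus step, circularized by terminal-overlap
trimming, and annotated by projecting the guide's features through
local alignments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .assemble import Contig
from .recruit import (
    AlignParams,
    AlignmentHit,
    SeedIndex,
    align_sequence,
    build_index,
    decode,
    encode,
)
from .seqio import Annotation, Feature, Read, SeqRecord, revcomp

logger = logging.getLogger(__name__)

INVERTEBRATE_MITO_TABLE = 5
_TABLE5 = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE]


class NoMitochondrialContigs(ValueError):
    pass


@dataclass
class Placement:
    contig_id: str
    strand: str
    guide_start: int
    guide_end: int
    contig_start: int
    contig_end: int


@dataclass
class Scaffold:
    guide_reference_id: str
    guide_length: int
    placed: List[Placement]
    gaps: List[Tuple[int, int]]
    merged_sequence: str
    rejected_contig_ids: List[str] = field(default_factory=list)


@dataclass
class Mitogenome:
    sequence: str
    circular: bool
    annotation: Optional[Annotation] = None
    rotation_anchor: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScaffoldParams:
    min_identity: float = 0.70  # contig validation vs guide
    min_contig_coverage: float = 0.30
    merge_identity: float = 0.98  # overlapping placements must agree this well
    min_new_bases: int = 50  # secondary placements must add novel contig coverage


def _project_hit(hit: AlignmentHit, query_len: int) -> Tuple[int, int]:
    """Extend a local hit's guide interval by the clipped query ends."""
    if hit.strand == "+":
        start = hit.ref_start - hit.read_start
        end = hit.ref_end + (query_len - hit.read_end)
    else:
        start = hit.ref_start - (query_len - hit.read_end)
        end = hit.ref_end + hit.read_start
    return start, end


def scaffold_contigs(
    contigs: Sequence[Contig],
    guide: SeqRecord,
    align_p: Optional[AlignParams] = None,
    params: Optional[ScaffoldParams] = None,
) -> Scaffold:
    """Order, orient and merge contigs on the guide.

    A contig joins the scaffold only if its best hit identity and its
    aligned coverage pass the validation thresholds; everything else is
    listed in ``rejected_contig_ids`` for leakage triage.  Overlapping
    agreeing placements are merged by per-column majority (ties go to the
    base from the contig with higher mean k-mer coverage); a conflicting
    overlap is resolved in favor of the higher-scoring placement.
    """
    align_p = align_p or AlignParams()
    sp = params or ScaffoldParams()
    index = build_index([guide], align_p.k)
    L = len(guide.sequence)

    cov_by_contig: Dict[str, Contig] = {c.id: c for c in contigs}
    candidates: List[Tuple[AlignmentHit, Contig]] = []
    rejected: List[str] = []
    for c in contigs:
        hits = align_sequence(c.sequence, c.id, index, align_p)
        hits = [h for h in hits if h.identity >= sp.min_identity]
        if not hits:
            rejected.append(c.id)
            continue
        covered = np.zeros(len(c.sequence), dtype=bool)
        for h in hits:
            covered[h.read_start : h.read_end] = True
        if covered.mean() < sp.min_contig_coverage:
            rejected.append(c.id)
            continue
        # greedy supplementary-hit selection: keep hits adding novel contig bases
        taken = np.zeros(len(c.sequence), dtype=bool)
        for h in hits:  # already sorted score-desc
            novel = int((~taken[h.read_start : h.read_end]).sum())
            need = min(sp.min_new_bases, h.read_end - h.read_start)
            if not taken.any() or novel >= need:
                candidates.append((h, c))
                taken[h.read_start : h.read_end] = True
    if not candidates:
        raise NoMitochondrialContigs("no mitochondrial contigs")

    candidates.sort(key=lambda hc: (-hc[0].score, hc[0].reference_id, hc[0].ref_start))
    counts = np.zeros((4, L), dtype=np.int32)
    bestcov = np.zeros((4, L), dtype=np.float64)
    covered = np.zeros(L, dtype=bool)
    placements: List[Placement] = []
    for hit, contig in candidates:
        qs, qe = hit.read_start, hit.read_end
        gs, ge = hit.ref_start, hit.ref_end
        if hit.strand == "+":
            sub = contig.sequence[qs:qe]
        else:
            sub = revcomp(contig.sequence[qs:qe])
        enc = encode(sub)
        if len(enc) != ge - gs:
            continue  # gapped projection not representable; skip conservative
        # conflict check against current consensus over already-covered columns
        ov = covered[gs:ge]
        if ov.sum() >= 20:
            cons = np.argmax(counts[:, gs:ge], axis=0)
            agree = (cons[ov] == enc[ov]).mean()
            if agree < sp.merge_identity:
                continue  # lower-scoring conflicting placement dropped
        novel = ~ov
        cols = np.arange(gs, ge)
        valid = enc < 4
        counts[enc[valid], cols[valid]] += 1
        w = contig.mean_kmer_coverage
        sel = bestcov[enc[valid], cols[valid]] < w
        bestcov[enc[valid][sel], cols[valid][sel]] = w
        covered[gs:ge] = True
        # record the novel (non-overlapping) contiguous runs as placements
        for rs, re_ in _runs(novel):
            placements.append(
                Placement(contig.id, hit.strand, gs + rs, gs + re_, qs + rs, qs + re_)
            )
    gaps = _runs(~covered)
    # consensus: majority per column, ties -> base from higher-coverage contig
    cons_idx = np.zeros(L, dtype=np.int64)
    maxc = counts.max(axis=0)
    for j in np.nonzero(covered)[0]:
        col = counts[:, j]
        tied = np.nonzero(col == maxc[j])[0]
        if len(tied) == 1:
            cons_idx[j] = tied[0]
        else:
            cons_idx[j] = tied[np.argmax(bestcov[tied, j])]
    seq = np.where(covered, cons_idx, 4)
    merged = decode(seq.astype(np.uint8))
    placements.sort(key=lambda pl: (pl.guide_start, pl.contig_id))
    return Scaffold(guide.id, L, placements, gaps, merged, rejected)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True, half-open."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# Gap filling


@dataclass
class GapFillParams:
    flank: int = 100
    min_overlap: int = 20
    overlap_identity: float = 0.95
    bridge_identity: float = 0.98
    bridge_len: int = 20
    relaxed_min_score_a: float = 15.0
    offset_slack: int = 3


def _consensus_of(votes: np.ndarray) -> np.ndarray:
    out = np.argmax(votes, axis=0).astype(np.uint8)
    out[votes.sum(axis=0) == 0] = 4
    return out


def _best_overlap(ca: np.ndarray, oa: int, cb: np.ndarray, ob: int, gp: GapFillParams):
    """Best-scoring suffix/prefix overlap of consensus b onto consensus a.

    Offsets hint the layout; the true shift is searched within
    ``offset_slack`` of the hint.  Returns (score, rel_offset) or None.
    """
    nominal = ob - oa
    best = None
    for rel in range(nominal - gp.offset_slack, nominal + gp.offset_slack + 1):
        s = max(0, rel)
        e = min(len(ca), rel + len(cb))
        if e - s < gp.min_overlap:
            continue
        x = ca[s:e]
        y = cb[s - rel : e - rel]
        ok = (x < 4) & (y < 4)
        n_ok = int(ok.sum())
        if n_ok < gp.min_overlap:
            continue
        ident = float((x[ok] == y[ok]).sum()) / n_ok
        if ident < gp.overlap_identity:
            continue
        score = ident * (e - s)
        if best is None or score > best[0]:
            best = (score, rel)
    return best


class _Piece:
    __slots__ = ("votes", "offset", "cons")

    def __init__(self, votes: np.ndarray, offset: int):
        self.votes = votes
        self.offset = offset
        self.cons = _consensus_of(votes)


def _olc_pieces(seqs_offsets: List[Tuple[np.ndarray, int]], gp: GapFillParams, max_reads: int = 250):
    """Greedy overlap-layout-consensus over offset-hinted oriented reads.

    Left-to-right sweeps merging each piece into its best-overlapping
    neighbor until a fixed point; returns (votes, offset) pieces.
    """
    seqs_offsets = sorted(seqs_offsets, key=lambda t: t[1])
    if len(seqs_offsets) > max_reads:
        # deterministic even thinning keeps the layout spanning the region
        step = len(seqs_offsets) / max_reads
        seqs_offsets = [seqs_offsets[int(i * step)] for i in range(max_reads)]
    pieces: List[_Piece] = []
    for enc, off in seqs_offsets:
        votes = np.zeros((4, len(enc)), dtype=np.int32)
        valid = enc < 4
        votes[enc[valid], np.nonzero(valid)[0]] += 1
        pieces.append(_Piece(votes, off))
    changed = True
    while changed and len(pieces) > 1:
        changed = False
        pieces.sort(key=lambda p: p.offset)
        out = [pieces[0]]
        for nxt in pieces[1:]:
            cur = out[-1]
            ov = None
            if nxt.offset - (cur.offset + cur.votes.shape[1]) <= gp.offset_slack:
                ov = _best_overlap(cur.cons, cur.offset, nxt.cons, nxt.offset, gp)
            if ov is None:
                out.append(nxt)
                continue
            _, rel = ov
            lo = min(0, rel)
            hi = max(cur.votes.shape[1], rel + nxt.votes.shape[1])
            votes = np.zeros((4, hi - lo), dtype=np.int32)
            votes[:, -lo : -lo + cur.votes.shape[1]] += cur.votes
            votes[:, rel - lo : rel - lo + nxt.votes.shape[1]] += nxt.votes
            out[-1] = _Piece(votes, cur.offset + lo)
            changed = True
        pieces = out
    return [(p.votes, p.offset) for p in pieces]


def fill_gaps(
    scaffold: Scaffold,
    all_reads: Sequence[Read],
    guide: SeqRecord,
    align_p: Optional[AlignParams] = None,
    params: Optional[GapFillParams] = None,
) -> Scaffold:
    """Fill scaffold gaps from raw reads recruited near each gap.

    Reads aligning (relaxed score threshold) within gap +/- flank are
    oriented to the guide's plus strand and assembled by a greedy
    overlap-layout-consensus step; the patch is spliced in only when it
    bridges both flanks at high identity.  Unfillable gaps remain N.
    """
    if not scaffold.gaps:
        return scaffold
    gp = params or GapFillParams()
    base = align_p or AlignParams()
    relaxed = AlignParams(
        k=base.k, seed_mismatches=base.seed_mismatches, match=base.match,
        mismatch=base.mismatch, gap_open=base.gap_open, gap_extend=base.gap_extend,
        min_score_a=gp.relaxed_min_score_a, min_score_b=base.min_score_b,
    )
    index = build_index([guide], relaxed.k)
    placed_reads: List[Tuple[int, int, np.ndarray]] = []  # (start, end, oriented enc)
    for r in all_reads:
        hits = align_sequence(r.sequence, r.id, index, relaxed)
        if not hits:
            continue
        h = hits[0]
        s, e = _project_hit(h, len(r.sequence))
        enc = encode(r.sequence if h.strand == "+" else revcomp(r.sequence))
        placed_reads.append((s, e, enc))
    placed_reads.sort(key=lambda t: t[0])
    starts = np.array([t[0] for t in placed_reads], dtype=np.int64)
    ends = np.array([t[1] for t in placed_reads], dtype=np.int64)

    merged = list(scaffold.merged_sequence)
    menc = encode(scaffold.merged_sequence)
    remaining: List[Tuple[int, int]] = []
    for gs, ge in scaffold.gaps:
        lo, hi = gs - gp.flank, ge + gp.flank
        sel = np.nonzero((ends > lo) & (starts < hi))[0]
        if len(sel) == 0:
            remaining.append((gs, ge))
            continue
        seqs = [(placed_reads[i][2], int(starts[i])) for i in sel]
        pieces = _olc_pieces(seqs, gp)
        patch = None
        for votes, off in pieces:
            cons = _consensus_of(votes)
            span0, span1 = off, off + len(cons)
            lb = min(gp.bridge_len, gs)
            rb = min(gp.bridge_len, scaffold.guide_length - ge)
            if span0 > gs - lb or span1 < ge + rb:
                continue
            if np.any(cons[gs - off : ge - off] == 4):
                continue
            ok = True
            if lb >= gp.min_overlap or (lb > 0 and lb >= gp.bridge_len):
                fl = menc[gs - lb : gs]
                pl = cons[gs - lb - off : gs - off]
                good = (fl < 4) & (pl < 4)
                if good.sum() == 0 or (fl[good] == pl[good]).mean() < gp.bridge_identity:
                    ok = False
            if rb >= gp.min_overlap or (rb > 0 and rb >= gp.bridge_len):
                fr = menc[ge : ge + rb]
                pr = cons[ge - off : ge + rb - off]
                good = (fr < 4) & (pr < 4)
                if good.sum() == 0 or (fr[good] == pr[good]).mean() < gp.bridge_identity:
                    ok = False
            if ok:
                patch = decode(cons[gs - off : ge - off])
                break
        if patch is None:
            remaining.append((gs, ge))
        else:
            merged[gs:ge] = list(patch)
    new_seq = "".join(merged)
    return Scaffold(
        scaffold.guide_reference_id,
        scaffold.guide_length,
        scaffold.placed,
        remaining,
        new_seq,
        scaffold.rejected_contig_ids,
    )


# ---------------------------------------------------------------------------
# Circularization


def circularize(
    scaffold: Union[Scaffold, str],
    guide: Optional[SeqRecord] = None,
    guide_annotation: Optional[Annotation] = None,
    anchor: Optional[str] = None,
    min_overlap: int = 50,
    min_identity: float = 0.99,
    max_overlap: int = 600,
    align_p: Optional[AlignParams] = None,
) -> Mitogenome:
    """Trim terminal self-overlap and rotate to the anchor gene.

    Requires gap-free sequence ends; with no detectable terminal overlap
    the molecule is returned linear with a warning.
    """
    seq = scaffold if isinstance(scaffold, str) else scaffold.merged_sequence
    L = len(seq)
    if "N" in seq[:min_overlap] or "N" in seq[-min_overlap:]:
        warnings.warn("scaffold ends contain gaps; cannot circularize", stacklevel=2)
        return Mitogenome(seq, circular=False)
    enc = encode(seq)
    found = 0
    for t in range(min(max_overlap, L // 2), min_overlap - 1, -1):
        a, b = enc[:t], enc[-t:]
        good = (a < 4) & (b < 4)
        if good.sum() >= min_overlap and (a[good] == b[good]).mean() >= min_identity:
            found = t
            break
    if not found:
        warnings.warn("no terminal overlap detected; returning linear molecule", stacklevel=2)
        return Mitogenome(seq, circular=False)
    seq = seq[: L - found]
    mito = Mitogenome(seq, circular=True)
    if guide is not None and guide_annotation is not None:
        feats = sorted(
            (f for f in guide_annotation.features if not f.absent),
            key=lambda f: f.start,
        )
        if feats:
            anchor_feat = guide_annotation.get(anchor) if anchor else feats[0]
            mito = rotate_to_anchor(mito, anchor_feat, guide, align_p)
    return mito


def rotate_to_anchor(
    mito: Mitogenome,
    feature: Feature,
    guide: SeqRecord,
    align_p: Optional[AlignParams] = None,
) -> Mitogenome:
    """Rotate a circular molecule so the anchor gene starts at 0 on +."""
    p = align_p or AlignParams()
    gseq = _feature_seq(guide.sequence, feature)
    L = len(mito.sequence)
    ext = mito.sequence + mito.sequence[: min(len(gseq) + 100, L)]
    index = build_index([SeqRecord("mito", ext)], p.k)
    hits = align_sequence(gseq, feature.gene_id, index, p)
    if not hits:
        warnings.warn(f"anchor gene {feature.gene_id!r} not located; no rotation", stacklevel=2)
        return mito
    h = hits[0]
    s, e = _project_hit(h, len(gseq))
    seq = mito.sequence
    if h.strand == "-":
        seq = revcomp(seq)
        s = L - (e % L if e % L else L)
        if s < 0:
            s += L
    s %= L
    seq = seq[s:] + seq[:s]
    return Mitogenome(seq, True, mito.annotation, feature.gene_id)


# ---------------------------------------------------------------------------
# Annotation transfer and ORF checking


def _feature_seq(genome: str, f: Feature) -> str:
    if f.wrap:
        seg = genome[f.start :] + genome[: f.end]
    else:
        seg = genome[f.start : f.end]
    return revcomp(seg) if f.strand == "-" else seg


_STOPS = set(_TABLE5.stop_codons)
_STARTS = set(_TABLE5.start_codons)


def transfer_annotation(
    mito: Union[Mitogenome, str],
    guide_annotation: Annotation,
    guide_seq: Union[SeqRecord, str],
    align_p: Optional[AlignParams] = None,
    snap_window: int = 6,
) -> Annotation:
    """Project each guide feature onto the assembled molecule independently.

    PCG boundaries are snapped to the nearest in-frame start/stop codon
    within +/- ``snap_window`` bases; features that cannot be located are
    flagged absent.
    """
    p = align_p or AlignParams()
    if isinstance(mito, Mitogenome):
        seq, circular = mito.sequence, mito.circular
    else:
        seq, circular = mito, True
    gseq = guide_seq.sequence if isinstance(guide_seq, SeqRecord) else guide_seq
    L = len(seq)
    ext = seq + (seq[: min(600, L)] if circular else "")
    index = build_index([SeqRecord("mito", ext)], p.k)
    features: List[Feature] = []
    absent: List[str] = []
    for f in guide_annotation.features:
        if f.absent:
            absent.append(f.gene_id)
            continue
        fseq = _feature_seq(gseq, f)
        hits = align_sequence(fseq, f.gene_id, index, p)
        if not hits or hits[0].identity < 0.5:
            absent.append(f.gene_id)
            features.append(Feature(f.gene_id, f.type, 0, 0, f.strand, absent=True))
            continue
        h = hits[0]
        s, e = _project_hit(h, len(fseq))
        s, e = max(s, 0), min(e, len(ext))
        strand = "+" if h.strand == "+" else "-"
        if f.type == "PCG":
            s, e = _snap_orf(ext, s, e, strand, snap_window)
        if s >= L:
            s, e = s - L, e - L
        wrap = e > L
        if wrap:
            features.append(Feature(f.gene_id, f.type, s, e - L, strand, wrap=True))
        else:
            features.append(Feature(f.gene_id, f.type, s, e, strand))
    return Annotation(features, L, circular, absent=absent)


def _snap_orf(seq: str, s: int, e: int, strand: str, window: int) -> Tuple[int, int]:
    """Snap CDS bounds to an in-frame start/stop within the window."""
    deltas = [0, -3, 3, -6, 6][: 2 * (window // 3) + 1]
    if strand == "+":
        for d in deltas:
            if 0 <= s + d <= len(seq) - 3 and seq[s + d : s + d + 3] in _STARTS:
                s = s + d
                break
        for d in deltas:
            if 3 <= e + d <= len(seq) and seq[e + d - 3 : e + d] in _STOPS:
                e = e + d
                break
    else:
        # gene 5' end is at e on the forward strand
        for d in deltas:
            if 3 <= e + d <= len(seq) and revcomp(seq[e + d - 3 : e + d]) in _STARTS:
                e = e + d
                break
        for d in deltas:
            if 0 <= s + d <= len(seq) - 3 and revcomp(seq[s + d : s + d + 3]) in _STOPS:
                s = s + d
                break
    return s, e


@dataclass
class OrfRow:
    gene_id: str
    has_start: bool
    internal_stop_count: int
    frame_intact: bool


@dataclass
class OrfReport:
    rows: List[OrfRow]

    @property
    def all_clean(self) -> bool:
        return all(r.internal_stop_count == 0 for r in self.rows)


def check_orfs(
    mito: Union[Mitogenome, str],
    annotation: Annotation,
    table: int = INVERTEBRATE_MITO_TABLE,
) -> OrfReport:
    seq = mito.sequence if isinstance(mito, Mitogenome) else mito
    tab = CodonTable.unambiguous_dna_by_id[table]
    rows = []
    for f in annotation.by_type("PCG"):
        cds = _feature_seq(seq, f)
        frame_intact = len(cds) % 3 == 0
        trimmed = cds[: len(cds) - len(cds) % 3]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aa = str(Seq(trimmed).translate(table=table))
        internal = aa[:-1].count("*") if aa else 0
        has_start = cds[:3] in set(tab.start_codons)
        rows.append(OrfRow(f.gene_id, has_start, internal, frame_intact))
    return OrfReport(rows)


# ---------------------------------------------------------------------------
# High-level driver


def choose_guide(
    contigs: Sequence[Contig],
    candidates: Sequence[SeqRecord],
    align_p: Optional[AlignParams] = None,
) -> SeqRecord:
    """Pick the candidate with the highest total contig alignment score."""
    p = align_p or AlignParams()
    best = None
    for cand in candidates:
        index = build_index([cand], p.k)
        total = 0
        for c in contigs:
            hits = align_sequence(c.sequence, c.id, index, p)
            if hits:
                total += hits[0].score
        if best is None or total > best[0] or (total == best[0] and cand.id < best[1].id):
            best = (total, cand)
    if best is None:
        raise ValueError("no guide candidates supplied")
    return best[1]


def finish(
    contigs: Sequence[Contig],
    reads: Sequence[Read],
    guide: SeqRecord,
    guide_annotation: Annotation,
    align_p: Optional[AlignParams] = None,
    circular_extension: int = 150,
) -> Tuple[Mitogenome, dict]:
    """Scaffold -> fill gaps -> circularize -> annotate -> ORF check."""
    align_p = align_p or AlignParams()
    gseq = guide.sequence
    ext_guide = SeqRecord(guide.id, gseq + gseq[:circular_extension])
    scaffold = scaffold_contigs(contigs, ext_guide, align_p)
    scaffold = fill_gaps(scaffold, reads, ext_guide, align_p)
    mito = circularize(scaffold, guide, guide_annotation, align_p=align_p)
    annotation = transfer_annotation(mito, guide_annotation, gseq, align_p)
    mito.annotation = annotation
    orfs = check_orfs(mito, annotation)
    report = {
        "circular": mito.circular,
        "length": len(mito.sequence),
        "n_gaps": len(scaffold.gaps),
        "gap_bases": int(sum(e - s for s, e in scaffold.gaps)),
        "rejected_contigs": scaffold.rejected_contig_ids,
        "absent_features": annotation.absent,
        "orfs_clean": orfs.all_clean,
        "orf_rows": [vars(r) for r in orfs.rows],
    }
    if not orfs.all_clean:
        logger.warning("internal stop codons detected in transferred PCGs")
    return mito, report
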