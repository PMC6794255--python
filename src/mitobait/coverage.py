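"""Per-position and per-gene coverage over the final mitogenome.

Each read contributes depth over the reference interval of its single
best alignment; circular molecules are handled by aligning against a
junction-extended copy and folding positions back.  Low-coverage runs
mirror the below-4x flagging used for the hard-to-assemble regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .finishing import Mitogenome
from .recruit import AlignParams, align_sequence, build_index
from .seqio import Annotation, Read, SeqRecord


@dataclass
class CoverageProfile:
    per_position: np.ndarray  # int depth, length = mitogenome length
    total_aligned_bases: int
    cap_for_plots: int = 5000

    def __len__(self) -> int:
        return len(self.per_position)

    def capped(self) -> np.ndarray:
        """Rendering copy only; stored depths are never capped."""
        return np.minimum(self.per_position, self.cap_for_plots)


@dataclass
class GeneCoverage:
    gene_id: str
    type: str
    mean_depth: float
    min_depth: int
    fraction_below_threshold: float


def coverage_profile(
    reads: Sequence[Read],
    mito: Union[Mitogenome, SeqRecord],
    align_p: Optional[AlignParams] = None,
) -> CoverageProfile:
    p = align_p or AlignParams()
    if isinstance(mito, Mitogenome):
        seq, circular = mito.sequence, mito.circular
    else:
        seq, circular = mito.sequence, True
    L = len(seq)
    max_rl = max((len(r) for r in reads), default=0)
    ext = min(max_rl, L) if circular else 0
    index = build_index([SeqRecord("mito", seq + seq[:ext] if ext else seq)], p.k)
    depth = np.zeros(L, dtype=np.int64)
    total = 0
    for r in reads:
        hits = align_sequence(r.sequence, r.id, index, p)
        if not hits:
            continue
        h = hits[0]  # single best alignment only
        s, e = h.ref_start, h.ref_end
        total += e - s
        if e <= L:
            depth[s:e] += 1
        else:  # wraps the origin of the circular molecule
            depth[s:L] += 1
            depth[: e - L] += 1
    return CoverageProfile(depth, total)


def per_gene_coverage(
    profile: CoverageProfile,
    annotation: Annotation,
    low_threshold: int = 4,
) -> List[GeneCoverage]:
    depth = profile.per_position
    L = len(depth)
    if annotation.seq_length > L:
        raise ValueError(
            f"annotation length {annotation.seq_length} exceeds profile length {L}"
        )
    rows = []
    for f in annotation.features:
        if f.absent:
            continue
        if not f.wrap and f.end > L:
            raise ValueError(f"feature {f.gene_id} outside profile")
        if f.wrap:
            d = np.concatenate([depth[f.start :], depth[: f.end]])
        else:
            d = depth[f.start : f.end]
        rows.append(
            GeneCoverage(
                f.gene_id,
                f.type,
                float(d.mean()),
                int(d.min()),
                float((d < low_threshold).mean()),
            )
        )
    return rows


def low_coverage_regions(
    profile: Union[CoverageProfile, np.ndarray],
    threshold: int = 4,
    min_run: int = 10,
) -> List[Tuple[int, int]]:
    """Maximal half-open runs of depth < threshold, at least min_run long."""
    depth = profile.per_position if isinstance(profile, CoverageProfile) else np.asarray(profile)
    low = depth < threshold
    if not low.any():
        return []
    d = np.diff(low.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if low[0]:
        starts.insert(0, 0)
    if low[-1]:
        ends.append(len(low))
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_run]


# ---------------------------------------------------------------------------
# Plain-text emitters


def write_bedgraph(profile: CoverageProfile, seqid: str, path: Union[str, Path]) -> None:
    depth = profile.per_position
    with open(path, "w") as fh:
        i = 0
        L = len(depth)
        while i < L:
            j = i + 1
            while j < L and depth[j] == depth[i]:
                j += 1
            fh.write(f"{seqid}\t{i}\t{j}\t{int(depth[i])}\n")
            i = j


def write_bed(intervals: Sequence[Tuple[int, int]], seqid: str, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{seqid}\t{s}\t{e}\n")


def read_bed(path: Union[str, Path]) -> List[Tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.split("\t")
            out.append((int(cols[1]), int(cols[2])))
    return out


def write_gene_coverage_tsv(rows: Sequence[GeneCoverage], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttype\tmean_depth\tmin_depth\tfraction_below_threshold\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.type}\t{r.mean_depth:.3f}\t{r.min_depth}"
                f"\t{r.fraction_below_threshold:.4f}\n"
            )
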