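"""Contig triage: target mitochondrial vs contaminant vs nuclear leakage.

Classification is nucleotide alignment against user-supplied local
databases with precedence target > contaminant > nuclear; anything with
no passing hit is unassigned.  The summary table mirrors the
count-(percentage) layout of the published leakage analysis: one decimal
place, two when the percentage is below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assemble import Contig
from .recruit import AlignParams, SeedIndex, align_sequence, build_index
from .seqio import SeqRecord

CLASSES = ("target", "contaminant", "nuclear", "unassigned")


@dataclass
class ContigCall:
    contig_id: str
    klass: str
    best_hit_db: Optional[str]
    identity: float
    coverage_of_contig: float


@dataclass
class LeakageReport:
    per_contig: List[ContigCall]
    summary: Dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.summary.values()) != self.total:
            raise ValueError("class counts must sum to total")


@dataclass
class LeakageThresholds:
    min_identity: float = 0.80
    min_contig_coverage: float = 0.30


def _db_match(
    seq: str, seq_id: str, index: Optional[SeedIndex], p: AlignParams
) -> Tuple[float, float]:
    """(best identity, fraction of contig covered by passing hits)."""
    if index is None:
        return 0.0, 0.0
    hits = align_sequence(seq, seq_id, index, p)
    if not hits:
        return 0.0, 0.0
    covered = np.zeros(len(seq), dtype=bool)
    for h in hits:
        covered[h.read_start : h.read_end] = True
    return max(h.identity for h in hits), float(covered.mean())


def classify_contigs(
    contigs: Sequence[Contig],
    target_ref: Sequence[SeqRecord],
    nuclear_db: Optional[Sequence[SeqRecord]] = None,
    contaminant_db: Optional[Sequence[SeqRecord]] = None,
    thresholds: Optional[LeakageThresholds] = None,
    align_p: Optional[AlignParams] = None,
) -> LeakageReport:
    th = thresholds or LeakageThresholds()
    p = align_p or AlignParams()
    indices: List[Tuple[str, Optional[SeedIndex]]] = []
    for name, db in (("target", target_ref), ("contaminant", contaminant_db), ("nuclear", nuclear_db)):
        indices.append((name, build_index(db, p.k) if db else None))
    per_contig: List[ContigCall] = []
    counts = {c: 0 for c in CLASSES}
    for c in contigs:
        call = ContigCall(c.id, "unassigned", None, 0.0, 0.0)
        for name, index in indices:  # precedence order
            ident, cov = _db_match(c.sequence, c.id, index, p)
            if ident >= th.min_identity and cov >= th.min_contig_coverage:
                call = ContigCall(c.id, name, name, ident, cov)
                break
            if ident > call.identity:
                call.identity, call.coverage_of_contig, call.best_hit_db = ident, cov, name
        per_contig.append(call)
        counts[call.klass] += 1
    return LeakageReport(per_contig, counts, len(per_contig))


def format_count_pct(count: int, total: int) -> str:
    """'count (pct%)' with one decimal, two when the percentage is < 1%."""
    if total <= 0:
        return f"{count:,} (0.0%)"
    pct = 100.0 * count / total
    cell = f"{pct:.2f}%" if pct < 1.0 else f"{pct:.1f}%"
    return f"{count:,} ({cell})"


def summarize_leakage(report: LeakageReport) -> List[Tuple[str, str]]:
    """Table rows: Total, target, contaminant, nuclear (count + percentage)."""
    rows = [("Total", f"{report.total:,}")]
    labels = {
        "target": "Target mitochondrial contigs",
        "contaminant": "Contaminant leakage",
        "nuclear": "Nuclear leakage",
    }
    for klass in ("target", "contaminant", "nuclear"):
        rows.append((labels[klass], format_count_pct(report.summary.get(klass, 0), report.total)))
    if report.summary.get("unassigned"):
        rows.append(("Unassigned", format_count_pct(report.summary["unassigned"], report.total)))
    return rows


def summary_from_counts(
    target: int, contaminant: int, nuclear: int, unassigned: int = 0
) -> List[Tuple[str, str]]:
    """Summary rows straight from class counts (no per-contig records)."""
    total = target + contaminant + nuclear + unassigned
    report = LeakageReport(
        per_contig=[],
        summary={
            "target": target,
            "contaminant": contaminant,
            "nuclear": nuclear,
            "unassigned": unassigned,
        },
        total=total,
    )
    return summarize_leakage(report)


def percentage_of(count: int, total: int) -> float:
    """The numeric percentage exactly as printed in the summary cell."""
    cell = format_count_pct(count, total)
    return float(cell.split("(")[1].rstrip("%)"))
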