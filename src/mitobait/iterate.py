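"""Orchestration of the map -> assemble loop with plateau detection.

Each iteration recruits the FULL read set: iteration 1 against the
user-supplied (non-conspecific) references, every later iteration against
the contigs of the previous one, which fully replace the reference set.
The loop stops at ``max_iterations`` or as soon as the recruited-read
fraction is stationary (early stopping can be disabled to mimic a fixed
iteration count).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

from .assemble import AssemblyParams, Contig, assemble, contig_stats, contigs_to_records
from .recruit import AlignParams, build_index, filter_reads, recruit_reads
from .seqio import Read, SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class IterationStats:
    iteration: int  # 1-based
    recruited_reads: int
    recruited_fraction: float
    n_contigs: int
    mean_contig_len: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.recruited_fraction <= 1.0:
            raise ValueError("recruited_fraction must be in [0, 1]")


@dataclass
class LoopParams:
    max_iterations: int = 10
    plateau_rel_tol: float = 0.001  # of total reads
    plateau_patience: int = 2
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.plateau_rel_tol < 0:
            raise ValueError("plateau tolerance must be >= 0")


def detect_plateau(stats: Sequence[IterationStats], loop_p: LoopParams) -> bool:
    """True iff the last ``plateau_patience`` deltas of recruited_fraction
    are each below ``plateau_rel_tol`` in magnitude."""
    if not stats:
        raise ValueError("stats must be non-empty")
    n = loop_p.plateau_patience
    if len(stats) < n + 1:
        return False
    fracs = [s.recruited_fraction for s in stats[-(n + 1):]]
    return all(abs(b - a) < loop_p.plateau_rel_tol for a, b in zip(fracs, fracs[1:]))


def run_iterations(
    reads: Sequence[Read],
    initial_refs: Sequence[SeqRecord],
    align_p: Optional[AlignParams] = None,
    asm_p: Optional[AssemblyParams] = None,
    loop_p: Optional[LoopParams] = None,
    on_iteration: Optional[Callable[[IterationStats, List[Contig]], None]] = None,
) -> Tuple[List[Contig], List[IterationStats], bool]:
    """Run the iterative baiting loop.

    Returns (contigs of the last completed iteration, per-iteration stats,
    converged flag).  ``on_iteration`` is invoked after every iteration so
    interrupted runs remain inspectable.
    """
    align_p = align_p or AlignParams()
    asm_p = asm_p or AssemblyParams()
    loop_p = loop_p or LoopParams()
    if not initial_refs:
        raise ValueError("initial reference set must be non-empty")
    total = len(reads)
    refs: Sequence[SeqRecord] = initial_refs
    stats: List[IterationStats] = []
    contigs: List[Contig] = []
    prev_recruited = 0
    for it in range(1, loop_p.max_iterations + 1):
        t0 = time.perf_counter()
        index = build_index(refs, align_p.k)
        recruited_ids, _ = recruit_reads(reads, index, align_p)
        recruited = filter_reads(reads, recruited_ids)
        if not recruited:
            logger.warning(
                "iteration %d recruited zero reads; terminating without assembly", it
            )
            stats.append(IterationStats(it, 0, 0.0, 0, 0.0))
            if on_iteration:
                on_iteration(stats[-1], [])
            return [], stats, False
        if len(recruited) < prev_recruited:
            logger.warning(
                "iteration %d recruited fewer reads (%d) than iteration %d (%d)",
                it, len(recruited), it - 1, prev_recruited,
            )
        prev_recruited = len(recruited)
        contigs = assemble(recruited, asm_p, iteration=it)
        n, mean_len, _, _ = contig_stats(contigs)
        st = IterationStats(it, len(recruited), len(recruited) / total if total else 0.0, n, mean_len)
        stats.append(st)
        logger.info(
            "iteration %d: %d/%d reads recruited, %d contigs (mean %.0f bp) in %.1fs",
            it, st.recruited_reads, total, n, mean_len, time.perf_counter() - t0,
        )
        if on_iteration:
            on_iteration(st, contigs)
        if not contigs:
            logger.warning("iteration %d produced no contigs; terminating", it)
            return [], stats, False
        if loop_p.early_stop and detect_plateau(stats, loop_p):
            return contigs, stats, True
        refs = contigs_to_records(contigs)
    return contigs, stats, detect_plateau(stats, loop_p)


def write_stats_tsv(stats: Sequence[IterationStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\trecruited\tfraction\tn_contigs\tmean_len\n")
        for s in stats:
            fh.write(
                f"{s.iteration}\t{s.recruited_reads}\t{s.recruited_fraction:.6f}"
                f"\t{s.n_contigs}\t{s.mean_contig_len:.1f}\n"
            )
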