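"""Sequence I/O for the pipeline: FASTQ/FASTA/GFF3 plus quality trimming.

Coordinates are 0-based half-open everywhere in memory; GFF3 on disk is
1-based inclusive and converted at the boundary.  FASTQ qualities are
Sanger Phred+33.  Gzip is handled transparently for FASTQ by file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

DNA_ALPHABET = frozenset("ACGTN")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control_region")

# GFF3 column-3 terms used on disk for each in-memory feature type.
_GFF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control_region": "D_loop"}
_GFF_TYPE_INV = {v: k for k, v in _GFF_TYPE.items()}


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input, naming the failing record index."""


@dataclass
class TruthLabel:
    """Origin of a simulated read: class plus source coordinates."""

    origin: str  # "mito" | "nuclear" | "contaminant"
    source: str  # gene id, transcript id, or "polycistron"/"genome"
    start: int = 0
    end: int = 0
    strand: str = "+"


@dataclass
class Read:
    id: str
    sequence: str
    qualities: Sequence[int]
    mate: int = 0  # 0 = unpaired, 1/2 = mate number
    truth_label: Optional[TruthLabel] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SeqRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    gene_id: str
    type: str
    start: int
    end: int
    strand: str
    wrap: bool = False
    absent: bool = False

    def length(self, seq_length: int) -> int:
        if self.wrap:
            return (seq_length - self.start) + self.end
        return self.end - self.start


@dataclass
class Annotation:
    features: list
    seq_length: int
    circular: bool = True
    absent: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"duplicate feature id {f.gene_id!r}")
            seen.add(f.gene_id)
            if f.absent:
                continue
            if f.wrap:
                if not (0 <= f.end <= f.start <= self.seq_length):
                    raise ValueError(f"feature {f.gene_id}: bad wrap coordinates")
            elif not (0 <= f.start < f.end <= self.seq_length):
                raise ValueError(
                    f"feature {f.gene_id}: 0 <= {f.start} < {f.end} <= "
                    f"{self.seq_length} violated"
                )

    def by_type(self, ftype: str) -> list:
        return [f for f in self.features if f.type == ftype and not f.absent]

    def get(self, gene_id: str) -> Feature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)


@dataclass
class TrimParams:
    """Quality-trimming rules (leading/trailing clip + 5'->3' sliding window)."""

    leading_q: int = 3
    trailing_q: int = 3
    window_len: int = 25
    window_q: float = 33.0
    min_len: int = 45

    def __post_init__(self) -> None:
        if min(self.leading_q, self.trailing_q, self.window_len) < 0:
            raise ValueError("trim thresholds must be >= 0")
        if self.min_len <= 0:
            raise ValueError("min_len must be > 0")


def default_trim_params(read_length: int) -> TrimParams:
    """Two stock parameter sets: MINLEN 45 for short (<=60 nt) reads, 90 otherwise."""
    return TrimParams(min_len=45 if read_length <= 60 else 90)


DISCARD = None  # quality_trim sentinel: reads below min_len map to DISCARD


def quality_trim(read: Read, p: TrimParams) -> Optional[Read]:
    """Trim a read; returns DISCARD (None) when the survivor is < min_len.

    Order: leading clip, trailing clip, then a 5'->3' sliding window that
    cuts at the start of the first window whose mean quality is below
    ``window_q``, followed by a final trailing clip so the operation is
    idempotent.
    """
    q = read.qualities
    start, end = 0, len(q)
    while start < end and q[start] < p.leading_q:
        start += 1
    while end > start and q[end - 1] < p.trailing_q:
        end -= 1
    w = p.window_len
    if w > 0 and end - start >= w:
        acc = sum(q[start : start + w])
        i = start
        while True:
            if acc < p.window_q * w:
                end = i
                break
            if i + w >= end:
                break
            acc += q[i + w] - q[i]
            i += 1
    while end > start and q[end - 1] < p.trailing_q:
        end -= 1
    if end - start < p.min_len:
        return DISCARD
    if start == 0 and end == len(q):
        return read
    return replace(read, sequence=read.sequence[start:end], qualities=list(q[start:end]))


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq(handle: IO[str], mate: int = 0) -> Iterator[Read]:
    n = 0
    while True:
        lines = [handle.readline() for _ in range(4)]
        if not lines[0]:
            return
        if not lines[3]:
            raise FastqFormatError(f"truncated FASTQ record at record {n}")
        header = lines[0].rstrip("\n")
        seq = lines[1].strip().upper()
        plus = lines[2].rstrip("\n")
        qual = lines[3].strip()
        if not header.startswith("@") or not plus.startswith("+"):
            raise FastqFormatError(f"malformed FASTQ record at record {n}")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"sequence/quality length mismatch at record {n}"
            )
        rid = header[1:].split()[0] if len(header) > 1 else ""
        if not rid:
            raise FastqFormatError(f"empty read id at record {n}")
        m = mate
        if m == 0 and rid.endswith(("/1", "/2")):
            m = int(rid[-1])
            rid = rid[:-2]
        yield Read(rid, seq, [ord(c) - 33 for c in qual], mate=m)
        n += 1


def read_fastq(path: Union[str, Path], paired: bool = False) -> Iterator[Read]:
    """Stream Reads from a FASTQ file (interleaved if ``paired``).

    For paired data in two files use :func:`read_fastq_pair`.
    """
    with _open_text(path) as fh:
        if not paired:
            yield from _parse_fastq(fh)
            return
        prev = None
        for read in _parse_fastq(fh):
            if prev is None:
                prev = read
                continue
            if prev.id != read.id:
                raise FastqFormatError(
                    f"desynchronized mates: {prev.id!r} followed by {read.id!r}"
                )
            if prev.mate == 0:
                prev.mate, read.mate = 1, 2
            yield prev
            yield read
            prev = None
        if prev is not None:
            raise FastqFormatError(f"unpaired trailing read {prev.id!r}")


def read_fastq_pair(path1: Union[str, Path], path2: Union[str, Path]) -> Iterator[Read]:
    """Stream synchronized mates from two FASTQ files as (R1, R2, R1, ...)."""
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1, it2 = _parse_fastq(fh1, mate=1), _parse_fastq(fh2, mate=2)
        for r1 in it1:
            r2 = next(it2, None)
            if r2 is None:
                raise FastqFormatError(f"mate file ended early at read {r1.id!r}")
            if r1.id != r2.id:
                raise FastqFormatError(
                    f"desynchronized mates: {r1.id!r} vs {r2.id!r}"
                )
            yield r1
            yield r2
        if next(it2, None) is not None:
            raise FastqFormatError("second mate file has extra records")


def write_fastq(reads: Iterable[Read], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            rid = f"{r.id}/{r.mate}" if r.mate else r.id
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{rid}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> list:
    with _open_text(path) as fh:
        return [
            SeqRecord(title.split()[0], seq, " ".join(title.split()[1:]))
            for title, seq in SimpleFastaParser(fh)
        ]


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path], wrap: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.sequence), wrap):
                    fh.write(rec.sequence[i : i + wrap] + "\n")
            else:
                fh.write(rec.sequence + "\n")


# ---------------------------------------------------------------------------
# GFF3
#
# Wrap-around features (crossing the origin of a circular molecule) are
# written as two lines sharing the same ID attribute and read back as a
# single Feature with wrap=True.


def write_gff3(annotation: Annotation, path: Union[str, Path], seqid: str = "mito") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.seq_length}\n")
        circ = "true" if annotation.circular else "false"
        fh.write(
            f"{seqid}\tmitobait\tregion\t1\t{annotation.seq_length}\t.\t+\t.\t"
            f"ID=region0;Is_circular={circ}\n"
        )
        for f in annotation.features:
            if f.absent:
                continue
            gtype = _GFF_TYPE.get(f.type, f.type)
            if f.wrap:
                parts = [(f.start, annotation.seq_length), (0, f.end)]
            else:
                parts = [(f.start, f.end)]
            for s, e in parts:
                fh.write(
                    f"{seqid}\tmitobait\t{gtype}\t{s + 1}\t{e}\t.\t{f.strand}\t.\t"
                    f"ID={f.gene_id}\n"
                )


def read_gff3(path: Union[str, Path]) -> Annotation:
    seq_length = 0
    circular = True
    parts: dict = {}
    order: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                seq_length = int(line.split()[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"bad GFF3 line: {line!r}")
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise ValueError(f"GFF3 end < start on line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"feat{len(order)}")
            if cols[2] == "region":
                circular = attrs.get("Is_circular", "true") == "true"
                seq_length = max(seq_length, end)
                continue
            ftype = _GFF_TYPE_INV.get(cols[2], cols[2])
            entry = (start - 1, end, cols[6], ftype)
            if fid in parts:
                parts[fid].append(entry)
            else:
                parts[fid] = [entry]
                order.append(fid)
    features = []
    for fid in order:
        segs = parts[fid]
        if len(segs) == 1:
            s, e, strand, ftype = segs[0]
            features.append(Feature(fid, ftype, s, e, strand))
        else:
            # two segments sharing an ID: the origin-spanning convention
            segs = sorted(segs)
            strand, ftype = segs[0][2], segs[0][3]
            head = segs[0]  # starts at 0
            tail = segs[-1]  # ends at seq_length
            features.append(Feature(fid, ftype, tail[0], head[1], strand, wrap=True))
    return Annotation(features, seq_length, circular)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
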