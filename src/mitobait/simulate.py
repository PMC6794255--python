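"""Labeled synthetic mitogenomes, references and RNA-Seq read sets.

The generator emulates the statistical structure the pipeline has to
cope with: a circular 37-gene mitogenome with a repeat-rich control
region, polycistronic baseline coverage plus per-gene mature-transcript
expression with mature-tRNA depletion, nuclear transcripts (one carrying
a NUMT insert), an unrelated contaminant genome, substitution errors and
mutated/rearranged reference molecules.  Every read carries a truth
label.  A single seed drives named RNG substreams so outputs are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import Annotation, Feature, Read, SeqRecord, TruthLabel, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stop codons of the invertebrate mitochondrial code
_STOP_CODONS = {"TAA", "TAG"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]

# Default 37-gene layout: (name, type, length, strand).  Lengths are
# stylized but in the range typical of insect mitogenomes; PCG lengths are
# multiples of three.  The control region is last so its length absorbs
# whatever remains of the requested genome length.
DEFAULT_GENE_ORDER: List[Tuple[str, str, int, str]] = [
    ("trnI", "tRNA", 66, "+"), ("trnQ", "tRNA", 69, "-"), ("trnM", "tRNA", 68, "+"),
    ("nad2", "PCG", 1020, "+"), ("trnW", "tRNA", 67, "+"), ("trnC", "tRNA", 63, "-"),
    ("trnY", "tRNA", 65, "-"), ("cox1", "PCG", 1536, "+"), ("trnL2", "tRNA", 70, "+"),
    ("cox2", "PCG", 684, "+"), ("trnK", "tRNA", 71, "+"), ("trnD", "tRNA", 66, "+"),
    ("atp8", "PCG", 159, "+"), ("atp6", "PCG", 678, "+"), ("cox3", "PCG", 786, "+"),
    ("trnG", "tRNA", 65, "+"), ("nad3", "PCG", 351, "+"), ("trnA", "tRNA", 64, "+"),
    ("trnR", "tRNA", 65, "+"), ("trnN", "tRNA", 66, "+"), ("trnS1", "tRNA", 67, "+"),
    ("trnE", "tRNA", 68, "+"), ("trnF", "tRNA", 66, "-"), ("nad5", "PCG", 1716, "-"),
    ("trnH", "tRNA", 65, "-"), ("nad4", "PCG", 1338, "-"), ("nad4l", "PCG", 294, "-"),
    ("trnT", "tRNA", 64, "+"), ("trnP", "tRNA", 66, "-"), ("nad6", "PCG", 498, "+"),
    ("cob", "PCG", 1140, "+"), ("trnS2", "tRNA", 69, "+"), ("nad1", "PCG", 936, "-"),
    ("trnL1", "tRNA", 68, "-"), ("rrnL", "rRNA", 1300, "-"), ("trnV", "tRNA", 70, "-"),
    ("rrnS", "rRNA", 800, "-"),
]

# Stylized relative expression of mature transcripts (high cox/cob/rRNA,
# low atp8/nad4l); tRNA weights are further thinned by mature depletion.
DEFAULT_EXPRESSION: Dict[str, float] = {
    "cox1": 8.0, "cox2": 5.0, "cox3": 5.0, "cob": 6.0,
    "nad1": 3.5, "nad2": 3.5, "nad3": 2.0, "nad4": 4.0, "nad4l": 1.5,
    "nad5": 5.0, "nad6": 2.0, "atp6": 3.0, "atp8": 1.5,
    "rrnL": 12.0, "rrnS": 10.0,
    "control_region": 0.02,
}
DEFAULT_TRNA_EXPRESSION = 0.4


def tiny_gene_order(scale: float = 1.0) -> List[Tuple[str, str, int, str]]:
    """A shrunken 37-gene layout (~3.6 kb genome) for fast unit tests."""
    out = []
    for name, ftype, length, strand in DEFAULT_GENE_ORDER:
        if ftype == "PCG":
            length = max(90, (int(length * 0.12 * scale) // 3) * 3)
        elif ftype == "rRNA":
            length = max(120, int(length * 0.15 * scale))
        out.append((name, ftype, length, strand))
    return out


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 16000
    gene_order: Optional[List[Tuple[str, str, int, str]]] = None
    control_region_min: int = 400
    cr_repeat_len: int = 60
    cr_repeat_copies: int = 8
    spacer_len: int = 2
    read_length: int = 51
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    n_reads: int = 10000
    mito_fraction: float = 0.10
    nuclear_fraction: Optional[float] = None  # default: the remainder
    contaminant_fraction: float = 0.0
    per_gene_expression: Dict[str, float] = field(default_factory=dict)
    trna_expression: float = DEFAULT_TRNA_EXPRESSION
    polycistron_baseline: float = 15.0  # weight of the unprocessed full molecule
    trna_mature_depletion: float = 0.90
    error_rate: float = 0.0
    reference_divergence: float = 0.02
    n_nuclear_transcripts: int = 20
    numt_weight: float = 0.5
    nuclear_weight_sigma: float = 1.0  # lognormal sigma of transcript expression
    contaminant_genome_length: int = 40000
    base_quality: int = 38

    def __post_init__(self) -> None:
        fracs = self.mito_fraction + self.contaminant_fraction + (self.nuclear_fraction or 0.0)
        if fracs > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("mito_fraction", "contaminant_fraction", "trna_mature_depletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if any(w <= 0 for w in self.per_gene_expression.values()):
            raise ValueError("expression weights must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG substream derived from the single master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class TruthSet:
    true_mitogenome: SeqRecord
    true_annotation: Annotation


@dataclass
class ReadSet:
    reads: List[Read]
    truth: TruthSet
    nuclear_transcripts: List[SeqRecord]
    contaminant_genome: SeqRecord

    def labels(self) -> List[TruthLabel]:
        return [r.truth_label for r in self.reads]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """Start codon + non-stop codons + terminal stop; length % 3 == 0."""
    if length % 3 or length < 9:
        raise ValueError("PCG length must be a multiple of 3 and >= 9")
    n_mid = length // 3 - 2
    idx = rng.integers(0, len(_NONSTOP_CODONS), n_mid)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in idx) + "TAA"


def make_mitogenome(cfg: SimConfig) -> Tuple[SeqRecord, Annotation]:
    """Deterministic circular genome: 13 clean ORFs, 22 tRNAs, 2 rRNAs and
    a tandem-repeat control region filling the remaining length."""
    rng = cfg.rng("genome")
    order = cfg.gene_order or DEFAULT_GENE_ORDER
    gene_total = sum(length for _, _, length, _ in order)
    spacer_total = cfg.spacer_len * (len(order) + 1)
    cr_len = cfg.genome_length - gene_total - spacer_total
    if cr_len < cfg.control_region_min:
        raise ValueError(
            f"gene lengths ({gene_total} bp + spacers) exceed genome_length "
            f"{cfg.genome_length} minus the minimum control region"
        )
    parts: List[str] = []
    features: List[Feature] = []
    pos = 0
    for name, ftype, length, strand in order:
        if ftype == "PCG":
            gene = _random_orf(rng, length)
        else:
            gene = _random_dna(rng, length)
        parts.append(revcomp(gene) if strand == "-" else gene)
        features.append(Feature(name, ftype, pos, pos + length, strand))
        pos += length
        parts.append(_random_dna(rng, cfg.spacer_len))
        pos += cfg.spacer_len
    motif = _random_dna(rng, cfg.cr_repeat_len)
    repeat = motif * cfg.cr_repeat_copies
    flank = cr_len - len(repeat)
    if flank < 2:
        raise ValueError("control region too short for the requested repeat")
    cr = _random_dna(rng, flank // 2) + repeat + _random_dna(rng, flank - flank // 2)
    parts.append(cr)
    features.append(Feature("control_region", "control_region", pos, pos + cr_len, "+"))
    pos += cr_len
    parts.append(_random_dna(rng, cfg.spacer_len))
    pos += cfg.spacer_len
    genome = "".join(parts)
    assert len(genome) == pos == cfg.genome_length
    record = SeqRecord("true_mito", genome, "simulated circular mitogenome")
    return record, Annotation(features, len(genome), circular=True)


def mutate_reference(
    genome: SeqRecord, divergence: float, seed: int
) -> SeqRecord:
    """Substitute exactly round(divergence * L) uniformly chosen sites."""
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    L = len(genome.sequence)
    n = int(round(divergence * L))
    if n == 0:
        return SeqRecord(f"{genome.id}_div0", genome.sequence, genome.description)
    rng = np.random.default_rng(seed)
    sites = rng.choice(L, size=n, replace=False)
    shifts = rng.integers(1, 4, size=n)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[seq[sites]]
    seq[sites] = _BASES[(codes + shifts) % 4]
    return SeqRecord(
        f"{genome.id}_div{divergence:g}", seq.tobytes().decode(), "mutated reference"
    )


def rearrange_reference(
    genome: SeqRecord,
    annotation: Annotation,
    permutation_seed: Optional[int] = None,
    permutation: Optional[Sequence[int]] = None,
    flips: Optional[Sequence[bool]] = None,
) -> Tuple[SeqRecord, Annotation]:
    """Permute (and optionally strand-flip) gene blocks into a new circle.

    A block is a feature plus its trailing spacer, so the multiset of
    per-gene sequences is preserved exactly.
    """
    feats = sorted(annotation.features, key=lambda f: f.start)
    bounds = [f.start for f in feats] + [annotation.seq_length]
    blocks = [
        (genome.sequence[bounds[i] : bounds[i + 1]], feats[i]) for i in range(len(feats))
    ]
    head = genome.sequence[: bounds[0]]
    n = len(blocks)
    if permutation is None:
        rng = np.random.default_rng(permutation_seed)
        permutation = list(rng.permutation(n))
        if flips is None:
            flips = list(rng.random(n) < 0.3)
    if flips is None:
        flips = [False] * n
    parts = [head]
    new_feats: List[Feature] = []
    pos = len(head)
    for bi, flip in zip(permutation, flips):
        seq, f = blocks[bi]
        flen = f.end - f.start
        if flip:
            seq = revcomp(seq)
            fstart = pos + (len(seq) - flen)
            strand = "-" if f.strand == "+" else "+"
        else:
            fstart = pos
            strand = f.strand
        parts.append(seq)
        new_feats.append(Feature(f.gene_id, f.type, fstart, fstart + flen, strand))
        pos += len(seq)
    new_seq = "".join(parts)
    assert len(new_seq) == len(genome.sequence)
    return (
        SeqRecord(f"{genome.id}_rearr", new_seq, "rearranged reference"),
        Annotation(new_feats, len(new_seq), circular=True),
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[arr[hit]]
    arr[hit] = _BASES[(codes + rng.integers(1, 4, len(hit))) % 4]
    return arr.tobytes().decode()


def _circular_slice(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start : start + length]
    return seq[start:] + seq[: (start + length) % L]


@dataclass
class _Source:
    name: str
    transcript: str  # 5'->3' mature sequence (or the full molecule)
    weight: float
    genome_start: int
    strand: str
    circular: bool = False


def _mito_sources(cfg: SimConfig, truth: TruthSet) -> List[_Source]:
    genome = truth.true_mitogenome.sequence
    expr = dict(DEFAULT_EXPRESSION)
    expr.update(cfg.per_gene_expression)
    sources = [
        _Source("polycistron", genome, cfg.polycistron_baseline, 0, "+", circular=True)
    ]
    for f in truth.true_annotation.features:
        if f.type == "tRNA":
            w = expr.get(f.gene_id, cfg.trna_expression) * (1.0 - cfg.trna_mature_depletion)
        else:
            w = expr.get(f.gene_id, 1.0)
        if w <= 0:
            continue
        seg = genome[f.start : f.end]
        transcript = revcomp(seg) if f.strand == "-" else seg
        sources.append(_Source(f.gene_id, transcript, w, f.start, f.strand))
    return sources


def simulate_reads(truth: TruthSet, cfg: SimConfig) -> ReadSet:
    """Draw a labeled read set; byte-identical for identical (cfg, truth)."""
    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rl = cfg.read_length
    n_mito = int(round(cfg.n_reads * cfg.mito_fraction))
    n_cont = int(round(cfg.n_reads * cfg.contaminant_fraction))
    if cfg.nuclear_fraction is not None:
        n_nuc = int(round(cfg.n_reads * cfg.nuclear_fraction))
        n_mito = min(n_mito, cfg.n_reads - n_cont - n_nuc) if n_mito + n_cont + n_nuc > cfg.n_reads else n_mito
    n_nuc = cfg.n_reads - n_mito - n_cont

    genome = truth.true_mitogenome.sequence

    # nuclear transcript pool, transcript 0 carries the NUMT insert
    rng_nuc = cfg.rng("nuclear_transcripts")
    transcripts: List[SeqRecord] = []
    weights_nuc: List[float] = []
    for i in range(cfg.n_nuclear_transcripts):
        tlen = int(rng_nuc.integers(500, 2501))
        seq = _random_dna(rng_nuc, tlen)
        if i == 0 and n_nuc > 0:
            ins_len = int(rng_nuc.integers(200, 501))
            ins_start = int(rng_nuc.integers(0, len(genome) - ins_len))
            ins_div = float(rng_nuc.uniform(0.02, 0.10))
            insert = mutate_reference(
                SeqRecord("numt_src", genome[ins_start : ins_start + ins_len]),
                ins_div,
                int(rng_nuc.integers(0, 2**31)),
            ).sequence
            mid = tlen // 2
            seq = seq[:mid] + insert + seq[mid:]
        transcripts.append(SeqRecord(f"nuc_tx{i}", seq))
        w = float(rng_nuc.lognormal(0.0, cfg.nuclear_weight_sigma))
        if i == 0:
            w = cfg.numt_weight
        weights_nuc.append(w * len(seq))

    rng_cont = cfg.rng("contaminant")
    contaminant = SeqRecord(
        "contaminant_genome", _random_dna(rng_cont, cfg.contaminant_genome_length)
    )

    rng = cfg.rng("reads")
    reads: List[Read] = []

    def emit(seq: str, label: TruthLabel, prefix: str, i: int) -> None:
        if rng.random() < 0.5:
            seq = revcomp(seq)
            label = replace(label, strand="-" if label.strand == "+" else "+")
        seq = _apply_errors(seq, rng, cfg.error_rate)
        quals = [cfg.base_quality] * len(seq)
        if cfg.paired and len(seq) >= 2 * 30:
            frag = seq
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            reads.append(Read(f"{prefix}{i}", r1, [cfg.base_quality] * len(r1), mate=1, truth_label=label))
            reads.append(Read(f"{prefix}{i}", r2, [cfg.base_quality] * len(r2), mate=2, truth_label=label))
        else:
            reads.append(Read(f"{prefix}{i}", seq, quals, truth_label=label))

    def draw_len() -> int:
        if not cfg.paired:
            return rl
        f = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        return max(f, rl)

    # mitochondrial reads
    sources = _mito_sources(cfg, truth)
    w = np.array([s.weight for s in sources], dtype=float)
    w /= w.sum()
    picks = rng.choice(len(sources), size=n_mito, p=w)
    for i in range(n_mito):
        s = sources[picks[i]]
        flen = draw_len()
        if s.circular:
            start = int(rng.integers(0, len(s.transcript)))
            frag = _circular_slice(s.transcript, start, min(flen, len(s.transcript)))
            label = TruthLabel("mito", "polycistron", start, (start + len(frag)) % len(s.transcript), "+")
        else:
            tlen = len(s.transcript)
            take = min(flen, tlen)
            start = int(rng.integers(0, tlen - take + 1))
            frag = s.transcript[start : start + take]
            if s.strand == "+":
                gs = s.genome_start + start
            else:
                gs = s.genome_start + (tlen - (start + take))
            label = TruthLabel("mito", s.name, gs, gs + take, s.strand)
        emit(frag, label, "m", i)

    # nuclear reads
    wn = np.array(weights_nuc, dtype=float)
    wn /= wn.sum()
    picks = rng.choice(len(transcripts), size=n_nuc, p=wn)
    for i in range(n_nuc):
        t = transcripts[picks[i]]
        flen = draw_len()
        take = min(flen, len(t.sequence))
        start = int(rng.integers(0, len(t.sequence) - take + 1))
        emit(
            t.sequence[start : start + take],
            TruthLabel("nuclear", t.id, start, start + take, "+"),
            "n",
            i,
        )

    # contaminant reads
    for i in range(n_cont):
        flen = draw_len()
        start = int(rng.integers(0, len(contaminant.sequence) - flen + 1))
        emit(
            contaminant.sequence[start : start + flen],
            TruthLabel("contaminant", contaminant.id, start, start + flen, "+"),
            "c",
            i,
        )

    return ReadSet(reads, truth, transcripts, contaminant)


def simulate_dataset(cfg: SimConfig) -> ReadSet:
    """Genome + annotation + reads in one call."""
    genome, annotation = make_mitogenome(cfg)
    return simulate_reads(TruthSet(genome, annotation), cfg)


def write_labels_tsv(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\tsource\tstart\tend\tstrand\n")
        for r in reads:
            t = r.truth_label
            if t is None:
                fh.write(f"{r.id}\tunknown\t.\t.\t.\t.\n")
            else:
                fh.write(f"{r.id}\t{t.origin}\t{t.source}\t{t.start}\t{t.end}\t{t.strand}\n")
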