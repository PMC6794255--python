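import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitobait.seqio import revcomp, write_fastq
from mitobait.simulate import (
    DEFAULT_GENE_ORDER,
    SimConfig,
    TruthSet,
    make_mitogenome,
    mutate_reference,
    rearrange_reference,
    simulate_dataset,
    simulate_reads,
    tiny_gene_order,
)
from mitobait.finishing import check_orfs


class TestMakeMitogenome:
    def test_reproducible_for_same_seed(self, tiny_cfg):
        g1, a1 = make_mitogenome(tiny_cfg)
        g2, a2 = make_mitogenome(tiny_cfg)
        assert g1.sequence == g2.sequence
        assert [vars(f) for f in a1.features] == [vars(f) for f in a2.features]

    def test_gene_census(self, tiny_truth):
        ann = tiny_truth.true_annotation
        assert len(ann.by_type("PCG")) == 13
        assert len(ann.by_type("tRNA")) == 22
        assert len(ann.by_type("rRNA")) == 2
        assert len(ann.by_type("control_region")) == 1

    def test_all_orfs_clean(self, tiny_truth):
        report = check_orfs(tiny_truth.true_mitogenome.sequence, tiny_truth.true_annotation)
        assert len(report.rows) == 13
        assert report.all_clean
        assert all(r.has_start and r.frame_intact for r in report.rows)

    def test_features_tile_without_overlap(self, tiny_truth):
        feats = sorted(tiny_truth.true_annotation.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end <= b.start
        assert feats[-1].end <= tiny_truth.true_annotation.seq_length

    def test_requested_length_honored(self, tiny_cfg):
        g, _ = make_mitogenome(tiny_cfg)
        assert len(g.sequence) == tiny_cfg.genome_length

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_mitogenome(SimConfig(genome_length=10000))


class TestMutateReference:
    def test_zero_divergence_identity(self, tiny_truth):
        out = mutate_reference(tiny_truth.true_mitogenome, 0.0, 5)
        assert out.sequence == tiny_truth.true_mitogenome.sequence

    def test_same_seed_same_mutant(self, tiny_truth):
        a = mutate_reference(tiny_truth.true_mitogenome, 0.05, 5)
        b = mutate_reference(tiny_truth.true_mitogenome, 0.05, 5)
        assert a.sequence == b.sequence

    @given(div=st.sampled_from([0.01, 0.02, 0.05, 0.12]), seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_realized_divergence_concentrates(self, tiny_truth, div, seed):
        g = tiny_truth.true_mitogenome
        out = mutate_reference(g, div, seed)
        ham = sum(a != b for a, b in zip(g.sequence, out.sequence))
        realized = ham / len(g.sequence)
        assert abs(realized - div) <= 0.1 * div + 1e-9

    def test_divergence_bounds(self, tiny_truth):
        with pytest.raises(ValueError):
            mutate_reference(tiny_truth.true_mitogenome, 0.5, 1)


class TestRearrangeReference:
    def test_identity_permutation_returns_input(self, tiny_truth):
        g, ann = tiny_truth.true_mitogenome, tiny_truth.true_annotation
        n = len(ann.features)
        out, oann = rearrange_reference(g, ann, permutation=list(range(n)))
        assert out.sequence == g.sequence
        assert [(f.gene_id, f.start, f.end, f.strand) for f in oann.features] == [
            (f.gene_id, f.start, f.end, f.strand)
            for f in sorted(ann.features, key=lambda f: f.start)
        ]

    def test_gene_sequence_multiset_preserved(self, tiny_truth):
        g, ann = tiny_truth.true_mitogenome, tiny_truth.true_annotation

        def gene_seqs(seq, annotation):
            out = []
            for f in annotation.features:
                s = seq[f.start : f.end]
                out.append(revcomp(s) if f.strand == "-" else s)
            return Counter(out)

        out, oann = rearrange_reference(g, ann, permutation_seed=3)
        assert gene_seqs(out.sequence, oann) == gene_seqs(g.sequence, ann)
        assert len(out.sequence) == len(g.sequence)

    def test_single_block_reversal(self, tiny_truth):
        g, ann = tiny_truth.true_mitogenome, tiny_truth.true_annotation
        n = len(ann.features)
        flips = [False] * n
        flips[2] = True
        out, oann = rearrange_reference(g, ann, permutation=list(range(n)), flips=flips)
        feats = sorted(ann.features, key=lambda f: f.start)
        target = feats[2]
        new = oann.get(target.gene_id)
        orig_gene = g.sequence[target.start : target.end]
        new_gene = out.sequence[new.start : new.end]
        assert new.strand != target.strand
        assert new_gene == revcomp(orig_gene)

    def test_deterministic_for_seed(self, tiny_truth):
        g, ann = tiny_truth.true_mitogenome, tiny_truth.true_annotation
        a, _ = rearrange_reference(g, ann, permutation_seed=9)
        b, _ = rearrange_reference(g, ann, permutation_seed=9)
        assert a.sequence == b.sequence


class TestSimulateReads:
    def test_label_conservation(self, tiny_cfg, tiny_readset):
        counts = Counter(r.truth_label.origin for r in tiny_readset.reads)
        assert sum(counts.values()) == tiny_cfg.n_reads
        assert set(counts) <= {"mito", "nuclear", "contaminant"}

    def test_pure_mito_library(self, tiny_truth):
        cfg = SimConfig(
            seed=2, gene_order=tiny_gene_order(), genome_length=4200,
            n_reads=200, mito_fraction=1.0,
        )
        rs = simulate_reads(tiny_truth, cfg)
        assert all(r.truth_label.origin == "mito" for r in rs.reads)

    def test_nonpositive_n_reads_rejected(self, tiny_truth, tiny_cfg):
        from dataclasses import replace

        with pytest.raises(ValueError, match="n_reads"):
            simulate_reads(tiny_truth, replace(tiny_cfg, n_reads=0))

    def test_byte_identical_fastq_for_seed(self, tiny_cfg, tiny_truth):
        def dump():
            rs = simulate_reads(tiny_truth, tiny_cfg)
            buf = io.StringIO()
            for r in rs.reads:
                buf.write(f"@{r.id}\n{r.sequence}\n")
            return buf.getvalue()

        assert dump() == dump()

    def test_mito_read_origin_intervals_valid(self, tiny_truth, tiny_readset):
        L = len(tiny_truth.true_mitogenome.sequence)
        genome = tiny_truth.true_mitogenome.sequence
        checked = 0
        for r in tiny_readset.reads:
            t = r.truth_label
            if t.origin != "mito" or t.source != "polycistron":
                continue
            frag = (
                genome[t.start : t.end]
                if t.start < t.end
                else genome[t.start :] + genome[: t.end]
            )
            assert r.sequence in (frag, revcomp(frag))
            checked += 1
        assert checked > 10

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="fractions"):
            SimConfig(mito_fraction=0.8, contaminant_fraction=0.3)

    def test_error_rate_bound(self):
        with pytest.raises(ValueError, match="error_rate"):
            SimConfig(error_rate=0.2)


class TestCoverageShape:
    """Expectation oracle: mean depth of a gene ~ n * L_read * w / (W * L_gene)."""

    def test_pcg_exceeds_depleted_trna(self):
        cfg = SimConfig(
            seed=3, gene_order=tiny_gene_order(), genome_length=4200,
            n_reads=4000, mito_fraction=1.0, trna_mature_depletion=0.95,
        )
        genome, ann = make_mitogenome(cfg)
        rs = simulate_reads(TruthSet(genome, ann), cfg)
        depth = np.zeros(len(genome.sequence))
        for r in rs.reads:
            t = r.truth_label
            if t.source == "polycistron":
                continue
            if t.start < t.end:
                depth[t.start : t.end] += 1
            else:
                depth[t.start :] += 1
                depth[: t.end] += 1
        cox1 = ann.get("cox1")
        trna = ann.get("trnI")
        mean_cox1 = depth[cox1.start : cox1.end].mean()
        mean_trna = depth[trna.start : trna.end].mean()
        # expectation check at 3 sigma: cox1 w/L vastly exceeds depleted tRNA
        assert mean_cox1 > mean_trna

    def test_expectation_formula_for_gene(self):
        cfg = SimConfig(
            seed=4, gene_order=tiny_gene_order(), genome_length=4200,
            n_reads=6000, mito_fraction=1.0, trna_mature_depletion=0.9,
        )
        genome, ann = make_mitogenome(cfg)
        rs = simulate_reads(TruthSet(genome, ann), cfg)
        from mitobait.simulate import _mito_sources

        sources = _mito_sources(cfg, TruthSet(genome, ann))
        W = sum(s.weight for s in sources)
        w_cox1 = next(s.weight for s in sources if s.name == "cox1")
        n_cox1 = sum(
            1 for r in rs.reads if r.truth_label.source == "cox1"
        )
        expected = cfg.n_reads * w_cox1 / W
        assert abs(n_cox1 - expected) <= 3 * np.sqrt(expected) + 1


class TestPairedEnd:
    def test_paired_fragments(self):
        cfg = SimConfig(
            seed=8, gene_order=tiny_gene_order(), genome_length=4200,
            n_reads=200, mito_fraction=1.0, paired=True, read_length=93,
        )
        genome, ann = make_mitogenome(cfg)
        rs = simulate_reads(TruthSet(genome, ann), cfg)
        pairs = {}
        for r in rs.reads:
            if r.mate:
                pairs.setdefault(r.id, []).append(r)
        assert pairs, "some fragments should be long enough to pair"
        n_full = 0
        for rid, mates in pairs.items():
            assert sorted(m.mate for m in mates) == [1, 2]
            # fragments from short transcripts are truncated to the source
            assert all(len(m) <= 93 for m in mates)
            n_full += all(len(m) == 93 for m in mates)
            # both mates come from one fragment, hence one source
            assert mates[0].truth_label.source == mates[1].truth_label.source
        assert n_full >= 0.5 * len(pairs)


class TestSimulateDataset:
    def test_returns_databases_for_triage(self):
        cfg = SimConfig(
            seed=6, gene_order=tiny_gene_order(), genome_length=4200,
            n_reads=300, mito_fraction=0.5, contaminant_fraction=0.2,
        )
        rs = simulate_dataset(cfg)
        assert len(rs.nuclear_transcripts) == cfg.n_nuclear_transcripts
        assert len(rs.contaminant_genome.sequence) == cfg.contaminant_genome_length
        # NUMT transcript carries a recognizable mitochondrial insert
        numt = rs.nuclear_transcripts[0]
        assert len(numt.sequence) > 500
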