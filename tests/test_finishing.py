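import numpy as np
import pytest

from mitobait.assemble import Contig
from mitobait.finishing import (
    GapFillParams,
    Mitogenome,
    NoMitochondrialContigs,
    check_orfs,
    choose_guide,
    circularize,
    fill_gaps,
    finish,
    scaffold_contigs,
    transfer_annotation,
)
from mitobait.seqio import Annotation, Feature, SeqRecord, revcomp
from mitobait.simulate import (
    SimConfig,
    TruthSet,
    make_mitogenome,
    mutate_reference,
    simulate_reads,
    tiny_gene_order,
)
from .conftest import make_read, random_dna


@pytest.fixture(scope="module")
def guide_seq():
    rng = np.random.default_rng(101)
    return random_dna(rng, 3000)


@pytest.fixture(scope="module")
def guide(guide_seq):
    return SeqRecord("guide", guide_seq)


def frag_contigs(seq, bounds, prefix="c", coverage=10.0):
    out = []
    for i, (s, e) in enumerate(bounds):
        out.append(Contig(f"{prefix}{i}", seq[s:e], mean_kmer_coverage=coverage))
    return out


class TestScaffoldContigs:
    def test_exact_fragments_with_overlaps_merge_to_guide(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(0, 1100), (1000, 2100), (2000, 3000)])
        sc = scaffold_contigs(contigs, guide)
        assert sc.merged_sequence == guide_seq
        assert sc.gaps == []
        covered = sum(p.guide_end - p.guide_start for p in sc.placed)
        assert covered + sum(e - s for s, e in sc.gaps) == len(guide_seq)

    def test_reverse_complement_contig_equivalent(self, guide, guide_seq):
        fwd = frag_contigs(guide_seq, [(0, 1600), (1500, 3000)])
        rev = [
            Contig(fwd[0].id, revcomp(fwd[0].sequence), mean_kmer_coverage=10.0),
            fwd[1],
        ]
        a = scaffold_contigs(fwd, guide)
        b = scaffold_contigs(rev, guide)
        assert a.merged_sequence == b.merged_sequence
        assert b.placed[0].strand == "-"

    def test_gap_interval_complement(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(0, 500), (570, 3000)])
        sc = scaffold_contigs(contigs, guide)
        assert sc.gaps == [(500, 570)]
        assert set(sc.merged_sequence[500:570]) == {"N"}

    def test_unrelated_contig_rejected_for_triage(self, guide, guide_seq, rng):
        contigs = frag_contigs(guide_seq, [(0, 3000)]) + [
            Contig("junk", random_dna(rng, 800))
        ]
        sc = scaffold_contigs(contigs, guide)
        assert sc.rejected_contig_ids == ["junk"]

    def test_no_passing_contig_raises(self, guide, rng):
        with pytest.raises(NoMitochondrialContigs):
            scaffold_contigs([Contig("junk", random_dna(rng, 500))], guide)

    def test_gap_accounting_exact(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(100, 900), (1200, 2500)])
        sc = scaffold_contigs(contigs, guide)
        placed = sum(p.guide_end - p.guide_start for p in sc.placed)
        gaps = sum(e - s for s, e in sc.gaps)
        assert placed + gaps == len(guide_seq)


class TestFillGaps:
    def test_gap_closed_by_reads(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(0, 1400), (1470, 3000)])
        sc = scaffold_contigs(contigs, guide)
        assert sc.gaps == [(1400, 1470)]
        rng = np.random.default_rng(7)
        reads = []
        for i in range(120):
            start = int(rng.integers(1250, 1600 - 51))
            seq = guide_seq[start : start + 51]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(make_read(seq, f"g{i}"))
        out = fill_gaps(sc, reads, guide)
        assert out.gaps == []
        assert out.merged_sequence == guide_seq

    def test_zero_coverage_gap_persists(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(0, 1400), (1470, 3000)])
        sc = scaffold_contigs(contigs, guide)
        out = fill_gaps(sc, [make_read(guide_seq[0:51], "far")], guide)
        assert out.gaps == [(1400, 1470)]
        assert set(out.merged_sequence[1400:1470]) == {"N"}

    def test_complete_scaffold_returned_unchanged(self, guide, guide_seq):
        contigs = frag_contigs(guide_seq, [(0, 3000)])
        sc = scaffold_contigs(contigs, guide)
        assert fill_gaps(sc, [], guide) is sc


class TestCircularize:
    def test_terminal_overlap_trimmed(self, guide_seq):
        seq = guide_seq + guide_seq[:80]
        mito = circularize(seq)
        assert mito.circular
        assert len(mito.sequence) == len(guide_seq)

    def test_no_overlap_stays_linear(self, guide_seq):
        with pytest.warns(UserWarning, match="no terminal overlap"):
            mito = circularize(guide_seq)
        assert not mito.circular

    def test_gappy_ends_refuse_circularization(self, guide_seq):
        seq = "N" * 30 + guide_seq
        with pytest.warns(UserWarning, match="gaps"):
            mito = circularize(seq)
        assert not mito.circular

    def test_rotation_to_anchor_gene(self, guide_seq):
        # anchor gene at position 1000 of the guide
        ann = Annotation([Feature("anchor", "PCG", 1000, 1300, "+")], 3000, True)
        guide = SeqRecord("g", guide_seq)
        rolled = guide_seq[500:] + guide_seq[:500]  # anchor now at 500
        mito = circularize(rolled + rolled[:80], guide, ann)
        assert mito.circular
        assert mito.rotation_anchor == "anchor"
        assert mito.sequence.startswith(guide_seq[1000:1060])


@pytest.fixture(scope="module")
def annotated():
    cfg = SimConfig(seed=9, gene_order=tiny_gene_order(), genome_length=4200)
    return make_mitogenome(cfg)


class TestTransferAnnotation:

    def test_identity_projection(self, annotated):
        genome, ann = annotated
        out = transfer_annotation(genome.sequence, ann, genome.sequence)
        assert out.absent == []
        for f, g in zip(ann.features, out.features):
            assert (f.gene_id, f.start, f.end, f.strand) == (
                g.gene_id, g.start, g.end, g.strand,
            )

    def test_projection_through_substitutions(self, annotated):
        genome, ann = annotated
        cox1 = ann.get("cox1")
        rng = np.random.default_rng(5)
        seq = list(genome.sequence)
        for pos in rng.choice(np.arange(cox1.start + 10, cox1.end - 10), 10, replace=False):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        mutated = "".join(seq)
        out = transfer_annotation(mutated, ann, genome.sequence)
        g = out.get("cox1")
        assert (g.start, g.end, g.strand) == (cox1.start, cox1.end, cox1.strand)

    def test_feature_missing_flagged_absent(self, annotated):
        genome, ann = annotated
        cox1 = ann.get("cox1")
        # delete cox1 from the target molecule entirely
        target = genome.sequence[: cox1.start] + genome.sequence[cox1.end :]
        out = transfer_annotation(target, ann, genome.sequence)
        assert "cox1" in out.absent

    def test_rearranged_target_found_in_its_own_order(self, annotated):
        from mitobait.simulate import rearrange_reference

        genome, ann = annotated
        rearranged, _ = rearrange_reference(genome, ann, permutation_seed=13)
        out = transfer_annotation(rearranged.sequence, ann, genome.sequence)
        located = [f for f in out.features if not f.absent]
        assert len(located) >= 30
        order = [f.gene_id for f in sorted(located, key=lambda f: f.start)]
        guide_order = [
            f.gene_id
            for f in sorted(ann.features, key=lambda f: f.start)
            if f.gene_id in set(order)
        ]
        assert order != guide_order  # placement is per-feature, not guide-imposed


class TestCheckOrfs:
    def test_truth_genome_all_clean(self, tiny_truth):
        report = check_orfs(
            tiny_truth.true_mitogenome.sequence, tiny_truth.true_annotation
        )
        assert report.all_clean and len(report.rows) == 13

    def test_injected_internal_stop_detected(self, tiny_truth):
        genome = tiny_truth.true_mitogenome.sequence
        ann = tiny_truth.true_annotation
        f = ann.get("cox1")
        assert f.strand == "+"
        mid = f.start + ((f.end - f.start) // 2 // 3) * 3
        seq = genome[:mid] + "TAA" + genome[mid + 3 :]
        report = check_orfs(seq, ann)
        row = next(r for r in report.rows if r.gene_id == "cox1")
        assert row.internal_stop_count == 1
        assert not report.all_clean

    def test_empty_annotation_empty_report(self, tiny_truth):
        empty = Annotation([], tiny_truth.true_annotation.seq_length, True)
        report = check_orfs(tiny_truth.true_mitogenome.sequence, empty)
        assert report.rows == []
        assert report.all_clean


class TestChooseGuide:
    def test_lower_divergence_wins(self, tiny_truth):
        genome = tiny_truth.true_mitogenome
        near = mutate_reference(genome, 0.02, 1)
        far = mutate_reference(genome, 0.15, 2)
        contigs = [Contig("c1", genome.sequence[500:2500])]
        assert choose_guide(contigs, [far, near]).id == near.id


class TestFinishEndToEnd:
    def test_tiny_pipeline_recovers_truth(self, tiny_cfg, tiny_truth, tiny_readset):
        from mitobait.iterate import LoopParams, run_iterations

        genome = tiny_truth.true_mitogenome
        ref = mutate_reference(genome, 0.02, 42)
        contigs, _, _ = run_iterations(
            tiny_readset.reads, [ref], loop_p=LoopParams(max_iterations=3, early_stop=False)
        )
        mito, report = finish(contigs, tiny_readset.reads, ref, tiny_truth.true_annotation)
        assert mito.circular
        assert len(mito.sequence) == len(genome.sequence)
        assert report["orfs_clean"]
        # perfect identity outside the control region
        cr = tiny_truth.true_annotation.get("control_region")
        matches = sum(
            a == b
            for a, b in zip(mito.sequence[: cr.start], genome.sequence[: cr.start])
        )
        assert matches == cr.start
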