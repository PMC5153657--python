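"""Scaffold construction geometry, end-to-end mate alignment, duplicate
collapse, chimera-aware counting, and the expression and multi-gene
filters."""

import numpy as np
import pandas as pd
import pytest

from circage._seq import revcomp
from circage.genome import GenomeBundle
from circage.junctionquant import (CircJunction, JunctionAlignment,
                                   JunctionCountMatrix, align_to_scaffolds,
                                   build_scaffolds, count_junctions, dedupe,
                                   expression_filter, merge_annotations,
                                   multigene_filter)
from circage.synthdata import SimulationConfig


@pytest.fixture(scope="module")
def flat_genome():
    rng = np.random.default_rng(31)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return GenomeBundle({"chr1": seq}, [])


class TestBuildScaffolds:
    def test_plus_strand_geometry(self, flat_genome):
        g = flat_genome.sequences["chr1"]
        (s,) = build_scaffolds(
            [CircJunction("c1", "chr1", 1000, 2000, "+")], flat_genome)
        assert s.sequence == g[1900:2000] + g[1000:1100]
        assert s.offset == 100 and len(s.sequence) == 200
        assert not s.short_circle_overlap

    def test_minus_strand_reads_in_transcript_orientation(self, flat_genome):
        g = flat_genome.sequences["chr1"]
        (s,) = build_scaffolds(
            [CircJunction("c1", "chr1", 1000, 2000, "-")], flat_genome)
        assert s.sequence == revcomp(g[1000:1100]) + revcomp(g[1900:2000])
        assert s.offset == 100

    def test_short_circle_overlap_flagged(self, flat_genome):
        (s,) = build_scaffolds(
            [CircJunction("c1", "chr1", 1000, 1150, "+")], flat_genome)
        assert len(s.sequence) == 200 and s.short_circle_overlap
        g = flat_genome.sequences["chr1"]
        assert s.sequence == g[1050:1150] + g[1000:1100]  # overlapping content

    def test_tiny_span_uses_span_flanks(self, flat_genome):
        (s,) = build_scaffolds(
            [CircJunction("c1", "chr1", 1000, 1080, "+")], flat_genome)
        assert s.offset == 80 and len(s.sequence) == 160

    def test_zero_span_rejected(self, flat_genome):
        with pytest.raises(ValueError, match="span"):
            build_scaffolds([CircJunction("c1", "chr1", 1000, 1000, "+")],
                            flat_genome)

    def test_known_and_denovo_merge_to_one(self, flat_genome):
        known = [CircJunction("k1", "chr1", 1000, 2000, "+", source="known")]
        denovo = [CircJunction("d1", "chr1", 1000, 2000, "+")]
        merged = merge_annotations(known, denovo)
        assert len(merged) == 1 and merged[0].source == "both"
        assert merged[0].circ_id == "k1"
        scaffolds = build_scaffolds(merged, flat_genome)
        assert len(scaffolds) == 1 and scaffolds[0].source == "both"


@pytest.fixture(scope="module")
def scaffold(flat_genome):
    return build_scaffolds(
        [CircJunction("c1", "chr1", 1000, 2000, "+")], flat_genome)


class TestAlignToScaffolds:

    def test_exact_copy_aligns_at_its_offset(self, scaffold):
        mate = scaffold[0].sequence[30:155]
        (a,) = align_to_scaffolds([("r1", mate)], scaffold)
        assert (a.circ_id, a.start, a.strand, a.score, a.mismatches) == \
            ("c1", 30, "+", 0, 0)

    def test_reverse_mate_aligns_minus(self, scaffold):
        mate = revcomp(scaffold[0].sequence[30:155])
        (a,) = align_to_scaffolds([("r1", mate)], scaffold)
        assert (a.start, a.strand) == (30, "-")

    def test_three_substitutions_exceed_score_budget(self, scaffold):
        mate = list(scaffold[0].sequence[30:155])
        for p in (10, 60, 110):
            mate[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[p]]
        assert align_to_scaffolds([("r1", "".join(mate))], scaffold) == []

    def test_two_substitutions_still_pass(self, scaffold):
        mate = list(scaffold[0].sequence[30:155])
        for p in (10, 60):
            mate[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[p]]
        (a,) = align_to_scaffolds([("r1", "".join(mate))], scaffold)
        assert a.score == -12 and a.mismatches == 2

    def test_linear_region_mate_has_no_end_to_end_placement(self, flat_genome,
                                                            scaffold):
        # a 125-nt mate from the genomic region *linearly* downstream of the
        # acceptor cannot fit the 200-nt scaffold end-to-end anywhere:
        # exhaustive check over all offsets and orientations
        g = flat_genome.sequences["chr1"]
        mate = g[1050:1175]  # crosses scaffold's right edge content
        scaf = scaffold[0].sequence
        for oriented in (mate, revcomp(mate)):
            for start in range(0, len(scaf) - len(mate) + 1):
                assert sum(a != b for a, b in
                           zip(oriented, scaf[start:start + 125])) > 2
        assert align_to_scaffolds([("r1", mate)], scaffold) == []

    def test_junction_coverage_overhang_enforced(self, scaffold):
        # a mate placed at start 91 would leave only 9 nt on the donor side
        mate = scaffold[0].sequence[91 - 125 + 200:]  # not 125nt; build properly
        mate = scaffold[0].sequence[75:200]
        (a,) = align_to_scaffolds([("r1", mate)], scaffold)
        assert a.start == 75
        assert align_to_scaffolds([("r1", mate)], scaffold,
                                  min_overhang=26) == []

    def test_ambiguous_multi_scaffold_mate_discarded(self, flat_genome):
        g = flat_genome.sequences["chr1"]
        circs = [CircJunction("c1", "chr1", 1000, 2000, "+"),
                 CircJunction("c2", "chr1", 1000, 2000, "-")]
        # same junction on both strands -> c2 scaffold is the revcomp of c1;
        # any junction mate matches both at equal score
        scaffolds = build_scaffolds(circs, flat_genome)
        mate = scaffolds[0].sequence[30:155]
        assert align_to_scaffolds([("r1", mate)], scaffolds) == []


class TestDedupe:
    def _aln(self, rid, circ="c1", start=30, strand="+", score=0, lib="l1"):
        return JunctionAlignment(rid, circ, start, strand, score, 0, lib)

    def test_exact_duplicates_collapse_to_best(self):
        out = dedupe([self._aln("r2"), self._aln("r1")])
        assert len(out) == 1 and out[0].read_id == "r1"  # smallest id on tie

    def test_nearby_starts_not_collapsed(self):
        out = dedupe([self._aln("r1", start=30), self._aln("r2", start=31)])
        assert len(out) == 2

    def test_idempotent(self):
        alns = [self._aln(f"r{i}", start=i % 3) for i in range(10)]
        once = dedupe(alns)
        assert dedupe(once) == once

    def test_higher_score_wins(self):
        out = dedupe([self._aln("r1", score=-6), self._aln("r2", score=0)])
        assert out[0].read_id == "r2"


class TestCountJunctions:
    def _scafs(self, flat_genome):
        return build_scaffolds([CircJunction("cA", "chr1", 200, 1200, "+"),
                                CircJunction("cB", "chr1", 1400, 2400, "+")],
                               flat_genome)

    def test_counts_deduplicated_mates(self, flat_genome):
        scafs = self._scafs(flat_genome)
        alns = [JunctionAlignment(f"f{i}/1", "cA", 20 + i, "+", 0, 0, "l1")
                for i in range(6)]
        m = count_junctions({"l1": alns}, scafs, ["l1"],
                            fragment_of=lambda r: r.split("/")[0])
        assert m.counts.loc["cA", "l1"] == 6
        assert m.counts.loc["cB", "l1"] == 0

    def test_chimeric_fragment_excluded_entirely(self, flat_genome):
        scafs = self._scafs(flat_genome)
        alns = [JunctionAlignment("f1/1", "cA", 30, "+", 0, 0, "l1"),
                JunctionAlignment("f1/2", "cB", 40, "-", 0, 0, "l1"),
                JunctionAlignment("f2/1", "cA", 50, "+", 0, 0, "l1")]
        m = count_junctions({"l1": alns}, scafs, ["l1"],
                            fragment_of=lambda r: r.split("/")[0])
        assert m.counts.loc["cA", "l1"] == 1
        assert m.counts.loc["cB", "l1"] == 0

    def test_library_totals_add_linear_reads(self, flat_genome):
        scafs = self._scafs(flat_genome)
        alns = [JunctionAlignment("f1/1", "cA", 30, "+", 0, 0, "l1")]
        m = count_junctions({"l1": alns}, scafs, ["l1"],
                            linear_reads={"l1": 999},
                            fragment_of=lambda r: r.split("/")[0])
        assert m.library_totals["l1"] == 1000


class TestExpressionFilter:
    def _matrix(self, row):
        libs = [f"t_{a}_r{i}" for a in ("young", "old") for i in (1, 2, 3)]
        counts = pd.DataFrame([row], index=["c1"], columns=libs)
        design = pd.DataFrame([dict(library=l, tissue="t",
                                    age=l.split("_")[1],
                                    replicate=int(l[-1])) for l in libs])
        return JunctionCountMatrix(counts, {l: 10000 for l in libs}), design

    @pytest.mark.parametrize("row,kept", [
        ([1, 1, 1, 1, 1, 1], True),    # exactly 6 across the tissue
        ([5, 0, 0, 0, 0, 0], False),   # sum 5 -> dropped
        ([0, 0, 0, 6, 0, 0], True),    # no per-library requirement
        ([2, 1, 1, 1, 1, 1], True),    # 7
    ])
    def test_sum_cutoff_boundaries(self, row, kept):
        matrix, design = self._matrix(row)
        filtered, retained = expression_filter(matrix, design)
        assert (("c1" in retained["t"]) is kept)
        assert (len(filtered.counts) == 1) is kept

    def test_wrong_library_count_strict_raises(self):
        matrix, design = self._matrix([1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="libraries"):
            expression_filter(matrix, design.iloc[:5], strict=True)

    def test_proportional_threshold_when_not_strict(self):
        matrix, design = self._matrix([1, 1, 1, 1, 1, 0])
        sub = design.iloc[:5]
        m = JunctionCountMatrix(matrix.counts[list(sub.library)],
                                matrix.library_totals)
        _, retained = expression_filter(m, sub, strict=False)
        assert "c1" in retained["t"]  # 5 reads >= 6*5/6


@pytest.fixture(scope="module")
def dup_study():
    cfg = SimulationConfig(
        seed=21, n_chromosomes=1, chrom_length=500_000, n_genes=12,
        n_circ_genes=4, multi_circle_genes=0, duplicated_gene_pairs=1,
        n_fragments_per_library=10,
        groups=(("cortex", "young"),), n_replicates=1)
    from circage.synthdata import generate_genome

    return generate_genome(cfg)


class TestMultigeneFilter:

    def test_duplicated_pair_junction_removed(self, dup_study):
        bundle = dup_study
        ga = bundle.gene("dup01a")
        gb = bundle.gene("dup01b")
        # junction start in an exon of gene A, end in an exon of gene B: the
        # C4a/C4b-like artifact of a linear splice across duplicated genes
        j = CircJunction("bad", ga.chrom, ga.transcripts[0].exons[1][0],
                         gb.transcripts[0].exons[1][1], ga.strand)
        kept, removed = multigene_filter([j], bundle)
        assert [c.circ_id for c in removed] == ["bad"] and kept == []

    def test_single_gene_junction_kept_with_host(self, dup_study):
        bundle = dup_study
        g = next(g for g in bundle.genes if not g.gene_id.startswith("dup"))
        tx = g.transcripts[0]
        j = CircJunction("ok", g.chrom, tx.exons[1][0], tx.exons[2][1],
                         g.strand)
        kept, removed = multigene_filter([j], bundle)
        assert removed == [] and kept[0].host_gene == g.gene_id

    def test_intergenic_junction_kept_as_intergenic(self, dup_study):
        bundle = dup_study
        last_end = max(g.span[1] for g in bundle.genes)
        j = CircJunction("int1", "chr1", last_end + 100, last_end + 400, "+")
        kept, removed = multigene_filter([j], bundle)
        assert removed == [] and kept[0].host_gene == "intergenic"


class TestQuantificationOracle:
    def test_counts_equal_truth_with_duplicates_injected(self, tiny_study):
        bundle, circs, truth, libs = tiny_study
        ann = [CircJunction(c.circ_id, c.chrom, c.start, c.end, c.strand)
               for c in circs]
        scaffolds = build_scaffolds(ann, bundle)
        libs_order = truth.library_ids()
        alns = {}
        for lib in libs_order:
            mates = [(f"{r.name}/{m}", s) for r in libs[lib]
                     for m, s in ((1, r.seq1), (2, r.seq2))]
            alns[lib] = dedupe(align_to_scaffolds(mates, scaffolds,
                                                  library=lib))
        m = count_junctions(alns, scaffolds, libs_order,
                            fragment_of=lambda r: r.rsplit("/", 1)[0])
        expected = truth.expected_scaffold_counts(flank=100, min_overhang=10)
        pd.testing.assert_frame_equal(
            m.counts.sort_index(), expected.sort_index(), check_dtype=False)

    def test_score_threshold_monotonicity(self, tiny_study):
        bundle, circs, truth, libs = tiny_study
        ann = [CircJunction(c.circ_id, c.chrom, c.start, c.end, c.strand)
               for c in circs]
        scaffolds = build_scaffolds(ann, bundle)
        lib = truth.library_ids()[0]
        mates = [(f"{r.name}/{m}", s) for r in libs[lib]
                 for m, s in ((1, r.seq1), (2, r.seq2))]
        loose = dedupe(align_to_scaffolds(mates, scaffolds, -15, library=lib))
        strict = dedupe(align_to_scaffolds(mates, scaffolds, -6, library=lib))
        assert len(strict) <= len(loose)
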