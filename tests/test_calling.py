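import numpy as np
import pytest

from alubis.calling import (
    InsertionCluster,
    JunctionCall,
    annotate_genic_context,
    annotate_novelty,
    classify_junction,
    cluster_candidates,
    load_gene_models,
    round_pct,
    summarize_libraries,
)
from alubis.mapper import Alignment, MappedRead
from alubis.reference import AluAnnotation, AluAnnotationTable


def mapped(read_id, chrom, start, end, space="CT", status="unique"):
    return MappedRead(
        read_id,
        Alignment(read_id, chrom, start, end, space, 1.0, end - start, 0, float(end - start)),
        status,
    )


def call(read_id, chrom, pos, library="L1", verdict="putative_novel"):
    return JunctionCall(read_id, library, chrom, pos, None, verdict)


@pytest.fixture()
def alu_table():
    return AluAnnotationTable(
        [
            AluAnnotation("chr1", 5000, 5290, "AluY", "+"),
            AluAnnotation("chr1", 9000, 9290, "AluYb8", "-"),
        ]
    )


class TestClassifyJunction:
    def test_within_window_is_known_adjacent(self, alu_table):
        # flank ends 3 bp upstream of an annotated AluY start
        jc = classify_junction(mapped("r", "chr1", 4800, 4997), alu_table)
        assert jc.verdict == "known_adjacent"
        assert jc.junction_pos == 4997
        assert jc.distance_to_nearest_alu == 3

    def test_far_from_any_annotation_is_novel(self, alu_table):
        jc = classify_junction(mapped("r", "chr1", 6300, 6500), alu_table)
        assert jc.verdict == "putative_novel"

    def test_minus_strand_uses_ga_alignment_start(self, alu_table):
        # flank of a '-' element maps downstream of the element end
        jc = classify_junction(mapped("r", "chr1", 9292, 9400, space="GA"), alu_table)
        assert jc.junction_pos == 9292
        assert jc.verdict == "known_adjacent"

    def test_window_boundary(self, alu_table):
        assert classify_junction(
            mapped("r", "chr1", 4800, 4990), alu_table
        ).verdict == "known_adjacent"
        assert classify_junction(
            mapped("r", "chr1", 4800, 4989), alu_table
        ).verdict == "putative_novel"

    def test_empty_table_warns_and_calls_novel(self, caplog):
        jc = classify_junction(mapped("r", "chr1", 100, 200), AluAnnotationTable())
        assert jc.verdict == "putative_novel"
        assert jc.distance_to_nearest_alu is None

    def test_requires_unique_read(self, alu_table):
        with pytest.raises(ValueError):
            classify_junction(MappedRead("r", None, "unmapped"), alu_table)

    def test_shift_invariance(self, alu_table):
        shift = 1000
        shifted = AluAnnotationTable(
            [
                AluAnnotation(r.chrom, r.start + shift, r.end + shift, r.family, r.strand)
                for r in alu_table
            ]
        )
        for start, end in [(4800, 4997), (6300, 6500), (100, 200)]:
            v1 = classify_junction(mapped("r", "chr1", start, end), alu_table).verdict
            v2 = classify_junction(
                mapped("r", "chr1", start + shift, end + shift), shifted
            ).verdict
            assert v1 == v2


class TestClustering:
    def test_chain_within_window_is_one_cluster(self):
        calls = [call("a", "c", 1000), call("b", "c", 1004), call("c", "c", 1009)]
        clusters = cluster_candidates(calls)
        assert len(clusters) == 1
        assert clusters[0].breakpoint_lo == 1000
        assert clusters[0].breakpoint_hi == 1009
        assert clusters[0].n_reads == 3

    def test_distant_junctions_split(self):
        clusters = cluster_candidates([call("a", "c", 1000), call("b", "c", 1050)])
        assert len(clusters) == 2

    def test_chromosomes_never_merge(self):
        clusters = cluster_candidates([call("a", "c1", 1000), call("b", "c2", 1000)])
        assert len(clusters) == 2

    def test_known_adjacent_excluded(self):
        calls = [call("a", "c", 1000), call("b", "c", 1001, verdict="known_adjacent")]
        clusters = cluster_candidates(calls)
        assert len(clusters) == 1
        assert clusters[0].read_ids == ["a"]

    def test_partition_property(self, rng):
        calls = [
            call(f"r{i}", "c", int(p))
            for i, p in enumerate(sorted(rng.integers(0, 100_000, size=300)))
        ]
        clusters = cluster_candidates(calls)
        assert sum(c.n_reads for c in clusters) == len(calls)
        ids = [rid for c in clusters for rid in c.read_ids]
        assert sorted(ids) == sorted(c.read_id for c in calls)

    def test_planted_cluster_recovery_327_from_1762(self, rng):
        # 327 well-separated sites; 1762 junction calls jittered around them
        sites = np.cumsum(rng.integers(100, 500, size=327)) + 10_000
        libraries = [f"L{i}" for i in range(8)]
        calls = []
        for i in range(1762):
            site = sites[i % 327]
            pos = int(site + rng.integers(-3, 4))
            calls.append(call(f"r{i}", "c", pos, library=libraries[i % 8]))
        clusters = cluster_candidates(calls, merge_window=10)
        assert len(clusters) == 327
        assert sum(c.n_reads for c in clusters) == 1762


class TestNovelty:
    def _clusters(self, positions):
        return [
            InsertionCluster(f"cl{i}", "c", p, p, [f"r{i}"], {"L1": 1})
            for i, p in enumerate(positions)
        ]

    def test_empty_known_table_all_novel(self):
        clusters = annotate_novelty(self._clusters([100, 5000]), [])
        assert all(c.novel for c in clusters)

    def test_exact_known_site_not_novel(self):
        clusters = annotate_novelty(self._clusters([1000]), [("c", 1000, 1001)])
        assert clusters[0].novel is False

    def test_window_and_chromosome(self):
        clusters = annotate_novelty(
            self._clusters([1000, 2000]), [("c", 1049, 1050), ("other", 2000, 2001)]
        )
        assert clusters[0].novel is False  # within 50 bp
        assert clusters[1].novel is True  # different chromosome

    def test_316_of_327_echo(self, rng):
        positions = (np.cumsum(rng.integers(200, 400, size=327)) + 5000).tolist()
        known = [("c", p, p + 1) for p in positions[:11]]
        clusters = annotate_novelty(self._clusters(positions), known)
        assert sum(c.novel for c in clusters) == 316


class TestGenicContext:
    GENE_BED = (
        "c\t1000\t9000\tgeneA\t0\t+\t2000\t8000\t0\t3\t1500,1000,1500\t0,3000,6500\n"
    )

    @pytest.fixture()
    def transcripts(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text(self.GENE_BED)
        return load_gene_models(path)

    def _cluster_at(self, pos):
        return InsertionCluster("cl", "c", pos, pos, ["r"], {"L1": 1})

    def test_intronic(self, transcripts):
        (cl,) = annotate_genic_context([self._cluster_at(2800)], transcripts)
        assert cl.genic_context == "intronic"
        assert cl.gene_id == "geneA"

    def test_intergenic(self, transcripts):
        (cl,) = annotate_genic_context([self._cluster_at(20_000)], transcripts)
        assert cl.genic_context == "intergenic"
        assert cl.gene_id is None

    def test_utr_and_cds(self, transcripts):
        (cl,) = annotate_genic_context([self._cluster_at(1500)], transcripts)
        assert cl.genic_context == "utr5"
        (cl,) = annotate_genic_context([self._cluster_at(4500)], transcripts)
        assert cl.genic_context == "exonic"

    def test_geometric_oracle(self, transcripts, rng):
        # context fractions of random placements match bp fractions
        span = 10_000
        expected = {"exonic": 0, "utr5": 0, "utr3": 0, "intronic": 0, "intergenic": 0}
        for pos in range(span):
            ctx = transcripts[0].context_at(pos) or "intergenic"
            expected[ctx] += 1
        positions = rng.integers(0, span, size=4000)
        clusters = annotate_genic_context(
            [self._cluster_at(int(p)) for p in positions], transcripts
        )
        observed = {k: 0 for k in expected}
        for cl in clusters:
            observed[cl.genic_context] += 1
        for ctx, n_bp in expected.items():
            frac = n_bp / span
            se = np.sqrt(frac * (1 - frac) / len(positions))
            assert abs(observed[ctx] / len(positions) - frac) < max(4 * se, 0.01), ctx


class TestSummarize:
    def test_printed_ratio_example(self):
        clusters = [
            InsertionCluster(f"cl{i}", "c", i * 100, i * 100, ["r"], {"NC2": 1})
            for i in range(159)
        ]
        table, _ = summarize_libraries(
            clusters, {"NC2": {"reads_mapped": 460_438, "regions_mapped": 47_071}}
        )
        assert table.loc[0, "ratio"] == 0.34

    def test_single_cluster_single_read(self):
        clusters = [InsertionCluster("cl1", "c", 10, 10, ["r"], {"L1": 1})]
        table, agg = summarize_libraries(
            clusters, {"L1": {"reads_mapped": 10, "regions_mapped": 200}}
        )
        assert table.loc[0, "ratio"] == round(100 / 200, 2)
        assert agg["pct_clusters_multi_read"] == 0.0

    def test_missing_library_raises(self):
        clusters = [InsertionCluster("cl1", "c", 10, 10, ["r"], {"LX": 1})]
        with pytest.raises(KeyError, match="LX"):
            summarize_libraries(clusters, {"L1": {"reads_mapped": 1, "regions_mapped": 1}})

    def test_region_incidence_vs_distinct_count(self):
        clusters = [
            InsertionCluster("cl1", "c", 10, 10, ["a", "b"], {"L1": 1, "L2": 1}),
            InsertionCluster("cl2", "c", 500, 500, ["c"], {"L1": 1}),
        ]
        totals = {
            "L1": {"reads_mapped": 5, "regions_mapped": 100},
            "L2": {"reads_mapped": 5, "regions_mapped": 100},
        }
        _, agg = summarize_libraries(clusters, totals)
        assert agg["total_insertion_regions"] == 3
        assert agg["n_clusters"] == 2
        # equality iff no multi-library cluster
        solo = [InsertionCluster("cl1", "c", 10, 10, ["a"], {"L1": 1})]
        _, agg2 = summarize_libraries(solo, totals)
        assert agg2["total_insertion_regions"] == agg2["n_clusters"]

    def test_round_pct(self):
        assert round_pct(163, 327) == 49.8
        assert round_pct(19, 21) == 90.5
        with pytest.raises(ZeroDivisionError):
            round_pct(1, 0)
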