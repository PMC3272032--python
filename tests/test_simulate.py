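import numpy as np
import pytest

from alubis._align import revcomp
from alubis.consensus import DEFAULT_CONSENSUS
from alubis.features import detect_tsd, measure_polya
from alubis.methylation import cpg_positions
from alubis.simulate import (
    MethylationProfile,
    NickSiteError,
    PlacementError,
    SimulationConfig,
    assign_methylome,
    find_nick_sites,
    make_reference,
    read_truth_frame,
    simulate_dataset,
    simulate_reads,
    simulate_tprt_insertion,
    write_fastq,
)


class TestConfig:
    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="tsd_length_range"):
            SimulationConfig(tsd_length_range=(10, 4))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="conversion_rate"):
            SimulationConfig(conversion_rate=1.2)

    def test_libraries_nonempty(self):
        with pytest.raises(ValueError, match="library_ids"):
            SimulationConfig(library_ids=())


class TestMakeReference:
    def test_zero_background_empty_table(self):
        config = SimulationConfig(seed=1, genome_length=12_000, n_background_alus=0)
        genome, table = make_reference(config)
        assert len(table) == 0
        assert len(genome[config.chrom_name]) == 12_000

    def test_seed_determinism(self):
        config = SimulationConfig(seed=7, genome_length=30_000, n_background_alus=4)
        g1, t1 = make_reference(config)
        g2, t2 = make_reference(config)
        assert g1 == g2
        assert [(r.chrom, r.start, r.end, r.family, r.strand) for r in t1] == [
            (r.chrom, r.start, r.end, r.family, r.strand) for r in t2
        ]

    def test_twenty_copies_realignment_oracle(self):
        from alubis._align import make_aligner, aligned_pairs

        config = SimulationConfig(
            seed=3, genome_length=100_000, n_background_alus=20,
            background_divergence=0.03,
        )
        genome, table = make_reference(config)
        assert len(table) == 20
        aligner = make_aligner(mode="local", bisulfite=False)
        for rec in table:
            segment = genome[rec.chrom][rec.start : rec.end]
            if rec.strand == "-":
                segment = revcomp(segment)
            cons = DEFAULT_CONSENSUS[rec.family]
            aln = aligner.align(cons, segment)[0]
            pairs = aligned_pairs(aln)
            matches = sum(1 for t, q in pairs if cons[t] == segment[q])
            assert matches / len(pairs) >= 1.0 - 3 * config.background_divergence

    def test_annotations_within_bounds_and_disjoint(self):
        config = SimulationConfig(seed=9, genome_length=60_000, n_background_alus=10)
        genome, table = make_reference(config)
        recs = sorted(table.records, key=lambda r: r.start)
        for rec in recs:
            assert 0 <= rec.start < rec.end <= 60_000
        for a, b in zip(recs, recs[1:]):
            assert a.end <= b.start

    def test_too_short_genome_placement_error(self):
        with pytest.raises(PlacementError, match="cannot place"):
            make_reference(
                SimulationConfig(seed=1, genome_length=11_000, n_background_alus=30)
            )

    def test_minimum_length_guard(self):
        with pytest.raises(ValueError, match="10 kb"):
            make_reference(SimulationConfig(genome_length=5_000))


class TestNickSites:
    def test_motif_and_neighbors_found(self):
        seq = "GGGGTTAAAAGGGGGGTTAAATGGGG"
        sites = find_nick_sites(seq)
        assert 6 in sites  # perfect TTAAAA at 4: nick between TT and AAAA
        assert 18 in sites  # TTAAAT: one mismatch

    def test_distance_two_excluded(self):
        assert find_nick_sites("GGGGTTAATTGGGG") == []


@pytest.fixture(scope="module")
def sim():
    config = SimulationConfig(
        seed=21, genome_length=80_000, n_background_alus=3,
        n_novel_insertions=10, hemizygous_prob=0.4,
    )
    genome, table = make_reference(config)
    return config, simulate_tprt_insertion(genome, table, config, 10)


class TestTprtInsertion:

    def test_truth_count_and_length_conservation(self, sim):
        config, result = sim
        assert len(result.truths) == 10
        hapA = result.haplotypes["hapA"].seqs[config.chrom_name]
        expected = config.genome_length + sum(t.inserted_length for t in result.truths)
        assert len(hapA) == expected

    def test_tsd_verbatim_on_both_sides(self, sim):
        config, result = sim
        hap = result.haplotypes["hapA"]
        seq = hap.seqs[config.chrom_name]
        for t in result.truths:
            site = hap.elements[t.locus_id]
            tsd = t.tsd_seq
            assert seq[site.start - len(tsd) : site.start] == tsd
            assert seq[site.tail_end : site.tail_end + len(tsd)] == tsd

    def test_body_matches_subfamily_consensus(self, sim):
        config, result = sim
        hap = result.haplotypes["hapA"]
        seq = hap.seqs[config.chrom_name]
        for t in result.truths:
            site = hap.elements[t.locus_id]
            body = seq[site.start : site.body_end]
            assert body == DEFAULT_CONSENSUS[t.subfamily][t.truncated_5p :]

    def test_nick_site_is_tt_aaaa_like(self, sim):
        config, result = sim
        ref = result.reference[config.chrom_name]
        for t in result.truths:
            window = ref[t.breakpoint - 2 : t.breakpoint + 4]
            mm = sum(1 for a, b in zip(window, "TTAAAA") if a != b)
            assert mm <= 1

    def test_hemizygous_second_haplotype_unmodified(self, sim):
        config, result = sim
        hemi = [t for t in result.truths if t.zygosity == "hemizygous"]
        assert hemi, "fixture should include hemizygous events"
        hapB = result.haplotypes["hapB"]
        for t in hemi:
            assert t.locus_id not in hapB.elements
            assert t.locus_id in hapB.empty_sites
        homo = [t for t in result.truths if t.zygosity == "homozygous"]
        for t in homo:
            assert t.locus_id in hapB.elements

    def test_fixed_tsd_and_polya_round_trip(self):
        config = SimulationConfig(
            seed=2, genome_length=40_000, n_background_alus=0,
            n_novel_insertions=2, tsd_length_range=(12, 12),
            polya_length_range=(40, 40),
        )
        genome, table = make_reference(config)
        result = simulate_tprt_insertion(genome, table, config, 2)
        hap = result.haplotypes["hapA"]
        seq = hap.seqs[config.chrom_name]
        for t in result.truths:
            site = hap.elements[t.locus_id]
            assert len(t.tsd_seq) == 12
            assert seq[site.start - 12 : site.start] == seq[site.tail_end : site.tail_end + 12]
            assert measure_polya(seq[site.body_end : site.tail_end]) == 40
            up = seq[site.start - 25 : site.start]
            down = seq[site.tail_end : site.tail_end + 25]
            assert detect_tsd(up, down) == t.tsd_seq

    def test_truncation_zero_full_length(self, sim):
        config, result = sim
        assert all(t.truncated_5p == 0 for t in result.truths)
        assert all(
            t.body_length == len(DEFAULT_CONSENSUS[t.subfamily]) for t in result.truths
        )

    def test_no_eligible_site_error(self):
        config = SimulationConfig(seed=1, genome_length=12_000, n_background_alus=0)
        genome = {config.chrom_name: "G" * 12_000}
        with pytest.raises(NickSiteError, match="no eligible"):
            simulate_tprt_insertion(genome, __import__("alubis.reference", fromlist=["AluAnnotationTable"]).AluAnnotationTable(), config, 1)

    def test_too_many_requested_error(self):
        config = SimulationConfig(seed=1, genome_length=12_000, n_background_alus=0,
                                  flank_length_range=(40, 60))
        genome, table = make_reference(config)
        with pytest.raises(NickSiteError, match="eligible"):
            simulate_tprt_insertion(genome, table, config, 500)


class TestMethylome:
    def test_uniform_profile_one(self):
        seqs = {"c": "ACGTTACGGACGTT"}
        meth = assign_methylome(seqs, 1.0)
        for pos in cpg_positions(seqs["c"]):
            assert meth.prob("c", pos) == 1.0

    def test_non_cpg_cytosines_zero(self):
        meth = assign_methylome({"c": "ACTTACGT"}, 1.0)
        assert meth.prob("c", 1) == 0.0  # C not followed by G

    def test_island_override(self):
        seqs = {"c": "CGCGCGCGCGCGCGCG"}
        meth = assign_methylome(seqs, 0.9, [("c", 4, 10, 0.0)])
        for pos in cpg_positions(seqs["c"]):
            expected = 0.0 if 4 <= pos < 10 else 0.9
            assert meth.prob("c", pos) == expected

    def test_out_of_bounds_override_rejected(self):
        with pytest.raises(ValueError, match="outside genome bounds"):
            assign_methylome({"c": "ACGT"}, 0.5, [("c", 0, 100, 0.5)])

    def test_binomial_sampling_matches_planted_level(self, rng):
        seqs = {"c": "TTCGTT" * 50}
        meth = assign_methylome(seqs, 0.907)
        draws = [
            rng.random() < meth.prob("c", p)
            for _ in range(40)
            for p in cpg_positions(seqs["c"])
        ]
        level = np.mean(draws)
        se = np.sqrt(0.907 * (1 - 0.907) / len(draws))
        assert abs(level - 0.907) < 3 * se


@pytest.fixture(scope="module")
def base_config():
    return SimulationConfig(
        seed=31, genome_length=50_000, n_background_alus=4,
        n_novel_insertions=3, reads_per_locus=3, error_rate=0.0,
    )


class TestSimulateReads:

    def _dataset(self, config):
        return simulate_dataset(config)

    def test_full_conversion_no_methylation_removes_all_c(self, base_config):
        import dataclasses

        config = dataclasses.replace(
            base_config, conversion_rate=1.0,
            methylation=MethylationProfile(default_level=0.0, element_level=0.0),
        )
        ds = self._dataset(config)
        assert ds.reads
        for read in ds.reads:
            assert "C" not in read.seq

    def test_full_methylation_retains_exactly_cpg_cytosines(self, base_config):
        import dataclasses

        config = dataclasses.replace(
            base_config, conversion_rate=1.0,
            methylation=MethylationProfile(default_level=1.0, element_level=1.0),
        )
        ds = self._dataset(config)
        for read in ds.reads:
            hap = ds.tprt.haplotypes[read.haplotype]
            seq = hap.seqs[read.chrom]
            segment = seq[read.span_start : read.span_end]
            molecule = segment if read.strand == "+" else revcomp(segment)
            for i, base in enumerate(molecule):
                if read.strand == "+":
                    g = read.span_start + i
                    is_cpg_c = seq[g : g + 2] == "CG"
                else:
                    g = read.span_end - 1 - i
                    is_cpg_c = molecule[i] == "C" and g > 0 and seq[g - 1 : g + 1] == "CG"
                if base == "C":
                    assert read.seq[i] == ("C" if is_cpg_c else "T")
                else:
                    assert read.seq[i] == base

    def test_determinism_and_truth_conservation(self, base_config, tmp_path):
        ds1 = self._dataset(base_config)
        ds2 = self._dataset(base_config)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(p1, ds1.reads)
        write_fastq(p2, ds2.reads)
        assert p1.read_bytes() == p2.read_bytes()
        truth = read_truth_frame(ds1.reads)
        assert len(truth) == len(ds1.reads)

    def test_flank_exceeding_upstream_skipped_with_warning(self, caplog):
        import dataclasses

        config = SimulationConfig(
            seed=5, genome_length=20_000, n_background_alus=0,
            n_novel_insertions=1, reads_per_locus=2, min_site_spacing=100,
        )
        genome, table = make_reference(config)
        sim = simulate_tprt_insertion(genome, table, config, 1)
        config = dataclasses.replace(config, flank_length_range=(19_000, 19_500))
        meth = {
            name: assign_methylome(h.seqs, 0.5)
            for name, h in sim.haplotypes.items()
        }
        import logging

        with caplog.at_level(logging.WARNING, logger="alubis.simulate"):
            reads = simulate_reads(sim, meth, config)
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_no_elements_raises(self):
        config = SimulationConfig(seed=5, genome_length=20_000, n_background_alus=0,
                                  n_novel_insertions=1)
        genome, table = make_reference(config)
        sim = simulate_tprt_insertion(genome, table, config, 1)
        sim.haplotypes["hapA"].elements = {}
        with pytest.raises(ValueError, match="no Alu element"):
            simulate_reads(sim, {}, config)


class TestDatasetDeterminism:
    def test_dataset_end_to_end_deterministic(self, small_dataset):
        config = small_dataset.config
        again = simulate_dataset(config, n_genes=4)
        assert again.reference == small_dataset.reference
        assert [r.seq for r in again.reads] == [r.seq for r in small_dataset.reads]
        assert [t.tsd_seq for t in again.truths] == [
            t.tsd_seq for t in small_dataset.truths
        ]
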