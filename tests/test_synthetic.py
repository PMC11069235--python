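import numpy as np
import pandas as pd
import pytest
from scipy import stats

from occumap.annotation import classify_by_length
from occumap.coverage import load_reads
from occumap.synthetic import (
    OccupancyModel,
    condition_suite,
    ip_yield_spikein_fraction,
    make_genes,
    make_genome,
    simulate_reads,
    write_read_bed,
    write_sam,
)


class TestMakeGenome:
    def test_sizes_table_rows(self):
        sizes = make_genome(2, 200_000, spikein_chroms=1)
        assert len(sizes) == 3
        assert sizes["chrS1"] == 200_000
        assert any(c.startswith("spombe_") for c in sizes)

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            make_genome(0, 1000)


class TestMakeGenes:
    def test_all_five_length_classes_populated(self):
        sizes = make_genome(2, 200_000)
        genes = make_genes(sizes, n=100, seed=1)
        classes = set(classify_by_length(genes).values())
        assert {"XS", "S", "M", "L", "XL"} <= classes

    def test_min_gap_respected_and_genes_fit(self):
        sizes = make_genome(2, 200_000)
        genes = make_genes(sizes, n=100, min_gap=150, seed=2)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            assert 0 <= g.start < g.end <= sizes[g.chrom]
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                assert b.start - a.end >= 150

    def test_strands_are_mixed(self):
        genes = make_genes(make_genome(2, 200_000), n=100, seed=3)
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}

    def test_seed_reproducibility(self):
        sizes = make_genome(2, 200_000)
        a = make_genes(sizes, n=50, seed=7)
        b = make_genes(sizes, n=50, seed=7)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in a] == \
               [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in b]

    def test_genome_too_small_errors(self):
        with pytest.raises(ValueError, match="too small"):
            make_genes(make_genome(1, 5_000), n=100, seed=0)


class TestOccupancyModel:
    def test_background_only_with_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            OccupancyModel("background_only", amplitude=5.0)

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            OccupancyModel(
                "mixture", amplitude=1.0,
                components=((0.6, OccupancyModel("tss_peak", amplitude=1.0)),
                            (0.6, OccupancyModel("tts_peak", amplitude=1.0))),
            )


@pytest.fixture(scope="module")
def small_sim():
    sizes = make_genome(2, 100_000)
    genes = make_genes(sizes, n=40, seed=11)
    model = OccupancyModel("uniform_gene_body", amplitude=500.0,
                           background_rate=5.0)
    rs, truth = simulate_reads(genes, model, sizes, n_reads=30_000,
                               spikein_fraction=0.1, seed=11)
    return sizes, genes, model, rs, truth


class TestSimulateReads:
    def test_read_count_conservation(self, small_sim):
        _, _, _, rs, _ = small_sim
        assert rs.experiment_reads + rs.spikein_reads == 30_000

    def test_spikein_count_binomial(self, small_sim):
        _, _, _, rs, _ = small_sim
        n, p = 30_000, 0.1
        sd = np.sqrt(n * p * (1 - p))
        assert abs(rs.spikein_reads - n * p) < 4 * sd

    def test_read_length_is_51(self, small_sim):
        _, _, _, rs, _ = small_sim
        lengths = rs.reads["end"] - rs.reads["start"]
        # truncation at chromosome bounds may shorten a handful of reads
        assert (lengths <= 51).all() and (lengths == 51).mean() > 0.99

    def test_deterministic_given_seed(self, small_sim):
        sizes, genes, model, rs, truth = small_sim
        rs2, truth2 = simulate_reads(genes, model, sizes, n_reads=30_000,
                                     spikein_fraction=0.1, seed=11)
        pd.testing.assert_frame_equal(rs.reads, rs2.reads)
        assert truth.expected_counts == truth2.expected_counts

    def test_uniform_counts_proportional_to_length(self, small_sim):
        """Under the uniform gene-body landscape, per-gene read counts are
        multinomial with probabilities proportional to gene length."""
        sizes, genes, model, rs, truth = small_sim
        counts = []
        expected = []
        for g in genes:
            sel = (
                (rs.reads["chrom"] == g.chrom)
                & (rs.reads["start"] >= g.start - 60)
                & (rs.reads["start"] < g.end + 10)
            )
            counts.append(int(sel.sum()))
            expected.append(truth.expected_counts[g.gene_id])
        # rescale expectation to the observed total (background reads and
        # window slop shift totals slightly)
        expected = np.array(expected) * sum(counts) / sum(expected)
        chi2 = stats.chisquare(counts, expected)
        assert chi2.pvalue > 1e-3

    def test_zero_mass_landscape_errors(self):
        sizes = make_genome(1, 50_000)
        genes = make_genes(sizes, n=10, seed=4)
        model = OccupancyModel("background_only", background_rate=0.0)
        with pytest.raises(ValueError, match="zero total mass"):
            simulate_reads(genes, model, sizes, n_reads=100, seed=0)

    def test_sam_round_trip(self, tmp_path, small_sim):
        sizes, _, _, rs, _ = small_sim
        path = tmp_path / "sim.sam"
        write_sam(rs, sizes, path)
        back = load_reads(path, chrom_sizes=sizes)
        assert back.experiment_reads == rs.experiment_reads
        assert back.spikein_reads == rs.spikein_reads

    def test_bed_round_trip(self, tmp_path, small_sim):
        sizes, _, _, rs, _ = small_sim
        path = tmp_path / "sim.bed"
        write_read_bed(rs, path)
        back = load_reads(path, chrom_sizes=sizes)
        assert back.experiment_reads == rs.experiment_reads
        assert back.spikein_reads == rs.spikein_reads


class TestIpYield:
    def test_background_only_fraction_equals_chromatin_fraction(self):
        assert ip_yield_spikein_fraction(0.0, 1000.0, 0.1) == pytest.approx(0.1)

    def test_signal_dilutes_spikein(self):
        f = ip_yield_spikein_fraction(9000.0, 1000.0, 0.1)
        assert f < 0.02


@pytest.fixture(scope="module")
def tiny_suite():
    return condition_suite(seed=3, n_reads=20_000, n_genes=40,
                           chrom_length=120_000)


class TestConditionSuite:
    def test_design_layout(self, tiny_suite):
        assert set(tiny_suite.samples) == {
            "rad6_wt", "h3k4me3_wt", "set1_tiered", "swd2_wt", "swd2_dset1",
            "swd2_drad6", "notag",
        }
        assert len(tiny_suite.samples["swd2_wt"]) == 2
        assert len(tiny_suite.samples["notag"]) == 1

    def test_wt_mixture_plants_both_peaks(self, tiny_suite):
        offsets = tiny_suite.truths["swd2_wt"][0].peak_offsets
        assert set(offsets) == {"tss_peak", "tts_peak"}

    def test_background_conditions_carry_more_spikein(self, tiny_suite):
        wt = tiny_suite.samples["swd2_wt"][0]
        drad6 = tiny_suite.samples["swd2_drad6"][0]
        assert drad6.spikein_reads > 5 * wt.spikein_reads

    def test_suite_determinism(self, tiny_suite):
        again = condition_suite(seed=3, n_reads=20_000, n_genes=40,
                                chrom_length=120_000)
        pd.testing.assert_frame_equal(
            tiny_suite.samples["swd2_wt"][0].reads,
            again.samples["swd2_wt"][0].reads,
        )
        assert tiny_suite.truths["swd2_wt"][0].to_dict() == \
            again.truths["swd2_wt"][0].to_dict()

    def test_write_emits_text_artifacts(self, tiny_suite, tmp_path):
        tiny_suite.write(tmp_path / "out", read_format="bed")
        out = tmp_path / "out"
        for fname in ("chrom.sizes", "genes.bed", "expression_rpkm.tsv",
                      "truth.json", "swd2_wt_rep1.bed", "notag_rep1.bed"):
            assert (out / fname).exists()
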