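import numpy as np
import pytest

from occumap.annotation import GeneRecord, GeneSet, classify_by_length
from occumap.coverage import CoverageTrack
from occumap.profile import (
    anchor_matrix,
    metagene,
    sort_rows_by_length,
    tiered_heatmaps,
    write_matrix_tsv,
    write_metagene_tsv,
)

from conftest import anchor_matrix_oracle


def rpm_track(data, sample_id="t"):
    return CoverageTrack(
        sample_id=sample_id,
        data={c: np.asarray(a, dtype=np.float32) for c, a in data.items()},
        units="RPM",
    )


@pytest.fixture
def const_track(toy_sizes):
    return rpm_track({c: np.full(n, 2.0) for c, n in toy_sizes.items()})


class TestAnchorMatrix:
    def test_constant_field_gives_constant_cells(self, const_track, toy_genes):
        m = anchor_matrix(const_track, toy_genes, flank_up=500, flank_down=500,
                          bin_size=50)
        inbounds = ~np.isnan(m.values)
        assert inbounds.any()
        np.testing.assert_allclose(m.values[inbounds], 2.0)

    def test_raw_track_rejected(self, toy_genes, toy_sizes):
        raw = CoverageTrack("t", {c: np.zeros(n, np.float32)
                                  for c, n in toy_sizes.items()}, units="raw")
        with pytest.raises(ValueError, match="RPM"):
            anchor_matrix(raw, toy_genes)

    def test_flank_not_divisible_by_bin_rejected(self, const_track, toy_genes):
        with pytest.raises(ValueError, match="divisible"):
            anchor_matrix(const_track, toy_genes, flank_up=500, flank_down=500,
                          bin_size=33)

    def test_minus_strand_spike_flipped_downstream(self, toy_sizes):
        # gene2 is minus strand [3000, 5400): TSS anchor 5400, +100
        # downstream lies at genomic base 5400 - 1 - 100 = 5299
        data = {c: np.zeros(n) for c, n in toy_sizes.items()}
        data["chrA"][5299] = 7.0
        track = rpm_track(data)
        g = GeneSet([GeneRecord("gene2", "chrA", 3000, 5400, "-")])
        m = anchor_matrix(track, g, flank_up=500, flank_down=500, bin_size=1)
        row = m.values[0]
        assert row[np.searchsorted(m.bin_offsets, 100.0)] == 7.0
        assert np.nansum(row) == 7.0

    def test_out_of_bounds_masked_not_zero(self, toy_sizes):
        track = rpm_track({c: np.full(n, 3.0) for c, n in toy_sizes.items()})
        g = GeneSet([GeneRecord("edge", "chrA", 100, 900, "+")])
        m = anchor_matrix(track, g, flank_up=500, flank_down=500, bin_size=100)
        # bins entirely upstream of base 0 are NaN, not 0
        assert np.isnan(m.values[0, 0])
        assert m.values[0, -1] == 3.0

    def test_gene_on_absent_chromosome_errors(self, const_track):
        g = GeneSet([GeneRecord("x", "chrZ", 0, 100, "+")])
        with pytest.raises(ValueError, match="chrZ"):
            anchor_matrix(const_track, g)

    @pytest.mark.parametrize("anchor", ["TSS", "TTS"])
    def test_matches_per_base_oracle(self, toy_sizes, toy_genes, anchor):
        rng = np.random.default_rng(11)
        track = rpm_track({c: rng.random(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, anchor=anchor, flank_up=300,
                          flank_down=450, bin_size=50)
        oracle = anchor_matrix_oracle(track, toy_genes, anchor, 300, 450, 50)
        np.testing.assert_allclose(m.values, oracle, rtol=1e-6, equal_nan=True)

    def test_strand_mirror_reproduces_matrix(self):
        """Flipping a gene's strand and reflecting the track about the
        anchor-pair leaves the matrix unchanged."""
        L = 4000
        rng = np.random.default_rng(12)
        vals = rng.random(L)
        fwd_gene = GeneSet([GeneRecord("g", "chrA", 1500, 2500, "+")])
        # reflected gene occupies the mirror interval with '-' strand; its
        # TSS (exclusive end) maps onto the forward gene's TSS under
        # p -> L - 1 - p reflection of the track.
        rev_gene = GeneSet([GeneRecord("g", "chrA", L - 2500, L - 1500, "-")])
        fwd = rpm_track({"chrA": vals})
        rev = rpm_track({"chrA": vals[::-1].copy()})
        m1 = anchor_matrix(fwd, fwd_gene, flank_up=400, flank_down=600, bin_size=20)
        m2 = anchor_matrix(rev, rev_gene, flank_up=400, flank_down=600, bin_size=20)
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-6)


class TestSortRows:
    def test_descending_length_with_id_ties(self):
        genes = GeneSet([
            GeneRecord("b", "chrA", 0, 1500, "+"),
            GeneRecord("a", "chrA", 2000, 3500, "+"),
            GeneRecord("c", "chrA", 4000, 7000, "+"),
            GeneRecord("d", "chrA", 8000, 8500, "+"),
        ])
        track = rpm_track({"chrA": np.zeros(10_000)})
        m = anchor_matrix(track, genes, flank_up=100, flank_down=100, bin_size=100)
        s = sort_rows_by_length(m, genes)
        assert s.gene_ids == ["c", "a", "b", "d"]
        assert s.row_order == "length_desc"

    def test_idempotent(self, toy_genes, toy_sizes):
        track = rpm_track({c: np.zeros(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, flank_up=100, flank_down=100,
                          bin_size=50)
        once = sort_rows_by_length(m, toy_genes)
        twice = sort_rows_by_length(once, toy_genes)
        assert once.gene_ids == twice.gene_ids


class TestMetagene:
    def test_singleton_group_equals_row(self, toy_sizes, toy_genes):
        rng = np.random.default_rng(13)
        track = rpm_track({c: rng.random(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, flank_up=200, flank_down=200,
                          bin_size=50)
        prof = metagene(m, {"gene1": "solo"})["solo"]
        np.testing.assert_allclose(prof, m.row("gene1"), equal_nan=True)

    def test_mean_of_constant_rows(self, toy_sizes):
        genes = GeneSet([GeneRecord("g1", "chrA", 2000, 3000, "+"),
                         GeneRecord("g2", "chrB", 2000, 3000, "+")])
        track = rpm_track({"chrA": np.full(10_000, 1.0),
                           "chrB": np.full(6_000, 3.0)})
        m = anchor_matrix(track, genes, flank_up=500, flank_down=500, bin_size=100)
        prof = metagene(m)["all"]
        np.testing.assert_allclose(prof, 2.0)

    def test_equals_brute_force_row_mean(self, toy_sizes, toy_genes):
        rng = np.random.default_rng(14)
        track = rpm_track({c: rng.random(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, flank_up=300, flank_down=300,
                          bin_size=50)
        groups = dict.fromkeys(["gene1", "gene3", "gene5"], "G")
        prof = metagene(m, groups)["G"]
        rows = [m.row(g) for g in ("gene1", "gene3", "gene5")]
        np.testing.assert_allclose(prof, np.nanmean(rows, axis=0), equal_nan=True)

    def test_empty_group_errors_with_label(self, toy_sizes, toy_genes):
        track = rpm_track({c: np.zeros(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, flank_up=100, flank_down=100,
                          bin_size=50)
        with pytest.raises(ValueError, match="ghost"):
            metagene(m, {"unknown_gene": "ghost"})


class TestTieredHeatmaps:
    def test_tier_partition_covers_genes(self, toy_sizes, toy_genes):
        track = rpm_track({c: np.ones(n) for c, n in toy_sizes.items()})
        tiers = {"gene1": "high", "gene2": "high", "gene3": "medium",
                 "gene4": "low", "gene5": "low"}
        mats = tiered_heatmaps(track, toy_genes, tiers, flank_up=100,
                               flank_down=100, bin_size=50)
        assert sum(len(m.gene_ids) for m in mats.values()) == len(toy_genes)

    def test_missing_tier_errors(self, toy_sizes, toy_genes):
        track = rpm_track({c: np.ones(n) for c, n in toy_sizes.items()})
        tiers = dict.fromkeys(["gene1", "gene2", "gene3", "gene4", "gene5"],
                              "high")
        with pytest.raises(ValueError, match="empty"):
            tiered_heatmaps(track, toy_genes, tiers)


class TestMatrixIO:
    def test_matrix_tsv_and_sidecar(self, tmp_path, toy_sizes, toy_genes):
        rng = np.random.default_rng(15)
        track = rpm_track({c: rng.random(n) for c, n in toy_sizes.items()})
        m = anchor_matrix(track, toy_genes, flank_up=200, flank_down=200,
                          bin_size=100)
        out = tmp_path / "m.tsv"
        write_matrix_tsv(m, out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(toy_genes) + 1
        assert (tmp_path / "m.tsv.json").exists()
        profs = metagene(m)
        write_metagene_tsv(profs, m, tmp_path / "mg.tsv")
        assert len((tmp_path / "mg.tsv").read_text().splitlines()) == 1 + m.n_bins
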