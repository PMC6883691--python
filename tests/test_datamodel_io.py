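"""Domain containers, file round-trips, and CpG-to-region summarisation."""
import numpy as np
import pandas as pd
import pytest

from methdecon import (
    CpGMeasurementTable,
    GenomicRegion,
    IdentifiabilityError,
    RegionStateMatrix,
    ValidationError,
)
from methdecon.io import (
    load_packaged_regions,
    read_beta_table,
    read_bismark_coverage,
    read_regions,
    summarize_regions,
    write_beta_table,
    write_bismark_coverage,
    write_regions,
)

from conftest import make_region_state


def _beta_sample(sample_id, chrom, pos, beta):
    return CpGMeasurementTable(
        sample_id=sample_id,
        data=pd.DataFrame(
            {
                "cpg_id": [f"c{p}" for p in pos],
                "chrom": chrom,
                "pos": pos,
                "beta": beta,
            }
        ),
    )


def _count_sample(sample_id, chrom, pos, meth, unmeth):
    return CpGMeasurementTable(
        sample_id=sample_id,
        data=pd.DataFrame(
            {
                "cpg_id": [f"c{p}" for p in pos],
                "chrom": chrom,
                "pos": pos,
                "meth": meth,
                "unmeth": unmeth,
            }
        ),
    )


class TestGenomicRegion:
    def test_half_open_membership(self):
        reg = GenomicRegion("chr1", 10, 20, "r0")
        assert reg.contains("chr1", 10)
        assert reg.contains("chr1", 19)
        assert not reg.contains("chr1", 20)
        assert not reg.contains("chr2", 15)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValidationError):
            GenomicRegion("chr1", 20, 20, "bad")


class TestRegionStateMatrix:
    def test_full_rank_accepted(self):
        rsm = make_region_state([[1, 0], [0, 1], [1, 1]])
        assert rsm.n_regions == 3 and rsm.n_cell_types == 2

    def test_rank_deficient_names_dependent_columns(self):
        with pytest.raises(IdentifiabilityError, match="ctB"):
            make_region_state(
                [[1, 1], [0, 0], [1, 1]], cell_types=["ctA", "ctB"]
            )

    def test_overlapping_regions_rejected(self):
        regions = [
            GenomicRegion("chr1", 0, 100, "a"),
            GenomicRegion("chr1", 50, 150, "b"),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            RegionStateMatrix(regions, ["x"], np.array([[1], [0]]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            make_region_state([[0.5, 0], [0, 1]])


class TestRegionBed:
    def test_round_trip(self, tmp_path):
        rsm = make_region_state([[1, 0], [0, 1], [1, 1]], ["CD4T", "Gran"])
        path = tmp_path / "regions.bed"
        write_regions(rsm, path)
        back = read_regions(path)
        assert back.cell_types == ["CD4T", "Gran"]
        np.testing.assert_array_equal(back.Z, rsm.Z)
        assert [r.start for r in back.regions] == [r.start for r in rsm.regions]

    def test_rank_deficient_file_raises(self, tmp_path):
        path = tmp_path / "bad.bed"
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 1000],
                "end": [500, 1500],
                "region_id": ["a", "b"],
                "x": [1, 1],
                "y": [1, 1],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(IdentifiabilityError):
            read_regions(path)

    def test_malformed_coordinates(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chrom\tstart\tend\tregion_id\tx\nchr1\toops\t5\tr\t1\n")
        with pytest.raises(ValidationError):
            read_regions(path)

    def test_packaged_fixture_is_binary_full_rank(self):
        rsm = load_packaged_regions()
        assert rsm.n_cell_types == 6
        assert rsm.n_regions >= 6
        assert set(np.unique(rsm.Z)) <= {0, 1}


class TestBetaTable:
    def test_read_splits_samples_and_validates(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(
            "cpg_id\tchrom\tpos\ts1\ncg1\tchr1\t100\t0.2\ncg2\tchr1\t200\t0.9\n"
        )
        tables = read_beta_table(path)
        assert len(tables) == 1 and len(tables[0].data) == 2
        np.testing.assert_allclose(tables[0].levels(), [0.2, 0.9])

    def test_out_of_range_beta_errors_without_clamp(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("cpg_id\tchrom\tpos\ts1\ncg1\tchr1\t100\t-0.5\n")
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            read_beta_table(path)

    def test_clamp_rule(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("cpg_id\tchrom\tpos\ts1\ncg1\tchr1\t100\t1.0000001\n")
        tables = read_beta_table(path, clamp=True)
        assert tables[0].data["beta"].iloc[0] == 1.0

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        pos = np.arange(100, 400, 10)
        samples = [
            _beta_sample(f"s{i}", "chr1", pos, rng.uniform(size=len(pos)))
            for i in range(3)
        ]
        path = tmp_path / "b.tsv"
        write_beta_table(samples, path)
        back = read_beta_table(path)
        for orig, rt in zip(samples, back):
            np.testing.assert_array_equal(
                rt.data["beta"].to_numpy(), orig.data["beta"].to_numpy()
            )


class TestBismarkCoverage:
    def test_level_from_counts(self):
        t = _count_sample("s", "chr1", [100], [8], [2])
        np.testing.assert_allclose(t.levels(), [0.8])

    def test_zero_coverage_is_missing(self):
        t = _count_sample("s", "chr1", [100, 200], [0, 5], [0, 5])
        lev = t.levels()
        assert np.isnan(lev[0]) and lev[1] == 0.5

    def test_read_converts_to_zero_based(self, tmp_path):
        path = tmp_path / "c.cov"
        path.write_text(
            "chr1\t100\t100\t80.0\t8\t2\nchr1\t200\t200\t0.0\t0\t0\nchr2\t5\t5\t50.0\t3\t3\n"
        )
        t = read_bismark_coverage(path)
        assert len(t.data) == 3
        assert t.data["pos"].tolist() == [99, 199, 4]
        lev = t.levels()
        assert lev[0] == 0.8 and np.isnan(lev[1])

    def test_round_trip_counts(self, tmp_path):
        t = _count_sample("s", "chr1", [99, 199], [8, 0], [2, 0])
        path = tmp_path / "rt.cov"
        write_bismark_coverage(t, path)
        back = read_bismark_coverage(path)
        np.testing.assert_array_equal(back.data["meth"], t.data["meth"])
        np.testing.assert_array_equal(back.data["unmeth"], t.data["unmeth"])
        np.testing.assert_array_equal(back.data["pos"], t.data["pos"])


class TestSummarizeRegions:
    @pytest.fixture
    def two_regions(self):
        return make_region_state(
            [[1, 0], [0, 1]], cell_types=["a", "b"]
        )  # chr1:[0,500) and chr1:[1000,1500)

    def test_unweighted_mean(self, two_regions):
        s = _beta_sample("s1", "chr1", [100, 200, 1100], [0.2, 0.4, 0.6])
        mat = summarize_regions([s], two_regions, weighting="unweighted")
        np.testing.assert_allclose(mat.Y[:, 0], [0.3, 0.6])
        assert mat.cpg_counts.iloc[:, 0].tolist() == [2, 1]

    def test_coverage_weighting_pools_counts(self, two_regions):
        s = _count_sample("s1", "chr1", [100, 200, 1100], [8, 2, 1], [2, 8, 0])
        mat = summarize_regions([s], two_regions, weighting="coverage")
        np.testing.assert_allclose(mat.Y[:, 0], [0.5, 1.0])

    def test_weightings_agree_at_equal_coverage(self, two_regions):
        s = _count_sample("s1", "chr1", [100, 200], [8, 2], [2, 8])
        cov = summarize_regions([s], two_regions.__class__(
            regions=[two_regions.regions[0]], cell_types=["a"],
            Z=np.array([[1]])), weighting="coverage")
        unw = summarize_regions([s], two_regions.__class__(
            regions=[two_regions.regions[0]], cell_types=["a"],
            Z=np.array([[1]])), weighting="unweighted")
        np.testing.assert_allclose(cov.Y, unw.Y)

    def test_half_open_boundaries(self, two_regions):
        # region 0 spans [0, 500): position 500 excluded, position 0 included
        s = _beta_sample("s1", "chr1", [0, 500, 1000], [0.2, 0.8, 0.5])
        mat = summarize_regions([s], two_regions, weighting="unweighted")
        assert mat.Y[0, 0] == 0.2  # only the CpG at 0
        assert mat.Y[1, 0] == 0.5  # CpG at 1000 (== start) included

    def test_uncovered_region_is_missing(self, two_regions):
        s = _beta_sample("s1", "chr1", [100], [0.2])
        with pytest.warns(UserWarning, match="missing"):
            mat = summarize_regions([s], two_regions)
        assert np.isnan(mat.Y[1, 0]) and mat.Y[0, 0] == 0.2

    def test_sample_with_no_overlap_errors(self, two_regions):
        s = _beta_sample("lost", "chr9", [100], [0.2])
        with pytest.raises(ValidationError, match="lost"):
            summarize_regions([s], two_regions)

    def test_output_in_unit_interval(self, two_regions, rng):
        pos = np.arange(0, 1500, 37)
        s = _beta_sample("s1", "chr1", pos, rng.uniform(size=len(pos)))
        mat = summarize_regions([s], two_regions)
        vals = mat.Y[~np.isnan(mat.Y)]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_drop_sparse_regions(self, two_regions):
        s1 = _beta_sample("s1", "chr1", [100], [0.2])
        s2 = _beta_sample("s2", "chr1", [150], [0.4])
        with pytest.warns(UserWarning):
            mat = summarize_regions(
                [s1, s2], two_regions, drop_sparse_regions=True
            )
        assert mat.n_regions == 1
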