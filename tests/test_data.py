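"""Data model, coverage-file I/O, filtering and region arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kormeth.data import (
    CGI1,
    CGI2,
    CHROMOSOME,
    DEFAULT_REGISTRY,
    DMR_REGION,
    EH1,
    CoverageParseError,
    CpGSite,
    GenomicRegion,
    MethylationCountMatrix,
    UndefinedRateError,
    ValidationError,
    apply_coverage_filter,
    assign_sites_to_regions,
    read_coverage_file,
    read_region_registry,
    region_length,
    site_rate,
    write_coverage_file,
    write_region_registry,
)


class TestSiteRate:
    @pytest.mark.parametrize(
        "meth,unmeth,expected",
        [(5, 5, 0.5), (0, 10, 0.0), (23, 2, 0.92), (10, 0, 1.0)],
    )
    def test_values(self, meth, unmeth, expected):
        assert site_rate(meth, unmeth) == pytest.approx(expected)

    def test_zero_coverage_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            site_rate(0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            site_rate(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_rate_always_in_unit_interval(self, m, u):
        if m + u == 0:
            return
        assert 0.0 <= site_rate(m, u) <= 1.0


class TestCoverageIO:
    def test_single_row(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr8\t53254514\t53254514\t92.0\t23\t2\n")
        vec = read_coverage_file(p)
        assert vec == {("chr8", 53254514): (23, 2)}

    def test_round_trip_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(3)
        counts = {
            (CHROMOSOME, int(pos)): (int(m), int(u))
            for pos, m, u in zip(
                rng.choice(np.arange(53246080, 53256098), 50, replace=False),
                rng.integers(0, 500, 50),
                rng.integers(1, 500, 50),
            )
        }
        p = tmp_path / "rt.cov"
        write_coverage_file(p, counts)
        assert read_coverage_file(p) == counts

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "bad.cov"
        p.write_text("chr8\t100\t100\t0.0\t-1\t5\n")
        with pytest.raises(ValidationError):
            read_coverage_file(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.cov"
        p.write_text("chr8\t100\t100\t0.0\t3\t5\nchr8\tnot_an_int\t1\t0\t1\t1\n")
        with pytest.raises(CoverageParseError, match=":2"):
            read_coverage_file(p)

    def test_rows_outside_window_dropped(self, tmp_path):
        p = tmp_path / "w.cov"
        p.write_text("chr8\t53254514\t53254514\t92.0\t23\t2\nchr8\t1000\t1000\t50.0\t1\t1\n")
        win = GenomicRegion("w", "chr8", 53246080, 53256098)
        vec = read_coverage_file(p, window=win)
        assert list(vec) == [("chr8", 53254514)]

    def test_empty_file_gives_empty_vector(self, tmp_path):
        p = tmp_path / "e.cov"
        p.write_text("")
        assert read_coverage_file(p) == {}


class TestRegions:
    @pytest.mark.parametrize(
        "region,convention,expected",
        [
            (CGI1, "inclusive", 416),
            (CGI2, "inclusive", 542),
            (DMR_REGION, "difference", 184),
        ],
    )
    def test_published_lengths(self, region, convention, expected):
        assert region_length(region, convention) == expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError):
            GenomicRegion("bad", "chr8", 10, 5)

    def test_boundary_membership_inclusive(self):
        s = CpGSite("x", CHROMOSOME, CGI1.start)
        assert assign_sites_to_regions([s], [CGI1])["x"] == ["CGI-1"]
        e = CpGSite("y", CHROMOSOME, CGI1.end)
        assert assign_sites_to_regions([e], [CGI1])["y"] == ["CGI-1"]

    def test_site_before_enhancer_is_not_a_member(self):
        # the most-upstream differential site sits just outside the enhancer
        cg17 = CpGSite("CG17", CHROMOSOME, 53254514)
        assert "EH1" not in assign_sites_to_regions([cg17], [EH1])["CG17"]

    def test_empty_registry(self):
        s = CpGSite("x", CHROMOSOME, 53250000)
        assert assign_sites_to_regions([s], []) == {"x": []}

    def test_membership_invariant_under_region_order(self):
        sites = [CpGSite(f"s{i}", CHROMOSOME, 53246080 + 997 * i) for i in range(10)]
        fwd = assign_sites_to_regions(sites, list(DEFAULT_REGISTRY))
        rev = assign_sites_to_regions(sites, list(DEFAULT_REGISTRY)[::-1])
        assert fwd == rev

    def test_chromosome_mismatch_raises(self):
        s = CpGSite("x", "chr1", 53250000)
        with pytest.raises(ValidationError):
            assign_sites_to_regions([s], [CGI1])

    def test_registry_round_trip(self, tmp_path):
        p = tmp_path / "regions.tsv"
        write_region_registry(DEFAULT_REGISTRY, p)
        back = read_region_registry(p)
        assert list(back) == list(DEFAULT_REGISTRY)

    def test_registry_requires_coordinate_flag(self, tmp_path):
        p = tmp_path / "bed.tsv"
        p.write_text("chr8\t1\t10\tx\n")
        with pytest.raises(ValidationError, match="1-based"):
            read_region_registry(p)


class TestCoverageFilter:
    def _matrix(self, coverages, meth_frac=0.5):
        sites = [CpGSite(f"CG{j}", CHROMOSOME, 53253000 - j) for j in range(coverages.shape[1])]
        meth = (coverages * meth_frac).astype(int)
        return MethylationCountMatrix(
            [f"s{i}" for i in range(coverages.shape[0])],
            sites,
            meth,
            coverages - meth,
        )

    def test_cell_below_threshold_masked_boundary_kept(self):
        cov = np.array([[24, 25], [30, 30]])
        m = self._matrix(cov)
        out, rep = apply_coverage_filter(m, min_coverage=25)
        assert not out.mask[0, 0] and out.mask[0, 1] and out.mask.sum() == 3
        assert rep.n_masked_low_coverage == 1

    def test_identity_when_all_covered(self):
        cov = np.full((4, 3), 40)
        m = self._matrix(cov)
        out, rep = apply_coverage_filter(m, min_coverage=25)
        assert out.mask.all()
        assert rep.n_masked_low_coverage == 0 and rep.n_sites_dropped == 0

    def test_site_dropped_when_group_too_thin(self):
        cov = np.array([[30, 10], [30, 10], [30, 30], [30, 30], [30, 30], [30, 30]])
        m = self._matrix(cov)
        groups = {f"s{i}": ("BPD" if i < 3 else "HC") for i in range(6)}
        out, rep = apply_coverage_filter(m, 25, groups, min_per_group=2)
        assert [s.site_id for s in out.sites] == ["CG0"]
        assert rep.dropped_site_ids == ["CG1"]

    def test_all_masked_is_legal_and_flagged(self):
        cov = np.full((3, 2), 5)
        m = self._matrix(cov)
        out, rep = apply_coverage_filter(m, min_coverage=25)
        assert rep.everything_masked

    @given(st.integers(1, 60))
    @settings(max_examples=20, deadline=None)
    def test_every_unmasked_cell_meets_threshold(self, min_cov):
        rng = np.random.default_rng(min_cov)
        cov = rng.integers(0, 80, size=(6, 5))
        m = self._matrix(cov)
        out, _ = apply_coverage_filter(m, min_coverage=min_cov)
        assert (out.coverage()[out.mask] >= min_cov).all()

    def test_masked_cells_never_contribute(self, toy_matrix):
        toy_matrix.mask[0, 0] = False
        rates = toy_matrix.rates()
        assert np.isnan(rates[0, 0])
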