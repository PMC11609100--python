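"""DMR calling: run detection, correlation structure, group test."""

import numpy as np
import pandas as pd
import pytest

from kormeth.data import CHROMOSOME, CpGSite, MethylationCountMatrix, ValidationError
from kormeth.dmr import (
    DMRDefinition,
    SignificantRun,
    define_dmr,
    find_significant_runs,
    pairwise_rate_correlations,
)
from kormeth.dmr import test_dmr_mean as dmr_mean_test  # avoid pytest collection
from kormeth.regions import subject_region_means
from kormeth.data import GenomicRegion
from kormeth.simulate import simulate_cohort
from kormeth.sitewise import SiteTestResult, screen_sites

from conftest import tiny_config, tiny_site_map


def fake_results(pattern, signs=None):
    """SiteTestResults in gene order with a given significance pattern."""
    signs = signs or [1] * len(pattern)
    out = []
    for i, (sig, sgn) in enumerate(zip(pattern, signs)):
        out.append(
            SiteTestResult(
                site=CpGSite(f"CG{i + 1}", CHROMOSOME, 53253000 - 10 * i),
                rate_bpd=50.0,
                rate_hc=52.0,
                odds_ratio=np.exp(0.1 * sgn),
                log_odds_diff=0.1 * sgn,
                t_value=3.0 * sgn,
                df=91,
                p_raw=0.001 if sig else 0.5,
                p_normal=0.001 if sig else 0.5,
                n_used=95,
                p_adjusted=0.01 if sig else 0.6,
                significant=bool(sig),
            )
        )
    return out


class TestRuns:
    def test_published_pattern_yields_one_run_of_five(self):
        # eight hits: one solitary, five adjacent, then isolated sites
        res = fake_results([1, 0, 1, 1, 1, 1, 1, 0])
        rep = find_significant_runs(res, min_run=3)
        assert len(rep.runs) == 1
        assert rep.runs[0].site_ids == ["CG3", "CG4", "CG5", "CG6", "CG7"]
        assert rep.solitary == ["CG1"]

    def test_no_significant_sites(self):
        rep = find_significant_runs(fake_results([0, 0, 0]))
        assert rep.runs == [] and rep.solitary == []

    def test_short_prefix_reported_solitary(self):
        rep = find_significant_runs(fake_results([1, 1, 0, 1, 1, 1]), min_run=3)
        assert len(rep.runs) == 1
        assert rep.runs[0].site_ids == ["CG4", "CG5", "CG6"]
        assert rep.solitary == ["CG1", "CG2"]

    def test_sign_change_breaks_run(self):
        res = fake_results([1, 1, 1, 1], signs=[1, 1, -1, -1])
        rep = find_significant_runs(res, min_run=2)
        assert [r.site_ids for r in rep.runs] == [["CG1", "CG2"], ["CG3", "CG4"]]
        assert {r.effect_sign for r in rep.runs} == {1, -1}

    def test_untestable_sites_skipped_in_adjacency(self):
        res = fake_results([1, 0, 1, 1])
        res[1].flag = "untestable"
        rep = find_significant_runs(res, min_run=3)
        assert rep.runs[0].site_ids == ["CG1", "CG3", "CG4"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            find_significant_runs([])


def matrix_from_rates(rates, coverage=10_000):
    rates = np.asarray(rates, float)
    n, m = rates.shape
    sites = [CpGSite(f"CG{j + 1}", CHROMOSOME, 53253000 - 10 * j) for j in range(m)]
    meth = np.round(rates * coverage).astype(int)
    return MethylationCountMatrix(
        [f"s{i}" for i in range(n)], sites, meth, coverage - meth
    )


class TestCorrelations:
    def test_self_correlation_unit_diagonal(self):
        mx = matrix_from_rates(np.random.default_rng(0).uniform(0.2, 0.8, (6, 3)))
        corr = pairwise_rate_correlations(mx, ["CG1", "CG2", "CG3"])
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T, equal_nan=True)

    def test_exact_anticorrelation(self):
        y = np.array([0.1, 0.3, 0.5, 0.7])
        mx = matrix_from_rates(np.column_stack([y, 1 - y]))
        corr = pairwise_rate_correlations(mx, ["CG1", "CG2"])
        assert corr.loc["CG1", "CG2"] == pytest.approx(-1.0, abs=1e-9)

    def test_hand_computed_perfect_correlation(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        mx = matrix_from_rates(np.column_stack([a, 2 * a]))
        corr = pairwise_rate_correlations(mx, ["CG1", "CG2"])
        assert corr.loc["CG1", "CG2"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_site_gives_nan(self):
        mx = matrix_from_rates(np.column_stack([np.full(4, 0.5), [0.1, 0.2, 0.3, 0.4]]))
        corr = pairwise_rate_correlations(mx, ["CG1", "CG2"])
        assert np.isnan(corr.loc["CG1", "CG2"])


def cohort_with_block(shared_sd, seed=12, n=150):
    sites = tiny_site_map(n_sites=8, coverage_mean=100)
    cfg = tiny_config(
        seed=seed,
        n_bpd=n,
        n_hc=n,
        sites=sites,
        dmr_site_ids=("CG3", "CG4", "CG5"),
        dmr_shared_sd=shared_sd,
    )
    return simulate_cohort(cfg)


class TestDefineDmr:
    def run_for(self, ids):
        return SignificantRun(site_ids=list(ids), effect_sign=1)

    def test_shared_effect_block_accepted(self):
        ph, mx = cohort_with_block(0.4)
        dmr = define_dmr(self.run_for(["CG3", "CG4", "CG5"]), mx, min_median_r=0.6)
        assert dmr.accepted and dmr.median_r > 0.6

    def test_independent_sites_rejected(self):
        ph, mx = cohort_with_block(0.0)
        dmr = define_dmr(self.run_for(["CG3", "CG4", "CG5"]), mx, min_median_r=0.6)
        assert not dmr.accepted and "median pairwise r" in dmr.reject_reason

    def test_zero_threshold_accepts_any_run(self):
        ph, mx = cohort_with_block(0.0)
        dmr = define_dmr(self.run_for(["CG3", "CG4", "CG5"]), mx, min_median_r=0.0)
        assert dmr.accepted

    def test_interval_spans_members(self):
        ph, mx = cohort_with_block(0.3)
        dmr = define_dmr(self.run_for(["CG3", "CG4", "CG5"]), mx)
        pos = [s.position for s in mx.sites if s.site_id in dmr.member_sites]
        assert dmr.interval.start == min(pos) and dmr.interval.end == max(pos)

    def test_per_subject_mean_consistent_with_region_mean(self):
        ph, mx = cohort_with_block(0.3)
        dmr = define_dmr(self.run_for(["CG3", "CG4", "CG5"]), mx)
        region = GenomicRegion("R", CHROMOSOME, dmr.interval.start, dmr.interval.end)
        expected = subject_region_means(mx, region)
        pd.testing.assert_series_equal(
            dmr.per_subject_mean, expected, check_names=False
        )


class TestDmrMeanTest:
    def test_df_contract_full_cohort(self):
        effects = np.zeros(8)
        effects[2:5] = -0.15
        sites = tiny_site_map(n_sites=8, coverage_mean=100, group_effects=effects)
        cfg = tiny_config(seed=3, n_bpd=47, n_hc=48, sites=sites,
                          dmr_site_ids=("CG3", "CG4", "CG5"), dmr_shared_sd=0.2)
        ph, mx = simulate_cohort(cfg)
        dmr = define_dmr(SignificantRun(["CG3", "CG4", "CG5"], 1), mx, min_median_r=0)
        res = dmr_mean_test(dmr, ph)
        assert res.n_complete == 95 and res.df == 91

    def test_hypomethylated_block_gives_negative_coefficient(self):
        hits = 0
        for seed in range(10):
            effects = np.zeros(8)
            effects[2:5] = -0.15
            sites = tiny_site_map(n_sites=8, coverage_mean=150, group_effects=effects)
            cfg = tiny_config(seed=100 + seed, n_bpd=47, n_hc=48, sites=sites,
                              dmr_site_ids=("CG3", "CG4", "CG5"), dmr_shared_sd=0.1)
            ph, mx = simulate_cohort(cfg)
            dmr = define_dmr(SignificantRun(["CG3", "CG4", "CG5"], 1), mx, min_median_r=0)
            res = dmr_mean_test(dmr, ph)
            hits += res.group_coef < 0
        assert hits >= 9
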