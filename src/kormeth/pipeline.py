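"""End-to-end orchestration: filter -> region tests -> site screen -> DMR
call -> association models, with per-stage TSV/JSON outputs and a summary
document.  Fully deterministic given the seed (one global seed fans out to
per-stage substreams)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import dmr as dmrmod
from . import regions as regmod
from . import sitewise
from .data import (
    A_PRIORI_REGIONS,
    DEFAULT_REGISTRY,
    TARGET_WINDOW,
    FilterReport,
    ValidationError,
    apply_coverage_filter,
    matrix_from_coverage_dir,
    read_region_registry,
    read_sample_sheet,
    region_length,
    write_wide_counts,
)
from .descriptives import describe
from .simulate import default_config, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts_dir: str | None = None
    sample_sheet: str | None = None
    registry: str | None = None
    simulate: bool = False
    n_bpd: int = 47
    n_hc: int = 48
    min_coverage: int = 25
    min_per_group: int = 3
    alpha: float = 0.05
    min_run: int = 3
    min_median_r: float = 0.6
    bootstrap_reps: int = 10_000
    seed: int = 0
    output_dir: str = "results"


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_report: FilterReport
    descriptives: pd.DataFrame
    region_results: list
    site_results: list
    run_report: object
    dmrs: list
    dmr_tests: list
    association_tables: dict
    output_dir: Path


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = default_config(seed=config.seed, n_bpd=config.n_bpd, n_hc=config.n_hc)
        phenotypes, matrix = simulate_cohort(sim)
        registry = list(DEFAULT_REGISTRY)
        return phenotypes, matrix, registry
    for attr in ("counts_dir", "sample_sheet", "registry"):
        path = getattr(config, attr)
        if path is None or not Path(path).exists():
            raise ValidationError(f"missing input: {attr} = {path!r}")
    phenotypes = read_sample_sheet(config.sample_sheet)
    registry = read_region_registry(config.registry)
    window = next((r for r in registry if r.name == "window"), TARGET_WINDOW)
    # site inventory = union of positions present in the coverage files
    counts_dir = Path(config.counts_dir)
    from .data import CpGSite, read_coverage_file

    positions: set[tuple[str, int]] = set()
    for subj in phenotypes["subject_id"]:
        positions.update(read_coverage_file(counts_dir / f"{subj}.cov", subj, window=window))
    sites = [
        CpGSite(f"pos{p}", c, p)
        for c, p in sorted(positions, key=lambda cp: -cp[1])
    ]
    matrix = matrix_from_coverage_dir(counts_dir, list(phenotypes["subject_id"]), sites, window)
    return phenotypes, matrix, registry


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))

    phenotypes, matrix, registry = _load_inputs(config)
    logger.info("cohort: %d subjects, %d designed sites", matrix.n_subjects, matrix.n_sites)

    groups = dict(zip(phenotypes["subject_id"], phenotypes["group"]))
    filtered, report = apply_coverage_filter(
        matrix, config.min_coverage, groups, config.min_per_group
    )
    (out / "filter_report.json").write_text(report.to_json())
    write_wide_counts(filtered, out / "filtered_counts.tsv")
    logger.info(
        "coverage filter: %d cells masked, %d sites dropped, %d sites retained",
        report.n_masked_low_coverage,
        report.n_sites_dropped,
        filtered.n_sites,
    )

    desc = describe(phenotypes)
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)

    named = {r.name: r for r in registry}
    a_priori = [named.get(r.name, r) for r in A_PRIORI_REGIONS]
    region_results = regmod.test_regions(
        filtered,
        phenotypes,
        a_priori,
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    _region_table(region_results).to_csv(out / "region_tests.tsv", sep="\t", index=False)

    site_results = sitewise.screen_sites(
        filtered, phenotypes, alpha=config.alpha, min_per_group=config.min_per_group
    )
    sitewise.results_table(site_results).to_csv(out / "site_tests.tsv", sep="\t", index=False)
    n_sig = sum(r.significant for r in site_results)
    logger.info(
        "site screen: %d designed, %d tested, %d significant at FDR %.2f",
        matrix.n_sites,
        sum(1 for r in site_results if not r.flag),
        n_sig,
        config.alpha,
    )

    run_report = dmrmod.find_significant_runs(site_results, min_run=config.min_run)
    dmrs = []
    dmr_tests = []
    association_tables: dict[str, pd.DataFrame] = {}
    for i, run in enumerate(run_report.runs):
        dmr = dmrmod.define_dmr(
            run, filtered, min_median_r=config.min_median_r, name=f"DMR{i + 1}"
        )
        dmrs.append(dmr)
        if dmr.accepted:
            dmr_tests.append(dmrmod.test_dmr_mean(dmr, phenotypes))
            tbl = assoc.association_table(dmr.per_subject_mean, phenotypes)
            tbl.to_csv(out / f"associations_{dmr.name}.tsv", sep="\t", index=False)
            association_tables[dmr.name] = tbl
    _write_dmr_report(dmrs, dmr_tests, out / "dmr.json")

    result = PipelineResult(
        config=config,
        filter_report=report,
        descriptives=desc,
        region_results=region_results,
        site_results=site_results,
        run_report=run_report,
        dmrs=dmrs,
        dmr_tests=dmr_tests,
        association_tables=association_tables,
        output_dir=out,
    )
    (out / "summary.md").write_text(render_report(result))
    return result


def _region_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "region": r.region,
            "adjusted_mean_bpd": r.adjusted_mean_bpd,
            "adjusted_mean_hc": r.adjusted_mean_hc,
            "group_coef": r.group_coef,
            "t_value": r.t_value,
            "df": r.df,
            "p_value": r.p_value,
            "shapiro_p": r.shapiro_p,
            "breusch_pagan_p": r.breusch_pagan_p,
            "assumption_flag": r.assumption_flag,
            "n_complete": r.n_complete,
        }
        if r.bootstrap is not None:
            row.update(
                bootstrap_ci_low=r.bootstrap.ci_low,
                bootstrap_ci_high=r.bootstrap.ci_high,
                bootstrap_p=r.bootstrap.p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_dmr_report(dmrs, dmr_tests, path: Path) -> None:
    tests = {t.region: t for t in dmr_tests}
    payload = []
    for d in dmrs:
        entry = {
            "name": d.name,
            "member_sites": d.member_sites,
            "interval": {
                "chromosome": d.interval.chromosome,
                "start": d.interval.start,
                "end": d.interval.end,
                "length_inclusive_bp": region_length(d.interval, "inclusive"),
                "length_difference_bp": region_length(d.interval, "difference"),
            },
            "median_pairwise_r": d.median_r,
            "correlations": d.correlations.round(4).to_dict(),
            "accepted": d.accepted,
            "reject_reason": d.reject_reason,
            "effect_sign": d.effect_sign,
        }
        t = tests.get(d.name)
        if t is not None:
            entry["group_test"] = {
                "adjusted_mean_bpd": t.adjusted_mean_bpd,
                "adjusted_mean_hc": t.adjusted_mean_hc,
                "t_value": t.t_value,
                "df": t.df,
                "p_value": t.p_value,
                "n_complete": t.n_complete,
            }
        payload.append(entry)
    path.write_text(json.dumps(payload, indent=2, default=float))


def render_report(result: PipelineResult) -> str:
    """Deterministic human-readable summary of every stage."""
    lines = ["# OPRK1 promoter methylation analysis — summary", ""]
    rep = result.filter_report
    n_tested = sum(1 for r in result.site_results if not r.flag)
    lines += [
        "## Cohort and filtering",
        f"- designed CpG sites: {rep.n_sites_in}",
        f"- cells masked below {rep.min_coverage} reads: {rep.n_masked_low_coverage}",
        f"- sites dropped (<{rep.min_per_group} usable subjects in a group): {rep.n_sites_dropped}",
        f"- sites analyzed: {n_tested}",
        "",
        "## Group descriptives (Welch t; symptom scales one-sided)",
        result.descriptives.round(3).to_string(index=False),
        "",
        "## A priori region tests (mean rate % ~ group + age + BMI)",
    ]
    for r in result.region_results:
        boot = (
            f"; bootstrap p={r.bootstrap.p_value:.3f} "
            f"CI[{r.bootstrap.ci_low:.2f}, {r.bootstrap.ci_high:.2f}]"
            if r.bootstrap
            else ""
        )
        note = " [normality/heteroscedasticity flag]" if r.assumption_flag else ""
        lines.append(
            f"- {r.region}: BPD {r.adjusted_mean_bpd:.1f}% vs HC {r.adjusted_mean_hc:.1f}%, "
            f"t({r.df})={r.t_value:.2f}, p={r.p_value:.3f}{boot}{note}"
        )
    sig = [r for r in result.site_results if r.significant]
    lines += ["", "## Per-CpG screen (binomial GLM, BH-FDR)"]
    if sig:
        lines.append(f"- significant sites ({len(sig)}):")
        for r in sig:
            lines.append(
                f"    - {r.site.site_id} {r.site.chromosome}:{r.site.position} "
                f"BPD {r.rate_bpd:.2f}% HC {r.rate_hc:.2f}% OR {r.odds_ratio:.3f} "
                f"t({r.df})={r.t_value:.3f} p_adj={r.p_adjusted:.4f}"
            )
    else:
        lines.append("- zero significant sites at the FDR threshold")
    lines += ["", "## DMR calls"]
    if result.dmrs:
        for d in result.dmrs:
            status = "accepted" if d.accepted else f"rejected ({d.reject_reason})"
            lines.append(
                f"- {d.name}: {', '.join(d.member_sites)} "
                f"[{d.interval.chromosome}:{d.interval.start}-{d.interval.end}, "
                f"{region_length(d.interval, 'inclusive')} bp inclusive / "
                f"{region_length(d.interval, 'difference')} bp difference], "
                f"median r={d.median_r:.3f} — {status}"
            )
        for t in result.dmr_tests:
            lines.append(
                f"- {t.region} group test: BPD {t.adjusted_mean_bpd:.1f}% vs "
                f"HC {t.adjusted_mean_hc:.1f}%, t({t.df})={t.t_value:.2f}, p={t.p_value:.3f}"
            )
    else:
        lines.append("- no candidate runs")
    lines += ["", "## DMR associations (raw p values; no family-wise correction)"]
    if result.association_tables:
        for name, tbl in result.association_tables.items():
            ok = tbl[tbl["error"] == ""] if "error" in tbl.columns else tbl
            lines.append(f"### {name}")
            cols = ["predictor", "mode", "slope_b", "p_value", "n_complete"]
            lines.append(ok[cols].round(4).to_string(index=False))
    else:
        lines.append("- no accepted DMR, association models not run")
    return "\n".join(lines) + "\n"
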