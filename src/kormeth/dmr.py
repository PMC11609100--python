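"""DMR calling from runs of adjacent significant CpG sites.

A candidate DMR is a maximal run of consecutive *tested* sites (in gene
5'->3' order; adjacency is positional among post-filter sites, not
base-pair distance) that are FDR-significant with a common effect sign and
have length >= ``min_run``.  Shorter significant sites are reported as
solitary.  A run is accepted as a DMR when the median pairwise Pearson
correlation of its member-site rates across subjects reaches
``min_median_r`` (no published threshold exists; the full matrix is always
emitted so any other rule can be applied).

The DMR's per-subject mean rate (unweighted over member sites) is tested
between groups with the same adjusted linear model used for the a priori
regions.  Because that test ignores coverage, it can disagree in
significance with the count-weighted per-site tests; this is a documented
property, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenomicRegion, MethylationCountMatrix, ValidationError
from .regions import RegionTestResult, fit_region_model
from .sitewise import SiteTestResult


@dataclass
class SignificantRun:
    site_ids: list[str]
    effect_sign: int  # +1: hypomethylated in BPD (OR > 1), -1: the opposite


@dataclass
class RunReport:
    runs: list[SignificantRun]
    solitary: list[str]  # significant sites not in any run of length >= min_run


@dataclass
class DMRDefinition:
    name: str
    member_sites: list[str]
    interval: GenomicRegion
    correlations: pd.DataFrame  # symmetric, unit diagonal
    per_subject_mean: pd.Series  # fraction in [0, 1]
    effect_sign: int
    median_r: float
    accepted: bool
    reject_reason: str = ""


def find_significant_runs(
    site_results: list[SiteTestResult], min_run: int = 3
) -> RunReport:
    """Maximal same-sign runs of consecutive significant tested sites.

    ``site_results`` must already be in gene order (as from
    ``screen_sites``); untestable sites are excluded from the adjacency
    sequence.
    """
    if not site_results:
        raise ValidationError("empty site results")
    if min_run < 2:
        raise ValidationError("min_run must be >= 2")
    tested = [r for r in site_results if not r.flag]
    runs: list[SignificantRun] = []
    solitary: list[str] = []
    current: list[SiteTestResult] = []

    def flush() -> None:
        if len(current) >= min_run:
            runs.append(
                SignificantRun(
                    site_ids=[r.site.site_id for r in current],
                    effect_sign=int(np.sign(current[0].log_odds_diff)),
                )
            )
        else:
            solitary.extend(r.site.site_id for r in current)

    for r in tested:
        sign = int(np.sign(r.log_odds_diff)) if r.significant else 0
        if r.significant and (not current or sign == int(np.sign(current[0].log_odds_diff))):
            current.append(r)
        else:
            flush()
            current = [r] if r.significant else []
    flush()
    return RunReport(runs=runs, solitary=solitary)


def pairwise_rate_correlations(
    matrix: MethylationCountMatrix, site_ids: list[str], min_subjects: int = 3
) -> pd.DataFrame:
    """Pearson r of per-subject rates for each site pair, computed over
    subjects with both sites unmasked; NaN where a site is constant or
    fewer than ``min_subjects`` subjects overlap."""
    idx = [matrix.site_index(s) for s in site_ids]
    rates = matrix.rates()[:, idx]
    k = len(site_ids)
    out = np.full((k, k), np.nan)
    for a in range(k):
        out[a, a] = 1.0
        for b in range(a + 1, k):
            both = ~np.isnan(rates[:, a]) & ~np.isnan(rates[:, b])
            if both.sum() < min_subjects:
                continue
            xa, xb = rates[both, a], rates[both, b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue  # undefined correlation, leave NaN
            out[a, b] = out[b, a] = np.corrcoef(xa, xb)[0, 1]
    return pd.DataFrame(out, index=site_ids, columns=site_ids)


def define_dmr(
    run: SignificantRun,
    matrix: MethylationCountMatrix,
    min_median_r: float = 0.6,
    name: str = "DMR",
) -> DMRDefinition:
    """Quantify a candidate run and accept it as a DMR when the member
    sites' rates are sufficiently inter-correlated."""
    if not 0.0 <= min_median_r <= 1.0:
        raise ValidationError("min_median_r must lie in [0, 1]")
    corr = pairwise_rate_correlations(matrix, run.site_ids)
    k = len(run.site_ids)
    off_diag = corr.to_numpy()[np.triu_indices(k, 1)]
    median_r = float(np.nanmedian(off_diag)) if k > 1 else np.nan
    idx = [matrix.site_index(s) for s in run.site_ids]
    rates = matrix.rates()[:, idx]
    with np.errstate(invalid="ignore"):
        per_subject = pd.Series(
            np.nanmean(rates, axis=1), index=matrix.subjects, name=name
        )
    positions = [matrix.sites[j].position for j in idx]
    interval = GenomicRegion(
        name, matrix.sites[idx[0]].chromosome, min(positions), max(positions)
    )
    # a zero threshold disables the correlation gate entirely
    if min_median_r == 0.0:
        accepted = True
    else:
        accepted = bool(median_r >= min_median_r) if np.isfinite(median_r) else False
    return DMRDefinition(
        name=name,
        member_sites=list(run.site_ids),
        interval=interval,
        correlations=corr,
        per_subject_mean=per_subject,
        effect_sign=run.effect_sign,
        median_r=median_r,
        accepted=accepted,
        reject_reason=""
        if accepted
        else f"median pairwise r {median_r:.3f} < threshold {min_median_r}",
    )


def test_dmr_mean(dmr: DMRDefinition, phenotypes: pd.DataFrame) -> RegionTestResult:
    """Adjusted group comparison of the DMR per-subject mean rate; same
    contract as the a priori region test."""
    return fit_region_model(dmr.per_subject_mean, phenotypes, region_name=dmr.name)
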