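"""Region-level group comparison of mean methylation.

For each subject the region methylation is the unweighted mean of the
per-site rates over unmasked member sites.  Group differences are tested
with an ordinary least-squares model

    mean rate [%] ~ group + age + BMI

using the t of the group (BPD vs HC) coefficient with residual df
n_complete - 4.  Rates are modelled on the percentage scale to match how
region means are reported; no logit transform is applied at region level.
Model prerequisites are checked with Shapiro-Wilk (residual normality) and
Breusch-Pagan (homoscedasticity); a nonparametric case-resampling bootstrap
of the same regression is available as a robustness fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .data import GenomicRegion, MethylationCountMatrix, ValidationError


@dataclass
class BootstrapResult:
    n_replicates: int
    n_discarded: int  # replicates without both groups
    coef_mean: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RegionTestResult:
    region: str
    adjusted_mean_bpd: float  # % at mean age, mean BMI
    adjusted_mean_hc: float
    group_coef: float  # BPD - HC difference, percentage points
    t_value: float
    df: int
    p_value: float
    shapiro_p: float
    breusch_pagan_p: float
    n_complete: int
    assumption_flag: bool = False
    bootstrap: BootstrapResult | None = None


def subject_region_means(
    matrix: MethylationCountMatrix, region: GenomicRegion
) -> pd.Series:
    """Per-subject unweighted mean methylation rate (fraction in [0, 1])
    over the region's unmasked member sites; NaN when no member site is
    usable for a subject."""
    member_idx = [
        j
        for j, s in enumerate(matrix.sites)
        if s.chromosome == region.chromosome and region.contains(s.position)
    ]
    if not member_idx:
        return pd.Series(np.nan, index=matrix.subjects, name=region.name)
    rates = matrix.rates()[:, member_idx]
    cnt = (~np.isnan(rates)).sum(axis=1)
    sums = np.nansum(rates, axis=1)
    means = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return pd.Series(means, index=matrix.subjects, name=region.name)


def subject_region_mean(matrix: MethylationCountMatrix, region, subject: str) -> float:
    """Single-subject convenience wrapper around :func:`subject_region_means`."""
    val = subject_region_means(matrix, region).loc[subject]
    if np.isnan(val):
        raise ValidationError(f"{subject}: no usable member site in {region.name}")
    return float(val)


def _design(region_means: pd.Series, phenotypes: pd.DataFrame):
    """Complete-case design matrix [1, group(BPD=1), age, bmi] and outcome in %."""
    df = phenotypes.set_index("subject_id").loc[:, ["group", "age", "bmi"]].copy()
    df["y"] = region_means.reindex(df.index) * 100.0
    df = df.dropna()
    if len(df) < 5:
        raise ValidationError("need >= 5 complete cases")
    if df["group"].nunique() < 2:
        raise ValidationError("both groups must be represented")
    cols = [np.ones(len(df)), (df["group"] == "BPD").to_numpy(float)]
    # a constant covariate carries no information and would only make the
    # design singular; dropping it reduces the model to the plain comparison
    for cov in ("age", "bmi"):
        v = df[cov].to_numpy(float)
        if np.ptp(v) > 0:
            cols.append(v)
    X = np.column_stack(cols)
    labels = ["const", "group"] + [c for c in ("age", "bmi") if np.ptp(df[c].to_numpy(float)) > 0]
    return X, df["y"].to_numpy(float), df, labels


def fit_region_model(
    region_means: pd.Series,
    phenotypes: pd.DataFrame,
    region_name: str | None = None,
    check: bool = True,
) -> RegionTestResult:
    """OLS of region mean rate (%) on group + age + BMI.

    Adjusted group means are the model predictions at the sample-mean age
    and BMI; their difference equals the group coefficient exactly.
    """
    X, y, df, labels = _design(region_means, phenotypes)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError("collinear covariates: design matrix is rank deficient")
    model = sm.OLS(y, X).fit()
    n = len(y)
    coef = model.params[1]
    at_means = {"const": 1.0, "group": 0.0, "age": df["age"].mean(), "bmi": df["bmi"].mean()}
    row = np.array([at_means[lab] for lab in labels])
    mean_hc = float(model.params @ row)
    row[1] = 1.0
    mean_bpd = float(model.params @ row)
    if check:
        shapiro_p, bp_p, flag = check_assumptions(model, X)
    else:
        shapiro_p = bp_p = np.nan
        flag = False
    return RegionTestResult(
        region=region_name or str(region_means.name),
        adjusted_mean_bpd=mean_bpd,
        adjusted_mean_hc=mean_hc,
        group_coef=float(coef),
        t_value=float(model.tvalues[1]),
        df=int(n - X.shape[1]),
        p_value=float(model.pvalues[1]),
        shapiro_p=shapiro_p,
        breusch_pagan_p=bp_p,
        n_complete=n,
        assumption_flag=flag,
    )


def check_assumptions(fit, exog: np.ndarray, alpha: float = 0.05):
    """Shapiro-Wilk on residuals and Breusch-Pagan against the predictors.

    Returns (shapiro_p, breusch_pagan_p, flag) with flag=True when either
    test rejects at ``alpha``.
    """
    resid = np.asarray(fit.resid)
    if len(resid) < 5:
        raise ValidationError("need >= 5 residuals")
    if np.allclose(resid, resid[0]):
        raise ValidationError("constant residuals: diagnostics undefined")
    shapiro_p = float(stats.shapiro(resid).pvalue)
    bp_p = float(het_breuschpagan(resid, exog)[1])
    return shapiro_p, bp_p, bool(shapiro_p < alpha or bp_p < alpha)


def bootstrap_region_model(
    region_means: pd.Series,
    phenotypes: pd.DataFrame,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric case-resampling bootstrap of the group coefficient.

    Subjects are resampled with replacement and the OLS refit per
    replicate; replicates missing one group (or with a singular design) are
    discarded and counted.  The 95% CI is the percentile interval; the
    two-sided p is twice the smaller tail fraction at zero.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    X, y, _, _ = _design(region_means, phenotypes)
    n = len(y)
    rng = np.random.default_rng(seed)
    coefs = np.empty(n_replicates)
    n_discarded = 0
    kept = 0
    # vectorized in chunks: batched normal equations over resampled designs
    chunk = 2000
    while kept < n_replicates:
        b = min(chunk, n_replicates - kept)
        idx = rng.integers(0, n, size=(b, n))
        Xb = X[idx]  # (b, n, 4)
        yb = y[idx]  # (b, n)
        has_both = (Xb[:, :, 1].min(axis=1) == 0.0) & (Xb[:, :, 1].max(axis=1) == 1.0)
        G = np.einsum("bni,bnj->bij", Xb, Xb)
        h = np.einsum("bni,bn->bi", Xb, yb)
        ok = has_both & (np.linalg.matrix_rank(G) == X.shape[1])
        n_discarded += int(b - ok.sum())
        if ok.any():
            beta = np.linalg.solve(G[ok], h[ok][..., None])[..., 0]
            take = min(int(ok.sum()), n_replicates - kept)
            coefs[kept : kept + take] = beta[:take, 1]
            kept += take
    ci_low, ci_high = np.percentile(coefs, [2.5, 97.5])
    frac_le = float(np.mean(coefs <= 0))
    frac_ge = float(np.mean(coefs >= 0))
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    if n_discarded > 0.1 * n_replicates:
        import logging

        logging.getLogger(__name__).warning(
            "bootstrap discarded %d of %d replicates", n_discarded, n_replicates
        )
    return BootstrapResult(
        n_replicates=n_replicates,
        n_discarded=n_discarded,
        coef_mean=float(coefs.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
    )


def test_regions(
    matrix: MethylationCountMatrix,
    phenotypes: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    bootstrap_reps: int = 10_000,
    seed: int = 0,
    bootstrap_always: bool = True,
) -> list[RegionTestResult]:
    """Run the adjusted group comparison for each region; the bootstrap is
    computed for every region (it is the headline only where the normality
    check fires)."""
    results = []
    for k, region in enumerate(regions):
        means = subject_region_means(matrix, region)
        res = fit_region_model(means, phenotypes, region_name=region.name)
        if bootstrap_always and bootstrap_reps > 0:
            res.bootstrap = bootstrap_region_model(
                means, phenotypes, n_replicates=bootstrap_reps, seed=seed + k
            )
        results.append(res)
    return results
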