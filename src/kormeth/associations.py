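"""Symptom-severity and childhood-trauma associations with DMR methylation.

The DMR per-subject mean rate (%) is regressed on one predictor at a time —
a symptom scale entered as its raw mean score, or a CTQ measure entered
dimensionally (score) or categorically (exposure above the published
cutoff) — always controlling for age and BMI.  Slopes are therefore in
percentage points of methylation per unit predictor; a negative slope means
hypomethylation with greater severity/trauma.

No multiple-testing correction is applied across this family of models;
outputs carry raw p values and say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import ValidationError

#: Published mean-score cutoffs for at-least-moderate traumatization,
#: applied with a strictly-greater rule.
CTQ_CUTOFFS: dict[str, float] = {
    "CTQ_EA": 2.4,
    "CTQ_PA": 1.8,
    "CTQ_SA": 1.4,
    "CTQ_EN": 2.8,
    "CTQ_PN": 2.4,
}

SYMPTOM_SCALES = (
    "BSL23",
    "ZAN_BPD",
    "DES",
    "BIS",
    "BIS_motor",
    "BIS_attentional",
    "BIS_nonplanning",
)

CTQ_SCALES = ("CTQ", "CTQ_EA", "CTQ_PA", "CTQ_SA", "CTQ_EN", "CTQ_PN")


@dataclass
class AssociationResult:
    predictor: str
    mode: str  # "dimensional" or "categorical"
    cohort: str  # "pooled", "BPD", "HC"
    slope_b: float  # % methylation per predictor unit (or exposed-vs-not contrast)
    se: float
    t_value: float
    p_value: float
    n_complete: int
    df: int
    n_exposed: int | None = None  # categorical mode only


def ctq_categorize(
    phenotypes: pd.DataFrame, cutoffs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-subject exposure flags for each CTQ subscale (score strictly
    above the cutoff); missing scores yield missing flags."""
    cutoffs = CTQ_CUTOFFS if cutoffs is None else cutoffs
    unknown = set(cutoffs) - set(CTQ_CUTOFFS)
    if unknown:
        raise ValidationError(f"unknown CTQ subscale(s): {sorted(unknown)}")
    out = pd.DataFrame(index=phenotypes.index)
    out["subject_id"] = phenotypes["subject_id"]
    for sub, cut in cutoffs.items():
        if sub not in phenotypes.columns:
            raise ValidationError(f"sample sheet lacks {sub}")
        score = phenotypes[sub]
        flag = score > cut
        out[sub + "_exposed"] = flag.astype("boolean").mask(score.isna())
    return out


def _fit(
    dmr_means: pd.Series,
    phenotypes: pd.DataFrame,
    predictor: pd.Series,
    label: str,
    mode: str,
    cohort: str,
) -> AssociationResult:
    df = phenotypes.set_index("subject_id")[["group", "age", "bmi"]].copy()
    df["x"] = predictor.to_numpy()
    df["y"] = dmr_means.reindex(df.index) * 100.0
    if cohort != "pooled":
        df = df[df["group"] == cohort]
    df = df.dropna(subset=["x", "y", "age", "bmi"])
    if len(df) < 5:
        raise ValidationError(f"{label}/{cohort}: fewer than 5 complete cases")
    x = df["x"].to_numpy(float)
    if np.std(x) == 0:
        raise ValidationError(f"{label}: predictor has no variance")
    cols = [np.ones(len(df)), x]
    for cov in ("age", "bmi"):  # constant covariates drop out of the model
        v = df[cov].to_numpy(float)
        if np.ptp(v) > 0:
            cols.append(v)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"{label}: predictor collinear with covariates")
    fit = sm.OLS(df["y"].to_numpy(float), X).fit()
    n_exposed = int(x.sum()) if mode == "categorical" else None
    return AssociationResult(
        predictor=label,
        mode=mode,
        cohort=cohort,
        slope_b=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_complete=len(df),
        df=int(len(df) - X.shape[1]),
        n_exposed=n_exposed,
    )


def fit_scale_association(
    dmr_means: pd.Series,
    phenotypes: pd.DataFrame,
    scale: str,
    cohort: str = "pooled",
) -> AssociationResult:
    """OLS of DMR mean rate (%) on a symptom scale + age + BMI."""
    if scale not in phenotypes.columns:
        raise ValidationError(f"unknown scale {scale!r}")
    return _fit(
        dmr_means, phenotypes, phenotypes[scale], scale, "dimensional", cohort
    )


def fit_ctq_association(
    dmr_means: pd.Series,
    phenotypes: pd.DataFrame,
    subscale: str,
    mode: str = "dimensional",
    cohort: str = "pooled",
) -> AssociationResult:
    """CTQ association, dimensional (raw score) or categorical (exposure
    above the published cutoff)."""
    if mode == "dimensional":
        if subscale not in CTQ_SCALES:
            raise ValidationError(f"unknown CTQ measure {subscale!r}")
        return _fit(
            dmr_means, phenotypes, phenotypes[subscale], subscale, mode, cohort
        )
    if mode == "categorical":
        if subscale not in CTQ_CUTOFFS:
            raise ValidationError(f"no published cutoff for {subscale!r}")
        flags = ctq_categorize(phenotypes, {subscale: CTQ_CUTOFFS[subscale]})
        x = flags[subscale + "_exposed"].astype("float")
        valid = x.dropna()
        if valid.nunique() < 2:
            raise ValidationError(
                f"{subscale}: exposure flag constant (need exposed and unexposed subjects)"
            )
        return _fit(dmr_means, phenotypes, x, subscale + "_cat", mode, cohort)
    raise ValidationError("mode must be 'dimensional' or 'categorical'")


def association_table(
    dmr_means: pd.Series, phenotypes: pd.DataFrame, cohort: str = "pooled"
) -> pd.DataFrame:
    """All symptom-scale and CTQ association models (dimensional for every
    scale; categorical additionally for the five CTQ subscales).  Models
    whose preconditions fail (e.g. a constant exposure flag) are skipped
    with a note in the ``error`` column."""
    rows = []

    def push(fn, *args, **kw):
        try:
            r = fn(dmr_means, phenotypes, *args, cohort=cohort, **kw)
            rows.append({**r.__dict__, "error": ""})
        except ValidationError as exc:
            rows.append({"predictor": args[0], "error": str(exc)})

    for scale in SYMPTOM_SCALES:
        if scale in phenotypes.columns:
            push(fit_scale_association, scale)
    for sub in CTQ_SCALES:
        if sub in phenotypes.columns:
            push(fit_ctq_association, sub, mode="dimensional")
    for sub in CTQ_CUTOFFS:
        if sub in phenotypes.columns:
            push(fit_ctq_association, sub, mode="categorical")
    return pd.DataFrame(rows)
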