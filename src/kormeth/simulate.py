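"""Synthetic cohort generator.

The study's subject-level data are not public, so every downstream stage is
exercised on simulated cohorts with the statistical structure the analysis
assumes: 47 BPD + 48 HC female subjects with published phenotype
distributions; 189 CpG sites across the 10 kb *OPRK1* window (hg38
chr8:53246080-53256098) with a realistic baseline methylation profile
(hypomethylated CpG-island promoter flanked by a methylation gap); unequal
per-site read coverage; logit-scale group/age/BMI effects; and a correlated
five-site hypomethylated block at the published DMR coordinates
(chr8:53252014-53252198), induced by a shared per-subject random effect.

Counts are beta-binomial so overdispersion is available; the default
concentration is high (near-binomial) because the downstream model is a
plain binomial GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .data import (
    CHROMOSOME,
    DEFAULT_REGISTRY,
    CpGSite,
    MethylationCountMatrix,
    ValidationError,
    write_coverage_file,
    write_region_registry,
    write_sample_sheet,
)

# ---------------------------------------------------------------------------
# Published per-group phenotype summaries (mean, sd). BIS and CTQ subscale
# summaries are not published; those defaults are stated assumptions
# (docs/methods.md) for a severe clinical cohort vs screened controls.
# ---------------------------------------------------------------------------

DEFAULT_PHENOTYPE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"BPD": (25.21, 4.21), "HC": (24.71, 3.96)},
    "bmi": {"BPD": (24.28, 5.58), "HC": (22.88, 3.79)},
    "BSL23": {"BPD": (2.10, 0.76), "HC": (0.10, 0.17)},
    "ZAN_BPD": {"BPD": (1.22, 0.43), "HC": (0.02, 0.06)},
    "BIS": {"BPD": (2.36, 0.31), "HC": (1.68, 0.28)},
    "DES": {"BPD": (20.61, 14.00), "HC": (2.26, 1.80)},
    "CTQ": {"BPD": (2.34, 0.66), "HC": (1.18, 0.25)},
    "BIS_motor": {"BPD": (2.45, 0.40), "HC": (1.75, 0.35)},
    "BIS_attentional": {"BPD": (2.50, 0.45), "HC": (1.80, 0.35)},
    "BIS_nonplanning": {"BPD": (2.20, 0.40), "HC": (1.55, 0.30)},
    "CTQ_EA": {"BPD": (2.90, 1.00), "HC": (1.30, 0.40)},
    "CTQ_PA": {"BPD": (1.80, 0.80), "HC": (1.10, 0.20)},
    "CTQ_SA": {"BPD": (1.70, 1.00), "HC": (1.05, 0.10)},
    "CTQ_EN": {"BPD": (3.00, 1.00), "HC": (1.50, 0.50)},
    "CTQ_PN": {"BPD": (2.40, 0.90), "HC": (1.30, 0.40)},
}

#: Per-scale missingness probabilities (age/BMI are always complete),
#: mirroring the published per-scale ns of 44-48 out of 95.
DEFAULT_MISSING_RATE: dict[str, float] = {
    "BSL23": 0.02,
    "ZAN_BPD": 0.005,
    "BIS": 0.02,
    "DES": 0.03,
    "CTQ": 0.04,
    "BIS_motor": 0.02,
    "BIS_attentional": 0.02,
    "BIS_nonplanning": 0.02,
    "CTQ_EA": 0.04,
    "CTQ_PA": 0.04,
    "CTQ_SA": 0.04,
    "CTQ_EN": 0.04,
    "CTQ_PN": 0.04,
}

# Published differential sites: id -> (position, HC rate %, odds(HC)/odds(BPD)).
KNOWN_SITES: dict[int, tuple[int, float, float]] = {
    17: (53254514, 95.72, 1.870),
    34: (53252198, 56.63, 1.100),
    35: (53252152, 55.47, 1.090),
    36: (53252137, 68.80, 1.100),
    37: (53252029, 62.91, 1.120),
    38: (53252014, 56.59, 1.100),
    163: (53250525, 36.62, 1.130),
    175: (53248529, 81.17, 0.898),
}

DMR_SITE_IDS = ("CG34", "CG35", "CG36", "CG37", "CG38")

#: Reference ages used to centre covariate effects in the generator.
AGE_REF = 25.0
BMI_REF = 23.5

_SITE_MAP_SEED = 53251036  # fixed construction seed: the site map is a constant


@dataclass(frozen=True)
class SiteModel:
    """Generating model for one CpG site."""

    site: CpGSite
    baseline_logit: float  # logit methylation probability for an HC subject
    coverage_mean: float = 240.0
    coverage_dispersion: float = 12.0  # negative-binomial size parameter
    group_effect: float = 0.0  # logit(BPD) - logit(HC); negative = BPD hypomethylated
    age_slope: float = 0.01  # logit units per year
    bmi_slope: float = 0.005  # logit units per kg/m^2


@dataclass
class SimulationConfig:
    n_bpd: int = 47
    n_hc: int = 48
    seed: int = 0
    phenotype_params: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPE_PARAMS))
    missing_rate: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATE))
    sites: Sequence[SiteModel] = ()
    dmr_site_ids: tuple[str, ...] = DMR_SITE_IDS
    dmr_shared_sd: float = 0.25  # per-subject shared logit effect within the DMR
    concentration: float = 1000.0  # beta-binomial concentration; inf = binomial
    coverage_floor: int = 1

    def __post_init__(self) -> None:
        if self.n_bpd <= 0 or self.n_hc <= 0:
            raise ValidationError("subject counts must be positive")
        if self.dmr_shared_sd < 0:
            raise ValidationError("dmr_shared_sd must be >= 0")
        if not self.concentration > 0:
            raise ValidationError("concentration must be positive")
        for scale, per_group in self.phenotype_params.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValidationError(f"{scale}/{g}: negative sd")
        ids = {sm.site.site_id for sm in self.sites}
        if self.sites and not set(self.dmr_site_ids) <= ids:
            raise ValidationError("dmr_site_ids must be a subset of the site map")


def _segment_positions(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    """n distinct integer positions in [lo, hi], sorted descending."""
    pos = rng.choice(np.arange(lo, hi + 1), size=n, replace=False)
    return np.sort(pos)[::-1]


def default_site_map(
    coverage_mean: float = 240.0,
    coverage_dispersion: float = 12.0,
    n_low_coverage: int = 15,
    low_coverage_mean: float = 8.0,
    null_effects: bool = False,
) -> list[SiteModel]:
    """The 189-site design across the 10 kb window.

    Eight sites sit at the published differential coordinates with the
    published HC rates and odds ratios; CpG-island sites are hypomethylated
    (~4%), the island flanks ramp through the methylation gap, and distal
    sites are heavily methylated.  ``n_low_coverage`` generic sites get poor
    capture efficiency so the 25-read filter reproduces the designed->
    analyzed site bookkeeping.  The map is a deterministic constant (fixed
    internal construction seed).
    """
    rng = np.random.default_rng(_SITE_MAP_SEED)

    # segment -> (id range, position range, rate range 5'->3' along the gene)
    positions: dict[int, int] = {k: v[0] for k, v in KNOWN_SITES.items()}
    rates: dict[int, float] = {k: v[1] / 100.0 for k, v in KNOWN_SITES.items()}

    def fill(ids: range, pos: np.ndarray, rate_from: float, rate_to: float) -> None:
        ramp = np.linspace(rate_from, rate_to, len(ids))
        for i, (cg, p) in enumerate(zip(ids, pos)):
            positions[cg] = int(p)
            jitter = rng.normal(0.0, 0.10)
            rates[cg] = float(expit(logit(ramp[i]) + jitter))

    # gene-upstream flank (highest coordinates)
    fill(range(1, 17), _segment_positions(rng, 53254515, 53256098, 16), 0.90, 0.92)
    # between CG17 and the DMR; four sites inside the EH1 enhancer
    eh1_pos = _segment_positions(rng, 53253201, 53254400, 4)
    rest = np.concatenate(
        [
            _segment_positions(rng, 53254401, 53254513, 2),
            _segment_positions(rng, 53252199, 53253200, 10),
        ]
    )
    seg_b = np.sort(np.concatenate([eh1_pos, rest]))[::-1]
    fill(range(18, 34), seg_b, 0.62, 0.52)
    # falling slope between the DMR and CGI-1
    fill(range(39, 44), _segment_positions(rng, 53251884, 53252013, 5), 0.45, 0.18)
    # CpG island 1 (52 sites) and 2 (62 sites): sparse promoter methylation
    fill(range(44, 96), _segment_positions(rng, 53251468, 53251883, 52), 0.05, 0.04)
    fill(range(96, 101), _segment_positions(rng, 53251286, 53251467, 5), 0.10, 0.08)
    fill(range(101, 163), _segment_positions(rng, 53250744, 53251285, 62), 0.045, 0.04)
    # rising slope through intron 2 and the distal flank
    fill(range(164, 175), _segment_positions(rng, 53248530, 53250524, 11), 0.42, 0.78)
    fill(range(176, 190), _segment_positions(rng, 53246080, 53248528, 14), 0.80, 0.84)

    # poor-capture sites (dropped by the 25-read filter); never the known ones
    candidates = sorted(set(range(1, 190)) - set(KNOWN_SITES))
    low_ids = set(rng.choice(candidates, size=n_low_coverage, replace=False).tolist())

    def annotation(pos: int) -> str:
        if pos > 53254514:
            return "upstream"
        if pos >= 53250744:
            return "promoter"
        return "intron2"

    sites = []
    for cg in range(1, 190):
        pos = positions[cg]
        eff = 0.0
        if not null_effects and cg in KNOWN_SITES:
            eff = -np.log(KNOWN_SITES[cg][2])  # logit(BPD) - logit(HC)
        is_dmr = f"CG{cg}" in DMR_SITE_IDS
        sites.append(
            SiteModel(
                site=CpGSite(f"CG{cg}", CHROMOSOME, pos, annotation(pos)),
                baseline_logit=float(logit(rates[cg])),
                coverage_mean=low_coverage_mean if cg in low_ids else coverage_mean,
                coverage_dispersion=coverage_dispersion,
                group_effect=eff,
                age_slope=0.02 if is_dmr else 0.01,
                bmi_slope=0.01 if is_dmr else 0.005,
            )
        )
    assert [s.site.position for s in sites] == sorted(
        (s.site.position for s in sites), reverse=True
    )
    return sites


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed, sites=default_site_map(), **overrides)
    return cfg


def _stage_rng(seed: int, stage_index: int) -> np.random.Generator:
    """Per-stage PCG64 substream so stages can be rerun in isolation."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage_index,)))


def simulate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw a phenotype table from per-group zero-truncated normals.

    Scales are drawn independently given group (inter-scale correlation is
    not modelled).  Missing values are injected per scale at the configured
    rates; age and BMI are always complete.
    """
    rng = _stage_rng(config.seed, 0)
    n = config.n_bpd + config.n_hc
    groups = np.array(["BPD"] * config.n_bpd + ["HC"] * config.n_hc)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "group": groups,
        }
    )
    for scale, per_group in config.phenotype_params.items():
        vals = np.empty(n)
        for g in ("BPD", "HC"):
            mean, sd = per_group[g]
            idx = groups == g
            if sd == 0:
                vals[idx] = mean
            else:
                a = (0.0 - mean) / sd  # truncate at zero: scores are non-negative
                vals[idx] = truncnorm.rvs(
                    a, np.inf, loc=mean, scale=sd, size=int(idx.sum()), random_state=rng
                )
        df[scale] = vals
    for scale, p_miss in config.missing_rate.items():
        if scale in df.columns and p_miss > 0:
            miss = rng.random(n) < p_miss
            df.loc[miss, scale] = np.nan
    return df


def simulate_methylation(
    phenotypes: pd.DataFrame, config: SimulationConfig
) -> MethylationCountMatrix:
    """Draw per-subject, per-site read counts.

    coverage ~ NegBin(mean, dispersion) floored at ``coverage_floor``;
    latent methylation probability = inv-logit(baseline + group effect +
    age and BMI slopes + shared subject effect on DMR sites); methylated
    reads ~ BetaBinomial(coverage, probability, concentration).
    """
    if len(phenotypes) == 0:
        raise ValidationError("phenotype table is empty")
    if not config.sites:
        raise ValidationError("site map is empty")
    rng = _stage_rng(config.seed, 1)
    n = len(phenotypes)
    m = len(config.sites)
    is_bpd = (phenotypes["group"] == "BPD").to_numpy(dtype=float)
    age = phenotypes["age"].to_numpy(dtype=float)
    bmi = phenotypes["bmi"].to_numpy(dtype=float)
    u = rng.normal(0.0, config.dmr_shared_sd, size=n) if config.dmr_shared_sd > 0 else np.zeros(n)

    meth = np.zeros((n, m), dtype=np.int64)
    unmeth = np.zeros((n, m), dtype=np.int64)
    dmr = set(config.dmr_site_ids)
    for j, sm in enumerate(config.sites):
        k = sm.coverage_dispersion
        mu = sm.coverage_mean
        cov = rng.negative_binomial(k, k / (k + mu), size=n)
        cov = np.maximum(cov, config.coverage_floor)
        eta = (
            sm.baseline_logit
            + sm.group_effect * is_bpd
            + sm.age_slope * (age - AGE_REF)
            + sm.bmi_slope * (bmi - BMI_REF)
        )
        if sm.site.site_id in dmr:
            eta = eta + u
        p = expit(eta)
        if np.isfinite(config.concentration):
            a = p * config.concentration
            b = (1.0 - p) * config.concentration
            p_cell = rng.beta(a, b)
        else:
            p_cell = p
        y = rng.binomial(cov, p_cell)
        meth[:, j] = y
        unmeth[:, j] = cov - y
    return MethylationCountMatrix(
        subjects=phenotypes["subject_id"].tolist(),
        sites=[sm.site for sm in config.sites],
        meth=meth,
        unmeth=unmeth,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, MethylationCountMatrix]:
    phenotypes = simulate_phenotypes(config)
    matrix = simulate_methylation(phenotypes, config)
    return phenotypes, matrix


def export_cohort(
    phenotypes: pd.DataFrame,
    matrix: MethylationCountMatrix,
    directory: str | Path,
    registry=DEFAULT_REGISTRY,
) -> Path:
    """Write one Bismark-style coverage file per subject plus sample sheet
    and region registry; re-importable with exact count equality."""
    if len(phenotypes) == 0 or matrix.n_subjects == 0:
        raise ValidationError("cannot export an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts_dir = directory / "counts"
    counts_dir.mkdir(exist_ok=True)
    for i, subj in enumerate(matrix.subjects):
        vec = {}
        for j, site in enumerate(matrix.sites):
            if matrix.mask[i, j]:
                vec[(site.chromosome, site.position)] = (
                    int(matrix.meth[i, j]),
                    int(matrix.unmeth[i, j]),
                )
        write_coverage_file(counts_dir / f"{subj}.cov", vec)
    write_sample_sheet(phenotypes, directory / "sample_sheet.csv")
    write_region_registry(registry, directory / "regions.tsv")
    return directory
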