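import numpy as np
import pandas as pd
import pytest

from kormeth.data import CHROMOSOME, CpGSite, MethylationCountMatrix
from kormeth.simulate import (
    DEFAULT_MISSING_RATE,
    SimulationConfig,
    SiteModel,
    default_config,
    simulate_cohort,
)


def tiny_site_map(
    n_sites: int = 12,
    coverage_mean: float = 60.0,
    group_effects=None,
    baseline_logit: float = 0.2,
):
    """A small synthetic site map on the real window for fast tests."""
    positions = np.linspace(53252500, 53253600, n_sites).astype(int)[::-1]
    sites = []
    for j, pos in enumerate(positions):
        eff = 0.0 if group_effects is None else float(group_effects[j])
        sites.append(
            SiteModel(
                site=CpGSite(f"CG{j + 1}", CHROMOSOME, int(pos)),
                baseline_logit=baseline_logit,
                coverage_mean=coverage_mean,
                coverage_dispersion=10.0,
                group_effect=eff,
                age_slope=0.0,
                bmi_slope=0.0,
            )
        )
    return sites


def tiny_config(seed=0, n_bpd=20, n_hc=20, dmr_shared_sd=0.0, concentration=np.inf, **kw):
    sites = kw.pop("sites", tiny_site_map())
    return SimulationConfig(
        n_bpd=n_bpd,
        n_hc=n_hc,
        seed=seed,
        sites=sites,
        dmr_site_ids=kw.pop("dmr_site_ids", ()),
        dmr_shared_sd=dmr_shared_sd,
        concentration=concentration,
        missing_rate=kw.pop("missing_rate", {}),
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = tiny_config(seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size study cohort, shared across tests (read-only)."""
    cfg = default_config(seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """Hand-built 4-subject, 3-site matrix with known rates."""
    sites = [
        CpGSite("A", CHROMOSOME, 53253000),
        CpGSite("B", CHROMOSOME, 53252900),
        CpGSite("C", CHROMOSOME, 53252800),
    ]
    meth = np.array([[10, 4, 1], [20, 8, 2], [30, 12, 3], [40, 16, 4]])
    unmeth = np.array([[90, 16, 9], [80, 12, 8], [70, 8, 7], [60, 4, 6]])
    return MethylationCountMatrix(["s1", "s2", "s3", "s4"], sites, meth, unmeth)


def make_phenotypes(n_bpd=10, n_hc=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_bpd + n_hc
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": ["BPD"] * n_bpd + ["HC"] * n_hc,
            "age": rng.normal(25, 4, n).clip(18, 60),
            "bmi": rng.normal(23, 3, n).clip(15, 45),
        }
    )
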