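import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ewsurv.mcmc import MCMCConfig, PosteriorDraws
from ewsurv.model import DesignInfo, RegressionSpec

settings.register_profile("suite", deadline=None, max_examples=60, derandomize=True)
settings.load_profile("suite")


def make_table(rows):
    """Rows of (day, deaths, **covariates) -> mortality table with defaults."""
    records = []
    for row in rows:
        rec = {
            "population_type": "short-lived",
            "replicate": "b1t1",
            "age_at_spray": 14,
            "sex": "M",
            "treatment": "uninfected",
        }
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


def make_posterior(columns: dict, factors=("treatment",), levels=None,
                   references=None) -> PosteriorDraws:
    """Hand-built PosteriorDraws (e.g. degenerate single-value chains) with a
    matching DesignInfo, for exercising summaries without running MCMC."""
    levels = levels or {"treatment": ["infected", "uninfected"]}
    spec = RegressionSpec(
        factors=tuple(factors), reference_levels=dict(references or {})
    )
    info = DesignInfo(spec, levels)
    draws = pd.DataFrame(columns)
    missing = [c for c in ["alpha", "theta", *info.coef_names] if c not in draws]
    if missing:
        raise ValueError(f"make_posterior missing columns {missing}")
    cfg = MCMCConfig(n_draws=len(draws) * 2, burn_in=len(draws), thin=1,
                     min_retained=0)
    return PosteriorDraws(draws=draws, config=cfg, design_info=info)


@pytest.fixture(scope="session")
def two_arm_fit():
    """One modest seeded fit on simulated two-arm data, shared across tests.

    Truth: alpha=1.5, theta=2, sigma_uninfected=20, treatment effect -0.105.
    """
    from ewsurv import ExpWeibullSurvivalRegression, simulate_two_arm

    table = simulate_two_arm(
        1000, alpha=1.5, theta=2.0, sigma_uninfected=20.0,
        treatment_effect=-0.105, seed=42,
    )
    est = ExpWeibullSurvivalRegression(
        factors=("treatment",), n_draws=12_000, burn_in=3_000, thin=3,
        min_retained=0, seed=42,
    ).fit(table)
    return est
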