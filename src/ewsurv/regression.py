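"""Scikit-learn style estimator wrapping design building and MCMC.

`ExpWeibullSurvivalRegression` is the package's front door: configure the
covariate structure, priors and chain schedule in the constructor, call
:meth:`fit` on a long-format mortality table, then query posterior
summaries.  It follows sklearn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores, no mutation of constructor
arguments), so it composes with sklearn tooling such as ``clone``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import summaries as _summaries
from .mcmc import MCMCConfig, PosteriorDraws, run_mcmc
from .model import PriorSpec, RegressionSpec

__all__ = ["ExpWeibullSurvivalRegression", "fit_exp_weibull_regression"]


class ExpWeibullSurvivalRegression(BaseEstimator):
    """Bayesian exponentiated-Weibull survival regression.

    Time to death is exponentiated-Weibull with shared shapes (alpha, theta)
    and a cohort scale sigma = exp(x . beta) linked log-linearly to
    categorical covariates.  The posterior over (alpha, theta, beta) is
    sampled by adaptive Metropolis-within-Gibbs.

    Parameters
    ----------
    factors, interactions, reference_levels
        Covariate structure; see :class:`ewsurv.model.RegressionSpec`.
    priors
        :class:`ewsurv.model.PriorSpec`; ``None`` means the weakly
        informative defaults (Normal(0, 10^2) coefficients, Half-Normal(5)
        shapes).
    n_draws, burn_in, thin, min_retained, proposal_scale, beta_blocking,
    adapt
        Chain schedule; see :class:`ewsurv.mcmc.MCMCConfig`.
    fix_alpha, fix_theta
        Pin a shape parameter at a constant instead of sampling it.
    seed
        Seed for the (single) chain; fits are bit-reproducible given it.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Retained thinned draws with provenance.
    design_info_ : DesignInfo
        Bound covariate levels and coefficient names.
    coef_names_ : list of str
    acceptance_rates_ : dict
        Post-burn-in acceptance rate per proposal block.
    """

    def __init__(
        self,
        factors: Sequence[str] = ("treatment", "sex"),
        interactions: Sequence[Sequence[str]] = (),
        reference_levels: Mapping[str, str] | None = None,
        priors: PriorSpec | None = None,
        n_draws: int = 40_000,
        burn_in: int = 10_000,
        thin: int = 10,
        min_retained: int = 2_000,
        proposal_scale: float = 0.1,
        beta_blocking: str = "coordinate",
        adapt: bool = True,
        fix_alpha: float | None = None,
        fix_theta: float | None = None,
        seed: int = 0,
    ):
        self.factors = factors
        self.interactions = interactions
        self.reference_levels = reference_levels
        self.priors = priors
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.thin = thin
        self.min_retained = min_retained
        self.proposal_scale = proposal_scale
        self.beta_blocking = beta_blocking
        self.adapt = adapt
        self.fix_alpha = fix_alpha
        self.fix_theta = fix_theta
        self.seed = seed

    def _spec(self) -> RegressionSpec:
        return RegressionSpec(
            factors=tuple(self.factors),
            interactions=tuple(tuple(i) for i in self.interactions),
            reference_levels=dict(self.reference_levels or {}),
        )

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_draws=self.n_draws,
            burn_in=self.burn_in,
            thin=self.thin,
            min_retained=self.min_retained,
            seed=self.seed,
            proposal_scale=self.proposal_scale,
            beta_blocking=self.beta_blocking,
            adapt=self.adapt,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ExpWeibullSurvivalRegression":
        """Sample the posterior for a mortality table ``X`` (y is ignored)."""
        draws = run_mcmc(
            X,
            self._spec(),
            self.priors or PriorSpec(),
            self._config(),
            fix_alpha=self.fix_alpha,
            fix_theta=self.fix_theta,
        )
        self.draws_ = draws
        self.design_info_ = draws.design_info
        self.coef_names_ = list(draws.design_info.coef_names)
        self.acceptance_rates_ = dict(draws.acceptance_rates)
        self.n_events_ = float(X["deaths"].sum())
        return self

    def _check_fitted(self) -> PosteriorDraws:
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return self.draws_

    # ---- posterior summaries ------------------------------------------------

    def sigma_draws(self, profile: Mapping) -> np.ndarray:
        """Per-draw cohort scale for a covariate profile."""
        return _summaries.sigma_draws(self._check_fitted(), profile)

    def predict_survival(
        self, profile: Mapping, times: Sequence[float], level: float = 0.95
    ) -> pd.DataFrame:
        """Posterior median survival curve with credible band."""
        return _summaries.survival_band(self._check_fitted(), profile, times, level)

    def immunity(
        self,
        infected_profile: Mapping,
        uninfected_profile: Mapping,
        level: float = 0.95,
        labels: Mapping | None = None,
    ):
        """Percent-change-in-scale immunity statistic between two profiles."""
        return _summaries.immunity_percent_change(
            self._check_fitted(), infected_profile, uninfected_profile, level, labels
        )

    def hazard_ratio(
        self,
        profile_a: Mapping,
        profile_b: Mapping,
        times: Sequence[float],
        level: float = 0.95,
        baseline: str = "M",
    ):
        """Posterior hazard-ratio curve h_A(t)/h_B(t)."""
        return _summaries.hazard_ratio(
            self._check_fitted(), profile_a, profile_b, times, level, baseline
        )

    def median_residual_lifetime(
        self, profile: Mapping, t0_list: Sequence[float], level: float = 0.95
    ) -> pd.DataFrame:
        """Posterior median residual lifetime at each starting age."""
        return _summaries.mrl_summary(self._check_fitted(), profile, t0_list, level)

    def credible_interval(self, name: str, level: float = 0.95):
        """Equal-tailed credible interval for one sampled parameter."""
        return self._check_fitted().credible_interval(name, level)


def fit_exp_weibull_regression(
    table: pd.DataFrame, **params
) -> ExpWeibullSurvivalRegression:
    """Functional convenience wrapper around the estimator."""
    return ExpWeibullSurvivalRegression(**params).fit(table)
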