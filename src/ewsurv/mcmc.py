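"""Metropolis-within-Gibbs sampler with burn-in, adaptation and thinning.

No conditional conjugacy exists for the exponentiated-Weibull regression, so
"Gibbs + Metropolis-Hastings" is realised as blockwise random-walk
Metropolis updates cycling over parameter blocks: log(alpha), log(theta)
and the coefficient vector (jointly or coordinate-wise).  Sampling the
shapes on the log scale keeps proposals inside the support; the Jacobian
of the transform is included in the target.

Proposal scales are adapted toward a target acceptance rate during burn-in
only, so the retained chain is a fixed-kernel Markov chain.  Retained draws
are every ``thin``-th post-burn-in draw, ``floor((n_draws - burn_in)/thin)``
rows in total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from . import model as _model

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "sample_metropolis_within_gibbs",
    "run_mcmc",
    "check_autocorrelation",
    "credible_interval",
    "DegenerateChainError",
    "InitializationError",
]


class DegenerateChainError(ValueError):
    """Chain has zero variance; autocorrelation undefined."""


class InitializationError(RuntimeError):
    """Log-posterior non-finite at the initial point."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule and proposal settings.

    Desk-scale defaults (40k draws / 10k burn-in / thin 10) are a scaled-down
    version of the production schedule of 800k-1M draws, 200k-300k burn-in
    and thinning of 200-250, retaining at least ``min_retained`` (2000) draws
    either way.
    """

    n_draws: int = 40_000
    burn_in: int = 10_000
    thin: int = 10
    min_retained: int = 2_000
    seed: int = 0
    proposal_scale: float = 0.1
    beta_blocking: str = "coordinate"  # or "joint"
    adapt: bool = True
    target_accept: float = 0.3
    adapt_interval: int = 100

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("require 0 <= burn_in < n_draws")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.beta_blocking not in ("coordinate", "joint"):
            raise ValueError("beta_blocking must be 'coordinate' or 'joint'")
        if self.n_retained < self.min_retained:
            raise ValueError(
                f"schedule retains {self.n_retained} draws, fewer than "
                f"min_retained={self.min_retained}"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_draws - self.burn_in) // self.thin

    @classmethod
    def production_scale(cls, seed: int = 0, **kw) -> "MCMCConfig":
        """Full-length schedule: 900k draws, 250k burn-in, thin 225."""
        kw.setdefault("n_draws", 900_000)
        kw.setdefault("burn_in", 250_000)
        kw.setdefault("thin", 225)
        return cls(seed=seed, **kw)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in samples with provenance.

    ``draws`` has one named column per parameter (alpha, theta, then
    coefficient names); ``acceptance_rates`` are post-burn-in per block;
    ``autocorrelations`` map each parameter to its lag-1..10 ACF.
    """

    draws: pd.DataFrame
    config: MCMCConfig
    design_info: "_model.DesignInfo | None" = None
    acceptance_rates: dict = field(default_factory=dict)
    autocorrelations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    def credible_interval(self, name: str, level: float = 0.95):
        return credible_interval(self.draws[name].to_numpy(), level)

    def to_csv(self, path) -> None:
        """Write draws as CSV plus a ``.meta.json`` sidecar with provenance."""
        path = Path(path)
        self.draws.to_csv(path, index=False)
        meta = {
            "config": asdict(self.config),
            "acceptance_rates": self.acceptance_rates,
            "design_info": (
                self.design_info.to_dict() if self.design_info is not None else None
            ),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        path = Path(path)
        draws = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        info = (
            _model.DesignInfo.from_dict(meta["design_info"])
            if meta.get("design_info")
            else None
        )
        return cls(
            draws=draws,
            config=MCMCConfig(**meta["config"]),
            design_info=info,
            acceptance_rates=meta.get("acceptance_rates", {}),
        )


def sample_metropolis_within_gibbs(
    log_target: Callable[[np.ndarray], float],
    x0: Sequence[float],
    blocks: Sequence[Sequence[int]],
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    scales: Sequence[float] | None = None,
):
    """Generic blockwise random-walk Metropolis sampler.

    Returns ``(kept, acceptance_rates, final_scales)`` where ``kept`` is the
    (n_retained, dim) matrix of thinned post-burn-in states and
    ``acceptance_rates`` are measured after burn-in only.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise InitializationError(
            f"log target non-finite at initial point {x.tolist()}"
        )
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    nb = len(blocks)
    scale = np.full(nb, config.proposal_scale, dtype=float)
    if scales is not None:
        scale[:] = np.asarray(scales, dtype=float)

    kept = np.empty((config.n_retained, x.size))
    k = 0
    acc_post = np.zeros(nb)
    n_post = 0
    acc_win = np.zeros(nb)

    for it in range(config.n_draws):
        in_burn = it < config.burn_in
        for b, idx in enumerate(blocks):
            prop = x.copy()
            prop[idx] += scale[b] * rng.standard_normal(idx.size)
            lp_prop = float(log_target(prop))
            if lp_prop - lp > math.log(rng.random()):
                x, lp = prop, lp_prop
                if in_burn:
                    acc_win[b] += 1
                else:
                    acc_post[b] += 1
        if in_burn:
            if config.adapt and (it + 1) % config.adapt_interval == 0:
                rate = acc_win / config.adapt_interval
                scale *= np.exp(rate - config.target_accept)
                np.clip(scale, 1e-8, 1e3, out=scale)
                acc_win[:] = 0.0
        else:
            n_post += 1
            if n_post % config.thin == 0 and k < kept.shape[0]:
                kept[k] = x
                k += 1

    rates = acc_post / max(config.n_draws - config.burn_in, 1)
    return kept[:k], rates, scale


def _moment_init(design: _model.Design) -> tuple[float, float]:
    """Method-of-moments Weibull start (alpha fixed at 1).

    Matches the weighted mean/CV of observed death times to the Weibull
    moment relations; returns (theta0, log_sigma0).
    """
    from scipy.optimize import brentq
    from scipy.special import gamma as gamma_fn

    w = design.w / design.w.sum()
    m = float(np.dot(w, design.t))
    v = float(np.dot(w, (design.t - m) ** 2))
    if m <= 0 or v <= 0:
        return 1.0, math.log(max(m, 1.0))
    cv2 = v / m**2

    def eq(th):
        g1 = gamma_fn(1.0 + 1.0 / th)
        g2 = gamma_fn(1.0 + 2.0 / th)
        return g2 / g1**2 - 1.0 - cv2

    try:
        theta0 = brentq(eq, 0.1, 50.0)
    except ValueError:
        theta0 = 1.0
    sigma0 = m / gamma_fn(1.0 + 1.0 / theta0)
    return float(theta0), float(math.log(sigma0))


def run_mcmc(
    table,
    spec: "_model.RegressionSpec",
    priors: "_model.PriorSpec | None" = None,
    config: MCMCConfig | None = None,
    fix_alpha: float | None = None,
    fix_theta: float | None = None,
) -> PosteriorDraws:
    """Sample the posterior of (alpha, theta, beta) for a mortality table.

    ``fix_alpha`` / ``fix_theta`` pin a shape at a constant (useful for
    reduced special cases); fixed parameters still appear as constant
    columns in the output.  Reproducible given ``config.seed``.
    """
    priors = priors or _model.PriorSpec()
    config = config or MCMCConfig()
    design = _model.build_design(table, spec)
    p = design.info.n_coef

    theta0, b0 = _moment_init(design)
    free_alpha = fix_alpha is None
    free_theta = fix_theta is None

    # state layout: [log alpha?][log theta?][beta ...]
    layout: list[str] = []
    x0: list[float] = []
    if free_alpha:
        layout.append("log_alpha")
        x0.append(0.0)  # alpha = 1 start
    if free_theta:
        layout.append("log_theta")
        x0.append(math.log(theta0))
    layout += [f"beta{j}" for j in range(p)]
    x0 += [b0] + [0.0] * (p - 1)
    n_shape = int(free_alpha) + int(free_theta)

    def unpack(x):
        a = math.exp(x[0]) if free_alpha else fix_alpha
        th = math.exp(x[n_shape - 1]) if free_theta else fix_theta
        return a, th, x[n_shape:]

    def log_target(x):
        a, th, beta = unpack(x)
        lp = priors.log_prior(a, th, beta)
        if not np.isfinite(lp):
            return -np.inf
        lp += _model.design_log_likelihood(design, a, th, beta)
        if not np.isfinite(lp):
            return -np.inf
        # Jacobian of the log transform for free shapes
        if free_alpha:
            lp += x[0]
        if free_theta:
            lp += x[n_shape - 1]
        return lp

    blocks: list[list[int]] = [[i] for i in range(n_shape)]
    if config.beta_blocking == "joint":
        blocks.append(list(range(n_shape, n_shape + p)))
    else:
        blocks += [[i] for i in range(n_shape, n_shape + p)]

    rng = np.random.default_rng(config.seed)
    kept, rates, _ = sample_metropolis_within_gibbs(
        log_target, x0, blocks, config, rng=rng
    )

    cols = {}
    cols["alpha"] = np.exp(kept[:, 0]) if free_alpha else np.full(len(kept), fix_alpha)
    cols["theta"] = (
        np.exp(kept[:, n_shape - 1]) if free_theta else np.full(len(kept), fix_theta)
    )
    for j, name in enumerate(design.info.coef_names):
        cols[name] = kept[:, n_shape + j]
    draws = pd.DataFrame(cols)

    block_names = (["log_alpha"] if free_alpha else []) + (
        ["log_theta"] if free_theta else []
    )
    if config.beta_blocking == "joint":
        block_names.append("beta")
    else:
        block_names += [f"beta[{n}]" for n in design.info.coef_names]
    acc = {name: float(r) for name, r in zip(block_names, rates)}

    autocorr = {}
    for name in draws.columns:
        v = draws[name].to_numpy()
        if np.ptp(v) > 0:
            autocorr[name] = check_autocorrelation(v, range(1, 11))
    return PosteriorDraws(
        draws=draws,
        config=config,
        design_info=design.info,
        acceptance_rates=acc,
        autocorrelations=autocorr,
    )


def check_autocorrelation(draws, lags) -> dict[int, float]:
    """Sample autocorrelation of a chain at the requested lags.

    Raises :class:`DegenerateChainError` for a constant chain instead of
    propagating NaNs.
    """
    v = np.asarray(draws, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("draws must be a 1-d vector with at least 2 elements")
    if np.ptp(v) == 0:
        raise DegenerateChainError(
            "chain is constant: variance zero, autocorrelation undefined"
        )
    lags = [int(l) for l in lags]
    full = _sm_acf(v, nlags=max(lags), fft=True)
    return {l: float(full[l]) for l in lags}


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a posterior draw vector."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    v = np.asarray(draws, dtype=float)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [tail, 1.0 - tail])
    return float(lo), float(hi)
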