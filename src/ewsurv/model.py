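"""Regression structure, priors and likelihood.

The scale of the exponentiated Weibull is tied to cohort covariates through
a log-linear (AFT-style) link,

    sigma_i = exp(x_i . beta),

where x_i expands categorical factors (treatment, sex, age group, ...) with
treatment coding against stated reference levels, plus optional pairwise
interactions.  The two shape parameters (alpha, theta) are shared across
cohorts.  A death recorded on day d is treated as an exact event at the
interval midpoint t = d - 0.5, and the likelihood is count-weighted:

    log L = sum_records deaths * log f(d - 0.5; alpha, theta, sigma_i)

which is identical to expanding every record into individual flies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data as _data
from .distribution import ew_logpdf

DEFAULT_REFERENCES = {"treatment": "uninfected", "sex": "M"}


@dataclass(frozen=True)
class RegressionSpec:
    """Covariate specification for the scale link.

    factors       : ordered factor (column) names entering main effects
    interactions  : pairs of factor names entering as products of dummies
    reference_levels : factor -> reference level; factors not listed default
        to :data:`DEFAULT_REFERENCES` or, failing that, the smallest level
        observed in the table (deterministic).
    """

    factors: tuple[str, ...] = ("treatment", "sex")
    interactions: tuple[tuple[str, str], ...] = ()
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(
            self, "interactions", tuple(tuple(i) for i in self.interactions)
        )
        for a, b in self.interactions:
            if a not in self.factors or b not in self.factors:
                raise ValueError(f"interaction ({a}, {b}) uses unknown factor")


class DesignInfo:
    """Bound design: factor levels observed in a table plus the spec.

    Knows how to produce the design row of any covariate profile, so that
    posterior summaries can be computed without the original table.
    """

    def __init__(self, spec: RegressionSpec, levels: Mapping[str, Sequence]):
        self.spec = spec
        self.levels = {f: list(levels[f]) for f in spec.factors}
        self.references = {}
        for f in spec.factors:
            ref = spec.reference_levels.get(f, DEFAULT_REFERENCES.get(f))
            if ref is None:
                if not self.levels[f]:
                    raise ValueError(f"factor {f!r} has no observed levels")
                ref = sorted(self.levels[f], key=str)[0]
            if not self.levels[f]:
                # empty table: bind to the reference level alone
                self.levels[f] = [ref]
            if ref not in self.levels[f]:
                raise ValueError(
                    f"reference level {ref!r} for factor {f!r} not among "
                    f"observed levels {self.levels[f]}"
                )
            self.references[f] = ref
        self._columns: list[tuple] = [("intercept",)]
        self.coef_names = ["intercept"]
        for f in spec.factors:
            for lv in self.levels[f]:
                if lv != self.references[f]:
                    self._columns.append(("main", f, lv))
                    self.coef_names.append(f"{f}[{lv}]")
        for fa, fb in spec.interactions:
            for la in self.levels[fa]:
                if la == self.references[fa]:
                    continue
                for lb in self.levels[fb]:
                    if lb == self.references[fb]:
                        continue
                    self._columns.append(("inter", fa, la, fb, lb))
                    self.coef_names.append(f"{fa}[{la}]:{fb}[{lb}]")

    @property
    def n_coef(self) -> int:
        return len(self.coef_names)

    def row(self, profile: Mapping) -> np.ndarray:
        """Design row for a covariate profile (factor -> level mapping)."""
        for f in self.spec.factors:
            if f not in profile:
                raise ValueError(f"profile missing factor {f!r}")
            if profile[f] not in self.levels[f]:
                raise ValueError(
                    f"unknown level {profile[f]!r} for factor {f!r}; "
                    f"known levels: {self.levels[f]}"
                )
        x = np.zeros(self.n_coef)
        for j, col in enumerate(self._columns):
            if col[0] == "intercept":
                x[j] = 1.0
            elif col[0] == "main":
                _, f, lv = col
                x[j] = 1.0 if profile[f] == lv else 0.0
            else:
                _, fa, la, fb, lb = col
                x[j] = 1.0 if (profile[fa] == la and profile[fb] == lb) else 0.0
        return x

    def matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Design matrix, one row per DataFrame row."""
        x = np.zeros((len(frame), self.n_coef))
        for j, col in enumerate(self._columns):
            if col[0] == "intercept":
                x[:, j] = 1.0
            elif col[0] == "main":
                _, f, lv = col
                x[:, j] = (frame[f] == lv).to_numpy(dtype=float)
            else:
                _, fa, la, fb, lb = col
                x[:, j] = (
                    (frame[fa] == la) & (frame[fb] == lb)
                ).to_numpy(dtype=float)
        return x

    def to_dict(self) -> dict:
        return {
            "factors": list(self.spec.factors),
            "interactions": [list(i) for i in self.spec.interactions],
            "reference_levels": dict(self.references),
            "levels": {k: list(v) for k, v in self.levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignInfo":
        spec = RegressionSpec(
            factors=tuple(d["factors"]),
            interactions=tuple(tuple(i) for i in d["interactions"]),
            reference_levels=dict(d["reference_levels"]),
        )
        return cls(spec, d["levels"])


@dataclass
class Design:
    """Count-weighted design ready for likelihood evaluation."""

    info: DesignInfo
    X: np.ndarray  # (r, p) design rows for distinct (covariates, day) records
    t: np.ndarray  # (r,) event times, day - 0.5
    w: np.ndarray  # (r,) death counts

    @property
    def n_events(self) -> float:
        return float(self.w.sum())


def build_design(table: pd.DataFrame, spec: RegressionSpec) -> Design:
    """Aggregate a mortality table into a count-weighted design.

    Rows are grouped by (factor levels, day); zero-death records are dropped
    (they carry no likelihood with full follow-up).  Count weighting is
    exactly equivalent to expanding each record into individual flies.
    """
    df = _data.validate_mortality_table(table)
    for f in spec.factors:
        if f not in df.columns:
            raise _data.SchemaError(f"factor {f!r} not a mortality-table column")
    levels = {f: sorted(df[f].unique(), key=str) for f in spec.factors}
    info = DesignInfo(spec, levels)
    grouped = (
        df.groupby(list(spec.factors) + ["day"], as_index=False, sort=True)["deaths"]
        .sum()
    )
    grouped = grouped[grouped["deaths"] > 0].reset_index(drop=True)
    X = info.matrix(grouped)
    t = grouped["day"].to_numpy(dtype=float) - 0.5
    w = grouped["deaths"].to_numpy(dtype=float)
    return Design(info=info, X=X, t=t, w=w)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative default priors.

    Coefficients beta_j ~ Normal(beta_loc, beta_scale^2) on the log-scale
    link (default Normal(0, 10^2)); shapes alpha, theta ~ Half-Normal(shape
    scale, default 5) on their natural positive support.  ``flat=True``
    drops all prior terms (improper; for checks only).
    """

    beta_loc: float = 0.0
    beta_scale: float = 10.0
    alpha_scale: float = 5.0
    theta_scale: float = 5.0
    flat: bool = False

    def log_prior(self, alpha: float, theta: float, beta: np.ndarray) -> float:
        if not (alpha > 0 and theta > 0):
            return -np.inf
        if self.flat:
            return 0.0
        hn_const = 0.5 * math.log(2.0 / math.pi)
        lp = (
            hn_const
            - math.log(self.alpha_scale)
            - 0.5 * (alpha / self.alpha_scale) ** 2
        )
        lp += (
            hn_const
            - math.log(self.theta_scale)
            - 0.5 * (theta / self.theta_scale) ** 2
        )
        beta = np.asarray(beta, dtype=float)
        lp += float(
            np.sum(
                -0.5 * math.log(2.0 * math.pi)
                - math.log(self.beta_scale)
                - 0.5 * ((beta - self.beta_loc) / self.beta_scale) ** 2
            )
        )
        return lp


def design_log_likelihood(
    design: Design, alpha: float, theta: float, beta: np.ndarray
) -> float:
    """Count-weighted log-likelihood on a prebuilt design.

    Returns -inf (rather than raising) for nonpositive shapes or any
    nonpositive implied scale, so samplers can reject such proposals.
    """
    if not (np.isfinite(alpha) and np.isfinite(theta) and alpha > 0 and theta > 0):
        return -np.inf
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError(
            f"beta has length {beta.shape}, design expects {design.X.shape[1]}"
        )
    if not np.all(np.isfinite(beta)):
        return -np.inf
    eta = design.X @ beta
    sigma = np.exp(eta)
    u = design.t / sigma
    z = u**theta
    with np.errstate(divide="ignore", invalid="ignore"):
        log_base = np.log(-np.expm1(-z))
        ll_terms = (
            math.log(alpha)
            + math.log(theta)
            - eta
            + (theta - 1.0) * np.log(u)
            - z
            + (alpha - 1.0) * log_base
        )
    total = float(np.dot(design.w, ll_terms))
    return total if np.isfinite(total) else -np.inf


def log_likelihood(
    table: pd.DataFrame,
    alpha: float,
    theta: float,
    beta: np.ndarray,
    spec: RegressionSpec,
) -> float:
    """Log-likelihood of a mortality table under the scale-link regression."""
    return design_log_likelihood(build_design(table, spec), alpha, theta, beta)


def log_posterior(
    table_or_design,
    alpha: float,
    theta: float,
    beta: np.ndarray,
    spec: RegressionSpec | None = None,
    priors: PriorSpec | None = None,
) -> float:
    """Unnormalised log-posterior: likelihood plus log prior density.

    Accepts either a mortality table (with ``spec``) or a prebuilt
    :class:`Design`.  -inf outside the support.
    """
    priors = priors or PriorSpec()
    lp = priors.log_prior(alpha, theta, np.asarray(beta, dtype=float))
    if not np.isfinite(lp):
        return -np.inf
    if isinstance(table_or_design, Design):
        design = table_or_design
    else:
        if spec is None:
            raise ValueError("spec required when passing a table")
        design = build_design(table_or_design, spec)
    return lp + design_log_likelihood(design, alpha, theta, beta)


# sanity check used by ew_logpdf consistency tests
def _loglik_reference(design: Design, alpha, theta, beta):
    """Slow reference path through distribution.ew_logpdf (used in tests)."""
    sigma = np.exp(design.X @ np.asarray(beta, dtype=float))
    terms = [
        wi * ew_logpdf(ti, alpha=alpha, theta=theta, sigma=si)
        for ti, wi, si in zip(design.t, design.w, sigma)
    ]
    return float(np.sum(terms))
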