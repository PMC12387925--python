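"""Synthetic mortality-cohort generator.

Emulates the structure of a spray-infection survival experiment on caged
flies: two population types (short- and long-lived) with four biological
and two technical replicates per condition, cohorts sprayed at a ladder of
adult ages (the long-lived type extends to two additional old ages), both
sexes, and three treatment arms (infected / uninfected / control).  Cage
sizes are drawn uniformly from a stated range (default 100-150 flies) and
every fly is followed to death: continuous exponentiated-Weibull death
times are binned to integer days post-spray by the ceiling (a death is
observed at the first daily check after it happens), so per-cohort death
counts always sum to the cage size and there is no censoring.

Each cohort's true scale is sigma_ref * exp(sum of log-scale effects) for
its treatment, sex, age and any treatment-by-age interaction; the shape
parameters are shared within a population type.  Effects are additive on
the log scale, matching the model's link exactly, so generated data sit
inside the fitted family and support parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import data as _data
from .distribution import ew_quantile

__all__ = [
    "PopulationTruth",
    "SimulationDesign",
    "default_paper_design",
    "cohort_sigma",
    "simulate_cohort",
    "simulate_experiment",
    "simulate_two_arm",
]


@dataclass(frozen=True)
class PopulationTruth:
    """Generating parameters for one population type."""

    alpha: float
    theta: float
    sigma_ref: float  # scale (days) at reference levels: uninfected, male, youngest age
    ages: tuple[int, ...]

    def __post_init__(self):
        if min(self.alpha, self.theta, self.sigma_ref) <= 0:
            raise ValueError("alpha, theta and sigma_ref must be positive")
        object.__setattr__(self, "ages", tuple(int(a) for a in self.ages))


@dataclass(frozen=True)
class SimulationDesign:
    """Full experiment layout plus generating truth.

    Effects are log-scale additive contributions to sigma keyed by level;
    reference levels (uninfected, male, youngest age) carry effect 0.
    ``interaction_effects`` maps (treatment, age) to an extra term, letting
    the infection penalty grow with age at spray.
    """

    populations: Mapping[str, PopulationTruth]
    treatment_effects: Mapping[str, float] = field(
        default_factory=lambda: {"infected": -0.10, "uninfected": 0.0, "control": 0.0}
    )
    sex_effects: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.0, "F": 0.06}
    )
    age_effects: Mapping[int, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, int], float] = field(default_factory=dict)
    n_bio_replicates: int = 4
    n_tech_replicates: int = 2
    cage_size_range: tuple[int, int] = (100, 150)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cage_size_range
        if not (1 <= lo <= hi):
            raise ValueError("cage_size_range must satisfy 1 <= lo <= hi")
        for pop, truth in self.populations.items():
            for age in truth.ages:
                for trt in self.treatment_effects:
                    for sex in self.sex_effects:
                        s = cohort_sigma(self, pop, age, sex, trt)
                        if not (np.isfinite(s) and s > 0):
                            raise ValueError(
                                f"implied sigma not positive/finite for cohort "
                                f"({pop}, {age}, {sex}, {trt})"
                            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = {k: asdict(v) for k, v in self.populations.items()}
        d["interaction_effects"] = {
            f"{t}:{a}": v for (t, a), v in self.interaction_effects.items()
        }
        return d


def default_paper_design(seed: int = 0) -> SimulationDesign:
    """Bundled default layout with synthetic truths.

    The long-lived type gets a larger reference scale (later deaths at every
    age), infection shortens life, the infection penalty deepens with age at
    spray (immunosenescence), and females outlive males.  Magnitudes are
    synthetic choices, not calibrated to any real cohort.
    """
    return SimulationDesign(
        populations={
            "short-lived": PopulationTruth(
                alpha=1.5, theta=2.2, sigma_ref=28.0, ages=(14, 28, 42)
            ),
            "long-lived": PopulationTruth(
                alpha=1.5, theta=2.2, sigma_ref=48.0, ages=(14, 28, 42, 56, 70)
            ),
        },
        treatment_effects={"infected": -0.10, "uninfected": 0.0, "control": 0.0},
        sex_effects={"M": 0.0, "F": 0.06},
        age_effects={14: 0.0, 28: -0.15, 42: -0.30, 56: -0.45, 70: -0.60},
        interaction_effects={
            ("infected", 14): 0.0,
            ("infected", 28): -0.04,
            ("infected", 42): -0.08,
            ("infected", 56): -0.12,
            ("infected", 70): -0.16,
        },
        seed=seed,
    )


def cohort_sigma(
    design: SimulationDesign, population_type: str, age: int, sex: str, treatment: str
) -> float:
    """True scale (days) implied by the design for one cohort."""
    truth = design.populations[population_type]
    eta = math.log(truth.sigma_ref)
    eta += design.treatment_effects.get(treatment, 0.0)
    eta += design.sex_effects.get(sex, 0.0)
    eta += design.age_effects.get(age, 0.0)
    eta += design.interaction_effects.get((treatment, age), 0.0)
    return math.exp(eta)


def simulate_cohort(
    design: SimulationDesign,
    population_type: str,
    age_at_spray: int,
    sex: str,
    treatment: str,
    replicate: str,
    n_flies: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Daily death counts for one cage.

    Continuous death times are drawn by inversion from the cohort's
    exponentiated Weibull and binned to integer days by ceiling; counts sum
    to ``n_flies``.
    """
    truth = design.populations[population_type]
    sigma = cohort_sigma(design, population_type, age_at_spray, sex, treatment)
    u = rng.random(n_flies)
    t = ew_quantile(u, alpha=truth.alpha, theta=truth.theta, sigma=sigma)
    days = np.maximum(np.ceil(t).astype(int), 1)
    counts = np.bincount(days)
    observed = np.nonzero(counts)[0]
    return pd.DataFrame(
        {
            "population_type": population_type,
            "replicate": replicate,
            "age_at_spray": age_at_spray,
            "sex": sex,
            "treatment": treatment,
            "day": observed,
            "deaths": counts[observed],
        }
    )


def simulate_experiment(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the full experiment: every (population, replicate, age, sex,
    treatment) cohort, deterministic given ``design.seed``."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    frames = []
    for pop in sorted(design.populations):
        truth = design.populations[pop]
        for bio in range(1, design.n_bio_replicates + 1):
            for tech in range(1, design.n_tech_replicates + 1):
                rep = f"b{bio}t{tech}"
                for age in truth.ages:
                    for trt in sorted(design.treatment_effects):
                        for sex in sorted(design.sex_effects):
                            lo, hi = design.cage_size_range
                            n = int(rng.integers(lo, hi + 1))
                            frames.append(
                                simulate_cohort(
                                    design, pop, age, sex, trt, rep, n, rng
                                )
                            )
    table = pd.concat(frames, ignore_index=True)
    return _data.validate_mortality_table(table)


def simulate_two_arm(
    n_per_arm: int,
    alpha: float,
    theta: float,
    sigma_uninfected: float,
    treatment_effect: float,
    seed: int = 0,
    population_type: str = "short-lived",
    age_at_spray: int = 14,
    sex_effect: float | None = None,
) -> pd.DataFrame:
    """Minimal two-arm (infected vs uninfected) cohort pair for recovery
    studies; one cage per arm (per sex when ``sex_effect`` is given), exact
    cage size ``n_per_arm``."""
    design = SimulationDesign(
        populations={
            population_type: PopulationTruth(
                alpha=alpha, theta=theta, sigma_ref=sigma_uninfected,
                ages=(age_at_spray,),
            )
        },
        treatment_effects={"infected": treatment_effect, "uninfected": 0.0},
        sex_effects={"M": 0.0, "F": sex_effect} if sex_effect is not None else {"M": 0.0},
        cage_size_range=(n_per_arm, n_per_arm),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    frames = []
    for trt in ("uninfected", "infected"):
        for sex in sorted(design.sex_effects):
            frames.append(
                simulate_cohort(
                    design, population_type, age_at_spray, sex, trt, "b1t1",
                    n_per_arm, rng,
                )
            )
    return pd.concat(frames, ignore_index=True)
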