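"""Design construction, count-weighted likelihood and posterior."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import make_table
from ewsurv.data import SchemaError, validate_mortality_table
from ewsurv.model import (
    PriorSpec,
    RegressionSpec,
    build_design,
    design_log_likelihood,
    log_likelihood,
    log_posterior,
    _loglik_reference,
)


def test_reference_only_design_is_intercept():
    table = make_table([{"day": d, "deaths": 3} for d in (2, 5, 9)])
    design = build_design(table, RegressionSpec(factors=("treatment",)))
    assert design.info.coef_names == ["intercept"]
    np.testing.assert_array_equal(design.X, np.ones((3, 1)))
    np.testing.assert_array_equal(design.t, [1.5, 4.5, 8.5])


def test_factorial_expansion_with_interaction():
    rows = []
    for sex in ("F", "M"):
        for trt in ("infected", "uninfected"):
            rows.append({"sex": sex, "treatment": trt, "day": 3, "deaths": 2})
    spec = RegressionSpec(
        factors=("treatment", "sex"), interactions=(("treatment", "sex"),)
    )
    design = build_design(make_table(rows), spec)
    # 4 distinct design rows, full-rank 4-column expansion
    assert design.X.shape == (4, 4)
    assert np.linalg.matrix_rank(design.X) == 4
    assert set(design.info.coef_names) == {
        "intercept", "treatment[infected]", "sex[F]", "treatment[infected]:sex[F]",
    }


def test_count_weighting_equals_per_fly_expansion():
    table = make_table(
        [
            {"day": 2, "deaths": 5, "treatment": "infected"},
            {"day": 4, "deaths": 3, "treatment": "uninfected"},
            {"day": 7, "deaths": 12, "treatment": "uninfected"},
        ]
    )
    expanded_rows = []
    for _, row in table.iterrows():
        for _ in range(int(row["deaths"])):
            r = row.to_dict()
            r["deaths"] = 1
            expanded_rows.append(r)
    import pandas as pd

    expanded = pd.DataFrame(expanded_rows)
    spec = RegressionSpec(factors=("treatment",))
    beta = np.array([3.0, -0.2])
    ll_weighted = log_likelihood(table, 1.4, 2.1, beta, spec)
    ll_expanded = log_likelihood(expanded, 1.4, 2.1, beta, spec)
    assert ll_weighted == pytest.approx(ll_expanded, rel=1e-12)


def test_exponential_single_death_closed_form():
    """One death at t = sigma under alpha=theta=1: loglik = -log(sigma) - 1."""
    sigma = 7.5  # day 8 -> event time 7.5
    table = make_table([{"day": 8, "deaths": 1}])
    spec = RegressionSpec(factors=("treatment",))
    ll = log_likelihood(table, 1.0, 1.0, np.array([math.log(sigma)]), spec)
    assert ll == pytest.approx(-math.log(sigma) - 1.0, rel=1e-12)


def test_loglik_linear_in_counts():
    table = make_table([{"day": d, "deaths": c} for d, c in ((2, 4), (5, 6), (9, 1))])
    doubled = table.assign(deaths=table.deaths * 2)
    spec = RegressionSpec(factors=("treatment",))
    beta = np.array([2.5])
    ll = log_likelihood(table, 1.3, 1.8, beta, spec)
    assert log_likelihood(doubled, 1.3, 1.8, beta, spec) == pytest.approx(
        2 * ll, rel=1e-12
    )


def test_loglik_matches_brute_force_per_fly():
    """20-fly toy table vs independent per-fly summation via the density."""
    table = make_table(
        [
            {"day": 3, "deaths": 6, "treatment": "infected"},
            {"day": 5, "deaths": 9, "treatment": "uninfected"},
            {"day": 11, "deaths": 5, "treatment": "infected"},
        ]
    )
    spec = RegressionSpec(factors=("treatment",))
    design = build_design(table, spec)
    beta = np.array([2.8, -0.3])
    fast = design_log_likelihood(design, 1.6, 2.2, beta)
    slow = _loglik_reference(design, 1.6, 2.2, beta)
    assert fast == pytest.approx(slow, rel=1e-12)


def test_loglik_invariances_and_link_contract():
    table = make_table(
        [
            {"day": 2, "deaths": 3, "treatment": "infected"},
            {"day": 6, "deaths": 8, "treatment": "uninfected"},
        ]
    )
    spec = RegressionSpec(factors=("treatment",))
    beta = np.array([3.1, -0.15])
    ll = log_likelihood(table, 1.2, 1.7, beta, spec)
    shuffled = table.iloc[::-1].reset_index(drop=True)
    assert log_likelihood(shuffled, 1.2, 1.7, beta, spec) == pytest.approx(ll)
    # splitting a count-k record into k singles leaves the likelihood unchanged
    split = make_table(
        [{"day": 2, "deaths": 1, "treatment": "infected"}] * 3
        + [{"day": 6, "deaths": 1, "treatment": "uninfected"}] * 8
    )
    assert log_likelihood(split, 1.2, 1.7, beta, spec) == pytest.approx(ll)
    # link contract: infected sigma = uninfected sigma * exp(delta) exactly
    design = build_design(table, spec)
    x_inf = design.info.row({"treatment": "infected"})
    x_unif = design.info.row({"treatment": "uninfected"})
    assert math.exp(x_inf @ beta) == pytest.approx(
        math.exp(x_unif @ beta) * math.exp(beta[1]), rel=1e-15
    )


def test_nonpositive_shapes_give_minus_inf_not_exception():
    table = make_table([{"day": 2, "deaths": 1}])
    spec = RegressionSpec(factors=("treatment",))
    assert log_likelihood(table, -1.0, 1.0, np.array([1.0]), spec) == -np.inf
    assert log_likelihood(table, 1.0, 0.0, np.array([1.0]), spec) == -np.inf
    assert log_posterior(table, -1.0, 1.0, np.array([1.0]), spec) == -np.inf


def test_flat_prior_posterior_equals_likelihood():
    table = make_table([{"day": d, "deaths": 2} for d in (3, 4, 9)])
    spec = RegressionSpec(factors=("treatment",))
    beta = np.array([2.0])
    lp = log_posterior(table, 1.5, 2.0, beta, spec, PriorSpec(flat=True))
    assert lp == pytest.approx(log_likelihood(table, 1.5, 2.0, beta, spec))


def test_prior_only_posterior_maximised_at_prior_mode():
    """Empty table: the posterior is the prior; the mode of a Normal(0, 10^2)
    coefficient prior sits at 0 (shapes' half-normal mode at 0+ is approached
    as the shape shrinks)."""
    empty = make_table([{"day": 1, "deaths": 0}]).iloc[0:0]
    spec = RegressionSpec(factors=("treatment",))
    priors = PriorSpec()
    at_mode = log_posterior(empty, 0.1, 0.1, np.array([0.0]), spec, priors)
    for b in (-2.0, 1.0, 5.0):
        assert at_mode > log_posterior(empty, 0.1, 0.1, np.array([b]), spec, priors)
    assert at_mode > log_posterior(empty, 3.0, 0.1, np.array([0.0]), spec, priors)


def test_posterior_matches_quadrature_normalised_density():
    """1-parameter toy: exponential likelihood in the intercept, independent
    quadrature normalisation of exp(log_posterior) matches an independently
    assembled likelihood-times-prior density."""
    from scipy.stats import expon, norm

    table = make_table([{"day": d, "deaths": 1} for d in (2, 3, 5, 7)])
    spec = RegressionSpec(factors=("treatment",))
    priors = PriorSpec(beta_scale=2.0)
    times = np.array([1.5, 2.5, 4.5, 6.5])
    grid = np.linspace(0.0, 3.5, 301)

    mine = np.array(
        [log_posterior(table, 1.0, 1.0, np.array([b]), spec, priors) for b in grid]
    )
    ref = np.array(
        [
            expon.logpdf(times, scale=math.exp(b)).sum() + norm.logpdf(b, 0, 2.0)
            for b in grid
        ]
    )
    # identical shape up to the constant half-normal prior mass on the shapes
    diff = mine - ref
    np.testing.assert_allclose(diff, diff[0], atol=1e-9)
    post_mine = np.exp(mine - mine.max())
    post_mine /= np.trapezoid(post_mine, grid)
    post_ref = np.exp(ref - ref.max())
    post_ref /= np.trapezoid(post_ref, grid)
    np.testing.assert_allclose(post_mine, post_ref, atol=1e-9)


def test_schema_errors_name_offender():
    bad = make_table([{"day": 2, "deaths": 1, "treatment": "sprayed-twice"}])
    with pytest.raises(SchemaError, match="sprayed-twice"):
        validate_mortality_table(bad)
    with pytest.raises(SchemaError, match="deaths"):
        validate_mortality_table(make_table([{"day": 2, "deaths": -1}]))
    with pytest.raises(SchemaError, match="missing"):
        validate_mortality_table(make_table([{"day": 1, "deaths": 0}]).drop(columns=["sex"]))
    with pytest.raises(SchemaError, match="factor"):
        build_design(
            make_table([{"day": 2, "deaths": 1}]),
            RegressionSpec(factors=("diet",)),
        )
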