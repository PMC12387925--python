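"""Posterior summaries: immunity statistic, hazard ratios, survival bands,
median residual lifetime and cross-population comparison."""

import math

import numpy as np
import pytest

from conftest import make_posterior
from ewsurv.distribution import ew_pdf, ew_sf, median_residual_lifetime
from ewsurv.summaries import (
    compare_populations,
    hazard_ratio,
    immunity_percent_change,
    mrl_summary,
    sigma_draws,
    survival_band,
)

INF = {"treatment": "infected"}
UNIF = {"treatment": "uninfected"}


def _degenerate(alpha=1.5, theta=2.0, b0=3.0, delta=-0.1, n=200):
    """Posterior with every draw identical (point mass)."""
    return make_posterior(
        {
            "alpha": np.full(n, alpha),
            "theta": np.full(n, theta),
            "intercept": np.full(n, b0),
            "treatment[infected]": np.full(n, delta),
        }
    )


def test_survival_band_degenerate_collapses_to_point_curve():
    fit = _degenerate()
    times = np.linspace(0, 60, 31)
    band = survival_band(fit, UNIF, times)
    truth = ew_sf(times, alpha=1.5, theta=2.0, sigma=math.exp(3.0))
    np.testing.assert_allclose(band["median"], truth, atol=1e-12)
    np.testing.assert_allclose(band["lo"], band["hi"], atol=1e-12)
    assert band["median"].iloc[0] == 1.0  # S(0) = 1 exactly
    assert np.all(np.diff(band["median"]) <= 0)
    assert band[["lo", "median", "hi"]].to_numpy().min() >= 0
    assert band[["lo", "median", "hi"]].to_numpy().max() <= 1


def test_survival_band_posterior_spread(two_arm_fit):
    band = two_arm_fit.predict_survival(UNIF, np.linspace(0, 40, 21))
    assert np.all(band["lo"] <= band["median"]) and np.all(band["median"] <= band["hi"])
    assert np.all(np.diff(band["median"]) <= 1e-12)


def test_immunity_zero_when_profiles_equal():
    fit = _degenerate(delta=0.0)
    est = immunity_percent_change(fit, INF, UNIF)
    assert est.estimate == 0.0
    assert est.ci == (0.0, 0.0)


def test_immunity_closed_form_for_fixed_effect():
    fit = _degenerate(delta=-0.05)
    est = immunity_percent_change(fit, INF, UNIF)
    assert est.estimate == pytest.approx(abs(math.exp(-0.05) - 1), rel=1e-12)
    assert est.signed_estimate == pytest.approx(math.exp(-0.05) - 1, rel=1e-12)
    assert est.ci[0] <= est.estimate <= est.ci[1]


def test_immunity_scale_free():
    """Multiplying every sigma draw by a constant (shifting the intercept)
    leaves the percent change unchanged."""
    rng = np.random.default_rng(5)
    n = 500
    cols = {
        "alpha": np.full(n, 1.5),
        "theta": np.full(n, 2.0),
        "intercept": rng.normal(3.0, 0.05, n),
        "treatment[infected]": rng.normal(-0.1, 0.02, n),
    }
    fit = make_posterior(cols)
    shifted = make_posterior({**cols, "intercept": cols["intercept"] + math.log(7.0)})
    a = immunity_percent_change(fit, INF, UNIF)
    b = immunity_percent_change(shifted, INF, UNIF)
    assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
    assert a.ci == pytest.approx(b.ci, rel=1e-12)


def test_hazard_ratio_identical_profiles_is_one():
    fit = _degenerate()
    curve = hazard_ratio(fit, UNIF, UNIF, times=[1, 5, 10, 30])
    np.testing.assert_allclose(curve.median, 1.0, atol=1e-12)
    np.testing.assert_allclose(curve.lo, 1.0, atol=1e-12)
    np.testing.assert_allclose(curve.hi, 1.0, atol=1e-12)


def test_hazard_ratio_weibull_closed_form():
    """alpha=1 with shared theta: HR is constant (sigma_A/sigma_B)^(-theta)."""
    theta, delta = 2.0, -0.1
    fit = _degenerate(alpha=1.0, theta=theta, delta=delta)
    times = [2.0, 10.0, 25.0]
    curve = hazard_ratio(fit, INF, UNIF, times=times)
    expected = math.exp(delta) ** (-theta)
    np.testing.assert_allclose(curve.median, expected, rtol=1e-12)


def test_hazard_ratio_matches_independent_composition():
    rng = np.random.default_rng(8)
    n = 100
    cols = {
        "alpha": rng.uniform(1.2, 1.8, n),
        "theta": rng.uniform(1.5, 2.5, n),
        "intercept": rng.normal(3.0, 0.05, n),
        "treatment[infected]": rng.normal(-0.1, 0.02, n),
    }
    fit = make_posterior(cols)
    times = np.array([3.0, 12.0, 30.0])
    curve = hazard_ratio(fit, INF, UNIF, times=times)
    # independent per-draw oracle via pdf/sf composition
    hr = np.empty((n, times.size))
    for i in range(n):
        s_inf = math.exp(cols["intercept"][i] + cols["treatment[infected]"][i])
        s_unif = math.exp(cols["intercept"][i])
        a, th = cols["alpha"][i], cols["theta"][i]
        h_inf = ew_pdf(times, alpha=a, theta=th, sigma=s_inf) / ew_sf(
            times, alpha=a, theta=th, sigma=s_inf
        )
        h_unif = ew_pdf(times, alpha=a, theta=th, sigma=s_unif) / ew_sf(
            times, alpha=a, theta=th, sigma=s_unif
        )
        hr[i] = h_inf / h_unif
    np.testing.assert_allclose(curve.median, np.median(hr, axis=0), rtol=1e-10)
    assert np.all(curve.lo > 0)


def test_mrl_summary_degenerate_matches_closed_form():
    fit = _degenerate(alpha=2.0, theta=1.5, b0=math.log(20.0), delta=0.0)
    out = mrl_summary(fit, UNIF, t0_list=[0.0, 10.0])
    for _, row in out.iterrows():
        expected = median_residual_lifetime(
            row["t0"], alpha=2.0, theta=1.5, sigma=20.0
        )
        assert row["median"] == pytest.approx(expected, rel=1e-12)
        assert row["lo"] == pytest.approx(row["hi"], rel=1e-12)


def test_mrl_summary_posterior(two_arm_fit):
    out = two_arm_fit.median_residual_lifetime(UNIF, t0_list=[0.0, 7.0, 14.0])
    assert (out["lo"] <= out["median"]).all() and (out["median"] <= out["hi"]).all()
    assert (out["median"] > 0).all()


def test_compare_populations_identical_and_permutation_invariant():
    rng = np.random.default_rng(3)
    n = 400
    cols = {
        "alpha": np.full(n, 1.5),
        "theta": np.full(n, 2.0),
        "intercept": rng.normal(3.0, 0.05, n),
        "treatment[infected]": rng.normal(-0.08, 0.01, n),
    }
    fit = make_posterior(cols)
    same = compare_populations(fit, fit, INF, UNIF)
    assert same.a.estimate == same.b.estimate
    assert same.a.ci == same.b.ci
    assert not same.separated
    # permuting draw order changes nothing
    perm = rng.permutation(n)
    fit_perm = make_posterior({k: np.asarray(v)[perm] for k, v in cols.items()})
    cmp2 = compare_populations(fit, fit_perm, INF, UNIF)
    assert cmp2.a.estimate == pytest.approx(cmp2.b.estimate, rel=1e-12)
    assert cmp2.a.ci == pytest.approx(cmp2.b.ci, rel=1e-12)


def test_compare_populations_separated_when_effects_differ():
    n = 300
    strong = _degenerate(delta=-0.06, n=n)
    rng = np.random.default_rng(11)
    weak = make_posterior(
        {
            "alpha": np.full(n, 1.5),
            "theta": np.full(n, 2.0),
            "intercept": np.full(n, 3.0),
            "treatment[infected]": rng.normal(-0.015, 0.002, n),
        }
    )
    out = compare_populations(strong, weak, INF, UNIF)
    assert out.b.estimate < out.a.estimate  # smaller change = stronger immunity
    assert out.separated


def test_sigma_draws_unknown_level_raises(two_arm_fit):
    with pytest.raises(ValueError, match="unknown level"):
        sigma_draws(two_arm_fit.draws_, {"treatment": "zapped"})
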