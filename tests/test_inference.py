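"""Standardization, SEXIT summaries, diagnostics, regression recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiocas import (
    CAS_PARAM_NAMES,
    RegressionSpec,
    diagnostics,
    fit_multivariate_regression,
    sexit_summary,
    simulate_cohort,
    standardize,
)
from cardiocas.inference import PosteriorDraws, _hdi, _sexit_row, destandardize


# ---------------------------------------------------------------- standardize

def test_subject_at_cohort_mean_standardizes_to_zero():
    # total B cells: cohort mean 9,752.43 /uL, SD 5,513.14 /uL; a column
    # symmetric about the mean leaves the middle subject exactly at it
    offsets = np.concatenate([-np.arange(1, 41), [0], np.arange(1, 41)])
    df = pd.DataFrame({"b_total": 9752.43 + 5513.14 * offsets / 40.0})
    out, meta = standardize(df)
    mid = int(np.flatnonzero(offsets == 0)[0])
    assert df["b_total"].iloc[mid] == pytest.approx(9752.43)
    assert out["b_total"].iloc[mid] == pytest.approx(0.0, abs=1e-8)
    assert meta["b_total"][0] == pytest.approx(9752.43)


def test_standardized_columns_have_unit_moments_and_round_trip():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.lognormal(1, 0.5, 200), "sex": rng.integers(0, 2, 200)})
    out, meta = standardize(df)
    assert out["x"].mean() == pytest.approx(0.0, abs=1e-8)
    assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
    assert np.array_equal(out["sex"], df["sex"])  # binary left as 0/1
    back = destandardize(out, meta)
    assert np.allclose(back["x"], df["x"], atol=1e-10)


def test_zero_sd_column_named_in_error():
    df = pd.DataFrame({"flatline": np.ones(50)})
    with pytest.raises(ValueError, match="flatline"):
        standardize(df)


# ---------------------------------------------------------------------- SEXIT

def test_pd_is_one_when_all_draws_positive():
    row = _sexit_row(np.abs(np.random.default_rng(0).standard_normal(5000)) + 0.01, 0.1)
    assert row["pd"] == 1.0


def test_standard_normal_draws_match_analytic_pd_and_ps():
    # oracle: pd -> 0.5 and ps -> 2*(1 - Phi(0.1)) = 0.9203 for N(0,1)
    rng = np.random.default_rng(42)
    x = rng.standard_normal(1_000_000)
    row = _sexit_row(x, 0.1)
    assert row["pd"] == pytest.approx(0.5, abs=0.002)
    assert row["ps"] == pytest.approx(2 * (1 - stats.norm.cdf(0.1)), abs=0.002)


def test_degenerate_point_mass_at_zero():
    row = _sexit_row(np.zeros(2000), 0.1)
    assert row["ps"] == 0.0
    assert row["pd"] == 0.5  # tie convention
    assert (row["hdi_low"], row["hdi_high"]) == (0.0, 0.0)


def test_sexit_mirror_symmetry():
    rng = np.random.default_rng(7)
    x = rng.gamma(2.0, 1.0, 20000) - 1.0
    a, b = _sexit_row(x, 0.1), _sexit_row(-x, 0.1)
    assert a["ps"] == b["ps"]
    assert a["pd"] == b["pd"]


def test_hdi_shorter_than_equal_tailed_and_inside_range():
    rng = np.random.default_rng(8)
    x = rng.lognormal(0.0, 0.7, 50000)
    lo, hi = _hdi(x)
    assert x.min() <= lo <= hi <= x.max()
    eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
    assert (hi - lo) <= (eq_hi - eq_lo) + 1e-12
    inside = np.mean((x >= lo) & (x <= hi))
    assert inside == pytest.approx(0.95, abs=0.001)


# ---------------------------------------------------------------- diagnostics

def _draws_obj(arrs):
    return PosteriorDraws(
        draws={"alpha": arrs},
        coef_names=list(arrs.keys()),
        responses=["alpha"],
        spec=RegressionSpec(responses=("alpha",)),
    )


def test_well_mixed_chains_pass_rhat(rng):
    arrs = {f"b{j}": rng.standard_normal((5, 2000)) for j in range(3)}
    report = diagnostics(_draws_obj(arrs))
    assert 0.99 <= report["max_rhat"] < 1.01
    assert not report["flagged"]


def test_offset_chains_flagged():
    rng = np.random.default_rng(2)
    bad = rng.standard_normal((2, 2000))
    bad[1] += 5.0  # two chains, means 5 SDs apart
    report = diagnostics(_draws_obj({"b": bad}), ess_threshold=0)
    assert report["max_rhat"] > 1.2
    assert "alpha:b" in report["flagged"]


def test_iid_draws_have_ess_near_n(rng):
    arrs = {"b": rng.standard_normal((4, 2500))}
    report = diagnostics(_draws_obj(arrs))
    assert report["min_ess"] == pytest.approx(10000, rel=0.2)


def test_single_chain_is_an_error(rng):
    with pytest.raises(ValueError, match="single chain"):
        diagnostics(_draws_obj({"b": rng.standard_normal((1, 2000))}))


# ----------------------------------------------------------------- regression

def _quick_spec(**kw):
    base = dict(chains=2, warmup=500, sampling=500, seed=0)
    base.update(kw)
    return RegressionSpec(**base)


def test_known_effect_recovered_from_cohort_parameters():
    """Single true standardized effect of 0.5 of total B cells on alpha;
    regression on the generator's own parameters recovers it."""
    eff = np.zeros((7, 10))
    eff[0, 1] = 0.5
    truth, _ = simulate_cohort(500, true_coefficients=eff, seed=3,
                               simulate_recordings=False)
    spec = _quick_spec(responses=("alpha",), seed=3)
    draws = fit_multivariate_regression(
        truth.parameter_table(), truth.immune_table, spec
    )
    sexit = sexit_summary(draws)
    row = sexit[(sexit.response == "alpha") & (sexit.coefficient == "b_total")].iloc[0]
    assert row["median"] == pytest.approx(0.5, abs=0.1)
    assert row["pd"] > 0.99


def test_bias_shrinks_with_sample_size():
    eff = np.zeros((7, 10))
    eff[0, 1] = 0.4
    errs = {}
    for n, tol in [(100, 0.3), (500, 0.13)]:
        truth, _ = simulate_cohort(n, true_coefficients=eff, seed=6,
                                   simulate_recordings=False)
        draws = fit_multivariate_regression(
            truth.parameter_table(), truth.immune_table,
            _quick_spec(responses=("alpha",), seed=6),
        )
        med = np.median(draws.pooled("alpha", "b_total"))
        errs[n] = abs(med - 0.4)
        assert errs[n] < tol


def test_null_calibration_pd_rarely_extreme():
    """With all true effects zero at the cohort's size (n = 81), pd
    exceeds 0.975 in at most ~10% of replicate analyses."""
    n_reps = 200
    extreme = 0
    total = 0
    base_seed = 900
    for rep in range(n_reps):
        truth, _ = simulate_cohort(81, seed=base_seed + rep,
                                   simulate_recordings=False)
        draws = fit_multivariate_regression(
            truth.parameter_table(), truth.immune_table,
            _quick_spec(responses=("alpha",), seed=base_seed + rep),
        )
        sexit = sexit_summary(draws)
        coefs = sexit[sexit.coefficient != "Intercept"]
        extreme += int((coefs["pd"] > 0.975).sum())
        total += len(coefs)
    assert extreme / total <= 0.10


def test_draw_count_matches_spec():
    truth, _ = simulate_cohort(60, seed=9, simulate_recordings=False)
    spec = _quick_spec(responses=("alpha",), chains=3, warmup=500, sampling=700)
    draws = fit_multivariate_regression(truth.parameter_table(), truth.immune_table, spec)
    assert draws.n_draws_per_parameter() == 3 * 700
    assert sexit_summary(draws).shape[0] == 7  # intercept + 6 predictors


def test_regression_spec_validation():
    with pytest.raises(ValueError):
        RegressionSpec(chains=1)
    with pytest.raises(ValueError):
        RegressionSpec(warmup=100)
    with pytest.raises(ValueError):
        RegressionSpec(prior_sd=0)
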