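"""Likelihood evaluation, fitting, pooling and profile CIs."""

import math

import numpy as np
import pytest

from morphsel.core_models import (
    DirectionalParams,
    FDParams,
    MigrationParams,
    allele_from_phenotype,
    iterate,
    phenotype_freq,
)
from morphsel.likelihood_fit import (
    FitSpec,
    SampleSeries,
    _ci_from_profile,
    background_equilibrium,
    fit,
    fit_combined,
    fit_fd_constrained,
    fit_pooled,
    neg2_loglik,
    predict_series,
    profile_ci,
)

from conftest import OCCASIONS, wf_series


def big_int_binom_neg2ll(k, n, P):
    """Independent exact oracle using Python big integers for the
    binomial coefficient."""
    return -2.0 * (math.log(math.comb(n, k)) + k * math.log(P)
                   + (n - k) * math.log(1 - P))


class TestSampleSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            SampleSeries("x", "white", (0, 1), (5,), (10, 10))
        with pytest.raises(ValueError):
            SampleSeries("x", "white", (1, 0), (5, 5), (10, 10))
        with pytest.raises(ValueError):
            SampleSeries("x", "white", (0, 1), (11, 5), (10, 10))

    def test_zero_total_occasions_are_usable_filtered(self):
        s = SampleSeries("x", "white", (0, 1, 2), (5, 0, 3), (10, 0, 10))
        u = s.usable()
        assert u.years == (0, 2)
        assert s.frequencies == (0.5, 0.3)


class TestPredictSeries:
    def test_neutral_constant(self):
        P = predict_series("DS", DirectionalParams(1.0), 0.3,
                           [1992, 1996, 2013])
        assert np.allclose(P, phenotype_freq(0.3))

    def test_full_replacement_one_step(self):
        P = predict_series("M", MigrationParams(1.0, 0.024), 0.3, [0, 1])
        assert P[0] == pytest.approx(phenotype_freq(0.3))
        assert P[1] == pytest.approx(0.047424, abs=1e-6)

    def test_fd_equilibrium_constant(self):
        p_star = allele_from_phenotype((1 - 1.03) / -0.42)
        P = predict_series("FD", FDParams(1.03, -0.42), p_star,
                           list(range(0, 22, 3)))
        assert np.allclose(P, P[0], atol=1e-9)


class TestNeg2Loglik:
    def test_matches_big_integer_oracle(self):
        s = SampleSeries("x", "white", (0,), (50,), (100,))
        got = neg2_loglik("DS", DirectionalParams(1.0),
                          allele_from_phenotype(0.5), s)
        assert got == pytest.approx(big_int_binom_neg2ll(50, 100, 0.5),
                                    rel=1e-12)

    def test_impossible_prediction_is_infinite(self):
        s = SampleSeries("x", "white", (0, 1), (3, 2), (10, 10))
        assert neg2_loglik("DS", DirectionalParams(0.9), 0.0, s) == math.inf

    def test_observed_frequencies_are_the_optimum(self):
        # with neutral dynamics the only free quantity is p0; the
        # likelihood peaks where predictions equal observed frequencies
        s = SampleSeries("x", "white", (0, 1), (30, 30), (100, 100))
        best = neg2_loglik("DS", DirectionalParams(1.0),
                           allele_from_phenotype(0.3), s)
        for p0 in (0.1, 0.2, 0.25, 0.4):
            assert neg2_loglik("DS", DirectionalParams(1.0), p0, s) > best


class TestFit:
    def test_noise_free_ds_recovery(self, declining_series):
        res = fit(declining_series, FitSpec(kind="DS"))
        assert res.converged
        assert res.estimates["w_colour"] == pytest.approx(0.9, abs=1e-3)
        assert res.estimates["p0"] == pytest.approx(0.3, abs=1e-3)
        assert res.k_params == 2

    def test_two_point_migration_closed_form(self):
        # one transition: m solves p1 = m*p_eq + (1-m)*p0 exactly, and
        # with huge counts the MLE must match the algebraic solution
        p_eq, p0_true, m_true = 0.01, 0.4, 0.15
        p1 = m_true * p_eq + (1 - m_true) * p0_true
        n = 10 ** 7
        s = SampleSeries("x", "white", (0, 1),
                         (round(phenotype_freq(p0_true) * n),
                          round(phenotype_freq(p1) * n)), (n, n))
        res = fit(s, FitSpec(kind="M", p_eq=p_eq))
        assert res.estimates["m"] == pytest.approx(m_true, abs=1e-3)

    def test_neutral_data_gives_near_zero_selection(self):
        traj_P = phenotype_freq(0.35)
        n = 10 ** 6
        s = SampleSeries("x", "white", OCCASIONS,
                         (round(traj_P * n),) * len(OCCASIONS),
                         (n,) * len(OCCASIONS))
        res = fit(s, FitSpec(kind="DS"))
        assert 1 - res.estimates["w_colour"] == pytest.approx(0.0, abs=1e-3)

    def test_fit_requires_two_usable_occasions(self):
        s = SampleSeries("x", "white", (0, 1), (5, 0), (10, 0))
        with pytest.raises(ValueError):
            fit(s, FitSpec(kind="DS"))


class TestProfileCI:
    def test_quadratic_profile_matches_wald(self):
        # Gaussian-like -2LL: ((x - mu)/se)^2 should give mu +/- 1.96 se
        mu, se = 0.9, 0.02
        lo, hi, flags = _ci_from_profile(
            lambda x: ((x - mu) / se) ** 2, mu, 0.0, 0.0, 2.0, level=0.95)
        assert lo == pytest.approx(mu - 1.959964 * se, rel=0.02)
        assert hi == pytest.approx(mu + 1.959964 * se, rel=0.02)
        assert not flags

    def test_level_zero_degenerate(self):
        lo, hi, _ = _ci_from_profile(lambda x: (x - 1) ** 2, 1.0, 0.0,
                                     0.0, 2.0, level=0.0)
        assert lo == hi == 1.0

    def test_endpoint_absent_at_parameter_bound(self):
        # flat profile never reaches the threshold: both ends absent
        lo, hi, _ = _ci_from_profile(lambda x: 0.0, 0.5, 0.0, 0.0, 1.0)
        assert lo is None and hi is None

    def test_ci_brackets_estimate_on_simulated_data(self, noisy_ds_series):
        spec = FitSpec(kind="DS")
        res = fit(noisy_ds_series, spec)
        lo, hi = profile_ci(noisy_ds_series, spec, res, "w_colour")
        assert lo < res.estimates["w_colour"] < hi
        assert "w_colour" in res.profile_cis


class TestCombinedAndPooled:
    def test_combined_two_identical_series_doubles(self, noisy_ds_series):
        spec = FitSpec(kind="DS")
        single = fit(noisy_ds_series, spec)
        twin = SampleSeries("copy", "white", noisy_ds_series.years,
                            noisy_ds_series.counts, noisy_ds_series.totals)
        both = fit_combined([noisy_ds_series, twin], spec)
        assert both.neg2LL == pytest.approx(2 * single.neg2LL, abs=1e-5)
        assert both.k_params == 2 * single.k_params

    def test_combined_single_series_is_fit(self, noisy_ds_series):
        spec = FitSpec(kind="DS")
        assert fit_combined([noisy_ds_series], spec).neg2LL == pytest.approx(
            fit(noisy_ds_series, spec).neg2LL)

    def test_parameter_bookkeeping(self):
        series = [wf_series("DS", DirectionalParams(0.9), seed=s).series
                  for s in (11, 12, 13, 14)]
        spec = FitSpec(kind="M", p_eq=0.024)
        combined = fit_combined(series, spec)
        assert combined.k_params == 8  # m + p0 per series
        ha = FitSpec(kind="HA")
        assert fit_pooled(series, ha, "pooled-I").k_params == 3
        assert fit_pooled(series, ha, "pooled-II").k_params == 2 + 4
        # df between combined and pooled-I for HA: 4*3 - 3 = 9

    def test_nesting_chain(self):
        series = [wf_series("DS", DirectionalParams(0.9), seed=s).series
                  for s in (21, 22, 23)]
        spec = FitSpec(kind="DS")
        combined = fit_combined(series, spec)
        p2 = fit_pooled(series, spec, "pooled-II")
        p1 = fit_pooled(series, spec, "pooled-I")
        assert combined.neg2LL <= p2.neg2LL + 1e-6
        assert p2.neg2LL <= p1.neg2LL + 1e-6

    def test_pooled_identical_copies_equal_combined(self, noisy_ds_series):
        spec = FitSpec(kind="DS")
        copies = [noisy_ds_series,
                  SampleSeries("c2", "white", noisy_ds_series.years,
                               noisy_ds_series.counts, noisy_ds_series.totals)]
        p1 = fit_pooled(copies, spec, "pooled-I")
        both = fit_combined(copies, spec)
        assert p1.neg2LL == pytest.approx(both.neg2LL, abs=1e-4)


class TestConstrainedFD:
    def test_constraint_identity(self):
        # data at equilibrium exactly P_bg: the constrained fit's
        # implied equilibrium is P_bg by construction
        P_bg = 0.0482
        res = fit_fd_constrained(
            SampleSeries("x", "white", OCCASIONS,
                         (round(P_bg * 10**5),) * 11, (10**5,) * 11), P_bg)
        a = res.estimates["a"]
        b = (1 - a) / P_bg
        assert (1 - a) / b == pytest.approx(P_bg)

    def test_constrained_never_beats_free_fit(self, noisy_ds_series):
        free = fit(noisy_ds_series, FitSpec(kind="FD"))
        constrained = fit_fd_constrained(noisy_ds_series, 0.0482)
        assert constrained.neg2LL >= free.neg2LL - 1e-6

    def test_decline_to_quarter_rejects_low_equilibrium(self):
        # a white-like decline levelling near 0.25 fits the constrained
        # model (equilibrium pinned at 4.8%) much worse
        out = wf_series("FD", FDParams(1.14, -0.70), seed=31)
        free = fit(out.series, FitSpec(kind="FD"))
        constrained = fit_fd_constrained(out.series, 0.0482)
        assert constrained.neg2LL - free.neg2LL > 3.841


class TestBackgroundEquilibrium:
    def test_single_constant_series(self):
        s = SampleSeries("x", "red", (0, 1), (2, 2), (200, 200))
        P, p = background_equilibrium([s])
        assert P == pytest.approx(0.01)
        assert p == pytest.approx(allele_from_phenotype(0.01))

    def test_mean_of_two_series(self):
        s1 = SampleSeries("x", "red", (0, 1), (2, 2), (100, 100))
        s2 = SampleSeries("y", "red", (0, 1), (4, 4), (100, 100))
        P, _ = background_equilibrium([s1, s2])
        assert P == pytest.approx(0.03)

    def test_phenotype_to_allele(self):
        s = SampleSeries("x", "red", (0,), (9975,), (10 ** 6,))
        P, p = background_equilibrium([s])
        assert p == pytest.approx(0.005, abs=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            background_equilibrium([])


def test_nested_models_never_fit_worse(noisy_ds_series):
    """Adding a free parameter cannot raise the minimised -2LL."""
    ds = fit(noisy_ds_series, FitSpec(kind="DS"))
    ha = fit(noisy_ds_series, FitSpec(kind="HA"))
    fd = fit(noisy_ds_series, FitSpec(kind="FD"))
    assert ha.neg2LL <= ds.neg2LL + 1e-6
    assert fd.neg2LL <= ds.neg2LL + 1e-6


def test_migration_recovery_at_design_scale():
    """Median migration-rate estimate across replicates simulated at
    m=0.07 stays within 0.015 of truth."""
    spec = FitSpec(kind="M", p_eq=0.005)
    ests = []
    for seed in range(40, 70):
        out = wf_series("M", MigrationParams(0.07, 0.005), seed=seed)
        ests.append(fit(out.series, spec).estimates["m"])
    assert abs(float(np.median(ests)) - 0.07) <= 0.015
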