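"""Multi-response estimation: objective, recovery, indeterminacy flags."""

import numpy as np
import pytest

from mrkinet import (RateConstants, RunConfig, Timecourse, ValidationError,
                     confidence_intervals, fit_network, objective)
from mrkinet.datamodel import ResponseSeries
from mrkinet.estimation import EstimationResult, default_weights, PARAM_NAMES
from mrkinet.synthetic import (NoiseSpec, default_initial_state,
                               generate_network_timecourse)

STUDY_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: structurally identifiable parameters of the 90 C truth set
IDENTIFIABLE = ("k3", "k5", "k6", "k9", "k10", "k11", "k13")


def result_at(estimates, data):
    """EstimationResult shell at given estimates (for CI-only tests)."""
    return EstimationResult(
        estimates=dict(estimates),
        half_widths={p: float("nan") for p in PARAM_NAMES},
        indeterminate={p: False for p in PARAM_NAMES},
        objective=objective(estimates, data),
        weights=default_weights(data),
        converged=True, n_multistarts=0, seed=0,
    )


class TestObjective:
    def test_zero_at_generating_constants(self, truth_90, noisefree_tc_90):
        assert objective(truth_90, noisefree_tc_90) < 1e-12

    def test_perturbing_active_pathway_increases(self, truth_90,
                                                 noisefree_tc_90):
        for p in ("k9", "k10", "k11", "k13", "k6"):
            for factor in (0.5, 2.0):
                kd = dict(truth_90)
                kd[p] = kd[p] * factor
                assert objective(kd, noisefree_tc_90) > 1e-6

    def test_linear_in_weights(self, truth_90, noisefree_tc_90):
        kd = dict(truth_90)
        kd["k9"] *= 1.3
        w = default_weights(noisefree_tc_90)
        base = objective(kd, noisefree_tc_90, w)
        doubled = objective(kd, noisefree_tc_90,
                            {r: 2 * v for r, v in w.items()})
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_response_order_invariance(self, truth_90, noisefree_tc_90):
        tc = noisefree_tc_90
        reordered = Timecourse(
            temperature=tc.temperature, times=tc.times,
            responses=dict(reversed(list(tc.responses.items()))))
        assert objective(truth_90, reordered) == pytest.approx(
            objective(truth_90, tc), rel=1e-12, abs=1e-18)

    def test_unknown_response_rejected(self, truth_90):
        tc = Timecourse(
            temperature=90.0, times=(0.0, 5.0, 10.0, 15.0),
            responses={"caffeine": ResponseSeries(
                "caffeine", (1.0, 1.0, 1.0, 1.0), "ug/g DS")})
        with pytest.raises(ValidationError):
            objective(truth_90, tc)


class TestFitNetwork:
    def test_noise_free_recovery(self, truth_90, noisefree_fit_90):
        """Identifiable rate constants recover within 10% from noise-free
        data; the structurally invisible steps are flagged, not trusted."""
        fit = noisefree_fit_90
        assert fit.converged
        assert fit.objective < 1e-8
        for p in IDENTIFIABLE:
            rel = abs(fit.estimates[p] - truth_90[p]) / truth_90[p]
            assert rel < 0.10, f"{p}: {rel:.3f}"
            assert not fit.indeterminate[p]
        # sucrose hydrolysis (rate nil) and the enediol->glucose back
        # reaction are not determinable from these data
        assert fit.indeterminate["k1"]
        assert fit.indeterminate["k4"]

    def test_flags_deterministic_given_seed(self, noisefree_tc_90,
                                            noisefree_fit_90):
        fit2 = fit_network(noisefree_tc_90, RunConfig(seed=1))
        assert fit2.indeterminate == noisefree_fit_90.indeterminate
        assert fit2.estimates == noisefree_fit_90.estimates

    def test_all_zero_truth(self):
        zeros = {p: 0.0 for p in PARAM_NAMES}
        tc = generate_network_timecourse(
            RateConstants.from_dict(zeros, 60.0), default_initial_state(),
            STUDY_TIMES, NoiseSpec())
        fit = fit_network(tc, RunConfig(seed=0, multistarts=2))
        assert fit.objective < 1e-10
        # every estimate collapses toward the zero bound or is flagged
        assert all(fit.estimates[p] < 1e-4 or fit.indeterminate[p]
                   for p in PARAM_NAMES)

    def test_noise_degrades_recovery(self, truth_90, noisefree_fit_90):
        """Median relative error over the well-identified constants grows
        when 5% measurement noise is added (scaled-down check: 6 starts)."""
        k = RateConstants.from_dict(truth_90, 90.0)
        noisy = generate_network_timecourse(
            k, default_initial_state(), STUDY_TIMES,
            NoiseSpec("multiplicative_gaussian", 0.05, 11))
        fit = fit_network(noisy, RunConfig(seed=3, multistarts=6))
        strong = ("k9", "k10", "k11", "k13")

        def med_err(f):
            return float(np.median([
                abs(f.estimates[p] - truth_90[p]) / truth_90[p]
                for p in strong]))

        assert med_err(noisefree_fit_90) < 1e-4
        assert med_err(fit) > med_err(noisefree_fit_90)
        assert med_err(fit) < 0.5  # still in the right range

    def test_too_few_points_rejected(self, truth_90):
        tc = generate_network_timecourse(
            RateConstants.from_dict(truth_90, 90.0),
            default_initial_state(), (0.0, 10.0, 30.0), NoiseSpec())
        with pytest.raises(ValidationError):
            fit_network(tc)

    def test_needs_t0_anchor(self, truth_90):
        tc = generate_network_timecourse(
            RateConstants.from_dict(truth_90, 90.0),
            default_initial_state(), (0.0, 5.0, 10.0, 15.0, 20.0),
            NoiseSpec())
        shifted = Timecourse(temperature=90.0,
                             times=tuple(t + 1 for t in tc.times),
                             responses=tc.responses)
        with pytest.raises(ValidationError):
            fit_network(shifted)


class TestConfidenceIntervals:
    def test_k4_truly_zero_flagged(self, truth_90, noisefree_tc_90):
        """With the enediol unobserved and k4 = 0, the back reaction to
        glucose has no detectable signature and must be flagged."""
        kd = dict(truth_90)
        kd["k4"] = 0.0
        tc = generate_network_timecourse(
            RateConstants.from_dict(kd, 90.0), default_initial_state(),
            STUDY_TIMES, NoiseSpec())
        res = confidence_intervals(result_at(kd, tc), tc)
        assert res.indeterminate["k4"]
        assert not res.indeterminate["k9"]

    def test_identifiable_half_widths_vanish_noise_free(self, truth_90,
                                                        noisefree_tc_90):
        res = confidence_intervals(result_at(truth_90, noisefree_tc_90),
                                   noisefree_tc_90)
        for p in IDENTIFIABLE:
            assert res.half_widths[p] < 1e-3 * truth_90[p]

    def test_bootstrap_agrees_with_linearized(self, truth_90):
        """Bootstrap and linearized intervals agree to within a small
        factor on the well-identified constants (40 resamples; row
        resampling over 7 time points under-disperses slightly)."""
        k = RateConstants.from_dict(truth_90, 90.0)
        tc = generate_network_timecourse(
            k, default_initial_state(), STUDY_TIMES,
            NoiseSpec("multiplicative_gaussian", 0.05, 100))
        cfg = RunConfig(seed=0, multistarts=8)
        fit = fit_network(tc, cfg)
        boot = confidence_intervals(fit, tc, method="bootstrap",
                                    config=cfg, n_boot=40)
        for p in ("k9", "k10", "k13"):
            ratio = fit.half_widths[p] / boot.half_widths[p]
            assert 1 / 3 < ratio < 3, f"{p}: {ratio:.2f}"

    def test_unknown_method_rejected(self, truth_90, noisefree_tc_90):
        with pytest.raises(ValidationError):
            confidence_intervals(result_at(truth_90, noisefree_tc_90),
                                 noisefree_tc_90, method="waldo")
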